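"""Yearly utilisation, switcher classification, channels and pharmacies."""

import pandas as pd
import pytest

from rxadhere import published
from rxadhere.trends import (
    channel_rates,
    classify_switchers,
    pharmacy_distribution,
    yearly_table,
    yearly_totals,
)


def _row(pid, date, substance, rx_format="electronic", rx_mode="inn",
         pharmacy="PH1"):
    return {
        "patient_id": pid, "dispense_date": pd.Timestamp(date),
        "prescribed_substance": substance, "rx_format": rx_format,
        "rx_mode": rx_mode, "pharmacy_id": pharmacy,
    }


def test_yearly_table_shares_sum_to_100():
    rec = pd.DataFrame(
        [
            _row("P1", "2019-01-01", "rivaroxaban"),
            _row("P1", "2019-02-01", "rivaroxaban"),
            _row("P2", "2019-03-01", "warfarin"),
            _row("P2", "2020-03-01", "warfarin"),
        ]
    )
    table = yearly_table(rec)
    assert table.groupby("year")["share_pct"].sum().round(6).eq(100.0).all()
    row = table[(table.year == 2019) & (table.substance == "rivaroxaban")]
    assert row["n"].item() == 2
    assert row["share_pct"].item() == pytest.approx(200 / 3)
    assert yearly_totals(table).to_dict() == {2019: 3, 2020: 1}


def test_single_substance_year_share_is_100():
    rec = pd.DataFrame([_row("P1", "2018-05-05", "warfarin")])
    assert yearly_table(rec)["share_pct"].item() == 100.0


def test_yearly_counts_match_generator_tally(cohort_small):
    records, _ = cohort_small
    table = yearly_table(records)
    assert int(table["n"].sum()) == len(records)
    direct = records.groupby(
        [pd.to_datetime(records.dispense_date).dt.year, "prescribed_substance"]
    ).size()
    for (_, row) in table.iterrows():
        assert direct.loc[(row.year, row.substance)] == row.n


def test_published_yearly_fixture_shares():
    table = published.yearly_table()
    y2022 = table[table.year == 2022]
    riva = y2022.loc[y2022.substance == "rivaroxaban", "n"].item()
    assert round(100.0 * riva / y2022["n"].sum(), 1) == 45.3
    assert int(table["n"].sum()) == 1_646_648
    assert yearly_totals(table).loc[2022] == 308_994


@pytest.mark.parametrize(
    "history, distinct, is_switcher, warf_to_doac, among_doacs",
    [
        ([("2017-01-01", "warfarin"), ("2019-01-01", "rivaroxaban")],
         2, True, True, False),
        ([("2019-%02d-01" % m, "rivaroxaban") for m in range(1, 6)],
         1, False, False, False),
        ([("2017-01-01", "warfarin"), ("2018-06-01", "dabigatran"),
          ("2020-01-01", "rivaroxaban")], 3, True, True, True),
        ([("2019-01-01", "rivaroxaban"), ("2020-01-01", "warfarin")],
         2, True, False, False),
    ],
)
def test_classify_switchers_cases(history, distinct, is_switcher,
                                  warf_to_doac, among_doacs):
    rec = pd.DataFrame([_row("P1", d, s) for d, s in history])
    per_patient, summary = classify_switchers(rec)
    p = per_patient.iloc[0]
    assert p.distinct_anticoagulants == distinct
    assert p.is_switcher == is_switcher
    assert p.warfarin_to_doac == warf_to_doac
    assert p.among_doacs == among_doacs
    assert summary["n_switchers"] == int(is_switcher)


def test_switcher_share_recovers_config(cohort5000):
    records, truth = cohort5000
    _, summary = classify_switchers(records)
    p = truth.config.switch_probability
    n = summary["n_patients"]
    se = (p * (1 - p) / n) ** 0.5
    assert abs(summary["switcher_pct"] / 100.0 - p) <= 3 * se


def test_channel_rates_toy():
    rec = pd.DataFrame(
        [
            _row("P1", "2018-01-01", "warfarin", rx_format="paper", rx_mode="brand"),
            _row("P1", "2018-02-01", "warfarin", rx_format="electronic"),
            _row("P2", "2018-03-01", "warfarin", rx_format="electronic"),
            _row("P2", "2018-04-01", "warfarin", rx_format="electronic"),
        ]
    )
    rates = channel_rates(rec).set_index("year")
    assert rates.loc[2018, "paper_pct"] == pytest.approx(25.0)
    assert rates.loc[2018, "electronic_pct"] == pytest.approx(75.0)
    assert rates.loc[2018, "inn_pct"] == pytest.approx(75.0)


def test_channel_rates_all_electronic():
    rec = pd.DataFrame([_row("P1", "2022-01-01", "rivaroxaban")])
    rates = channel_rates(rec)
    assert rates["paper_pct"].item() == 0.0
    assert rates["paper_pct"].item() + rates["electronic_pct"].item() == 100.0


def test_channel_adoption_recovery(cohort5000):
    records, truth = cohort5000
    rates = channel_rates(records).set_index("year")
    for year in (2017, 2018, 2020, 2022):
        p = truth.config.electronic_adoption[year]
        n = rates.loc[year, "n"]
        se = (p * (1 - p) / n) ** 0.5
        assert abs(rates.loc[year, "electronic_pct"] / 100.0 - p) <= 3 * se
        q = truth.config.inn_adoption[year]
        se_q = (q * (1 - q) / n) ** 0.5
        assert abs(rates.loc[year, "inn_pct"] / 100.0 - q) <= 3 * se_q


def test_pharmacy_distribution_toy():
    rows = []
    rows += [_row("P1", "2019-01-01", "warfarin", pharmacy="A")] * 3
    rows += [_row("P2", "2019-01-01", "warfarin", pharmacy=p) for p in "AB"]
    rows += [_row("P3", "2019-01-01", "warfarin", pharmacy=p) for p in "ABCDE"]
    dist = pharmacy_distribution(pd.DataFrame(rows))
    assert dist.set_index("n_pharmacies")["n_patients"].to_dict() == {1: 1, 2: 1, 5: 1}
    le2 = dist.loc[dist.n_pharmacies <= 2, "share_pct"].sum()
    assert le2 == pytest.approx(200 / 3)
    assert dist["cumulative_pct"].is_monotonic_increasing
    assert dist["cumulative_pct"].iloc[-1] == pytest.approx(100.0)


def test_pharmacy_distribution_matches_generator_ledger(cohort5000):
    records, truth = cohort5000
    dist = pharmacy_distribution(records)
    ledger = truth.patients["n_pharmacies"].value_counts().sort_index()
    measured = dist.set_index("n_pharmacies")["n_patients"]
    assert measured.to_dict() == {int(k): int(v) for k, v in ledger.items()}
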