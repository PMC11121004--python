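"""Drug-utilisation trends: yearly tables, switchers, channels, pharmacies."""

from __future__ import annotations

import pandas as pd

from .records import ANTICOAGULANT_SUBSTANCES, DOAC_SUBSTANCES


def yearly_table(records: pd.DataFrame) -> pd.DataFrame:
    """Yearly prescription counts and within-year shares per substance.

    The year is taken from the dispensing date (the claims row unit is a
    dispensed prescription). Returns columns ``year, substance, n,
    share_pct`` with one row per (year, substance) observed.
    """
    df = records.copy()
    df["year"] = pd.to_datetime(df["dispense_date"]).dt.year
    counts = (
        df.groupby(["year", "prescribed_substance"], sort=True)
        .size()
        .rename("n")
        .reset_index()
        .rename(columns={"prescribed_substance": "substance"})
    )
    totals = counts.groupby("year")["n"].transform("sum")
    counts["share_pct"] = 100.0 * counts["n"] / totals
    return counts


def yearly_totals(table: pd.DataFrame) -> pd.Series:
    """Per-year totals of a :func:`yearly_table` frame."""
    return table.groupby("year")["n"].sum()


def classify_switchers(
    records: pd.DataFrame,
    anticoagulants: frozenset[str] | set[str] = ANTICOAGULANT_SUBSTANCES,
    doacs: frozenset[str] | set[str] = DOAC_SUBSTANCES,
) -> tuple[pd.DataFrame, dict]:
    """Per-patient switcher profiles over the full prescribing history.

    A switcher has two or more distinct anticoagulant molecules
    *prescribed* across the study period (prescribing defines the therapy
    change; a one-off dispensing substitution does not). Categories, both
    of which may hold for one patient:

    - ``warfarin_to_doac``: a DOAC prescription strictly after the
      patient's first warfarin prescription;
    - ``among_doacs``: two or more distinct DOAC molecules.

    Returns (per-patient frame, summary dict). Patients with no
    anticoagulant prescriptions are not profiled.
    """
    df = records[records["prescribed_substance"].isin(anticoagulants)].copy()
    df = df.sort_values(["patient_id", "dispense_date"], kind="stable")
    profiles = []
    for pid, grp in df.groupby("patient_id", sort=True):
        subs = list(grp["prescribed_substance"])
        dates = list(pd.to_datetime(grp["dispense_date"]))
        distinct = sorted(set(subs))
        categories = set()
        if "warfarin" in distinct:
            first_warf = next(d for d, s in zip(dates, subs) if s == "warfarin")
            if any(s in doacs and d > first_warf for d, s in zip(dates, subs)):
                categories.add("warfarin_to_doac")
        if len(set(s for s in subs if s in doacs)) >= 2:
            categories.add("among_doacs")
        profiles.append(
            {
                "patient_id": pid,
                "distinct_anticoagulants": len(distinct),
                "is_switcher": len(distinct) >= 2,
                "warfarin_to_doac": "warfarin_to_doac" in categories,
                "among_doacs": "among_doacs" in categories,
            }
        )
    per_patient = pd.DataFrame(profiles)
    n = len(per_patient)
    n_sw = int(per_patient["is_switcher"].sum()) if n else 0
    dist = (
        per_patient.loc[per_patient["is_switcher"], "distinct_anticoagulants"]
        .value_counts()
        .sort_index()
        .to_dict()
        if n
        else {}
    )
    summary = {
        "n_patients": n,
        "n_switchers": n_sw,
        "switcher_pct": 100.0 * n_sw / n if n else None,
        "distinct_count_distribution": {int(k): int(v) for k, v in dist.items()},
        "distinct_count_share_of_switchers_pct": {
            int(k): 100.0 * int(v) / n_sw for k, v in dist.items()
        }
        if n_sw
        else {},
    }
    return per_patient, summary


def channel_rates(records: pd.DataFrame) -> pd.DataFrame:
    """Per-year paper/electronic and INN prescription shares (percent).

    ``paper_pct + electronic_pct == 100`` within each year.
    """
    df = records.copy()
    df["year"] = pd.to_datetime(df["dispense_date"]).dt.year
    out = []
    for year, grp in df.groupby("year", sort=True):
        n = len(grp)
        n_paper = int((grp["rx_format"] == "paper").sum())
        n_inn = int((grp["rx_mode"] == "inn").sum())
        out.append(
            {
                "year": int(year),
                "n": n,
                "paper_pct": 100.0 * n_paper / n,
                "electronic_pct": 100.0 * (n - n_paper) / n,
                "inn_pct": 100.0 * n_inn / n,
            }
        )
    return pd.DataFrame(out)


def pharmacy_distribution(records: pd.DataFrame) -> pd.DataFrame:
    """Distribution of distinct pharmacies visited per patient.

    Returns one row per distinct-pharmacy count ``k`` with the number of
    patients at exactly ``k``, the exclusive share, and the cumulative
    (``<= k``) share — the cumulative column is what "visited one or two
    pharmacies" refers to.
    """
    per_patient = records.groupby("patient_id")["pharmacy_id"].nunique()
    counts = per_patient.value_counts().sort_index()
    n = int(counts.sum())
    out = pd.DataFrame(
        {
            "n_pharmacies": counts.index.astype(int),
            "n_patients": counts.to_numpy(),
        }
    )
    out["share_pct"] = 100.0 * out["n_patients"] / n
    out["cumulative_pct"] = out["share_pct"].cumsum()
    return out.reset_index(drop=True)
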