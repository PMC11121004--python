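"""End-to-end orchestration: ingest -> filter -> adherence -> errors -> trends -> stats.

The pipeline is a pure function of (input records, configuration):
identical reruns produce identical outputs. Each stage logs one
structured line with its input/output row counts; the medication-error
and exclusion tallies are first-class fields of the summary because they
are the headline quantities of this kind of claims analysis.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import errors as errors_mod
from . import published, trends
from .pdc import compute_adherence, adherence_summary
from .records import (
    DEFAULT_DIAGNOSIS_CODES,
    DEFAULT_REGIMENS,
    DEFAULT_REIMBURSEMENT_LIST,
    DEFAULT_STUDY_WINDOW,
    filter_cohort,
    flag_off_list,
    read_prescriptions,
)
from .stats import chi_square_gof, welch_anova

log = logging.getLogger("rxadhere")


@dataclass
class RunConfig:
    """Pipeline configuration with the study defaults baked in."""

    diagnosis_codes: frozenset = DEFAULT_DIAGNOSIS_CODES
    window: tuple[date, date] = DEFAULT_STUDY_WINDOW
    cap_days: int = 90
    carryover: bool = True
    denominator_mode: str = "standard"
    adherence_thresholds: tuple[float, float] = (80.0, 90.0)
    gof_expected: str = "group_sizes"
    schema: Mapping | None = None
    strict: bool = False

    def validate(self) -> None:
        lo, hi = self.adherence_thresholds
        if not (0.0 < lo < hi < 100.0):
            raise ValueError(
                "adherence thresholds must be strictly increasing within (0, 100)"
            )
        if self.denominator_mode not in ("standard", "drop_last"):
            raise ValueError(f"unknown denominator_mode: {self.denominator_mode!r}")


def _stats_block(records: pd.DataFrame, adherence: pd.DataFrame, cfg: RunConfig) -> dict:
    """Welch ANOVA (age across adherence groups) and chi-square GOF blocks.

    Expected counts for the goodness-of-fit tests are proportional to the
    adherence-group sizes ("no deviation from a random distribution among
    the groups"), per ``cfg.gof_expected``.
    """
    overall = adherence[(adherence["scope"] == "overall_doac") & (~adherence["excluded"])]
    if not len(overall):
        return {"note": "no scored patients"}
    per_patient = (
        records.sort_values("dispense_date")
        .groupby("patient_id")
        .agg(age=("age", "last"), gender=("gender", "last"))
    )
    switch_pp, _ = trends.classify_switchers(records)
    merged = overall.merge(per_patient, on="patient_id", how="left").merge(
        switch_pp[["patient_id", "is_switcher"]], on="patient_id", how="left"
    )
    merged["is_switcher"] = merged["is_switcher"].fillna(False)

    out: dict = {}
    groups = {g: grp["age"].to_numpy() for g, grp in merged.groupby("group")}
    try:
        out["age_welch_anova"] = welch_anova(groups).as_dict()
    except ValueError as exc:
        out["age_welch_anova"] = {"error": str(exc)}

    sizes = merged.groupby("group").size()
    if cfg.gof_expected != "group_sizes":
        raise ValueError(f"unknown gof_expected: {cfg.gof_expected!r}")
    for label, flagcol in (("gender_female", merged["gender"] == "F"),
                           ("switcher", merged["is_switcher"].astype(bool))):
        obs = flagcol.groupby(merged["group"]).sum().reindex(sizes.index)
        try:
            out[f"{label}_gof"] = chi_square_gof(
                obs.to_numpy(float), sizes.to_numpy(float)
            ).as_dict()
        except ValueError as exc:
            out[f"{label}_gof"] = {"error": str(exc)}
    return out


def run_pipeline(
    records: pd.DataFrame | str | Path,
    config: RunConfig | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """Run every stage over a claims frame (or file path); return the summary.

    When ``outdir`` is given, per-stage tables are written there
    (adherence.tsv, crosstab.tsv, yearly.tsv, channel.tsv, pharmacies.tsv,
    rejections.tsv) together with ``summary.json``.
    """
    cfg = config or RunConfig()
    cfg.validate()
    if isinstance(records, (str, Path)):
        records, rejections = read_prescriptions(
            records, schema_config=cfg.schema, strict=cfg.strict
        )
    else:
        rejections = pd.DataFrame(columns=["row", "reason"])
    n_in = len(records)
    log.info("ingest: %d records, %d rejected", n_in, len(rejections))

    cohort, removed = filter_cohort(records, cfg.diagnosis_codes, cfg.window)
    log.info("filter: kept %d removed %s", len(cohort), removed)

    off_flags, off_rate = flag_off_list(cohort, DEFAULT_REIMBURSEMENT_LIST)
    adherence = compute_adherence(
        cohort,
        DEFAULT_REGIMENS,
        cfg.cap_days,
        cfg.carryover,
        cfg.denominator_mode,
        cfg.adherence_thresholds,
    )
    adh_summary = adherence_summary(adherence)
    log.info(
        "adherence: %d scored, %d excluded",
        adh_summary["n_scored"], adh_summary["n_excluded"],
    )

    xtab = errors_mod.crosstab(cohort)
    log.info("errors: %d mismatches of %d (%d patients)",
             xtab.n_mismatch, xtab.n_total, xtab.n_patients_affected)

    yearly = trends.yearly_table(cohort)
    switch_pp, switch_summary = trends.classify_switchers(cohort)
    channels = trends.channel_rates(cohort)
    pharmacies = trends.pharmacy_distribution(cohort)
    stats_block = _stats_block(cohort, adherence, cfg)

    summary = {
        "config": {
            "diagnosis_codes": sorted(cfg.diagnosis_codes),
            "window": [cfg.window[0].isoformat(), cfg.window[1].isoformat()],
            "cap_days": cfg.cap_days,
            "carryover": cfg.carryover,
            "denominator_mode": cfg.denominator_mode,
            "adherence_thresholds": list(cfg.adherence_thresholds),
            "gof_expected": cfg.gof_expected,
        },
        "ingest": {
            "n_records": n_in,
            "n_rejected": int(len(rejections)),
            "n_kept": int(len(cohort)),
            "removed": removed,
        },
        "off_list": {
            "n_flagged": int(off_flags.sum()) if len(off_flags) else 0,
            "rate_pct": 100.0 * off_rate,
        },
        "adherence": adh_summary,
        "dispensing_errors": xtab.summary(),
        "utilization": {
            "yearly_totals": {
                int(y): int(n) for y, n in trends.yearly_totals(yearly).items()
            },
            "switchers": switch_summary,
            "pharmacy_cumulative_pct": {
                int(k): float(v)
                for k, v in zip(pharmacies["n_pharmacies"], pharmacies["cumulative_pct"])
            },
        },
        "stats": stats_block,
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        adherence.to_csv(outdir / "adherence.tsv", sep="\t", index=False)
        if len(xtab.table):
            xtab.table.to_csv(outdir / "crosstab.tsv", sep="\t")
        yearly.to_csv(outdir / "yearly.tsv", sep="\t", index=False)
        channels.to_csv(outdir / "channel.tsv", sep="\t", index=False)
        pharmacies.to_csv(outdir / "pharmacies.tsv", sep="\t", index=False)
        rejections.to_csv(outdir / "rejections.tsv", sep="\t", index=False)
        switch_pp.to_csv(outdir / "switchers.tsv", sep="\t", index=False)
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


def reproduce_published(targets: list[str] | None = None) -> dict:
    """Recompute the published headline quantities from the packaged tables.

    Each entry reports the recomputed value, the printed reference and a
    pass flag (agreement at the printed precision). ``targets`` restricts
    the evaluation to a subset of the keys in
    :data:`rxadhere.published.REPORTED`.
    """
    yearly = published.yearly_table()
    y2022 = yearly[yearly["year"] == 2022]
    riva_share = round(
        100.0 * float(y2022.loc[y2022["substance"] == "rivaroxaban", "n"].sum())
        / float(y2022["n"].sum()),
        1,
    )
    grp = published.ADHERENCE_GROUPS
    above80 = round(
        100.0
        * float(grp.loc[grp["group"] != "below_80", "n"].sum())
        / float(grp["n"].sum()),
        1,
    )
    two_share = round(
        100.0 * published.SWITCHER_DISTINCT_COUNTS[2] / published.SWITCHERS_TOTAL, 1
    )
    computed = {
        "doac_mismatch_rate_pct": errors_mod.published_error_rate("cohort"),
        "doac_mismatch_count": errors_mod.published_offdiagonal_count(),
        "rivaroxaban_share_2022_pct": riva_share,
        "total_prescriptions_2012_2022": int(yearly["n"].sum()),
        "adherence_above_80_share_pct": above80,
        "switchers_two_agents_share_pct": two_share,
    }
    keys = targets or list(published.REPORTED)
    unknown = [k for k in keys if k not in published.REPORTED]
    if unknown:
        raise KeyError(f"unknown target(s): {unknown}")
    report = {}
    for k in keys:
        value, expected = computed[k], published.REPORTED[k]
        report[k] = {
            "value": value,
            "reported": expected,
            "pass": bool(np.isclose(value, expected, rtol=0, atol=1e-9)),
        }
    return report
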