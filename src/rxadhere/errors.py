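"""Prescribed-versus-dispensed conformity: cross-tabulation and error rates.

A dispensing (medication) error is any row whose dispensed
(substance, strength) key differs from the prescribed key. Brand names
never enter the key: INN-mode and brand-mode prescriptions are compared
identically on substance + strength. Errors are additionally labelled by
direction — the pharmacy handing out a higher or lower strength of the
same substance, or a different substance altogether.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import published
from .records import DOAC_SUBSTANCES

DIRECTION_HIGHER = "dispensed_higher"
DIRECTION_LOWER = "dispensed_lower"
DIRECTION_OTHER = "other_substance"


@dataclass
class CrossTabResult:
    """Prescribed-by-dispensed count matrix plus mismatch summary."""

    table: pd.DataFrame
    n_total: int
    n_mismatch: int
    n_patients_affected: int
    direction_counts: dict[str, int]

    @property
    def rate(self) -> float:
        return self.n_mismatch / self.n_total if self.n_total else 0.0

    @property
    def rate_pct(self) -> float:
        return 100.0 * self.rate

    def summary(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_mismatch": self.n_mismatch,
            "rate_pct": self.rate_pct,
            "n_patients_affected": self.n_patients_affected,
            "direction_counts": dict(self.direction_counts),
        }


def mismatch_flags(records: pd.DataFrame) -> pd.Series:
    """Boolean series: dispensed key differs from prescribed key."""
    return (records["prescribed_substance"] != records["dispensed_substance"]) | (
        records["prescribed_strength"] != records["dispensed_strength"]
    )


def crosstab(
    records: pd.DataFrame, substances: frozenset[str] | set[str] = DOAC_SUBSTANCES
) -> CrossTabResult:
    """Build the conformity cross-tab over rows prescribed within ``substances``.

    Rows whose prescribed substance falls outside the configured set are
    not classified (the published table is restricted to the DOACs).
    Prescribed keys that were never dispensed anywhere simply do not
    appear as rows.
    """
    sub = records[records["prescribed_substance"].isin(substances)]
    if not len(sub):
        return CrossTabResult(pd.DataFrame(), 0, 0, 0,
                              {DIRECTION_HIGHER: 0, DIRECTION_LOWER: 0,
                               DIRECTION_OTHER: 0})
    table = pd.crosstab(
        [sub["prescribed_substance"], sub["prescribed_strength"]],
        [sub["dispensed_substance"], sub["dispensed_strength"]],
    )
    table.index.names = ["prescribed_substance", "prescribed_strength"]
    table.columns.names = ["dispensed_substance", "dispensed_strength"]

    mm = mismatch_flags(sub)
    same_sub = sub["prescribed_substance"] == sub["dispensed_substance"]
    directions = {
        DIRECTION_HIGHER: int(
            (mm & same_sub & (sub["dispensed_strength"] > sub["prescribed_strength"])).sum()
        ),
        DIRECTION_LOWER: int(
            (mm & same_sub & (sub["dispensed_strength"] < sub["prescribed_strength"])).sum()
        ),
        DIRECTION_OTHER: int((mm & ~same_sub).sum()),
    }
    return CrossTabResult(
        table=table,
        n_total=int(len(sub)),
        n_mismatch=int(mm.sum()),
        n_patients_affected=int(sub.loc[mm, "patient_id"].nunique()),
        direction_counts=directions,
    )


def offdiagonal_count(table: pd.DataFrame) -> int:
    """Sum of cells whose prescribed key differs from the dispensed key."""
    total = 0
    for rx_key, row in table.iterrows():
        for disp_key, n in row.items():
            if tuple(rx_key) != tuple(disp_key):
                total += int(n)
    return int(total)


def published_offdiagonal_count() -> int:
    """Off-diagonal prescription count of the published DOAC conformity table."""
    return offdiagonal_count(published.doac_crosstab())


def published_error_rate(denominator: str = "cohort") -> float:
    """Headline dispensing-error rate (%) from the published conformity table.

    ``denominator="cohort"`` divides by the stated DOAC sub-cohort size;
    ``denominator="cells"`` divides by the table's own cell sum (the two
    differ slightly in the published data). Rounded to one decimal, as
    printed.
    """
    off = published_offdiagonal_count()
    if denominator == "cohort":
        total = published.DOAC_COHORT_PRESCRIPTIONS
    elif denominator == "cells":
        total = int(published.doac_crosstab().to_numpy().sum())
    else:
        raise ValueError(f"unknown denominator: {denominator!r}")
    return round(100.0 * off / total, 1)
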