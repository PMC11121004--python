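"""Modified proportion-of-days-covered (PDC) adherence with refill carryover.

The metric
----------
For a patient with dispensing dates :math:`t_1 < \\dots < t_k` of one
agent, the observation window is the half-open interval
:math:`[t_1, t_k)` and

.. math:: \\mathrm{PDC} = 100 \\times
          \\frac{\\#\\{\\text{days in } [t_1, t_k) \\text{ with supply on hand}\\}}
                {t_k - t_1}.

Early refills are carried over ("stockpiling"): leftover tablets from the
previous fill are added to the new supply, so an early refill pushes the
exhaustion date out rather than wasting the overlap. The final fill opens
no covered days, because coverage is truncated at the window end — this
is the "omit the last prescription" rule that keeps the metric from
rewarding a large terminal fill that was never observed in use.

Overall-DOAC adherence pools all direct-oral-anticoagulant fills of a
patient on one timeline: each agent keeps its own stock ledger, and a day
counts as covered when *any* agent's stock covers it, so a switch day is
never double-counted.

Patients need at least two fills (after same-day merging) on distinct
dates; otherwise the patient is excluded rather than scored.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .records import DEFAULT_REGIMENS, DrugRegimen

#: Maximum days of supply from a single prescription (3-month course limit).
DEFAULT_CAP_DAYS = 90

GROUP_BELOW_80 = "below_80"
GROUP_80_TO_90 = "from_80_to_90"
GROUP_ABOVE_90 = "above_90"

REASON_TOO_FEW = "fewer than two prescriptions"
REASON_ZERO_WINDOW = "zero-length observation window"


class InsufficientFills(ValueError):
    """Patient cannot be scored (fewer than two fills, or a degenerate window)."""


def days_supply(quantity: int, regimen: DrugRegimen, cap: int = DEFAULT_CAP_DAYS) -> int:
    """Convert a dispensed quantity of dose units into whole days of supply.

    ``floor(quantity / doses_per_day)``, truncated at the single-fill cap.
    A quantity below one day's doses is an error, not a zero-day fill.
    """
    if quantity <= 0:
        raise ValueError("quantity must be positive")
    days = int(quantity) // regimen.doses_per_day
    if days < 1:
        raise ValueError(
            f"sub-day supply: {quantity} units of {regimen.substance} "
            f"at {regimen.doses_per_day}/day"
        )
    return min(days, cap)


def _as_day_offsets(fills: Sequence[tuple]) -> tuple[np.ndarray, np.ndarray, object]:
    """Normalise fills to sorted integer day offsets; returns (days, supplies, origin)."""
    if not len(fills):
        return np.array([], dtype=int), np.array([], dtype=int), None
    dates = [f[0] for f in fills]
    supplies = np.asarray([int(f[1]) for f in fills])
    if isinstance(dates[0], (int, np.integer)):
        origin = min(dates)
        days = np.asarray([int(d) - origin for d in dates])
    else:
        ts = pd.to_datetime(pd.Series(list(dates)))
        origin = ts.min()
        days = (ts - origin).dt.days.to_numpy()
    order = np.argsort(days, kind="stable")
    return days[order], supplies[order], origin


def merge_same_day(days: np.ndarray, supplies: np.ndarray, cap: int) -> tuple[np.ndarray, np.ndarray]:
    """Merge same-day fills of one agent by summing supply, then re-capping."""
    if not len(days):
        return days, supplies
    out_d, out_s = [], []
    for d, s in zip(days, supplies):
        if out_d and out_d[-1] == d:
            out_s[-1] = min(out_s[-1] + s, cap)
        else:
            out_d.append(int(d))
            out_s.append(int(s))
    return np.asarray(out_d), np.asarray(out_s)


def _stream_segments(
    days: np.ndarray, supplies: np.ndarray, carryover: bool
) -> list[tuple[int, int]]:
    """Coverage segments (start, end) in day offsets for one agent's fills.

    With carryover, leftover stock at a refill is added on top of the new
    supply (covered-until advances by the full supply from whichever is
    later: the fill date or the current exhaustion date). Without it each
    fill covers only its own interval and overlap is wasted.
    """
    segments: list[tuple[int, int]] = []
    covered_until = -np.inf
    for d, s in zip(days, supplies):
        if carryover:
            start = int(max(d, covered_until))
            end = start + int(s)
            covered_until = end
        else:
            start, end = int(d), int(d) + int(s)
        segments.append((start, end))
    return segments


def _union_length(segments: Iterable[tuple[int, int]], lo: int, hi: int) -> int:
    """Total integer-day length of the union of segments clipped to [lo, hi)."""
    clipped = sorted(
        (max(a, lo), min(b, hi)) for a, b in segments if min(b, hi) > max(a, lo)
    )
    total = 0
    cur_a = cur_b = None
    for a, b in clipped:
        if cur_b is None or a > cur_b:
            if cur_b is not None:
                total += cur_b - cur_a
            cur_a, cur_b = a, b
        else:
            cur_b = max(cur_b, b)
    if cur_b is not None:
        total += cur_b - cur_a
    return total


def compute_pdc(
    fills: Sequence[tuple],
    cap: int = DEFAULT_CAP_DAYS,
    carryover: bool = True,
    denominator_mode: str = "standard",
) -> float:
    """PDC (percent) for one patient's fills of a single agent.

    Parameters
    ----------
    fills
        Sequence of ``(fill_date, days_supply)``; dates may be calendar
        dates or integer day offsets. Same-day fills are merged (supply
        summed, re-capped).
    cap
        Single-fill supply cap in days.
    carryover
        Stockpile leftover supply at refills (the default metric). The
        no-carryover variant is a sensitivity switch and is never larger.
    denominator_mode
        ``"standard"``: window ends at the last fill date, whose supply
        contributes nothing. ``"drop_last"``: the last fill is removed
        entirely and the window ends at the new last fill.

    Raises
    ------
    InsufficientFills
        Fewer than two merged fills, or all fills on one date.
    """
    days, supplies, _ = _as_day_offsets(fills)
    days, supplies = merge_same_day(days, supplies, cap)
    if denominator_mode == "drop_last":
        days, supplies = days[:-1], supplies[:-1]
    elif denominator_mode != "standard":
        raise ValueError(f"unknown denominator_mode: {denominator_mode!r}")
    if len(days) < 2:
        raise InsufficientFills(REASON_TOO_FEW)
    lo, hi = int(days[0]), int(days[-1])
    if hi == lo:
        raise InsufficientFills(REASON_ZERO_WINDOW)
    segments = _stream_segments(days, supplies, carryover)
    covered = _union_length(segments, lo, hi)
    return 100.0 * covered / (hi - lo)


def compute_overall_doac_pdc(
    fills_by_agent: Mapping[str, Sequence[tuple]],
    cap: int = DEFAULT_CAP_DAYS,
    carryover: bool = True,
    denominator_mode: str = "standard",
) -> float:
    """Pooled PDC over all DOAC agents of one patient.

    The window spans the first to the last DOAC fill of any agent; a day is
    covered when any agent's own stock ledger covers it (union coverage,
    per-agent carryover). With a single agent this reduces exactly to
    :func:`compute_pdc`. Under ``denominator_mode="drop_last"`` every fill
    event on the pooled last fill date is removed before the window is
    re-derived.
    """
    if denominator_mode not in ("standard", "drop_last"):
        raise ValueError(f"unknown denominator_mode: {denominator_mode!r}")
    dates_flat = [f[0] for fills in fills_by_agent.values() for f in fills]
    if len(dates_flat) < 2:
        raise InsufficientFills(REASON_TOO_FEW)

    if isinstance(dates_flat[0], (int, np.integer)):
        pooled_origin = min(int(d) for d in dates_flat)

        def offset(d):
            return int(d) - pooled_origin

    else:
        pooled_origin = pd.to_datetime(pd.Series(dates_flat)).min()

        def offset(d):
            return int((pd.Timestamp(d) - pooled_origin).days)

    # Merge same-day fills within each agent, keep per-agent streams.
    streams: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for agent, fills in fills_by_agent.items():
        if not len(fills):
            continue
        ordered = sorted(fills, key=lambda f: offset(f[0]))
        d = np.asarray([offset(f[0]) for f in ordered])
        s = np.asarray([int(f[1]) for f in ordered])
        streams[agent] = merge_same_day(d, s, cap)

    if denominator_mode == "drop_last":
        last_day = max(int(d[-1]) for d, _ in streams.values())
        streams = {
            agent: (d[d < last_day], s[d < last_day])
            for agent, (d, s) in streams.items()
        }
        streams = {a: v for a, v in streams.items() if len(v[0])}

    all_days = [int(x) for d, _ in streams.values() for x in d]
    if len(all_days) < 2:
        raise InsufficientFills(REASON_TOO_FEW)
    lo, hi = min(all_days), max(all_days)
    if hi == lo:
        raise InsufficientFills(REASON_ZERO_WINDOW)
    segments: list[tuple[int, int]] = []
    for d, s in streams.values():
        segments.extend(_stream_segments(d, s, carryover))
    covered = _union_length(segments, lo, hi)
    return 100.0 * covered / (hi - lo)


def classify_adherence(pdc: float, thresholds: tuple[float, float] = (80.0, 90.0)) -> str:
    """Three-group classification: <lo, [lo, hi], >hi (percent; default 80/90).

    The boundaries belong to the middle group: a PDC of exactly 80 or
    exactly 90 is "between 80% and 90%".
    """
    lo, hi = thresholds
    if not (0.0 < lo < hi < 100.0):
        raise ValueError("thresholds must be strictly increasing within (0, 100)")
    if not (0.0 <= pdc <= 100.0) or not np.isfinite(pdc):
        raise ValueError(f"PDC out of range: {pdc!r}")
    if pdc < lo:
        return GROUP_BELOW_80
    if pdc <= hi:
        return GROUP_80_TO_90
    return GROUP_ABOVE_90


def build_fills(
    records: pd.DataFrame,
    regimens: Mapping[str, DrugRegimen] | None = None,
    cap: int = DEFAULT_CAP_DAYS,
) -> pd.DataFrame:
    """Reduce validated claims rows to per-patient, per-agent fill events.

    Only DOAC rows enter adherence streams (warfarin and every other
    substance are dropped here). The dispensed substance defines the agent
    and its regimen — adherence measures what the patient actually had on
    hand. Same-day fills of the same agent are merged by summing days of
    supply and re-capping at ``cap``.

    Returns a frame with columns ``patient_id, agent, fill_date,
    days_supply`` sorted by patient, agent, date.
    """
    regimens = dict(regimens or DEFAULT_REGIMENS)
    doacs = {s for s, r in regimens.items() if r.is_doac}
    sub = records[records["dispensed_substance"].isin(doacs)]
    if not len(sub):
        return pd.DataFrame(
            columns=["patient_id", "agent", "fill_date", "days_supply"]
        )
    rows = []
    for (pid, agent), grp in sub.groupby(["patient_id", "dispensed_substance"], sort=True):
        reg = regimens[agent]
        d, s, origin = _as_day_offsets(
            list(
                zip(
                    grp["dispense_date"],
                    [days_supply(int(q), reg, cap) for q in grp["quantity"]],
                )
            )
        )
        d, s = merge_same_day(d, s, cap)
        base = pd.Timestamp(origin)
        for dd, ss in zip(d, s):
            rows.append(
                {
                    "patient_id": pid,
                    "agent": agent,
                    "fill_date": base + pd.Timedelta(days=int(dd)),
                    "days_supply": int(ss),
                }
            )
    out = pd.DataFrame(rows)
    return out.sort_values(["patient_id", "agent", "fill_date"]).reset_index(drop=True)


def compute_adherence(
    records: pd.DataFrame,
    regimens: Mapping[str, DrugRegimen] | None = None,
    cap: int = DEFAULT_CAP_DAYS,
    carryover: bool = True,
    denominator_mode: str = "standard",
    thresholds: tuple[float, float] = (80.0, 90.0),
) -> pd.DataFrame:
    """Per-patient adherence results (overall-DOAC plus per-agent scopes).

    Every patient with at least one DOAC fill gets an ``overall_doac`` row;
    patients who cannot be scored appear with ``excluded=True`` and a
    reason instead of a PDC. Per-agent rows are emitted for agents with at
    least two merged fills of that agent.

    Returns a frame with columns ``patient_id, scope, agent, pdc, group,
    n_fills, first_fill, last_fill, excluded, reason``.
    """
    fills = build_fills(records, regimens, cap)
    results = []
    for pid, grp in fills.groupby("patient_id", sort=True):
        by_agent = {
            agent: list(zip(sub["fill_date"], sub["days_supply"]))
            for agent, sub in grp.groupby("agent")
        }
        n_total = sum(len(v) for v in by_agent.values())
        first = grp["fill_date"].min()
        last = grp["fill_date"].max()
        try:
            pdc = compute_overall_doac_pdc(
                by_agent, cap, carryover, denominator_mode
            )
            results.append(
                dict(
                    patient_id=pid, scope="overall_doac", agent=None,
                    pdc=pdc, group=classify_adherence(pdc, thresholds), n_fills=n_total,
                    first_fill=first, last_fill=last, excluded=False, reason=None,
                )
            )
        except InsufficientFills as exc:
            results.append(
                dict(
                    patient_id=pid, scope="overall_doac", agent=None,
                    pdc=np.nan, group=None, n_fills=n_total,
                    first_fill=first, last_fill=last, excluded=True,
                    reason=str(exc),
                )
            )
        for agent, agent_fills in by_agent.items():
            if len(agent_fills) < 2:
                continue
            try:
                pdc = compute_pdc(agent_fills, cap, carryover, denominator_mode)
            except InsufficientFills:
                continue
            results.append(
                dict(
                    patient_id=pid, scope="per_agent", agent=agent,
                    pdc=pdc, group=classify_adherence(pdc, thresholds),
                    n_fills=len(agent_fills),
                    first_fill=min(f for f, _ in agent_fills),
                    last_fill=max(f for f, _ in agent_fills),
                    excluded=False, reason=None,
                )
            )
    cols = [
        "patient_id", "scope", "agent", "pdc", "group", "n_fills",
        "first_fill", "last_fill", "excluded", "reason",
    ]
    return pd.DataFrame(results, columns=cols)


def adherence_summary(results: pd.DataFrame) -> dict:
    """Cohort-level adherence summary from :func:`compute_adherence` output.

    Reports mean and median overall-DOAC PDC, per-agent mean PDC, the share
    of scored patients at or above 80%, group counts, and exclusion counts.
    """
    overall = results[(results["scope"] == "overall_doac")]
    scored = overall[~overall["excluded"]]
    n_scored = len(scored)
    groups = {
        g: int((scored["group"] == g).sum())
        for g in (GROUP_BELOW_80, GROUP_80_TO_90, GROUP_ABOVE_90)
    }
    per_agent = (
        results[results["scope"] == "per_agent"]
        .groupby("agent")["pdc"]
        .agg(["mean", "median", "count"])
    )
    summary = {
        "n_patients": int(overall["patient_id"].nunique()),
        "n_scored": n_scored,
        "n_excluded": int(overall["excluded"].sum()),
        "mean_pdc": float(scored["pdc"].mean()) if n_scored else None,
        "median_pdc": float(scored["pdc"].median()) if n_scored else None,
        "share_at_or_above_80_pct": (
            100.0 * (groups[GROUP_80_TO_90] + groups[GROUP_ABOVE_90]) / n_scored
            if n_scored
            else None
        ),
        "group_counts": groups,
        "per_agent_mean_pdc": {
            agent: float(row["mean"]) for agent, row in per_agent.iterrows()
        },
        "per_agent_n": {
            agent: int(row["count"]) for agent, row in per_agent.iterrows()
        },
    }
    return summary
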