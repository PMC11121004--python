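"""Synthetic reimbursement-claims cohorts with known ground truth.

The generator emulates a national AF/flutter reimbursement extract:
anticoagulated patients (warfarin and the four DOACs, with realistic
market-entry years), optional antiarrhythmic co-medication, the 2018
paper-to-electronic and 2020 brand-to-INN regime changes, per-row
dispensing errors, rare off-list prescribing, and a per-patient refill
habit that fixes the patient's true adherence.

Refill behaviour is a one-parameter model: each patient carries a
gap-inflation factor ``g`` and refills ``round(g * days_supply)`` days
(plus small integer jitter) after the previous fill. ``g = 1`` refills
exactly at exhaustion (PDC 100%); ``g > 1`` opens gaps, so expected PDC
falls roughly as ``100/g``. This gives closed-form expectations for
parameter-recovery tests without claiming to be a behavioural model of
real patients.

Ground truth (per-patient true PDC, switcher structure, per-row error and
off-list flags, emission tallies) is computed *inside* the generator with
:func:`truth_pdc`, a deliberately naive day-by-day simulation that never
uses interval arithmetic — it is the independent oracle the analytic PDC
implementation is tested against.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from datetime import date, timedelta
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .records import (
    ANTICOAGULANT_SUBSTANCES,
    DEFAULT_REGIMENS,
    DEFAULT_STUDY_WINDOW,
    DOAC_SUBSTANCES,
)
from .pdc import DEFAULT_CAP_DAYS, merge_same_day

#: First calendar year each anticoagulant appears in the reimbursement data.
AGENT_ENTRY_YEAR = {
    "warfarin": 2012,
    "rivaroxaban": 2018,
    "dabigatran": 2018,
    "edoxaban": 2019,
    "apixaban": 2020,
}

#: Initial-agent weights for therapy starting in or after 2018
#: (renormalised over the agents already on the market that year).
DOAC_ERA_MIX = {
    "rivaroxaban": 0.58,
    "edoxaban": 0.20,
    "dabigatran": 0.14,
    "apixaban": 0.02,
    "warfarin": 0.06,
}

STRENGTHS_MG: dict[str, tuple[float, ...]] = {
    "rivaroxaban": (15.0, 20.0),
    "dabigatran": (110.0, 150.0),
    "edoxaban": (30.0, 60.0),
    "apixaban": (2.5, 5.0),
    "warfarin": (3.0, 5.0),
    "amiodarone": (200.0,),
    "propafenone": (150.0,),
    "aethacizine": (50.0,),
    "metoprolol": (50.0,),
}

ANTIARRHYTHMICS = ("amiodarone", "propafenone", "aethacizine", "metoprolol")
ANTIARRHYTHMIC_DOSES_PER_DAY = {
    "amiodarone": 1, "propafenone": 3, "aethacizine": 3, "metoprolol": 2,
}

#: Substances used for injected off-list prescriptions (not reimbursable
#: for the AF/flutter diagnosis group in the default list).
OFF_LIST_SUBSTANCES = ("bisoprolol", "sotalol")

DIAGNOSIS_WEIGHTS = {
    "I48.0": 0.08, "I48.1": 0.06, "I48.2": 0.10, "I48.3": 0.03,
    "I48.4": 0.03, "I48.9": 0.70,
}
SPECIALITY_WEIGHTS = {
    "general practitioner": 0.921, "cardiologist": 0.043,
    "internist": 0.013, "other": 0.023,
}


def _default_electronic_adoption() -> dict[int, float]:
    # paper-form shares ~98.5% through 2017, 19.4% in 2018, 1.3% by 2022
    out = {y: 0.015 for y in range(2012, 2018)}
    out[2017] = 0.015
    out.update({2018: 0.806, 2019: 0.90, 2020: 0.95, 2021: 0.97, 2022: 0.987})
    return out


def _default_inn_adoption() -> dict[int, float]:
    out = {y: 0.002 for y in range(2012, 2018)}
    out.update({2018: 0.026, 2019: 0.031, 2020: 0.612, 2021: 0.806, 2022: 0.797})
    return out


@dataclass
class SyntheticCohortConfig:
    """Generator parameters; the defaults are the study conditions emulated.

    ``gap_inflation_median``/``gap_inflation_sigma`` parametrise the
    lognormal distribution of the per-patient refill-gap factor;
    ``dispensing_error_rate`` is the per-row probability that the pharmacy
    dispenses a different strength (mostly) or substance (rarely) than
    prescribed; adoption maps give the electronic and INN fractions per
    dispensing year.
    """

    n_patients: int = 500
    window: tuple[date, date] = DEFAULT_STUDY_WINDOW
    age_mean: float = 75.0
    age_sd: float = 9.6
    female_fraction: float = 0.596
    switch_probability: float = 0.418
    switch_type_weights: Mapping[str, float] = field(
        default_factory=lambda: {"warfarin_to_doac": 0.72, "among_doacs": 0.28}
    )
    gap_inflation_median: float = 1.35
    gap_inflation_sigma: float = 0.35
    fill_jitter_days: int = 2
    supply_days_choices: tuple[int, ...] = (30, 60, 90)
    supply_days_weights: tuple[float, ...] = (0.60, 0.15, 0.25)
    dispensing_error_rate: float = 0.011
    cross_substance_error_fraction: float = 0.10
    off_list_rate: float = 0.0005
    electronic_adoption: Mapping[int, float] = field(
        default_factory=_default_electronic_adoption
    )
    inn_adoption: Mapping[int, float] = field(default_factory=_default_inn_adoption)
    pharmacy_count_pmf: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.167, 2: 0.110, 3: 0.200, 4: 0.210,
                                 5: 0.160, 6: 0.153}
    )
    n_pharmacies_pool: int = 400
    comedication_probability: float = 0.40
    cap_days: int = DEFAULT_CAP_DAYS
    seed: int = 0

    def validate(self) -> None:
        for name in ("female_fraction", "switch_probability",
                     "dispensing_error_rate", "off_list_rate",
                     "cross_substance_error_fraction", "comedication_probability"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for m in (self.electronic_adoption, self.inn_adoption):
            if any(not 0.0 <= v <= 1.0 for v in m.values()):
                raise ValueError("adoption fractions must be in [0, 1]")
        if abs(sum(self.pharmacy_count_pmf.values()) - 1.0) > 1e-9:
            raise ValueError("pharmacy_count_pmf must sum to 1")
        lo, hi = self.window
        if (hi - lo).days < 180:
            raise ValueError(
                "study window shorter than 180 days cannot place two fills "
                "under the refill model"
            )
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")


@dataclass
class GroundTruth:
    """What the generator knows that the pipeline must recover.

    ``patients`` has one row per patient (true overall-DOAC PDC or an
    exclusion reason, per the day-by-day oracle; switcher structure;
    pharmacy count; the drawn gap-inflation factor). ``agent_pdc`` has one
    row per (patient, DOAC) with >= 2 fills. ``row_flags`` aligns with the
    emitted records frame and carries the injected error/off-list flags.
    """

    patients: pd.DataFrame
    agent_pdc: pd.DataFrame
    row_flags: pd.DataFrame
    config: SyntheticCohortConfig


def truth_pdc(fills: Sequence[tuple], cap: int = DEFAULT_CAP_DAYS) -> float:
    """Day-by-day oracle PDC for one agent's fills of one patient.

    Materialises a boolean per-day coverage array over the half-open
    window from first to last fill date: stock is topped up on fill days
    (same-day fills merged and re-capped first), one unit is consumed per
    covered day, and leftover stock carries over without limit. Raises
    ``ValueError`` for fewer than two merged fills or a zero-length window.
    """
    return truth_overall_pdc({"agent": list(fills)}, cap)


def truth_overall_pdc(
    fills_by_agent: Mapping[str, Sequence[tuple]], cap: int = DEFAULT_CAP_DAYS
) -> float:
    """Day-by-day oracle for the pooled (union-coverage) DOAC PDC."""
    streams = {}
    all_days: list[int] = []
    dates_flat = [f[0] for fills in fills_by_agent.values() for f in fills]
    if len(dates_flat) < 2:
        raise ValueError("fewer than two fills")
    if isinstance(dates_flat[0], (int, np.integer)):
        origin = min(int(d) for d in dates_flat)

        def off(d):
            return int(d) - origin

    else:
        origin = min(pd.Timestamp(d) for d in dates_flat)

        def off(d):
            return (pd.Timestamp(d) - origin).days

    for agent, fills in fills_by_agent.items():
        if not len(fills):
            continue
        ordered = sorted(fills, key=lambda f: off(f[0]))
        d = np.asarray([off(f[0]) for f in ordered])
        s = np.asarray([int(f[1]) for f in ordered])
        d, s = merge_same_day(d, s, cap)
        streams[agent] = (d, s)
        all_days.extend(int(x) for x in d)
    if len(all_days) < 2:
        raise ValueError("fewer than two fills")
    lo, hi = min(all_days), max(all_days)
    if hi == lo:
        raise ValueError("zero-length observation window")
    covered = np.zeros(hi - lo, dtype=bool)
    for d, s in streams.values():
        stock = 0
        supply_on = {int(dd) - lo: int(ss) for dd, ss in zip(d, s)}
        for day in range(hi - lo):
            if day in supply_on:
                stock += supply_on[day]
            if stock > 0:
                covered[day] = True
                stock -= 1
        # fills on the last day add stock outside the simulated range: ignored
    return 100.0 * covered.sum() / (hi - lo)


def _patient_rng(seed: int, patient_id: str) -> np.random.Generator:
    """Per-patient substream keyed by a stable hash of the patient id."""
    h = int.from_bytes(
        hashlib.sha256(patient_id.encode()).digest()[:4], "big"
    ) % (2**31)
    return np.random.default_rng([seed % (2**31), h])


def _weighted_choice(rng, mapping: Mapping) -> object:
    keys = list(mapping)
    w = np.asarray([mapping[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=w / w.sum())]


def _available_doacs(year: int) -> list[str]:
    return [a for a in sorted(DOAC_SUBSTANCES) if AGENT_ENTRY_YEAR[a] <= year]


def _initial_agent(rng, year: int) -> str:
    if year < 2018:
        return "warfarin"
    avail = [a for a, y in AGENT_ENTRY_YEAR.items() if y <= year]
    mix = {a: DOAC_ERA_MIX[a] for a in avail}
    return _weighted_choice(rng, mix)


def _doses_per_day(substance: str) -> int:
    if substance in DEFAULT_REGIMENS:
        return DEFAULT_REGIMENS[substance].doses_per_day
    return ANTIARRHYTHMIC_DOSES_PER_DAY.get(substance, 1)


def _fill_schedule(rng, cfg, start_day: int, end_day: int) -> tuple[np.ndarray, np.ndarray, float]:
    """Fill day offsets and supplies for one therapy stream.

    Returns (days, supplies, g). Gap to the next fill is
    ``max(1, round(g * supply) + jitter)``.
    """
    g = float(np.clip(
        rng.lognormal(np.log(cfg.gap_inflation_median), cfg.gap_inflation_sigma),
        0.80, 3.0,
    ))
    horizon = end_day - start_day
    max_fills = max(4, int(np.ceil(horizon / (0.8 * min(cfg.supply_days_choices)))) + 2)
    supplies = rng.choice(
        cfg.supply_days_choices, size=max_fills,
        p=np.asarray(cfg.supply_days_weights) / sum(cfg.supply_days_weights),
    )
    jitter = rng.integers(-cfg.fill_jitter_days, cfg.fill_jitter_days + 1,
                          size=max_fills)
    days, t, i = [], start_day, 0
    while t <= end_day and i < max_fills:
        days.append(t)
        t = t + max(1, int(round(g * int(supplies[i]))) + int(jitter[i]))
        i += 1
    return np.asarray(days), supplies[: len(days)].astype(int), g


def generate_cohort(
    config: SyntheticCohortConfig | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a claims frame plus ground truth, fully determined by the seed.

    Every emitted row passes :func:`rxadhere.records.validate_records` and
    the default cohort filter. Patient substreams are keyed by a stable
    hash of the patient id, so enlarging ``n_patients`` leaves existing
    patients' histories unchanged.
    """
    cfg = config or SyntheticCohortConfig()
    cfg.validate()
    win_lo, win_hi = cfg.window
    win_days = (win_hi - win_lo).days

    rows: list[dict] = []
    flag_error: list[bool] = []
    flag_off: list[bool] = []
    patient_rows: list[dict] = []
    agent_rows: list[dict] = []

    pharmacy_pool = [f"PH{i:04d}" for i in range(cfg.n_pharmacies_pool)]

    for idx in range(cfg.n_patients):
        pid = f"P{idx:06d}"
        rng = _patient_rng(cfg.seed, pid)

        gender = "F" if rng.random() < cfg.female_fraction else "M"
        age = int(np.clip(round(rng.normal(cfg.age_mean, cfg.age_sd)), 30, 100))
        diagnosis = _weighted_choice(rng, DIAGNOSIS_WEIGHTS)
        speciality = _weighted_choice(rng, SPECIALITY_WEIGHTS)
        k_pharm = int(_weighted_choice(rng, cfg.pharmacy_count_pmf))
        pharmacies = list(rng.choice(pharmacy_pool, size=k_pharm, replace=False))

        start_day = int(rng.integers(0, win_days - 180 + 1))
        start_date = win_lo + timedelta(days=start_day)

        first_agent = _initial_agent(rng, start_date.year)
        is_switcher = rng.random() < cfg.switch_probability

        days, supplies, g = _fill_schedule(rng, cfg, start_day, win_days)
        agents = [first_agent] * len(days)

        second_agent = None
        if is_switcher and len(days) >= 2:
            # switch at a fill that falls after the target DOAC's market entry
            if first_agent == "warfarin":
                switch_type = "warfarin_to_doac"
            else:
                switch_type = _weighted_choice(rng, cfg.switch_type_weights)
            eligible = [
                i for i in range(1, len(days))
                if (win_lo + timedelta(days=int(days[i]))).year >= 2018
            ]
            if eligible:
                si = int(rng.choice(eligible))
                sw_year = (win_lo + timedelta(days=int(days[si]))).year
                avail = _available_doacs(sw_year)
                if switch_type == "warfarin_to_doac" and first_agent != "warfarin":
                    # DOAC starter drawn into a warfarin-origin switch: treat
                    # as among-DOAC switch instead
                    switch_type = "among_doacs"
                choices = [a for a in avail if a != first_agent]
                if choices:
                    second_agent = str(rng.choice(choices))
                    for i in range(si, len(days)):
                        agents[i] = second_agent

        strength_pick = {
            a: float(STRENGTHS_MG[a][int(rng.integers(len(STRENGTHS_MG[a])))])
            for a in set(agents)
        }

        streams = [(days, supplies, agents)]
        if rng.random() < cfg.comedication_probability:
            comed = str(rng.choice(ANTIARRHYTHMICS))
            cdays, csupp, _ = _fill_schedule(rng, cfg, start_day, win_days)
            streams.append((cdays, csupp, [comed] * len(cdays)))
            strength_pick[comed] = float(STRENGTHS_MG[comed][0])

        # emit rows; channel/error draws are per row
        patient_row_list = []
        for sdays, ssupp, sagents in streams:
            for d, s, agent in zip(sdays, ssupp, sagents):
                patient_row_list.append((int(d), int(s), agent))
        patient_row_list.sort()

        for fill_i, (d, s, agent) in enumerate(patient_row_list):
            fdate = win_lo + timedelta(days=d)
            year = fdate.year
            dpd = _doses_per_day(agent)
            quantity = int(s) * dpd
            strength = strength_pick[agent]
            prescribed_sub, prescribed_str = agent, strength
            dispensed_sub, dispensed_str = agent, strength

            off_list = rng.random() < cfg.off_list_rate
            error = False
            if off_list:
                prescribed_sub = str(rng.choice(OFF_LIST_SUBSTANCES))
                prescribed_str = 5.0
                dispensed_sub, dispensed_str = prescribed_sub, prescribed_str
            elif rng.random() < cfg.dispensing_error_rate:
                error = True
                cross = rng.random() < cfg.cross_substance_error_fraction
                options = STRENGTHS_MG[agent]
                if cross and agent in DOAC_SUBSTANCES:
                    others = [a for a in _available_doacs(year) if a != agent]
                    if others:
                        dispensed_sub = str(rng.choice(others))
                        alt = STRENGTHS_MG[dispensed_sub]
                        dispensed_str = float(alt[int(rng.integers(len(alt)))])
                    else:
                        cross = False
                if not (cross and agent in DOAC_SUBSTANCES):
                    alts = [x for x in options if x != strength]
                    if alts:
                        dispensed_str = float(alts[int(rng.integers(len(alts)))])
                    else:
                        error = False  # single-strength substance: nothing to swap

            electronic = rng.random() < cfg.electronic_adoption.get(year, 0.0)
            inn = rng.random() < cfg.inn_adoption.get(year, 0.0)

            rows.append(
                {
                    "patient_id": pid,
                    "age": age,
                    "gender": gender,
                    "dispense_date": pd.Timestamp(fdate),
                    "diagnosis_code": diagnosis,
                    "prescribed_substance": prescribed_sub,
                    "prescribed_strength": prescribed_str,
                    "dispensed_substance": dispensed_sub,
                    "dispensed_strength": dispensed_str,
                    "quantity": quantity,
                    "rx_format": "electronic" if electronic else "paper",
                    "rx_mode": "inn" if inn else "brand",
                    "physician_speciality": speciality,
                    "pharmacy_id": pharmacies[fill_i % k_pharm],
                }
            )
            flag_error.append(error)
            flag_off.append(off_list)

        # ---- ground truth from the emitted rows (dispensed stream) ----
        my_rows = rows[-len(patient_row_list):]
        my_err = flag_error[-len(patient_row_list):]
        doac_fills: dict[str, list[tuple]] = {}
        prescribed_anticoags: list[str] = []
        for r in my_rows:
            sub = r["dispensed_substance"]
            if r["prescribed_substance"] in ANTICOAGULANT_SUBSTANCES:
                prescribed_anticoags.append(r["prescribed_substance"])
            if sub in DOAC_SUBSTANCES:
                ds = min(r["quantity"] // _doses_per_day(sub), cfg.cap_days)
                if ds >= 1:
                    doac_fills.setdefault(sub, []).append((r["dispense_date"], ds))

        distinct = len(set(prescribed_anticoags))
        try:
            overall = truth_overall_pdc(doac_fills, cfg.cap_days)
            reason = None
        except ValueError as exc:
            overall, reason = np.nan, str(exc)
        patient_rows.append(
            {
                "patient_id": pid, "age": age, "gender": gender,
                "gap_inflation": g, "is_switcher": distinct >= 2,
                "planned_switcher": bool(is_switcher and second_agent),
                "distinct_anticoagulants": distinct,
                "n_pharmacies": min(k_pharm, len(patient_row_list)),
                "true_overall_pdc": overall, "excluded_reason": reason,
                "n_rows": len(patient_row_list),
            }
        )
        for agent_name, fl in doac_fills.items():
            d_, s_ = merge_same_day(
                np.asarray([(pd.Timestamp(f[0]) - pd.Timestamp(win_lo)).days for f in fl]),
                np.asarray([f[1] for f in fl]), cfg.cap_days,
            )
            if len(d_) >= 2 and d_[-1] > d_[0]:
                agent_rows.append(
                    {
                        "patient_id": pid, "agent": agent_name,
                        "true_pdc": truth_pdc(list(zip(d_, s_)), cfg.cap_days),
                    }
                )

    records = pd.DataFrame(rows)
    records = records.sort_values(
        ["patient_id", "dispense_date"], kind="stable"
    ).reset_index(drop=False)
    order = records.pop("index")
    flags = pd.DataFrame(
        {
            "error": np.asarray(flag_error)[order],
            "off_list": np.asarray(flag_off)[order],
        }
    )
    truth = GroundTruth(
        patients=pd.DataFrame(patient_rows),
        agent_pdc=pd.DataFrame(agent_rows, columns=["patient_id", "agent", "true_pdc"]),
        row_flags=flags,
        config=cfg,
    )
    return records.reset_index(drop=True), truth
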