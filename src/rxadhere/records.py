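"""Claims record schema, file I/O, validation and cohort filters.

One row of a reimbursement-prescription extract is one dispensing event:
an anonymised patient, the substance/strength the physician prescribed,
the substance/strength the pharmacy actually dispensed, the quantity of
dose units handed over, and channel metadata (paper vs electronic form,
brand vs INN prescribing, pharmacy and physician identifiers).

Records are carried as a :class:`pandas.DataFrame` with the canonical
columns in :data:`CANONICAL_COLUMNS`; every reader/writer and every
downstream stage works on that frame.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from datetime import date
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

CANONICAL_COLUMNS = [
    "patient_id",
    "age",
    "gender",
    "dispense_date",
    "diagnosis_code",
    "prescribed_substance",
    "prescribed_strength",
    "dispensed_substance",
    "dispensed_strength",
    "quantity",
    "rx_format",
    "rx_mode",
    "physician_speciality",
    "pharmacy_id",
]

GENDERS = frozenset({"F", "M"})
RX_FORMATS = frozenset({"paper", "electronic"})
RX_MODES = frozenset({"brand", "inn"})

#: ICD-10 codes for atrial fibrillation and flutter used for cohort selection.
DEFAULT_DIAGNOSIS_CODES = frozenset(
    {"I48.0", "I48.1", "I48.2", "I48.3", "I48.4", "I48.9"}
)

#: Default study window (inclusive on both ends).
DEFAULT_STUDY_WINDOW = (date(2012, 1, 1), date(2022, 12, 31))

#: Substance-name aliases applied during normalisation (lowercased keys).
DEFAULT_ALIASES = {
    "clopidogrel + aspirin": "clopidogrel/aspirin",
    "clopidogrel+aspirin": "clopidogrel/aspirin",
    "aspirin/clopidogrel": "clopidogrel/aspirin",
    "acetylsalicylic acid/clopidogrel": "clopidogrel/aspirin",
}


def normalize_substance(name: str, aliases: Mapping[str, str] | None = None) -> str:
    """Lowercase, strip and alias-resolve an INN string."""
    key = str(name).strip().lower()
    table = DEFAULT_ALIASES if aliases is None else aliases
    return table.get(key, key)


@dataclass(frozen=True)
class DrugRegimen:
    """Dosing facts for one substance.

    ``doses_per_day`` is the pharmacological maintenance frequency used to
    convert a dispensed quantity of dose units into days of supply.
    Warfarin carries a regimen entry (it is an anticoagulant and counts for
    switcher detection) but is excluded from adherence because its dosing
    is INR-titrated and has no fixed daily frequency.
    """

    substance: str
    doses_per_day: int
    is_doac: bool
    is_anticoagulant: bool

    def __post_init__(self) -> None:
        if self.doses_per_day < 1:
            raise ValueError("doses_per_day must be a positive integer")


DEFAULT_REGIMENS: dict[str, DrugRegimen] = {
    r.substance: r
    for r in [
        DrugRegimen("dabigatran", 2, True, True),
        DrugRegimen("apixaban", 2, True, True),
        DrugRegimen("rivaroxaban", 1, True, True),
        DrugRegimen("edoxaban", 1, True, True),
        DrugRegimen("warfarin", 1, False, True),
    ]
}

DOAC_SUBSTANCES = frozenset(
    s for s, r in DEFAULT_REGIMENS.items() if r.is_doac
)
ANTICOAGULANT_SUBSTANCES = frozenset(
    s for s, r in DEFAULT_REGIMENS.items() if r.is_anticoagulant
)

#: Substances on the national reimbursement list for the I48 diagnosis group.
DEFAULT_I48_LIST = frozenset(
    {
        "aethacizine",
        "amiodarone",
        "apixaban",
        "atenolol",
        "dabigatran",
        "digoxin",
        "diltiazem",
        "edoxaban",
        "clopidogrel",
        "clopidogrel/aspirin",
        "metoprolol",
        "propafenone",
        "rivaroxaban",
        "warfarin",
        "verapamil",
    }
)


def diagnosis_group(code: str) -> str:
    """Collapse an ICD-10 code to its block, e.g. ``I48.2`` -> ``I48``."""
    return str(code).split(".")[0].strip().upper()


@dataclass(frozen=True)
class ReimbursementList:
    """Approved (diagnosis group, substance) pairs; lookups are case-insensitive."""

    allowed: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.allowed:
            raise ValueError("reimbursement list must be non-empty")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Iterable[str]]) -> "ReimbursementList":
        pairs = frozenset(
            (group.upper(), normalize_substance(s))
            for group, subs in mapping.items()
            for s in subs
        )
        return cls(pairs)

    def contains(self, code: str, substance: str) -> bool:
        return (diagnosis_group(code), normalize_substance(substance)) in self.allowed


DEFAULT_REIMBURSEMENT_LIST = ReimbursementList.from_mapping({"I48": DEFAULT_I48_LIST})


class SchemaError(ValueError):
    """Raised when an input file is missing a mandatory column."""


def _sniff_delimiter(path: Path) -> str:
    with open(path, "r", newline="") as fh:
        sample = fh.readline()
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t;").delimiter
    except csv.Error:
        return ","


def validate_records(raw: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Validate and type a raw string frame of claims rows.

    Returns ``(records, rejections)`` where ``records`` has canonical dtypes
    (dates as ``datetime64``, counts as integers, strengths as floats,
    substances lowercased) and ``rejections`` lists each bad row with the
    original row position and the first failed check.
    """
    missing = [c for c in CANONICAL_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")

    df = raw[CANONICAL_COLUMNS].copy()
    reasons = pd.Series("", index=df.index, dtype=object)

    def flag(mask: pd.Series, reason: str) -> None:
        sel = mask & (reasons == "")
        reasons[sel] = reason

    dates = pd.to_datetime(df["dispense_date"], errors="coerce", format="ISO8601")
    flag(dates.isna(), "unparseable date")

    quantity = pd.to_numeric(df["quantity"], errors="coerce")
    flag(quantity.isna(), "unparseable quantity")
    flag(quantity <= 0, "nonpositive quantity")
    flag(quantity != quantity.round(), "non-integer quantity")

    age = pd.to_numeric(df["age"], errors="coerce")
    flag(age.isna() | (age < 0), "invalid age")

    for col in ("prescribed_strength", "dispensed_strength"):
        strength = pd.to_numeric(df[col], errors="coerce")
        flag(strength.isna() | (strength <= 0), f"nonpositive {col}")

    flag(~df["gender"].astype(str).str.upper().isin(GENDERS), "invalid gender")
    flag(
        ~df["rx_format"].astype(str).str.lower().isin(RX_FORMATS),
        "invalid rx_format",
    )
    flag(~df["rx_mode"].astype(str).str.lower().isin(RX_MODES), "invalid rx_mode")
    flag(df["patient_id"].astype(str).str.strip() == "", "missing patient_id")

    bad = reasons != ""
    rejections = pd.DataFrame(
        {"row": df.index[bad], "reason": reasons[bad].to_numpy()}
    ).reset_index(drop=True)

    ok = df[~bad].copy()
    ok["dispense_date"] = dates[~bad]
    ok["quantity"] = quantity[~bad].astype(int)
    ok["age"] = age[~bad].astype(int)
    ok["gender"] = ok["gender"].astype(str).str.upper()
    ok["rx_format"] = ok["rx_format"].astype(str).str.lower()
    ok["rx_mode"] = ok["rx_mode"].astype(str).str.lower()
    for col in ("prescribed_strength", "dispensed_strength"):
        ok[col] = pd.to_numeric(ok[col]).astype(float)
    for col in ("prescribed_substance", "dispensed_substance"):
        ok[col] = ok[col].map(normalize_substance)
    ok["diagnosis_code"] = ok["diagnosis_code"].astype(str).str.strip().str.upper()
    return ok.reset_index(drop=True), rejections


def read_prescriptions(
    path: str | Path,
    schema_config: Mapping | None = None,
    delimiter: str | None = None,
    strict: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a delimited claims file into validated records.

    Parameters
    ----------
    path
        CSV/TSV file with a header row.
    schema_config
        Optional mapping with keys ``columns`` (file column -> canonical
        column rename map) and ``delimiter``.
    delimiter
        Field delimiter; overrides the config; auto-detected when absent.
    strict
        When true, any rejected row raises instead of being reported.

    Returns
    -------
    (records, rejections)
        Validated records and a per-row rejection report
        (columns ``row``, ``reason``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cfg = dict(schema_config or {})
    delim = delimiter or cfg.get("delimiter") or _sniff_delimiter(path)
    raw = pd.read_csv(path, sep=delim, dtype=str, keep_default_na=False)
    rename = cfg.get("columns")
    if rename:
        raw = raw.rename(columns=dict(rename))
    records, rejections = validate_records(raw)
    if strict and len(rejections):
        first = rejections.iloc[0]
        raise ValueError(
            f"{len(rejections)} rejected row(s); first: row {first['row']}: "
            f"{first['reason']}"
        )
    return records, rejections


def write_prescriptions(
    records: pd.DataFrame, path: str | Path, delimiter: str = ","
) -> None:
    """Write validated records back out in the canonical dialect (ISO dates)."""
    out = records[CANONICAL_COLUMNS].copy()
    out["dispense_date"] = pd.to_datetime(out["dispense_date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, sep=delimiter, index=False)


def filter_cohort(
    records: pd.DataFrame,
    diagnosis_codes: Iterable[str] | None = None,
    window: tuple[date, date] | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Keep rows matching the diagnosis set and the study window.

    Returns the kept rows and a per-reason removal tally
    (``{"diagnosis": ..., "window": ...}``). Rows failing both predicates
    count under ``diagnosis`` (first predicate applied).
    """
    codes = frozenset(diagnosis_codes) if diagnosis_codes else DEFAULT_DIAGNOSIS_CODES
    lo, hi = window or DEFAULT_STUDY_WINDOW
    dates = pd.to_datetime(records["dispense_date"])
    in_codes = records["diagnosis_code"].isin(codes)
    in_window = (dates >= pd.Timestamp(lo)) & (dates <= pd.Timestamp(hi))
    removed = {
        "diagnosis": int((~in_codes).sum()),
        "window": int((in_codes & ~in_window).sum()),
    }
    kept = records[in_codes & in_window].reset_index(drop=True)
    return kept, removed


def flag_off_list(
    records: pd.DataFrame, rlist: ReimbursementList | None = None
) -> tuple[pd.Series, float]:
    """Flag prescriptions whose prescribed substance is outside the approved list.

    Returns a boolean series aligned with ``records`` and the flagged
    fraction (``flagged / total``; 0.0 on empty input).
    """
    rlist = rlist or DEFAULT_REIMBURSEMENT_LIST
    if not len(records):
        return pd.Series(dtype=bool), 0.0
    groups = records["diagnosis_code"].map(diagnosis_group)
    subs = records["prescribed_substance"].map(normalize_substance)
    flags = ~pd.Series(
        [(g, s) in rlist.allowed for g, s in zip(groups, subs)],
        index=records.index,
    )
    return flags, float(flags.mean())
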