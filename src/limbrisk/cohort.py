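"""Cohort data model, CSV input/output and eligibility validation.

A cohort is an ordered collection of :class:`SubjectRecord` objects, one per
participant, holding the raw demographic, anthropometric, laboratory and
clinical fields from which every derived index is computed.  Derived indices
are never stored here: they are always recomputed from the raw fields (see
:mod:`limbrisk.biomarkers`), so a cohort file can never carry an index that is
inconsistent with its own labs.

Missing values are represented as ``None`` (``NaN`` in CSV round-trips) and
propagate as missing; subjects are dropped per-analysis rather than imputed,
mirroring the eligibility screen of the study design this package supports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

__all__ = [
    "SubjectRecord",
    "Cohort",
    "ValidationReport",
    "SchemaError",
    "ParseError",
    "read_cohort",
    "write_cohort",
    "validate_cohort",
    "REQUIRED_FIELDS",
    "NUMERIC_FIELDS",
]


class SchemaError(ValueError):
    """A required column is missing or unresolvable from the CSV header."""


class ParseError(ValueError):
    """A numeric field holds a non-numeric token."""


#: numeric per-subject fields, in canonical column order
NUMERIC_FIELDS: tuple[str, ...] = (
    "age",
    "dm_duration",
    "weight",
    "height",
    "wc",
    "fpg",
    "hba1c",
    "tc",
    "hdl_c",
    "ldl_c",
    "tg",
    "ferritin",
    "esr",
    "crp",
    "fibrinogen",
    "tnf_alpha",
    "il6",
    "fgf1",
    "mmp1",
    "neutrophils",
    "lymphocytes",
    "monocytes",
    "platelets",
    "neutrophil_pct",
    "albumin_g_dl",
    "abi",
    "toronto_symptoms",
    "toronto_failed_tests",
    "toronto_reflex_points",
)

#: fields a subject must carry (non-missing, in-range) to enter the analysis
REQUIRED_FIELDS: tuple[str, ...] = ("gender",) + NUMERIC_FIELDS

#: fields that appear as divisors and must be strictly positive
_POSITIVE_FIELDS = {"height", "hdl_c", "lymphocytes", "albumin_g_dl", "abi"}

_ALL_COLUMNS = (
    ("subject_id", "gender")
    + NUMERIC_FIELDS
    + ("pad_label", "dpn_label", "refused")
)


@dataclass
class SubjectRecord:
    """One participant's raw fields.

    Units: age and dm_duration in years; weight kg; height m; wc cm;
    fpg/tc/hdl_c/ldl_c/tg/fibrinogen mg/dL; hba1c and neutrophil_pct %;
    ferritin ng/mL; esr mm/hr; crp mg/L; tnf_alpha/il6/fgf1/mmp1 pg/mL;
    blood counts 10^3 cells/uL; albumin_g_dl g/dL; abi dimensionless.
    Toronto components are non-negative integer points.
    """

    subject_id: str
    gender: str | None = None  # "male" | "female"
    age: float | None = None
    dm_duration: float | None = None
    weight: float | None = None
    height: float | None = None
    wc: float | None = None
    fpg: float | None = None
    hba1c: float | None = None
    tc: float | None = None
    hdl_c: float | None = None
    ldl_c: float | None = None
    tg: float | None = None
    ferritin: float | None = None
    esr: float | None = None
    crp: float | None = None
    fibrinogen: float | None = None
    tnf_alpha: float | None = None
    il6: float | None = None
    fgf1: float | None = None
    mmp1: float | None = None
    neutrophils: float | None = None
    lymphocytes: float | None = None
    monocytes: float | None = None
    platelets: float | None = None
    neutrophil_pct: float | None = None
    albumin_g_dl: float | None = None
    abi: float | None = None
    toronto_symptoms: float | None = None
    toronto_failed_tests: float | None = None
    toronto_reflex_points: float | None = None
    pad_label: str | None = None  # "positive" | "negative"
    dpn_label: str | None = None
    refused: bool = False  # enrollment metadata, not inferable from labs


@dataclass
class Cohort:
    """Ordered collection of subjects with unique identifiers."""

    records: list[SubjectRecord] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.subject_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("subject_id values must be unique within a cohort")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def to_frame(self) -> pd.DataFrame:
        """Cohort as a DataFrame, one row per subject, canonical column order."""
        rows = []
        for r in self.records:
            rows.append({c: getattr(r, c) for c in _ALL_COLUMNS})
        df = pd.DataFrame(rows, columns=list(_ALL_COLUMNS))
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, provenance: str = "") -> "Cohort":
        records = []
        for _, row in df.iterrows():
            kwargs = {}
            for c in _ALL_COLUMNS:
                if c not in df.columns:
                    continue
                v = row[c]
                if c == "refused":
                    kwargs[c] = bool(v) and not pd.isna(v)
                elif pd.isna(v):
                    kwargs[c] = None
                elif c in ("subject_id", "gender", "pad_label", "dpn_label"):
                    kwargs[c] = str(v)
                else:
                    kwargs[c] = float(v)
            records.append(SubjectRecord(**kwargs))
        return cls(records=records, provenance=provenance)


@dataclass
class ValidationReport:
    """Outcome of the eligibility screen over one cohort.

    ``n_eligible = n_evaluated - n_refused - n_incomplete``; a subject counts
    as incomplete when any analysis-required field is missing or violates its
    range invariant (a zero divisor such as HDL-c makes downstream indices
    undefined, so it excludes the subject the same way a missing value does).
    """

    n_evaluated: int
    n_refused: int
    n_incomplete: int
    n_eligible: int
    violations: dict[str, list[str]]  # subject_id -> list of field problems

    def eligible_ids(self, cohort: Cohort) -> list[str]:
        bad = set(self.violations)
        return [
            r.subject_id
            for r in cohort
            if not r.refused and r.subject_id not in bad
        ]


def _field_violations(rec: SubjectRecord) -> list[str]:
    problems: list[str] = []
    if rec.gender not in ("male", "female"):
        problems.append("gender: must be 'male' or 'female'")
    for name in NUMERIC_FIELDS:
        v = getattr(rec, name)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            problems.append(f"{name}: missing")
            continue
        if not math.isfinite(v):
            problems.append(f"{name}: non-finite")
        elif name in _POSITIVE_FIELDS:
            if v <= 0:
                problems.append(f"{name}: must be > 0 (divisor)")
        elif v < 0:
            problems.append(f"{name}: must be >= 0")
    npct = rec.neutrophil_pct
    if npct is not None and not math.isnan(npct) and not 0 <= npct <= 100:
        problems.append("neutrophil_pct: must lie in [0, 100]")
    return problems


def validate_cohort(cohort: Cohort) -> ValidationReport:
    """Screen a cohort for analysis eligibility without mutating it.

    Refusals (the ``refused`` metadata flag) are excluded first; remaining
    subjects with any required-field violation are counted incomplete.
    """
    if len(cohort) == 0:
        raise ValueError("cannot validate an empty cohort")
    violations: dict[str, list[str]] = {}
    n_refused = 0
    n_incomplete = 0
    for rec in cohort:
        if rec.refused:
            n_refused += 1
            continue
        probs = _field_violations(rec)
        if probs:
            violations[rec.subject_id] = probs
            n_incomplete += 1
    n_eval = len(cohort)
    return ValidationReport(
        n_evaluated=n_eval,
        n_refused=n_refused,
        n_incomplete=n_incomplete,
        n_eligible=n_eval - n_refused - n_incomplete,
        violations=violations,
    )


def read_cohort(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    height_unit: str = "m",
    provenance: str | None = None,
) -> Cohort:
    """Read a cohort CSV (comma-separated, '.' decimal, UTF-8, header row).

    Parameters
    ----------
    path:
        CSV file with one subject per row.
    column_map:
        Optional mapping from file column names to canonical field names,
        for files with non-canonical headers.
    height_unit:
        ``"m"`` (default) or ``"cm"``; heights in cm are converted to meters
        on read so BMI and waist-to-height share a single stored height.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    if column_map:
        df = df.rename(columns=dict(column_map))
    required = ["subject_id"] + list(REQUIRED_FIELDS)
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"required column missing: {col}")
    records: list[SubjectRecord] = []
    for i, row in df.iterrows():
        kwargs: dict[str, object] = {"subject_id": row["subject_id"]}
        for c in ("gender", "pad_label", "dpn_label"):
            if c in df.columns:
                v = row[c].strip()
                kwargs[c] = v if v else None
        if "refused" in df.columns:
            v = row["refused"].strip().lower()
            kwargs["refused"] = v in ("1", "true", "yes")
        for c in NUMERIC_FIELDS:
            tok = row[c].strip()
            if tok == "" or tok.upper() in ("NA", "NAN"):
                kwargs[c] = None
                continue
            try:
                kwargs[c] = float(tok)
            except ValueError as exc:
                raise ParseError(
                    f"row {i}: non-numeric value {tok!r} in column {c}"
                ) from exc
        records.append(SubjectRecord(**kwargs))
    if height_unit == "cm":
        for r in records:
            if r.height is not None:
                r.height = r.height / 100.0
    elif height_unit != "m":
        raise ValueError("height_unit must be 'm' or 'cm'")
    return Cohort(records=records, provenance=provenance or str(path))


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort to CSV in the canonical schema read by :func:`read_cohort`."""
    df = cohort.to_frame()
    df["refused"] = df["refused"].map(lambda b: "true" if b else "false")
    df.to_csv(path, index=False, encoding="utf-8")
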