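"""Anthropometric, insulin-resistance and inflammation index panel.

Seventeen indices are derived per subject from the raw fields:

Anthropometric
    BMI = weight (kg) / height (m)^2; WHtR = WC (cm) / height (cm).

Insulin-resistance surrogates (Ln is the natural logarithm)
    TyG      = Ln(TG * FPG / 2)                  [TG, FPG in mg/dL]
    TyG-BMI  = TyG * BMI;  TyG-WC = TyG * WC;  TyG-WHtR = TyG * WHtR
    TG/HDL-c = TG / HDL-c
    METS-IR  = Ln(2*FPG + TG) * BMI / Ln(HDL-c)
    CHG      = Ln(TC * FPG / (2 * HDL-c))
    CHG-BMI  = CHG * BMI;  CHG-WC = CHG * WC;  CHG-WHtR = CHG * WHtR

Inflammation indices (counts in 10^3 cells/uL)
    NLR  = neutrophils / lymphocytes
    MLR  = monocytes / lymphocytes
    SII  = platelets * NLR                      [on the 10^3 cells/uL scale]
    CAR  = CRP (mg/L) / albumin (g/L)           [albumin stored in g/dL, x10]
    NPAR = neutrophil percentage (%) * 100 / albumin (g/dL)

Albumin is stored once, in g/dL (the unit NPAR uses); CAR converts it to g/L
explicitly, so the two indices cannot silently mix units.  No rounding happens
inside the panel — display rounding belongs to report generation.

Missing inputs propagate: each index is None whenever any of its inputs is
missing, and only that index is affected.  Present-but-invalid inputs (e.g. a
non-positive logarithm argument) raise :class:`DomainError` naming the field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields as dc_fields
from typing import Iterable

import pandas as pd

from .cohort import Cohort, SubjectRecord

__all__ = [
    "BiomarkerPanel",
    "DomainError",
    "PANEL_FIELDS",
    "anthropometric_indices",
    "tyg_index",
    "chg_index",
    "mets_ir_index",
    "lipid_ratio_tg_hdl",
    "anthropometric_scaled_index",
    "inflammation_ratios",
    "compute_full_panel",
    "panel_frame",
]


class DomainError(ValueError):
    """An index is mathematically undefined for the given (non-missing) input."""


@dataclass(frozen=True)
class BiomarkerPanel:
    """The 17 derived indices for one subject; None marks a missing value."""

    bmi: float | None = None
    whtr: float | None = None
    tyg: float | None = None
    tyg_bmi: float | None = None
    tyg_wc: float | None = None
    tyg_whtr: float | None = None
    tg_hdl: float | None = None
    mets_ir: float | None = None
    chg: float | None = None
    chg_bmi: float | None = None
    chg_wc: float | None = None
    chg_whtr: float | None = None
    nlr: float | None = None
    mlr: float | None = None
    sii: float | None = None
    car: float | None = None
    npar: float | None = None


PANEL_FIELDS: tuple[str, ...] = tuple(f.name for f in dc_fields(BiomarkerPanel))


def anthropometric_indices(
    weight: float, height: float, wc: float
) -> tuple[float, float]:
    """BMI (kg/m^2) and waist-to-height ratio from weight, height (m), WC (cm)."""
    if not height > 0:
        raise DomainError(f"height must be > 0, got {height}")
    bmi = weight / (height * height)
    whtr = wc / (height * 100.0)
    return bmi, whtr


def tyg_index(tg: float, fpg: float) -> float:
    """Triglyceride-glucose index: Ln(TG * FPG / 2), inputs in mg/dL."""
    if not (tg > 0 and fpg > 0):
        raise DomainError(f"tyg requires tg > 0 and fpg > 0, got tg={tg}, fpg={fpg}")
    return math.log(tg * fpg / 2.0)


def chg_index(tc: float, fpg: float, hdl_c: float) -> float:
    """Cholesterol-HDL-glucose index: Ln(TC * FPG / (2 * HDL-c))."""
    if not (tc > 0 and fpg > 0 and hdl_c > 0):
        raise DomainError(
            f"chg requires positive inputs, got tc={tc}, fpg={fpg}, hdl_c={hdl_c}"
        )
    return math.log((tc * fpg) / (2.0 * hdl_c))


def mets_ir_index(fpg: float, tg: float, bmi: float, hdl_c: float) -> float:
    """Metabolic score for insulin resistance: Ln(2*FPG + TG) * BMI / Ln(HDL-c)."""
    if not 2.0 * fpg + tg > 0:
        raise DomainError("mets_ir requires 2*fpg + tg > 0")
    if not hdl_c > 1.0:
        raise DomainError(
            f"mets_ir requires hdl_c > 1 (positive log denominator), got {hdl_c}"
        )
    return math.log(2.0 * fpg + tg) * bmi / math.log(hdl_c)


def lipid_ratio_tg_hdl(tg: float, hdl_c: float) -> float:
    """Triglyceride to HDL-cholesterol ratio (both mg/dL)."""
    if not hdl_c > 0:
        raise DomainError(f"tg_hdl requires hdl_c > 0, got {hdl_c}")
    return tg / hdl_c


def anthropometric_scaled_index(base: float, scale: float) -> float:
    """An Ln-scale index multiplied by an anthropometric measure (BMI/WC/WHtR)."""
    if not (math.isfinite(base) and math.isfinite(scale)):
        raise DomainError("base and scale must be finite")
    return base * scale


def inflammation_ratios(
    neutrophils: float,
    lymphocytes: float,
    monocytes: float,
    platelets: float,
    neutrophil_pct: float,
    crp: float,
    albumin_g_dl: float,
) -> tuple[float, float, float, float, float]:
    """NLR, MLR, SII, CAR and NPAR from blood count, CRP and albumin.

    Counts in 10^3 cells/uL; CRP in mg/L; albumin in g/dL (converted to g/L
    for CAR).  SII stays on the 10^3 cells/uL scale of its inputs.
    """
    if not lymphocytes > 0:
        raise DomainError(f"nlr/mlr/sii require lymphocytes > 0, got {lymphocytes}")
    if not albumin_g_dl > 0:
        raise DomainError(f"car/npar require albumin > 0, got {albumin_g_dl}")
    nlr = neutrophils / lymphocytes
    mlr = monocytes / lymphocytes
    sii = platelets * nlr
    car = crp / (albumin_g_dl * 10.0)  # g/dL -> g/L
    npar = neutrophil_pct * 100.0 / albumin_g_dl
    return nlr, mlr, sii, car, npar


def _present(*values: float | None) -> bool:
    return all(
        v is not None and not (isinstance(v, float) and math.isnan(v))
        for v in values
    )


def compute_full_panel(record: SubjectRecord) -> BiomarkerPanel:
    """Compute every derivable index for one subject.

    Each index is computed exactly when all of its raw inputs are present;
    a missing input leaves only its dependent indices missing.
    """
    r = record
    out: dict[str, float | None] = {k: None for k in PANEL_FIELDS}

    if _present(r.weight, r.height, r.wc):
        out["bmi"], out["whtr"] = anthropometric_indices(r.weight, r.height, r.wc)

    if _present(r.tg, r.fpg):
        out["tyg"] = tyg_index(r.tg, r.fpg)
        if out["bmi"] is not None:
            out["tyg_bmi"] = anthropometric_scaled_index(out["tyg"], out["bmi"])
        if _present(r.wc):
            out["tyg_wc"] = anthropometric_scaled_index(out["tyg"], r.wc)
        if out["whtr"] is not None:
            out["tyg_whtr"] = anthropometric_scaled_index(out["tyg"], out["whtr"])

    if _present(r.tg, r.hdl_c):
        out["tg_hdl"] = lipid_ratio_tg_hdl(r.tg, r.hdl_c)

    if _present(r.fpg, r.tg, r.hdl_c) and out["bmi"] is not None:
        out["mets_ir"] = mets_ir_index(r.fpg, r.tg, out["bmi"], r.hdl_c)

    if _present(r.tc, r.fpg, r.hdl_c):
        out["chg"] = chg_index(r.tc, r.fpg, r.hdl_c)
        if out["bmi"] is not None:
            out["chg_bmi"] = anthropometric_scaled_index(out["chg"], out["bmi"])
        if _present(r.wc):
            out["chg_wc"] = anthropometric_scaled_index(out["chg"], r.wc)
        if out["whtr"] is not None:
            out["chg_whtr"] = anthropometric_scaled_index(out["chg"], out["whtr"])

    if _present(r.neutrophils, r.lymphocytes, r.monocytes, r.platelets,
                r.neutrophil_pct, r.crp, r.albumin_g_dl):
        (out["nlr"], out["mlr"], out["sii"], out["car"], out["npar"]) = (
            inflammation_ratios(
                r.neutrophils, r.lymphocytes, r.monocytes, r.platelets,
                r.neutrophil_pct, r.crp, r.albumin_g_dl,
            )
        )
    return BiomarkerPanel(**out)


def panel_frame(cohort: Cohort | Iterable[SubjectRecord]) -> pd.DataFrame:
    """Panel for every subject as a DataFrame keyed by subject_id.

    Suitable for CSV export (one row per subject, one column per index).
    """
    rows = []
    for rec in cohort:
        panel = compute_full_panel(rec)
        row: dict[str, object] = {"subject_id": rec.subject_id}
        row.update({k: getattr(panel, k) for k in PANEL_FIELDS})
        rows.append(row)
    return pd.DataFrame(rows, columns=["subject_id", *PANEL_FIELDS])
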