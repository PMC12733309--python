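"""Synthetic cohort generator emulating a hospitalized type 2 diabetes population.

No individual-level data are available for the population this package was
designed around, so every pipeline stage is exercised on synthetic cohorts
whose statistical structure mirrors the published group summaries:

* right-skewed labs are modelled lognormal, with the two parameters solved in
  closed form from a target median ``m`` and IQR width ``w``
  (``sigma = asinh(w / 2m) / z_{0.75}``, ``mu = ln m``);
* symmetric variables (age, albumin, height, neutrophil percentage) are
  normal;
* outcome labels come from a latent-risk construction: a standard-normal
  duration latent ``z`` plus independent noise,
  ``risk = w * z + sqrt(1 - w^2) * eps``, with the top ``round(n * prevalence)``
  risks labelled positive — so diabetes duration separates both outcomes
  strongly, and the separation strength is one interpretable weight per
  outcome;
* group differences are encoded as multiplicative (lognormal) or additive
  (normal) shifts applied to the complication-negative group, oriented and
  sized from the published group medians/means;
* ankle-brachial index and Toronto components are generated consistently
  with the assigned labels, so re-deriving labels from the generated clinical
  fields reproduces them exactly;
* derived indices are never sampled — downstream panels must be computed
  from the generated raw fields.

Raw labs share a Gaussian copula with weak positive correlation (0.3) inside
the glycemic/lipid block; between-biomarker correlations are otherwise not
published and default to independence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .cohort import Cohort, SubjectRecord
from .classify import (
    TorontoAssessment,
    classify_dpn_from_toronto,
    classify_pad_from_abi,
    toronto_score,
)

__all__ = [
    "Marginal",
    "GeneratorConfig",
    "default_generator_config",
    "generate_cohort",
]

_Z75 = 0.6744897501960817  # standard normal 75th percentile


@dataclass(frozen=True)
class Marginal:
    """One variable's marginal law plus its between-group shift.

    ``kind="lognormal"``: ``median``/``iqr`` describe the complication-positive
    group; negatives are multiplied by ``neg_ratio``.  ``kind="normal"``:
    ``mean``/``sd`` describe the positive group; negatives are shifted by
    ``neg_shift``.  ``effect_outcome`` names which outcome drives the shift
    (None for no group difference).  ``decimals`` is the recording precision;
    ``lo``/``hi`` clip to the physiologically meaningful range.
    """

    kind: str
    median: float = 0.0
    iqr: float = 0.0
    mean: float = 0.0
    sd: float = 1.0
    effect_outcome: str | None = None
    neg_ratio: float = 1.0
    neg_shift: float = 0.0
    decimals: int = 2
    lo: float | None = None
    hi: float | None = None

    def lognormal_params(self) -> tuple[float, float]:
        if self.kind != "lognormal":
            raise ValueError("lognormal_params on a non-lognormal marginal")
        if self.median <= 0 or self.iqr <= 0:
            raise ValueError("lognormal marginal needs median > 0 and iqr > 0")
        sigma = math.asinh(self.iqr / (2.0 * self.median)) / _Z75
        return math.log(self.median), sigma


def _table_marginals() -> dict[str, Marginal]:
    """Default marginals calibrated to the published group summaries."""
    ln = "lognormal"
    return {
        # glycemic / lipid block (PAD-oriented shifts)
        "fpg": Marginal(ln, 230.0, 129.0, effect_outcome="pad", neg_ratio=153.0 / 230.0),
        "hba1c": Marginal(ln, 8.9, 3.0, effect_outcome="pad", neg_ratio=6.6 / 8.9, decimals=1),
        "tc": Marginal(ln, 176.0, 68.0, effect_outcome="pad", neg_ratio=216.5 / 176.0),
        "hdl_c": Marginal(ln, 42.0, 16.0, effect_outcome="pad", neg_ratio=36.0 / 42.0, lo=5.0),
        "ldl_c": Marginal(ln, 87.8, 39.8, effect_outcome="pad", neg_ratio=108.2 / 87.8),
        "tg": Marginal(ln, 171.0, 142.0, effect_outcome="pad", neg_ratio=139.5 / 171.0),
        # inflammation assays
        "il6": Marginal(ln, 8.71, 7.10, effect_outcome="pad", neg_ratio=7.29 / 8.71),
        "ferritin": Marginal(ln, 178.0, 101.0, effect_outcome="pad", neg_ratio=207.0 / 178.0),
        "esr": Marginal(ln, 34.0, 44.0, effect_outcome="pad", neg_ratio=26.5 / 34.0, decimals=0),
        "fibrinogen": Marginal(ln, 354.5, 147.0, effect_outcome="pad", neg_ratio=333.0 / 354.5),
        "fgf1": Marginal(ln, 574.38, 101.01, effect_outcome="pad", neg_ratio=532.82 / 574.38),
        "mmp1": Marginal(ln, 1541.82, 789.73, effect_outcome="pad", neg_ratio=1309.67 / 1541.82),
        "tnf_alpha": Marginal(ln, 77.03, 30.64, effect_outcome="dpn", neg_ratio=69.12 / 77.03),
        "crp": Marginal(ln, 0.60, 0.54, effect_outcome="dpn", neg_ratio=0.41 / 0.60),
        # blood count (10^3 cells/uL); platelets carry the SII group difference,
        # monocytes the MLR one
        "neutrophils": Marginal(ln, 4.0, 1.6),
        "lymphocytes": Marginal(ln, 2.0, 0.8, lo=0.3),
        "monocytes": Marginal(ln, 0.44, 0.20, effect_outcome="dpn", neg_ratio=0.38 / 0.44),
        "platelets": Marginal(ln, 258.0, 126.0, effect_outcome="pad", neg_ratio=357.0 / 517.0, decimals=0, lo=30.0),
        # anthropometrics / demographics / chemistry
        "wc": Marginal(ln, 104.0, 18.0, effect_outcome="pad", neg_ratio=103.5 / 104.0, decimals=0),
        "bmi": Marginal(ln, 32.0, 8.0, effect_outcome="pad", neg_ratio=31.0 / 32.0, decimals=1),
        "age": Marginal("normal", mean=63.88, sd=9.8, effect_outcome="pad",
                        neg_shift=54.14 - 63.88, decimals=0, lo=19.0, hi=95.0),
        "height": Marginal("normal", mean=1.70, sd=0.09, lo=1.40, hi=2.05),
        "neutrophil_pct": Marginal("normal", mean=55.0, sd=7.0, decimals=1, lo=5.0, hi=95.0),
        "albumin_g_dl": Marginal("normal", mean=4.3, sd=0.35, decimals=2, lo=2.0, hi=5.5),
    }


#: glycemic/lipid variables sharing weak positive copula correlation
_CORR_BLOCK = ("fpg", "hba1c", "tg", "tc", "ldl_c", "hdl_c")


@dataclass(frozen=True)
class GeneratorConfig:
    """Full specification of one synthetic cohort draw.

    ``pad_separation``/``dpn_separation`` are the latent weights w in
    [0, 1): the correlation between the duration latent and each outcome's
    latent risk.  At 0 the labels are independent of every lab (null cohort).
    """

    seed: int
    n_subjects: int = 110
    pad_prevalence: float = 82.0 / 110.0
    dpn_prevalence: float = 92.0 / 110.0
    marginals: Mapping[str, Marginal] = field(default_factory=_table_marginals)
    pad_separation: float = 0.80
    dpn_separation: float = 0.97
    # duration ~ round(exp(mu + sigma z)): pos-group median ~15 y, neg ~4 y
    duration_log_mu: float = 2.42
    duration_log_sigma: float = 0.90
    block_correlation: float = 0.3
    male_rate_pad_pos: float = 0.512
    male_rate_pad_neg: float = 0.643
    abi_range_pos: tuple[float, float] = (0.40, 0.89)
    abi_range_neg: tuple[float, float] = (0.95, 1.30)

    def __post_init__(self) -> None:
        if not 0 < self.pad_prevalence < 1 or not 0 < self.dpn_prevalence < 1:
            raise ValueError("prevalences must lie in (0, 1)")
        for w in (self.pad_separation, self.dpn_separation):
            if not 0.0 <= w < 1.0:
                raise ValueError("separation weights must lie in [0, 1)")
        if not -1.0 < self.block_correlation < 1.0:
            raise ValueError("block correlation must lie in (-1, 1)")


def default_generator_config(
    seed: int,
    n_subjects: int = 110,
    null_effects: bool = False,
) -> GeneratorConfig:
    """The study-population configuration, or its no-effect null counterpart.

    ``null_effects=True`` removes every between-group shift and decouples the
    labels from all labs (labels become pure coin flips at the configured
    prevalences) — the null cohort used for p-value calibration checks.
    """
    cfg = GeneratorConfig(seed=seed, n_subjects=n_subjects)
    if not null_effects:
        return cfg
    nulled = {
        name: replace(m, neg_ratio=1.0, neg_shift=0.0)
        for name, m in cfg.marginals.items()
    }
    return replace(
        cfg,
        marginals=nulled,
        pad_separation=0.0,
        dpn_separation=0.0,
        male_rate_pad_neg=cfg.male_rate_pad_pos,
    )


def _copula_draw(rng: np.random.Generator, names: list[str],
                 n: int, rho: float) -> dict[str, np.ndarray]:
    """Standard-normal draws, correlated rho within the glycemic/lipid block."""
    k = len(names)
    corr = np.eye(k)
    idx = [i for i, nm in enumerate(names) if nm in _CORR_BLOCK]
    for i in idx:
        for j in idx:
            if i != j:
                corr[i, j] = rho
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise ValueError("correlation matrix is not positive definite") from exc
    z = rng.standard_normal((n, k)) @ chol.T
    return {nm: z[:, i] for i, nm in enumerate(names)}


def _toronto_components(
    rng: np.random.Generator, target_total: int
) -> tuple[int, int, int]:
    """Random (symptoms, failed tests, reflex points) summing to target_total.

    Caps: symptoms <= 6, failed sensory tests <= 5, reflex points <= 4
    (patellar + Achilles, each graded 0/1/2).
    """
    lo_reflex = max(0, target_total - 11)
    reflex = int(rng.integers(lo_reflex, min(4, target_total) + 1))
    rem = target_total - reflex
    lo_failed = max(0, rem - 6)
    failed = int(rng.integers(lo_failed, min(5, rem) + 1))
    symptoms = rem - failed
    return symptoms, failed, reflex


def generate_cohort(config: GeneratorConfig) -> Cohort:
    """Draw one cohort from the configured joint law.

    Deterministic given the config (NumPy PCG64 stream seeded from
    ``config.seed``).  Group sizes are exact: ``round(n * prevalence)``
    subjects are labelled positive for each outcome.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    names = list(config.marginals)

    # latent duration + outcome labels
    z_dur = rng.standard_normal(n)
    eps_pad = rng.standard_normal(n)
    eps_dpn = rng.standard_normal(n)
    w_p, w_d = config.pad_separation, config.dpn_separation
    risk_pad = w_p * z_dur + math.sqrt(1.0 - w_p * w_p) * eps_pad
    risk_dpn = w_d * z_dur + math.sqrt(1.0 - w_d * w_d) * eps_dpn
    k_pad = int(round(n * config.pad_prevalence))
    k_dpn = int(round(n * config.dpn_prevalence))
    pad_pos = np.zeros(n, dtype=bool)
    dpn_pos = np.zeros(n, dtype=bool)
    pad_pos[np.argsort(risk_pad)[n - k_pad:]] = True
    dpn_pos[np.argsort(risk_dpn)[n - k_dpn:]] = True

    duration = np.rint(
        np.exp(config.duration_log_mu + config.duration_log_sigma * z_dur)
    )

    z = _copula_draw(rng, names, n, config.block_correlation)
    values: dict[str, np.ndarray] = {}
    for nm in names:
        m = config.marginals[nm]
        group_neg = ~pad_pos if m.effect_outcome == "pad" else ~dpn_pos
        if m.kind == "lognormal":
            mu, sigma = m.lognormal_params()
            v = np.exp(mu + sigma * z[nm])
            if m.effect_outcome is not None:
                v = np.where(group_neg, v * m.neg_ratio, v)
        elif m.kind == "normal":
            v = m.mean + m.sd * z[nm]
            if m.effect_outcome is not None:
                v = np.where(group_neg, v + m.neg_shift, v)
        else:
            raise ValueError(f"unknown marginal kind {m.kind!r} for {nm}")
        if m.lo is not None:
            v = np.maximum(v, m.lo)
        if m.hi is not None:
            v = np.minimum(v, m.hi)
        values[nm] = np.round(v, m.decimals)

    height = values.pop("height")
    bmi = values.pop("bmi")
    weight = np.round(bmi * height * height, 1)

    # clinical fields consistent with the assigned labels
    lo_p, hi_p = config.abi_range_pos
    lo_n, hi_n = config.abi_range_neg
    abi = np.where(
        pad_pos,
        rng.uniform(lo_p, hi_p, n),
        rng.uniform(lo_n, hi_n, n),
    )
    abi = np.round(abi, 2)

    male_prob = np.where(pad_pos, config.male_rate_pad_pos, config.male_rate_pad_neg)
    male = rng.uniform(size=n) < male_prob

    records: list[SubjectRecord] = []
    for i in range(n):
        target = int(rng.integers(7, 16)) if dpn_pos[i] else int(rng.integers(0, 7))
        symptoms, failed, reflex = _toronto_components(rng, target)
        assessment = TorontoAssessment(symptoms, failed, reflex)
        rec = SubjectRecord(
            subject_id=f"S{i + 1:04d}",
            gender="male" if male[i] else "female",
            age=float(values["age"][i]),
            dm_duration=float(duration[i]),
            weight=float(weight[i]),
            height=float(np.round(height[i], 2)),
            wc=float(values["wc"][i]),
            fpg=float(values["fpg"][i]),
            hba1c=float(values["hba1c"][i]),
            tc=float(values["tc"][i]),
            hdl_c=float(values["hdl_c"][i]),
            ldl_c=float(values["ldl_c"][i]),
            tg=float(values["tg"][i]),
            ferritin=float(values["ferritin"][i]),
            esr=float(values["esr"][i]),
            crp=float(values["crp"][i]),
            fibrinogen=float(values["fibrinogen"][i]),
            tnf_alpha=float(values["tnf_alpha"][i]),
            il6=float(values["il6"][i]),
            fgf1=float(values["fgf1"][i]),
            mmp1=float(values["mmp1"][i]),
            neutrophils=float(values["neutrophils"][i]),
            lymphocytes=float(values["lymphocytes"][i]),
            monocytes=float(values["monocytes"][i]),
            platelets=float(values["platelets"][i]),
            neutrophil_pct=float(values["neutrophil_pct"][i]),
            albumin_g_dl=float(values["albumin_g_dl"][i]),
            abi=float(abi[i]),
            toronto_symptoms=float(symptoms),
            toronto_failed_tests=float(failed),
            toronto_reflex_points=float(reflex),
        )
        rec.pad_label = classify_pad_from_abi(rec.abi)
        rec.dpn_label = classify_dpn_from_toronto(toronto_score(assessment))
        records.append(rec)
    return Cohort(records=records, provenance=f"synthetic(seed={config.seed})")
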