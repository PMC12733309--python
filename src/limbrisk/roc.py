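"""ROC curves, nonparametric AUROC with Hanley-McNeil inference, Youden cut-offs.

The area under the ROC curve is computed nonparametrically as the
Mann-Whitney probability that a randomly chosen positive subject scores above
a randomly chosen negative one, with ties counted half:

    AUROC = ( #{(i,j): s_i > s_j} + 0.5 * #{(i,j): s_i = s_j} ) / (n+ * n-)

over all positive/negative pairs (i, j).  Its standard error follows the
Hanley-McNeil exponential approximation

    SE^2 = [ A(1-A) + (n+ - 1)(Q1 - A^2) + (n- - 1)(Q2 - A^2) ] / (n+ n-),
    Q1 = A / (2 - A),   Q2 = 2 A^2 / (1 + A),

the 95% CI is the normal approximation A +/- 1.96 SE truncated to [0, 1], and
the p-value tests A = 0.5 with z = (A - 0.5)/SE, two-sided.

Candidate thresholds are the midpoints between consecutive distinct sorted
score values, plus a sentinel below the minimum and above the maximum, with
positivity defined as score >= threshold (every biomarker here is elevated in
the affected group; a ``direction`` flag inverts scores for markers oriented
the other way).  For integer-valued scores this yields the half-integer
cut-offs familiar from clinical ROC tables.  The Youden-optimal cut-off
maximises J = sensitivity + specificity - 1, ties broken toward the smallest
threshold (which maximises sensitivity at equal J).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "RocCurve",
    "RocInference",
    "RocResult",
    "auroc_mann_whitney",
    "auroc_inference",
    "roc_curve",
    "youden_optimal_cutoff",
    "roc_analysis",
    "plot_roc",
]


class SingleClassError(ValueError):
    """Both label classes are required for any ROC computation."""


@dataclass(frozen=True)
class RocCurve:
    """Sensitivity/specificity over the candidate threshold grid.

    ``thresholds`` ascend; positivity is score >= threshold, so sensitivity
    is nonincreasing and specificity nondecreasing along the grid.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    n_pos: int
    n_neg: int


@dataclass(frozen=True)
class RocInference:
    se: float
    ci95: tuple[float, float]
    p_value: float
    degenerate: bool  # zero SE away from the null value


@dataclass(frozen=True)
class RocResult:
    """One row of a clinical ROC table."""

    auroc: float
    se: float
    ci95: tuple[float, float]
    p_value: float
    cutoff: float
    sensitivity_at_cutoff: float  # percent
    specificity_at_cutoff: float  # percent
    n_pos: int
    n_neg: int
    degenerate: bool = False


def _check_labels(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pos = labels.astype(bool)
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise SingleClassError("need at least one positive and one negative label")
    return pos, ~pos


def auroc_mann_whitney(scores, labels) -> float:
    """AUROC as the tie-adjusted Mann-Whitney probability.

    Computed through midranks (equivalent to pairwise counting with half
    credit for ties, but O(n log n)).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pos, neg = _check_labels(y)
    ranks = stats.rankdata(s)
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def auroc_inference(area: float, n_pos: int, n_neg: int) -> RocInference:
    """Hanley-McNeil SE, normal-approximation 95% CI and two-sided p vs 0.5."""
    if not 0.0 <= area <= 1.0:
        raise ValueError(f"area must lie in [0, 1], got {area}")
    if n_pos < 1 or n_neg < 1:
        raise ValueError("n_pos and n_neg must be >= 1")
    a2 = area * area
    q1 = area / (2.0 - area)
    q2 = 2.0 * a2 / (1.0 + area)
    var = (
        area * (1.0 - area)
        + (n_pos - 1) * (q1 - a2)
        + (n_neg - 1) * (q2 - a2)
    ) / (n_pos * n_neg)
    se = math.sqrt(max(var, 0.0))
    if se == 0.0:
        degenerate = area != 0.5
        p = 1.0 if area == 0.5 else 0.0
        return RocInference(0.0, (area, area), p, degenerate)
    lo = max(0.0, area - 1.96 * se)
    hi = min(1.0, area + 1.96 * se)
    z = (area - 0.5) / se
    p = 2.0 * stats.norm.sf(abs(z))
    return RocInference(se, (lo, hi), float(min(p, 1.0)), False)


def roc_curve(scores, labels, direction: str = "higher-positive") -> RocCurve:
    """Build the ROC curve over midpoint candidate thresholds.

    ``direction="higher-positive"`` (default) treats larger scores as more
    disease-like; ``"lower-positive"`` negates the scores first.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if direction == "lower-positive":
        s = -s
    elif direction != "higher-positive":
        raise ValueError("direction must be 'higher-positive' or 'lower-positive'")
    pos, neg = _check_labels(y)
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    distinct = np.unique(s)
    if distinct.size == 1:
        thresholds = np.array([distinct[0] - 0.5, distinct[0] + 0.5])
    else:
        mids = (distinct[:-1] + distinct[1:]) / 2.0
        thresholds = np.concatenate(
            [[distinct[0] - 0.5], mids, [distinct[-1] + 0.5]]
        )
    sens = np.empty(thresholds.size)
    spec = np.empty(thresholds.size)
    s_pos, s_neg = s[pos], s[neg]
    for k, t in enumerate(thresholds):
        sens[k] = np.count_nonzero(s_pos >= t) / n_pos
        spec[k] = np.count_nonzero(s_neg < t) / n_neg
    return RocCurve(thresholds, sens, spec, n_pos, n_neg)


def youden_optimal_cutoff(curve: RocCurve) -> tuple[float, float, float]:
    """Threshold maximising J = sensitivity + specificity - 1 (ties -> smallest).

    Returns ``(cutoff, sensitivity, specificity)`` as proportions.
    """
    # exact integer arithmetic so that genuine J ties are broken by threshold,
    # not by floating-point noise: J ranks as TP*n_neg + TN*n_pos
    tp = np.rint(curve.sensitivity * curve.n_pos).astype(np.int64)
    tn = np.rint(curve.specificity * curve.n_neg).astype(np.int64)
    j_scaled = tp * curve.n_neg + tn * curve.n_pos
    best = int(np.argmax(j_scaled))  # first (smallest threshold) on ties
    return (
        float(curve.thresholds[best]),
        float(curve.sensitivity[best]),
        float(curve.specificity[best]),
    )


def trapezoidal_area(curve: RocCurve) -> float:
    """Area under the curve in (1-specificity, sensitivity) coordinates.

    Thresholds ascend, so reversing the stored arrays walks the ROC polygon
    from (0, 0) to (1, 1) with both coordinates nondecreasing.
    """
    fpr = (1.0 - curve.specificity)[::-1]
    return float(np.trapezoid(curve.sensitivity[::-1], fpr))


def roc_analysis(scores, labels, direction: str = "higher-positive") -> RocResult:
    """Full ROC summary: AUROC, Hanley-McNeil SE/CI/p, Youden cut-off."""
    s = np.asarray(scores, dtype=float)
    if direction == "lower-positive":
        s = -s
    curve = roc_curve(s, labels)
    area = auroc_mann_whitney(s, labels)
    inf = auroc_inference(area, curve.n_pos, curve.n_neg)
    cutoff, sens, spec = youden_optimal_cutoff(curve)
    if direction == "lower-positive":
        cutoff = -cutoff
    return RocResult(
        auroc=area,
        se=inf.se,
        ci95=inf.ci95,
        p_value=inf.p_value,
        cutoff=cutoff,
        sensitivity_at_cutoff=100.0 * sens,
        specificity_at_cutoff=100.0 * spec,
        n_pos=curve.n_pos,
        n_neg=curve.n_neg,
        degenerate=inf.degenerate,
    )


def plot_roc(curve: RocCurve, path=None, title: str = "ROC curve"):
    """Render the ROC curve (blue) with the reference diagonal (red).

    Requires matplotlib; returns the figure, optionally saving it to ``path``.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fpr = (1.0 - curve.specificity)[::-1]
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot([0, 1], [0, 1], color="red", lw=1, label="Reference line")
    ax.plot(fpr, curve.sensitivity[::-1], color="blue", lw=1.5,
            label="ROC curve")
    ax.set_xlabel("1 - Specificity")
    ax.set_ylabel("Sensitivity")
    ax.set_title(title)
    ax.legend(loc="lower right")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
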