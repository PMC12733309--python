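"""Normality-routed two-group comparisons and comparison-table generation.

The descriptive/inferential layer works the way the underlying clinical
analysis was run: each continuous variable is first tested for normality with
a one-sample Kolmogorov-Smirnov test against a normal law with the sample's
own mean and SD (Lilliefors correction available by configuration).  Variables
Gaussian in both groups are summarised as mean +/- SD and compared with
Student's t test; anything else is summarised as median (IQR) and compared
with the Mann-Whitney U test.  Categorical variables use Pearson's chi-square
on a 2x2 table without continuity correction.  No multiple-testing correction
is applied: the comparisons are exploratory by design.

The Mann-Whitney p-value is exact (full enumeration of the permutation
distribution of U, valid with ties) whenever the combined sample size is at
most ``EXACT_MWU_MAX_N``; larger samples use the tie-corrected normal
approximation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "NormalityResult",
    "ComparisonResult",
    "ContingencyTable2x2",
    "DegenerateSampleError",
    "assess_normality",
    "summarize_variable",
    "compare_continuous",
    "mann_whitney_u",
    "compare_categorical_2x2",
    "build_comparison_table",
    "EXACT_MWU_MAX_N",
]

#: combined-sample-size bound below which the Mann-Whitney p is exact
EXACT_MWU_MAX_N = 12

GAUSSIAN_ALPHA = 0.05  # KS p at or above this routes to the Gaussian summary


class DegenerateSampleError(ValueError):
    """A sample is empty, constant, or otherwise unusable for the test."""


@dataclass(frozen=True)
class NormalityResult:
    statistic: float
    p_value: float
    is_gaussian: bool


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of one two-group comparison."""

    variable: str
    group_labels: tuple[str, str]
    summaries: tuple[str, str]
    test_used: str  # "student_t" | "mann_whitney_u" | "chi_square"
    statistic: float
    p_value: float
    n_per_group: tuple[int, int]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 table of non-negative integer counts."""

    counts: tuple[tuple[int, int], tuple[int, int]]
    row_labels: tuple[str, str] = ("row0", "row1")
    col_labels: tuple[str, str] = ("col0", "col1")

    def __post_init__(self) -> None:
        flat = [c for row in self.counts for c in row]
        if any(c < 0 for c in flat):
            raise ValueError("counts must be non-negative")
        if sum(flat) == 0:
            raise ValueError("grand total must be positive")


def assess_normality(values: Sequence[float], method: str = "ks") -> NormalityResult:
    """Test a sample for normality.

    ``method="ks"`` (default) is the classical one-sample Kolmogorov-Smirnov
    test against a normal distribution with the sample's estimated mean and
    SD; ``method="lilliefors"`` applies the Lilliefors small-sample
    correction for the estimated parameters.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 4:
        raise DegenerateSampleError(f"need at least 4 values, got {x.size}")
    sd = x.std(ddof=1)
    if sd == 0:
        raise DegenerateSampleError("constant sample: normality is undefined")
    if method == "ks":
        stat, p = stats.kstest(x, "norm", args=(x.mean(), sd))
    elif method == "lilliefors":
        from statsmodels.stats.diagnostic import lilliefors

        stat, p = lilliefors(x, dist="norm")
    else:
        raise ValueError("method must be 'ks' or 'lilliefors'")
    return NormalityResult(float(stat), float(p), bool(p >= GAUSSIAN_ALPHA))


def _quantile(x: np.ndarray, q: float, method: str) -> float:
    if method == "linear":
        return float(np.quantile(x, q, method="linear"))
    if method == "weighted_average":
        # (n+1)-based convention common in menu-driven statistics software
        return float(np.quantile(x, q, method="weibull"))
    raise ValueError("quartile method must be 'linear' or 'weighted_average'")


def summarize_variable(
    values: Sequence[float],
    is_gaussian: bool,
    decimals: int = 2,
    quartile_method: str = "linear",
) -> str:
    """Format a sample as ``mean +/- SD`` (Gaussian) or ``median (IQR)``.

    SD uses the n-1 denominator; IQR is the single width Q3 - Q1.  A single
    observation reports an SD of 0.00.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size == 0:
        raise DegenerateSampleError("cannot summarize an empty sample")
    if is_gaussian:
        sd = x.std(ddof=1) if x.size > 1 else 0.0
        return f"{x.mean():.{decimals}f} ± {sd:.{decimals}f}"
    q1 = _quantile(x, 0.25, quartile_method)
    q3 = _quantile(x, 0.75, quartile_method)
    return f"{np.median(x):.{decimals}f} ({q3 - q1:.{decimals}f})"


def _exact_mwu(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by enumerating all group assignments.

    Valid with ties: ranks are midranks of the observed pooled sample, and
    the permutation distribution of U is built over every way of choosing
    which pooled positions form group a.  Two-sided p sums the probability
    of |U - mean| at least as large as observed.
    """
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n_a, n_b = len(a), len(b)
    n = n_a + n_b
    u_obs = ranks[:n_a].sum() - n_a * (n_a + 1) / 2.0
    mean_u = n_a * n_b / 2.0
    dev_obs = abs(u_obs - mean_u)
    total = math.comb(n, n_a)
    hits = 0
    base = n_a * (n_a + 1) / 2.0
    for idx in itertools.combinations(range(n), n_a):
        u = ranks[list(idx)].sum() - base
        if abs(u - mean_u) >= dev_obs - 1e-12:
            hits += 1
    return float(u_obs), hits / total


def mann_whitney_u(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U statistic (of group a) and p-value.

    Exact permutation p (valid with ties) when the combined sample size is at
    most :data:`EXACT_MWU_MAX_N`, tie-corrected normal approximation above.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size + b.size <= EXACT_MWU_MAX_N:
        return _exact_mwu(a, b)
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def compare_continuous(
    group_a: Sequence[float],
    group_b: Sequence[float],
    group_labels: tuple[str, str] = ("group_a", "group_b"),
    variable: str = "",
    normality_method: str = "ks",
    quartile_method: str = "linear",
) -> ComparisonResult:
    """Compare a continuous variable between two groups.

    Routing is a pure function of the per-group normality outcomes: both
    Gaussian -> two-sided Student's t (equal variances, matching the
    mean-comparison usage); otherwise -> two-sided Mann-Whitney U (exact for
    small combined samples, tie-corrected normal approximation otherwise).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    for label, x in zip(group_labels, (a, b)):
        if x.size < 2:
            raise DegenerateSampleError(f"group {label}: need at least 2 values")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        raise DegenerateSampleError(
            f"groups {group_labels[0]} and {group_labels[1]} are constant "
            "and identical; no comparison is defined"
        )

    def _gaussian(x: np.ndarray) -> bool:
        try:
            return assess_normality(x, method=normality_method).is_gaussian
        except DegenerateSampleError:
            return False

    both_gaussian = _gaussian(a) and _gaussian(b)
    if both_gaussian:
        res = stats.ttest_ind(a, b, equal_var=True)
        stat, p = float(res.statistic), float(res.pvalue)
        test = "student_t"
    else:
        stat, p = mann_whitney_u(a, b)
        test = "mann_whitney_u"
    summaries = (
        summarize_variable(a, both_gaussian, quartile_method=quartile_method),
        summarize_variable(b, both_gaussian, quartile_method=quartile_method),
    )
    return ComparisonResult(
        variable=variable,
        group_labels=group_labels,
        summaries=summaries,
        test_used=test,
        statistic=stat,
        p_value=min(p, 1.0),
        n_per_group=(int(a.size), int(b.size)),
    )


def compare_categorical_2x2(
    table: ContingencyTable2x2, variable: str = ""
) -> ComparisonResult:
    """Pearson chi-square on a 2x2 table, df=1, no continuity correction."""
    counts = np.asarray(table.counts, dtype=float)
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise DegenerateSampleError("zero margin in 2x2 table")
    chi2, p, _, _ = stats.chi2_contingency(counts, correction=False)
    col_tot = counts.sum(axis=0)
    pct = counts / col_tot * 100.0
    summaries = (
        f"{table.row_labels[0]} {pct[0, 0]:.1f}% / {table.row_labels[1]} {pct[1, 0]:.1f}%",
        f"{table.row_labels[0]} {pct[0, 1]:.1f}% / {table.row_labels[1]} {pct[1, 1]:.1f}%",
    )
    return ComparisonResult(
        variable=variable,
        group_labels=table.col_labels,
        summaries=summaries,
        test_used="chi_square",
        statistic=float(chi2),
        p_value=float(p),
        n_per_group=(int(col_tot[0]), int(col_tot[1])),
    )


def build_comparison_table(
    data: pd.DataFrame,
    outcome: str,
    variables: Iterable[str],
    categorical: Iterable[str] = ("gender",),
    normality_method: str = "ks",
    quartile_method: str = "linear",
) -> pd.DataFrame:
    """Per-variable two-group comparison table for one outcome.

    ``data`` holds one row per subject; ``outcome`` names a column with
    values "positive"/"negative".  Subjects missing a variable are dropped
    for that row only, with per-row n reported.  Rows that cannot be
    computed (all-missing, degenerate) are kept and flagged.
    """
    if outcome not in data.columns:
        raise KeyError(f"outcome column {outcome!r} not in data")
    lab = data[outcome]
    neg = data[lab == "negative"]
    pos = data[lab == "positive"]
    if len(neg) == 0 or len(pos) == 0:
        raise DegenerateSampleError(f"outcome {outcome!r} has an empty group")
    categorical = set(categorical)
    rows = []
    for var in variables:
        entry: dict[str, object] = {"variable": var}
        try:
            if var in categorical:
                levels = sorted(data[var].dropna().unique())
                if len(levels) != 2:
                    raise DegenerateSampleError(
                        f"{var}: need exactly 2 levels, got {levels}"
                    )
                counts = tuple(
                    tuple(int((grp[var] == lev).sum()) for grp in (neg, pos))
                    for lev in levels
                )
                res = compare_categorical_2x2(
                    ContingencyTable2x2(
                        counts=counts,
                        row_labels=(str(levels[0]), str(levels[1])),
                        col_labels=("negative", "positive"),
                    ),
                    variable=var,
                )
            else:
                res = compare_continuous(
                    neg[var].astype(float).to_numpy(),
                    pos[var].astype(float).to_numpy(),
                    group_labels=("negative", "positive"),
                    variable=var,
                    normality_method=normality_method,
                    quartile_method=quartile_method,
                )
        except (DegenerateSampleError, KeyError, ValueError) as exc:
            entry.update(
                summary_negative="", summary_positive="", test="not computable",
                statistic=float("nan"), p_value=float("nan"),
                n_negative=0, n_positive=0, note=str(exc),
            )
            rows.append(entry)
            continue
        entry.update(
            summary_negative=res.summaries[0],
            summary_positive=res.summaries[1],
            test=res.test_used,
            statistic=res.statistic,
            p_value=res.p_value,
            n_negative=res.n_per_group[0],
            n_positive=res.n_per_group[1],
            note="",
        )
        rows.append(entry)
    return pd.DataFrame(rows)
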