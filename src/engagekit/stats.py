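"""Nonparametric cohort statistics.

The analysis this package reproduces treats engagement outcomes as
nonnormal (they fail Kolmogorov-Smirnov normality and have |skewness| > 1),
so group comparisons use rank tests throughout: Mann-Whitney U for two
groups, Kruskal-Wallis for three or more, and Spearman rank correlation for
associations. Summaries are medians with interquartile ranges.

The Mann-Whitney z is computed in-package (normal approximation with
tie-corrected variance and a continuity correction) because scipy does not
expose it; U is cross-checked against an exhaustive pair-count oracle in the
test suite. Kruskal-Wallis, Spearman, Kolmogorov-Smirnov and skewness
delegate to scipy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import CHARACTERISTICS
from .errors import DegenerateDistributionError, UndefinedInputError

__all__ = [
    "DistributionDiagnostics",
    "MedianIQR",
    "MannWhitneyResult",
    "KruskalWallisResult",
    "CorrelationResult",
    "GroupSummary",
    "CohortComparisonResult",
    "diagnose_distribution",
    "median_iqr",
    "mann_whitney",
    "kruskal_wallis",
    "spearman",
    "compare_by_characteristics",
]


@dataclass
class DistributionDiagnostics:
    """Normality diagnostics: one-sample KS against a fitted normal plus
    bias-corrected sample skewness. ``normality_flag`` is the joint criterion:
    KS not significant *and* |skewness| <= 1."""

    variable: str
    n: int
    ks_statistic: float
    ks_p: float
    skewness: float
    normality_flag: bool
    alpha: float = 0.05


@dataclass(frozen=True)
class MedianIQR:
    median: float
    q1: float
    q3: float

    @property
    def width(self) -> float:
        return self.q3 - self.q1


@dataclass(frozen=True)
class MannWhitneyResult:
    """U is the first group's statistic (#pairs a>b plus half the ties);
    ``u_min`` is the smaller of the two group statistics, the convention many
    statistical packages print (which makes their z always <= 0)."""

    u: float
    z: float
    p_value: float
    n_a: int
    n_b: int

    @property
    def u_min(self) -> float:
        return min(self.u, self.n_a * self.n_b - self.u)


@dataclass(frozen=True)
class KruskalWallisResult:
    h: float
    p_value: float
    df: int


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    n: int


def diagnose_distribution(values, variable: str = "x", alpha: float = 0.05) -> DistributionDiagnostics:
    """KS test against a normal with the sample's mean/SD, bias-corrected
    skewness, and the joint normality flag."""
    v = np.asarray(values, dtype=float)
    if v.size < 8:
        raise UndefinedInputError("diagnose_distribution requires n >= 8")
    sd = v.std(ddof=1)
    if sd == 0:
        raise DegenerateDistributionError(f"{variable!r} is constant; diagnostics undefined")
    ks = sps.kstest(v, "norm", args=(v.mean(), sd))
    skew = float(sps.skew(v, bias=False))
    flag = (ks.pvalue >= alpha) and (abs(skew) <= 1.0)
    return DistributionDiagnostics(
        variable=variable,
        n=int(v.size),
        ks_statistic=float(ks.statistic),
        ks_p=float(ks.pvalue),
        skewness=skew,
        normality_flag=bool(flag),
        alpha=alpha,
    )


def median_iqr(values) -> MedianIQR:
    """Median and quartiles by linear interpolation (the convention common to
    mainstream statistical packages, under which the monotone-transport
    property of odd-sized samples holds)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise UndefinedInputError("median_iqr requires at least one value")
    q1, med, q3 = np.percentile(v, [25, 50, 75], method="linear")
    return MedianIQR(median=float(med), q1=float(q1), q3=float(q3))


def mann_whitney(a, b) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    U is computed from mid-ranks (equal to the count of cross-pairs where the
    first group's value is larger, plus half the ties); z uses the normal
    approximation with tie-corrected variance and a continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise UndefinedInputError("mann_whitney requires both groups nonempty")
    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    r_a = ranks[:n_a].sum()
    u_a = r_a - n_a * (n_a + 1) / 2.0

    n = n_a + n_b
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum()
    mu = n_a * n_b / 2.0
    if n > 1:
        sigma2 = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    else:
        sigma2 = 0.0
    if sigma2 <= 0:
        return MannWhitneyResult(u=float(u_a), z=0.0, p_value=1.0, n_a=n_a, n_b=n_b)
    d = u_a - mu
    # continuity correction shrinks |d| by 1/2
    d_corr = d - 0.5 * np.sign(d) if d != 0 else 0.0
    z = d_corr / np.sqrt(sigma2)
    p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
    return MannWhitneyResult(u=float(u_a), z=float(z), p_value=float(p), n_a=n_a, n_b=n_b)


def kruskal_wallis(groups) -> KruskalWallisResult:
    """Tie-corrected Kruskal-Wallis H with a chi-squared (k-1 df) p-value.

    Requires at least three nonempty groups (use :func:`mann_whitney` for
    two). When every pooled observation is identical, H is 0 by convention.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 3:
        raise UndefinedInputError("kruskal_wallis requires >= 3 groups (use mann_whitney for 2)")
    if any(g.size == 0 for g in groups):
        raise UndefinedInputError("kruskal_wallis requires all groups nonempty")
    total_n = sum(g.size for g in groups)
    if total_n < 5:
        raise UndefinedInputError("kruskal_wallis requires total n >= 5")
    pooled = np.concatenate(groups)
    df = len(groups) - 1
    if np.all(pooled == pooled[0]):
        return KruskalWallisResult(h=0.0, p_value=1.0, df=df)
    h, p = sps.kruskal(*groups)
    return KruskalWallisResult(h=float(h), p_value=float(p), df=df)


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation with mid-ranks for ties; two-sided p via the
    t approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise UndefinedInputError("spearman requires paired samples of equal length")
    if x.size < 3:
        raise UndefinedInputError("spearman requires n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedInputError("spearman is undefined for a constant variable")
    res = sps.spearmanr(x, y)
    return CorrelationResult(rho=float(res.statistic), p_value=float(res.pvalue), n=int(x.size))


@dataclass(frozen=True)
class GroupSummary:
    label: str
    n: int
    median: float
    q1: float
    q3: float

    @property
    def iqr_width(self) -> float:
        return self.q3 - self.q1


@dataclass
class CohortComparisonResult:
    """One characteristic x outcome comparison: group medians/IQRs plus the
    rank test (Mann-Whitney ``U/z`` for two categories, Kruskal-Wallis ``H``
    for three or more)."""

    characteristic: str
    metric: str
    groups: list[GroupSummary]
    statistic_label: str  # "U/z" or "H"
    statistic: float  # z (two groups) or H (>= 3 groups)
    p_value: float
    u: float | None = None
    p_adjusted: float | None = None
    notes: str = "no multiple-testing adjustment"

    @property
    def n_total(self) -> int:
        return sum(g.n for g in self.groups)


def compare_by_characteristics(
    summaries: pd.DataFrame,
    profiles: pd.DataFrame,
    metrics: tuple[str, ...] = ("engagement_index", "engagement_time_min"),
    characteristics: dict[str, tuple[str, ...]] | None = None,
    adjust: str | None = None,
) -> list[CohortComparisonResult]:
    """Run the characteristic-wise engagement comparisons.

    For every characteristic and every outcome metric, groups the scored
    participants by category and applies Mann-Whitney (two categories) or
    Kruskal-Wallis (three or more). Empty categories are dropped with a
    warning. No multiple-testing adjustment is applied by default, matching
    the reference analysis; ``adjust`` in {"holm", "bh"} fills
    ``p_adjusted`` per metric.
    """
    characteristics = dict(CHARACTERISTICS) if characteristics is None else characteristics
    df = summaries.reset_index().merge(profiles, on="participant_id", how="inner")
    results: list[CohortComparisonResult] = []
    for char, cats in characteristics.items():
        for metric in metrics:
            groups, labels = [], []
            for cat in cats:
                vals = df.loc[df[char] == cat, metric].to_numpy(dtype=float)
                if vals.size == 0:
                    warnings.warn(
                        f"dropping empty category {cat!r} of {char!r}", stacklevel=2
                    )
                    continue
                groups.append(vals)
                labels.append(cat)
            if len(groups) < 2:
                warnings.warn(
                    f"characteristic {char!r} has fewer than 2 nonempty categories; skipped",
                    stacklevel=2,
                )
                continue
            gsum = [
                GroupSummary(
                    label=lab,
                    n=int(v.size),
                    median=median_iqr(v).median,
                    q1=median_iqr(v).q1,
                    q3=median_iqr(v).q3,
                )
                for lab, v in zip(labels, groups)
            ]
            if len(groups) == 2:
                mw = mann_whitney(groups[0], groups[1])
                results.append(
                    CohortComparisonResult(
                        characteristic=char,
                        metric=metric,
                        groups=gsum,
                        statistic_label="U/z",
                        statistic=mw.z,
                        p_value=mw.p_value,
                        u=mw.u,
                    )
                )
            else:
                kw = kruskal_wallis(groups)
                results.append(
                    CohortComparisonResult(
                        characteristic=char,
                        metric=metric,
                        groups=gsum,
                        statistic_label="H",
                        statistic=kw.h,
                        p_value=kw.p_value,
                    )
                )
    if adjust is not None:
        _adjust_pvalues(results, adjust)
    return results


def _adjust_pvalues(results: list[CohortComparisonResult], method: str) -> None:
    from statsmodels.stats.multitest import multipletests

    key = {"holm": "holm", "bh": "fdr_bh"}.get(method)
    if key is None:
        raise ValueError("adjust must be one of {'holm', 'bh'}")
    for metric in {r.metric for r in results}:
        sub = [r for r in results if r.metric == metric]
        _, adj, _, _ = multipletests([r.p_value for r in sub], method=key)
        for r, p in zip(sub, adj):
            r.p_adjusted = float(p)
            r.notes = f"p adjusted ({method})"
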