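"""Non-parametric model-comparison machinery.

Covers the omnibus Friedman test over a cases-by-methods score matrix with
Kendall's W as effect size, Nemenyi critical differences for CD diagrams,
the exact (full-enumeration) Wilcoxon signed-rank test with matched-pairs
rank-biserial correlation, DeLong's test for correlated AUCs, and BCa
bootstrap confidence intervals.

Conventions: the Friedman statistic is the plain (tie-uncorrected)
formula with average ranks on ties; Wilcoxon drops zero differences and
enumerates all 2^n sign assignments of the remaining ranked absolute
differences; reported p-values are truncated (not rounded) to four
decimals so that 1/32 prints as 0.0312.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps


@dataclass
class StatResult:
    statistic: float
    p_value: float
    effect_size: Optional[float] = None
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    method: str = ""
    extra: Dict = field(default_factory=dict)


@dataclass
class ScoreMatrix:
    """N cases (rows: e.g. seeds x conditions) by k methods (columns)."""

    scores: np.ndarray
    method_names: List[str]
    case_labels: Optional[List[str]] = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.scores.ndim != 2:
            raise ValueError("scores must be a 2-D matrix")
        n, k = self.scores.shape
        if n < 2 or k < 2:
            raise ValueError("need at least 2 cases and 2 methods")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("score matrix contains missing or non-finite cells")
        if len(self.method_names) != k:
            raise ValueError("method_names length must equal the number of columns")


def _case_ranks(scores: np.ndarray) -> np.ndarray:
    """Within-case ranks, rank 1 = *highest* score, average ranks on ties."""
    return np.apply_along_axis(lambda r: sps.rankdata(-r), 1, scores)


def friedman(matrix: ScoreMatrix) -> StatResult:
    """Friedman rank test across k methods over N matched cases.

    Statistic: (12N / (k(k+1))) * sum_j rbar_j^2 - 3N(k+1), referred to a
    chi-square distribution with k-1 degrees of freedom.
    """
    n, k = matrix.scores.shape
    ranks = _case_ranks(matrix.scores)
    rbar = ranks.mean(axis=0)
    stat = 12.0 * n / (k * (k + 1)) * np.sum(rbar ** 2) - 3.0 * n * (k + 1)
    stat = max(stat, 0.0)  # full ties can go slightly negative in float
    p = float(sps.chi2.sf(stat, k - 1))
    w = stat / (n * (k - 1))
    return StatResult(statistic=float(stat), p_value=p, effect_size=float(w),
                      method="friedman", extra={"mean_ranks": rbar.tolist(),
                                                "method_names": matrix.method_names})


def kendalls_w(matrix: ScoreMatrix) -> float:
    """Kendall's coefficient of concordance W = chi2_F / (N (k-1))."""
    return float(friedman(matrix).effect_size)


#: Studentized-range q_alpha / sqrt(2) for the Nemenyi test, infinite df.
NEMENYI_Q = {
    0.05: {2: 1.960, 3: 2.343, 4: 2.569, 5: 2.728, 6: 2.850,
           7: 2.949, 8: 3.031, 9: 3.102, 10: 3.164},
    0.10: {2: 1.645, 3: 2.052, 4: 2.291, 5: 2.459, 6: 2.589,
           7: 2.693, 8: 2.780, 9: 2.855, 10: 2.920},
}


def nemenyi_cd(k: int, n: int, alpha: float = 0.05) -> float:
    """Critical difference CD = q_alpha * sqrt(k(k+1) / (6N))."""
    if alpha not in NEMENYI_Q:
        raise ValueError(f"alpha must be one of {sorted(NEMENYI_Q)}")
    table = NEMENYI_Q[alpha]
    if k not in table:
        raise ValueError(f"k={k} outside the packaged q table (2..{max(table)})")
    return float(table[k] * np.sqrt(k * (k + 1) / (6.0 * n)))


def nemenyi_cliques(mean_ranks: Sequence[float], cd: float) -> List[Tuple[int, ...]]:
    """Maximal groups of methods whose mean ranks differ by at most CD."""
    order = np.argsort(mean_ranks)
    r = np.asarray(mean_ranks, dtype=np.float64)
    cliques: List[Tuple[int, ...]] = []
    for i in order:
        group = tuple(sorted(j for j in range(len(r)) if abs(r[j] - r[i]) <= cd))
        if not any(set(group) <= set(g) for g in cliques):
            cliques.append(group)
    return cliques


def _signed_ranks(x: np.ndarray, y: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    d = np.asarray(x, dtype=np.float64) - np.asarray(y, dtype=np.float64)
    d = d[d != 0.0]
    if d.size == 0:
        raise ValueError("all paired differences are zero; no information")
    ranks = sps.rankdata(np.abs(d))
    return d, ranks


def wilcoxon_signed_rank_exact(x: Sequence[float], y: Sequence[float],
                               alternative: str = "greater") -> StatResult:
    """Exact Wilcoxon signed-rank test by full 2^n enumeration.

    Zero differences are dropped; ``alternative='greater'`` tests whether
    x tends to exceed y.  Exact enumeration is limited to n <= 20 pairs
    after zero removal.
    """
    if alternative not in ("two_sided", "greater", "less"):
        raise ValueError("alternative must be 'two_sided', 'greater' or 'less'")
    d, ranks = _signed_ranks(np.asarray(x), np.asarray(y))
    n = d.size
    if n > 20:
        raise ValueError(f"exact enumeration supports n <= 20 pairs, got {n}")
    w_plus = float(ranks[d > 0].sum())
    # distribution of W+ under the null: each rank is + with prob 1/2
    totals = np.zeros(1)
    for r in ranks:
        totals = np.concatenate([totals, totals + r])
    m = totals.size  # 2^n equally likely outcomes
    p_ge = np.count_nonzero(totals >= w_plus - 1e-9) / m
    p_le = np.count_nonzero(totals <= w_plus + 1e-9) / m
    if alternative == "greater":
        p = p_ge
    elif alternative == "less":
        p = p_le
    else:
        p = min(1.0, 2.0 * min(p_ge, p_le))
    r_rb = rank_biserial_from_ranks(d, ranks)
    return StatResult(statistic=w_plus, p_value=float(p), effect_size=r_rb,
                      method="wilcoxon_exact",
                      extra={"n": n, "alternative": alternative})


def rank_biserial_from_ranks(d: np.ndarray, ranks: np.ndarray) -> float:
    r_plus = float(ranks[d > 0].sum())
    r_minus = float(ranks[d < 0].sum())
    return (r_plus - r_minus) / (r_plus + r_minus)


def rank_biserial(x: Sequence[float], y: Sequence[float]) -> float:
    """Matched-pairs rank-biserial correlation in [-1, 1].

    Difference between the proportions of favorable (x > y) and
    unfavorable signed rank mass; zero differences are dropped.
    """
    d, ranks = _signed_ranks(np.asarray(x), np.asarray(y))
    return rank_biserial_from_ranks(d, ranks)


def _delong_placements(labels: np.ndarray, scores: np.ndarray) -> Tuple[float, np.ndarray, np.ndarray]:
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    # midrank placements: V10[i] = P(score_neg < pos_i) + 0.5 P(=)
    cmp = (pos[:, None] > neg[None, :]).astype(np.float64)
    cmp += 0.5 * (pos[:, None] == neg[None, :])
    v10 = cmp.mean(axis=1)
    v01 = cmp.mean(axis=0)
    return float(cmp.mean()), v10, v01


def delong(labels: Sequence[int], scores_a: Sequence[float],
           scores_b: Sequence[float]) -> StatResult:
    """DeLong's test for two correlated AUCs measured on the same cases.

    Returns delta AUC (a - b), its structural-components variance, the
    two-sided z-test p-value and a 95% CI for the difference.
    """
    y = np.asarray(labels).astype(int)
    sa = np.asarray(scores_a, dtype=np.float64)
    sb = np.asarray(scores_b, dtype=np.float64)
    if len(np.unique(y)) < 2:
        raise ValueError("DeLong requires both classes present")
    if not (y.shape == sa.shape == sb.shape):
        raise ValueError("labels and both score vectors must share one shape")
    auc_a, v10a, v01a = _delong_placements(y, sa)
    auc_b, v10b, v01b = _delong_placements(y, sb)
    m, n = v10a.size, v01a.size
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    cov = s10 / m + s01 / n
    delta = auc_a - auc_b
    var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var <= 0:
        p = 1.0
        ci = (delta, delta)
        z = 0.0
    else:
        se = np.sqrt(var)
        z = delta / se
        p = float(2.0 * sps.norm.sf(abs(z)))
        half = sps.norm.ppf(0.975) * se
        ci = (delta - half, delta + half)
    return StatResult(statistic=float(z), p_value=p, effect_size=float(delta),
                      ci_low=float(ci[0]), ci_high=float(ci[1]), method="delong",
                      extra={"auc_a": auc_a, "auc_b": auc_b, "var": float(var)})


def _bca_interval(thetas: np.ndarray, theta_hat: float, z0: float, a: float,
                  alpha: float) -> Tuple[float, float]:
    """BCa percentile adjustment given bootstrap replicates and (z0, a)."""
    z = sps.norm.ppf([alpha / 2, 1 - alpha / 2])
    adj = sps.norm.cdf(z0 + (z0 + z) / (1 - a * (z0 + z)))
    lo, hi = np.quantile(thetas, adj)
    return float(lo), float(hi)


def bca_ci(sample: Sequence[float], statistic_fn: Callable[[np.ndarray], float],
           B: int = 10000, alpha: float = 0.05,
           rng: Optional[np.random.Generator] = None) -> Tuple[float, float]:
    """Bias-corrected and accelerated bootstrap CI for a 1-sample statistic.

    Bias correction z0 comes from the fraction of bootstrap replicates
    below the point estimate; acceleration a from the jackknife skewness.
    Degenerate samples (zero-variance statistic) yield a zero-width
    interval at the point value.
    """
    arr = np.asarray(sample, dtype=np.float64)
    n = arr.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    rng = np.random.default_rng() if rng is None else rng
    theta_hat = float(statistic_fn(arr))
    idx = rng.integers(0, n, size=(B, n))
    try:
        # statistics that accept an axis argument (np.mean, np.median, ...)
        # are evaluated on all resamples at once
        thetas = np.asarray(statistic_fn(arr[idx], axis=-1), dtype=np.float64)
        if thetas.shape != (B,):
            raise TypeError
    except TypeError:
        thetas = np.array([statistic_fn(arr[row]) for row in idx], dtype=np.float64)
    if np.ptp(thetas) == 0.0:
        return theta_hat, theta_hat
    frac_below = np.mean(thetas < theta_hat)
    if frac_below in (0.0, 1.0):  # pathological; fall back to percentile
        z0 = 0.0
    else:
        z0 = float(sps.norm.ppf(frac_below))
    jack = np.array([statistic_fn(np.delete(arr, i)) for i in range(n)])
    diff = jack.mean() - jack
    denom = 6.0 * (np.sum(diff ** 2) ** 1.5)
    a = float(np.sum(diff ** 3) / denom) if denom > 0 else 0.0
    return _bca_interval(thetas, theta_hat, z0, a, alpha)


def truncate_p(p: float, decimals: int = 4) -> float:
    """Truncate (floor) a p-value for report tables: 1/32 -> 0.0312."""
    scale = 10 ** decimals
    return np.floor(p * scale + 1e-12) / scale
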