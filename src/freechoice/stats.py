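"""Figure-level statistics implemented from their defining formulas.

Paired t, Wilcoxon signed-rank (exact enumeration for small n), the 2×2
repeated-measures ANOVA interaction, the two-sample Kolmogorov–Smirnov test
(asymptotic p), Pearson correlation with Wald test, Fisher's r-to-z
comparison of two independent correlations, and Bonferroni adjustment.
These are the within-subject comparisons used throughout the behavioral
analyses; scipy/pingouin implement the same tests and serve as independent
cross-checks in the test suite, not as the implementation.
"""

from __future__ import annotations

import dataclasses
from functools import lru_cache

import numpy as np
from scipy import special
from scipy import stats as sps
from scipy.stats import rankdata


class StatsError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class PairedTResult:
    t: float
    df: int
    p: float


@dataclasses.dataclass(frozen=True)
class WilcoxonResult:
    T: float
    p: float
    n: int
    exact: bool


@dataclasses.dataclass(frozen=True)
class RmAnovaResult:
    """2×2 within-subject ANOVA; F_interaction with df (1, n−1)."""

    F_interaction: float
    df1: int
    df2: int
    p: float
    F_factor1: float = np.nan
    F_factor2: float = np.nan


@dataclasses.dataclass(frozen=True)
class KsResult:
    D: float
    p: float


@dataclasses.dataclass(frozen=True)
class PearsonResult:
    r: float
    p: float
    n: int
    t: float


@dataclasses.dataclass(frozen=True)
class FisherZResult:
    z: float
    p: float


def _as_paired(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise StatsError("paired samples must be 1-d and of equal length")
    if len(a) < 2:
        raise StatsError("need at least 2 subjects")
    return a, b


def paired_t(a, b) -> PairedTResult:
    """Two-tailed paired t-test: t = mean(d) / (sd(d)/√n), df = n−1."""
    a, b = _as_paired(a, b)
    d = a - b
    n = len(d)
    sd = d.std(ddof=1)
    if sd == 0:
        if np.all(d == 0):  # identical conditions: no evidence of any effect
            return PairedTResult(0.0, n - 1, 1.0)
        raise StatsError("zero difference variance: paired t undefined")
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    return PairedTResult(float(t), n - 1, float(p))


@lru_cache(maxsize=64)
def _signed_rank_cdf(n: int) -> np.ndarray:
    """CDF of the W+ signed-rank statistic under H0 (all 2^n sign patterns)."""
    max_sum = n * (n + 1) // 2
    counts = np.zeros(max_sum + 1)
    counts[0] = 1.0
    for r in range(1, n + 1):
        counts[r:] += counts[:-r].copy()
    return np.cumsum(counts) / 2.0**n


def wilcoxon_signed_rank(a, b, exact_max_n: int = 25) -> WilcoxonResult:
    """Wilcoxon signed-rank test; T = min of the signed-rank sums.

    Zero differences are dropped before ranking.  The p-value is computed by
    exact enumeration of all sign assignments for n ≤ ``exact_max_n`` when the
    absolute differences are tie-free, else by the normal approximation with
    tie correction and continuity correction.
    """
    a, b = _as_paired(a, b)
    d = (a - b)[a != b]
    n = len(d)
    if n == 0:
        raise StatsError("all differences are zero: Wilcoxon undefined")
    if n < 5:
        raise StatsError("need at least 5 nonzero differences")
    ranks = rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    w_neg = float(ranks[d < 0].sum())
    T = min(w_pos, w_neg)
    has_ties = len(np.unique(np.abs(d))) < n
    if n <= exact_max_n and not has_ties:
        cdf = _signed_rank_cdf(n)
        p = min(1.0, 2.0 * float(cdf[int(round(T))]))
        return WilcoxonResult(T, p, n, exact=True)
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(tie_counts**3 - tie_counts) / 48.0
    z = (T - mu + 0.5) / np.sqrt(var)
    p = min(1.0, 2.0 * sps.norm.cdf(z))
    return WilcoxonResult(T, float(p), n, exact=False)


def rm_anova_2x2(a_lo, a_hi, b_lo, b_hi) -> RmAnovaResult:
    """2×2 fully within-subject ANOVA from the sums-of-squares decomposition.

    Arguments are per-subject values for the four cells (factor1 = a/b,
    factor2 = lo/hi).  Each within-subject effect is tested against its own
    subject-by-effect error term; with 1-df effects the interaction F equals
    the squared paired t on the double differences.
    """
    cells = [np.asarray(c, dtype=float) for c in (a_lo, a_hi, b_lo, b_hi)]
    n = len(cells[0])
    if any(len(c) != n for c in cells) or n < 2:
        raise StatsError("complete per-subject 2x2 data with n >= 2 required")
    y = np.stack(
        [[cells[0], cells[1]], [cells[2], cells[3]]], axis=0
    )  # (factor1, factor2, subject)
    y = np.moveaxis(y, 2, 0)  # (subject, factor1, factor2)
    subj_mean = y.mean(axis=(1, 2), keepdims=True)
    cell_mean = y.mean(axis=0, keepdims=True)
    a_mean = y.mean(axis=(0, 2), keepdims=True)
    b_mean = y.mean(axis=(0, 1), keepdims=True)
    ia_mean = y.mean(axis=2, keepdims=True)  # subject x factor1
    ib_mean = y.mean(axis=1, keepdims=True)  # subject x factor2
    grand = y.mean()

    def effect_f(eff: np.ndarray, resid: np.ndarray):
        # each effect is 1 df; the common per-cell multiplicity cancels in F
        ss_eff = n * float(np.sum(eff**2))
        ss_err = float(np.sum(resid**2))
        df2 = n - 1
        F = ss_eff / (ss_err / df2) if ss_err > 0 else np.inf
        p = float(sps.f.sf(F, 1, df2)) if np.isfinite(F) else 0.0
        return F, p

    eff_a = a_mean - grand
    eff_b = b_mean - grand
    eff_ab = cell_mean - a_mean - b_mean + grand
    res_a = ia_mean - subj_mean - eff_a
    res_b = ib_mean - subj_mean - eff_b
    res_ab = y - ia_mean - ib_mean + subj_mean - cell_mean + a_mean + b_mean - grand
    f_a, _ = effect_f(eff_a, res_a)
    f_b, _ = effect_f(eff_b, res_b)
    f_ab, p_ab = effect_f(eff_ab, res_ab)
    return RmAnovaResult(float(f_ab), 1, n - 1, p_ab, float(f_a), float(f_b))


def ks_two_sample(x, y) -> KsResult:
    """Two-sample KS: D = max |ECDF_x − ECDF_y|, asymptotic p for all n."""
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    if len(x) == 0 or len(y) == 0:
        raise StatsError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    cdf_x = np.searchsorted(x, pooled, side="right") / len(x)
    cdf_y = np.searchsorted(y, pooled, side="right") / len(y)
    D = float(np.max(np.abs(cdf_x - cdf_y)))
    en = len(x) * len(y) / (len(x) + len(y))
    p = float(special.kolmogorov(np.sqrt(en) * D))
    return KsResult(D, min(1.0, p))


def pearson_wald(x, y) -> PearsonResult:
    """Pearson product-moment r with the Wald t-test, df = n−2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise StatsError("need paired 1-d samples with n >= 3")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt(np.sum(xc**2) * np.sum(yc**2))
    if denom == 0:
        raise StatsError("constant input: correlation undefined")
    r = float(np.sum(xc * yc) / denom)
    r = max(-1.0, min(1.0, r))
    n = len(x)
    if abs(r) == 1.0:
        return PearsonResult(r, 0.0, n, np.inf)
    t = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2.0 * sps.t.sf(abs(t), n - 2)
    return PearsonResult(r, float(p), n, float(t))


def fisher_rz_compare(r1: float, n1: int, r2: float, n2: int) -> FisherZResult:
    """Compare two independent correlations via Fisher's r-to-z transform.

    z = (atanh r₁ − atanh r₂) / √(1/(n₁−3) + 1/(n₂−3)), two-tailed normal p.
    """
    for r in (r1, r2):
        if abs(r) >= 1.0:
            raise StatsError("|r| = 1 has an infinite z-transform")
    if n1 < 4 or n2 < 4:
        raise StatsError("need n >= 4 in each sample")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = 2.0 * sps.norm.sf(abs(z))
    return FisherZResult(float(z), float(p))


def bonferroni(p, m: int):
    """Bonferroni adjustment: min(1, m·p) per value."""
    p_arr = np.asarray(p, dtype=float)
    if np.any((p_arr < 0) | (p_arr > 1)):
        raise StatsError("p-values must lie in [0, 1]")
    if m < 1:
        raise StatsError("family size m must be >= 1")
    out = np.minimum(1.0, m * p_arr)
    return float(out) if np.isscalar(p) or p_arr.ndim == 0 else out
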