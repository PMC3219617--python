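"""Shared statistical primitives for the integrated-network pipeline.

Exact tail probabilities (hypergeometric, binomial), the tissue/stage
specificity score (relative entropy against a uniform null), the
exponential degree-distribution fit, and thin wrappers around the rank
tests used in the per-layer comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


# ---------------------------------------------------------------------------
# Tissue / stage specificity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpecificityScore:
    """Relative entropy of a fractional expression profile vs. uniform.

    ``score`` is D(p || q) with q_i = 1/K, in bits by default; 0 means
    perfectly uniform expression, log2(K) means all expression in a
    single condition.
    """

    entity_id: str
    score: float
    n_conditions: int
    fractions: tuple[float, ...]

    @property
    def max_score(self) -> float:
        return math.log2(self.n_conditions)


def tsps(values, entity_id: str = "", base: float = 2.0) -> SpecificityScore:
    """Tissue (or stage) specificity score of one expression row.

    Parameters
    ----------
    values : array-like of K non-negative expression levels (K >= 2).
    base : logarithm base; 2 gives the score in bits.

    The score is sum_i p_i * log(p_i / (1/K)) with p_i = x_i / sum(x)
    and 0*log(0) := 0.  Raises ``ValueError`` on an all-zero row: a gene
    with no measured expression has no defined specificity.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("specificity needs a 1-D row of >=2 conditions")
    if np.any(x < 0):
        raise ValueError("expression levels must be non-negative")
    total = x.sum()
    if total <= 0:
        raise ValueError(f"all-zero expression row ({entity_id!r}): score undefined")
    k = x.size
    p = x / total
    nz = p > 0
    score = float(np.sum(p[nz] * (np.log(p[nz] * k) / np.log(base))))
    # clip tiny negative round-off; the divergence is >= 0
    score = max(score, 0.0)
    return SpecificityScore(entity_id, score, k, tuple(p))


# ---------------------------------------------------------------------------
# Exact tails
# ---------------------------------------------------------------------------

def hypergeom_log_upper_tail(overlap: int, size_a: int, size_b: int,
                             universe: int) -> float:
    """log P[X >= overlap], X ~ Hypergeom(universe, size_a, size_b).

    Summed in log space (log-gamma terms + logsumexp), so the log tail
    stays finite far below double-precision underflow.
    """
    from scipy.special import gammaln, logsumexp

    if not (0 <= overlap and size_a <= universe and size_b <= universe):
        raise ValueError("inconsistent hypergeometric sizes")
    if overlap > min(size_a, size_b):
        raise ValueError("overlap cannot exceed the smaller set")
    if overlap == 0:
        return 0.0
    ks = np.arange(overlap, min(size_a, size_b) + 1)
    ks = ks[universe - size_a - size_b + ks >= 0]

    def logc(n, r):
        return gammaln(n + 1) - gammaln(r + 1) - gammaln(n - r + 1)

    logpmf = (logc(size_a, ks) + logc(universe - size_a, size_b - ks)
              - logc(universe, size_b))
    return float(min(logsumexp(logpmf), 0.0))


def hypergeom_upper_tail(overlap: int, size_a: int, size_b: int, universe: int) -> float:
    """P[X >= overlap] for X ~ Hypergeom(universe, size_a, size_b).

    The probability that two sets of the given sizes, drawn from a
    shared universe, share at least ``overlap`` elements by chance.
    """
    return math.exp(hypergeom_log_upper_tail(overlap, size_a, size_b, universe))


def binomial_log_upper_tail(k: int, n: int, p0: float = 0.5) -> float:
    """log P[X >= k], X ~ Binomial(n, p0), exact in log space."""
    from scipy.special import gammaln, logsumexp

    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must lie strictly in (0, 1)")
    if k == 0:
        return 0.0
    ks = np.arange(k, n + 1)
    logpmf = (gammaln(n + 1) - gammaln(ks + 1) - gammaln(n - ks + 1)
              + ks * math.log(p0) + (n - ks) * math.log1p(-p0))
    return float(min(logsumexp(logpmf), 0.0))


def binomial_upper_tail(k: int, n: int, p0: float = 0.5) -> float:
    """Exact one-sided binomial tail P[X >= k], X ~ Binomial(n, p0)."""
    return math.exp(binomial_log_upper_tail(k, n, p0))


# ---------------------------------------------------------------------------
# Exponential degree-distribution fit
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExponentialFit:
    """Least-squares fit of log(count) vs. degree: count ∝ exp(-rate*k)."""

    rate: float
    r_squared: float
    intercept: float
    n_points: int


def fit_exponential(histogram: dict[int, int] | "np.ndarray") -> ExponentialFit | None:
    """Fit count ∝ exp(-λk) to a degree histogram on the log scale.

    ``histogram`` maps degree -> count (or is an array indexed by
    degree).  Degrees with zero count are excluded rather than
    pseudocounted.  Returns ``None`` (fit skipped) when fewer than 3
    distinct degrees carry mass — a line through <3 points says nothing.
    """
    if isinstance(histogram, dict):
        items = [(int(k), int(v)) for k, v in histogram.items() if v > 0]
    else:
        arr = np.asarray(histogram)
        items = [(int(k), int(v)) for k, v in enumerate(arr) if v > 0]
    if len(items) < 3:
        return None
    ks = np.array([k for k, _ in items], dtype=float)
    logc = np.log([c for _, c in items])
    slope, intercept = np.polyfit(ks, logc, 1)
    fitted = slope * ks + intercept
    ss_res = float(np.sum((logc - fitted) ** 2))
    ss_tot = float(np.sum((logc - logc.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return ExponentialFit(rate=-float(slope), r_squared=r2,
                          intercept=float(intercept), n_points=len(items))


# ---------------------------------------------------------------------------
# Rank tests
# ---------------------------------------------------------------------------

def ranksum(xs, ys) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact enumeration when both samples have n <= 10 and no ties cross
    the groups; otherwise the tie-corrected normal approximation.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.size == 0 or ys.size == 0:
        raise ValueError("rank-sum test needs non-empty samples")
    method = "exact" if (xs.size <= 10 and ys.size <= 10) else "asymptotic"
    try:
        res = sps.mannwhitneyu(xs, ys, alternative="two-sided", method=method)
    except ValueError:
        # exact method refuses ties; fall back to the corrected normal
        res = sps.mannwhitneyu(xs, ys, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def kruskal(groups) -> float:
    """Kruskal-Wallis H-test p-value across >=2 groups."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("kruskal needs >=2 non-empty groups")
    flat = np.concatenate(groups)
    if np.all(flat == flat[0]):
        return 1.0  # identical values everywhere: no evidence of difference
    return float(sps.kruskal(*groups).pvalue)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values (monotone step-up)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
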