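"""Frequentist and Bayesian comparison of classifier results.

The suite follows the usual protocol for comparing algorithms over
multiple observations (runs x datasets):

1. Friedman omnibus test on within-observation ranks (tie-corrected);
2. if it rejects at alpha = 0.05, pairwise two-sided Wilcoxon signed-rank
   tests with Holm step-down adjustment;
3. pairwise Bayesian signed-rank tests with a region of practical
   equivalence (rope): paired differences are counted as left / rope /
   right, a Dirichlet posterior is built on the counts (prior pseudocount
   mass in the rope), and sampled triplets give the probabilities that
   each outcome dominates.  Triplets map to barycentric coordinates inside
   an equilateral triangle for the usual simplex heatmap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats as sps

__all__ = [
    "BayesianResult",
    "ComparisonReport",
    "friedman_test",
    "wilcoxon_signed_rank",
    "holm_adjust",
    "bayesian_signed_rank",
    "barycentric_coordinates",
    "compare_methods",
]

# Equilateral triangle with unit sides: left/right base vertices and apex.
_V_LEFT = np.array([0.0, 0.0])
_V_RIGHT = np.array([1.0, 0.0])
_V_TOP = np.array([0.5, np.sqrt(3.0) / 2.0])


def friedman_test(values: np.ndarray) -> tuple[float, float]:
    """Friedman chi-square over an (observations x algorithms) matrix.

    Uses average ranks on ties and the classic tie correction; returns
    (statistic, p) with df = k - 1.  A matrix whose rows are all internally
    tied yields statistic 0 and p = 1.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] < 2 or values.shape[1] < 2:
        raise ValueError("need >= 2 observations and >= 2 algorithms")
    n, k = values.shape
    ranks = np.apply_along_axis(sps.rankdata, 1, values)
    rank_sums = ranks.sum(axis=0)
    # tie correction: 1 - sum(t^3 - t) / (n k (k^2 - 1))
    tie_term = 0.0
    for row in values:
        _, counts = np.unique(row, return_counts=True)
        tie_term += float(np.sum(counts**3 - counts))
    correction = 1.0 - tie_term / (n * k * (k**2 - 1))
    if correction <= 0:
        return 0.0, 1.0
    statistic = (
        12.0 / (n * k * (k + 1)) * np.sum(rank_sums**2) - 3.0 * n * (k + 1)
    ) / correction
    statistic = max(float(statistic), 0.0)
    p = float(sps.chi2.sf(statistic, df=k - 1))
    return statistic, p


def _signed_rank_distribution(ranks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact distribution of W+ over all sign assignments of given ranks.

    Ranks may be half-integers (average ranks on ties); they are doubled to
    integers and the distribution is built by dynamic-programming
    convolution.
    """
    doubled = np.round(ranks * 2).astype(int)
    total = doubled.sum()
    probs = np.zeros(total + 1)
    probs[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(probs)
        shifted[r:] = probs[: probs.size - r]
        probs = 0.5 * (probs + shifted)
    support = np.arange(total + 1) / 2.0
    return support, probs


def wilcoxon_signed_rank(a, b, exact_threshold: int = 25) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired series.

    Zero differences are dropped (classic convention); tied absolute
    differences receive average ranks.  The exact null distribution is used
    for n <= ``exact_threshold`` (tie-aware, by enumeration over sign
    assignments), otherwise a normal approximation with continuity and tie
    correction.  All-zero differences give p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("series must have equal length")
    d = b - a
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    if n < 5:
        raise ValueError("need >= 5 non-zero differences")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_threshold:
        support, probs = _signed_rank_distribution(ranks)
        lower = probs[support <= w_plus + 1e-9].sum()
        upper = probs[support >= w_plus - 1e-9].sum()
        return float(min(1.0, 2.0 * min(lower, upper)))
    mean = n * (n + 1) / 4.0
    _, counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(counts**3 - counts) / 48.0
    z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / np.sqrt(var)
    return float(min(1.0, 2.0 * sps.norm.sf(abs(z))))


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjustment, returned in the input order."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_max = 0.0
    for i, idx in enumerate(order):
        value = min(1.0, (m - i) * p[idx])
        running_max = max(running_max, value)
        adjusted[idx] = running_max
    return adjusted


@dataclass
class BayesianResult:
    p_left: float
    p_rope: float
    p_right: float
    rope_min: float
    rope_max: float
    counts: tuple
    sampled_triplets: np.ndarray = field(repr=False)
    expected_triplet: tuple = ()

    def __post_init__(self):
        total = self.p_left + self.p_rope + self.p_right
        if abs(total - 1.0) > 1e-9:
            raise ValueError("probabilities must sum to 1")


def bayesian_signed_rank(
    a,
    b,
    rope_min: float = -0.01,
    rope_max: float = 0.01,
    n_samples: int = 2000,
    prior_pseudocount: float = 1.0,
    rng: np.random.Generator | int | None = None,
) -> BayesianResult:
    """Count-based Bayesian comparison of paired series with a rope.

    Differences b - a are counted as below rope_min (left), inside the
    rope, or above rope_max (right).  A Dirichlet posterior with the prior
    pseudocount placed in the rope is sampled ``n_samples`` times; the
    reported probabilities are the fractions of samples in which each
    coordinate is the largest (ties split evenly).  The expected posterior
    triplet is also recorded.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or a.shape != b.shape:
        raise ValueError("series must be non-empty and of equal length")
    if rope_min > rope_max:
        raise ValueError("rope_min must be <= rope_max")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    d = b - a
    c_left = int(np.sum(d < rope_min))
    c_right = int(np.sum(d > rope_max))
    c_rope = d.size - c_left - c_right
    alpha = np.array([c_left, c_rope + prior_pseudocount, c_right], dtype=float)
    # gamma-based Dirichlet sampling: a zero count (with no prior mass) puts
    # an exact zero in that coordinate instead of raising
    gammas = np.where(alpha > 0, rng.gamma(np.maximum(alpha, 1e-12), 1.0, (n_samples, 3)), 0.0)
    triplets = gammas / gammas.sum(axis=1, keepdims=True)
    wins = np.zeros(3)
    max_mask = triplets == triplets.max(axis=1, keepdims=True)
    wins = (max_mask / max_mask.sum(axis=1, keepdims=True)).sum(axis=0) / n_samples
    return BayesianResult(
        p_left=float(wins[0]),
        p_rope=float(wins[1]),
        p_right=float(wins[2]),
        rope_min=rope_min,
        rope_max=rope_max,
        counts=(c_left, c_rope, c_right),
        sampled_triplets=triplets,
        expected_triplet=tuple(alpha / alpha.sum()),
    )


def barycentric_coordinates(triplet) -> np.ndarray:
    """Map a (left, rope, right) probability triplet into the triangle.

    Left vertex <-> b - a < 0, right vertex <-> b - a > 0, apex <-> rope.
    The map is affine: p_left * V_left + p_rope * V_top + p_right * V_right.
    """
    t = np.asarray(triplet, dtype=float)
    if t.ndim == 1:
        t = t[None, :]
    if t.shape[1] != 3 or np.any(t < -1e-12) or np.any(np.abs(t.sum(axis=1) - 1) > 1e-9):
        raise ValueError("triplets must be non-negative and sum to 1")
    points = t[:, 0, None] * _V_LEFT + t[:, 1, None] * _V_TOP + t[:, 2, None] * _V_RIGHT
    return points[0] if points.shape[0] == 1 else points


@dataclass
class ComparisonReport:
    method_names: list[str]
    friedman_statistic: float
    friedman_p: float
    pairwise_p: dict = field(default_factory=dict)  # raw Wilcoxon p per pair
    pairwise_p_holm: dict = field(default_factory=dict)
    bayesian: dict = field(default_factory=dict)  # BayesianResult per pair
    posthoc_run: bool = False

    def to_text(self) -> str:
        lines = [
            f"Friedman chi-square = {self.friedman_statistic:.4f}, "
            f"p = {self.friedman_p:.4g}",
        ]
        if not self.posthoc_run:
            lines.append("Post-hoc tests not run (Friedman p >= 0.05).")
            return "\n".join(lines)
        for pair in self.pairwise_p_holm:
            res = self.bayesian[pair]
            lines.append(
                f"{pair[0]} vs {pair[1]}: Wilcoxon p(Holm) = "
                f"{self.pairwise_p_holm[pair]:.4g}; Bayesian "
                f"P(left)={res.p_left:.3f} P(rope)={res.p_rope:.3f} "
                f"P(right)={res.p_right:.3f} (rope=[{res.rope_min}, {res.rope_max}])"
            )
        return "\n".join(lines)


def compare_methods(
    values: np.ndarray,
    method_names: list[str] | None = None,
    rope: tuple[float, float] = (-0.01, 0.01),
    n_samples: int = 2000,
    alpha: float = 0.05,
    rng: np.random.Generator | int | None = None,
) -> ComparisonReport:
    """Full comparison of >= 2 methods over aligned observations.

    ``values`` is (observations x methods).  The Friedman test gates the
    pairwise Wilcoxon (Holm-adjusted) and Bayesian signed-rank analyses.
    """
    values = np.asarray(values, dtype=float)
    k = values.shape[1]
    names = list(method_names) if method_names else [f"method_{i}" for i in range(k)]
    if len(names) != k:
        raise ValueError("method_names length must match column count")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    statistic, p = friedman_test(values)
    report = ComparisonReport(names, statistic, p)
    if p >= alpha:
        return report
    report.posthoc_run = True
    pairs = list(combinations(range(k), 2))
    raw = []
    for i, j in pairs:
        raw.append(wilcoxon_signed_rank(values[:, i], values[:, j]))
    adjusted = holm_adjust(raw)
    for (i, j), p_raw, p_adj in zip(pairs, raw, adjusted):
        key = (names[i], names[j])
        report.pairwise_p[key] = float(p_raw)
        report.pairwise_p_holm[key] = float(p_adj)
        report.bayesian[key] = bayesian_signed_rank(
            values[:, i], values[:, j], rope[0], rope[1], n_samples, rng=rng
        )
    return report
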