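"""Significance tests for parallelism of community change-vectors.

Three complementary approaches test whether a set of pairwise angles is
concentrated below the 90 deg expectation for independent (orthogonal)
change:

* a one-sample t-test (or, for non-normal angle sets, a one-sample
  Wilcoxon signed-rank test) of the angles against 90 deg, one-sided
  toward smaller angles;
* a Monte-Carlo test that simulates whole sets of k uniformly-random
  directions in the ordination's dimensionality and compares the observed
  mean pairwise angle with the simulated null means — this respects the
  non-independence of the C(k,2) pairwise angles, which share vectors;
* a Rayleigh test of unimodal concentration of the unit direction
  vectors, with S = k * d * Rbar^2 referred to a chi-square with d
  degrees of freedom.

The random-angle null is centered at 90 deg: two independent
uniformly-random directions in a high-dimensional space are nearly
orthogonal with overwhelming probability.

Spearman rank correlations (angle vs meanL, composition vs function) and
a paired comparison of two angle sets round out the toolkit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .vectors import ChangeVectorSet

__all__ = [
    "TestResult", "RandomAngleNull", "DegenerateSampleError",
    "shapiro_gate", "t_test_vs_90", "wilcoxon_vs_90",
    "random_angle_null", "monte_carlo_parallelism", "rayleigh_test",
    "spearman", "compare_angle_sets", "benjamini_hochberg",
]

logger = logging.getLogger(__name__)

NULL_ANGLE = 90.0  # degrees; expectation under independent change


class DegenerateSampleError(ValueError):
    """The sample has no variation (or too few values) for the test."""


@dataclass
class TestResult:
    method: str
    statistic: float
    p_value: float
    n: int
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.statistic):
            raise ValueError("test statistic is not finite")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value outside [0, 1]: {self.p_value}")
        if self.n < 1:
            raise ValueError("n must be >= 1")


@dataclass
class RandomAngleNull:
    """Null distribution of mean pairwise angles among k random directions."""

    d: int
    k: int
    iterations: int
    seed: int
    samples: np.ndarray  # per-iteration mean pairwise angle, degrees

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if len(self.samples) != self.iterations:
            raise ValueError("sample count does not match iterations")
        if ((self.samples < 0) | (self.samples > 180)).any():
            raise ValueError("angles must lie in [0, 180]")


def _angles_array(angles) -> np.ndarray:
    a = np.asarray(angles, dtype=float).ravel()
    if np.isnan(a).any():
        raise ValueError("angle sample contains NaN")
    return a


def shapiro_gate(angles, alpha: float = 0.05) -> str:
    """Shapiro-Wilk normality gate: "normal" iff p >= alpha.

    Drives automatic selection between the t-test (normal) and the
    Wilcoxon signed-rank test (non-normal).
    """
    a = _angles_array(angles)
    if len(a) < 3:
        raise DegenerateSampleError("Shapiro-Wilk needs at least 3 values")
    if np.ptp(a) == 0:
        raise DegenerateSampleError("constant sample: normality undefined")
    _, p = sps.shapiro(a)
    return "normal" if p >= alpha else "non_normal"


def t_test_vs_90(angles) -> TestResult:
    """One-sample t-test of angles against 90 deg, one-sided toward < 90.

    t = (mean - 90) / (s / sqrt(n)) with the n-1 sample standard
    deviation; p = P(T_{n-1} <= t), so p < 0.5 exactly when the mean angle
    falls on the parallel side of 90 deg.
    """
    a = _angles_array(angles)
    n = len(a)
    if n < 2:
        raise DegenerateSampleError("t-test needs at least 2 angles")
    if np.ptp(a) == 0:
        raise DegenerateSampleError("zero variance: t-statistic undefined")
    res = sps.ttest_1samp(a, NULL_ANGLE, alternative="less")
    return TestResult(method="t_vs_90", statistic=float(res.statistic),
                      p_value=float(res.pvalue), n=n,
                      extras={"mean_angle": float(a.mean()), "df": n - 1})


def _signed_rank_exact_cdf(ranks: np.ndarray, w_obs: float) -> float:
    """P(W+ <= w_obs) by dynamic programming over all 2^n sign patterns.

    `ranks` are the (possibly tie-averaged, hence half-integer) ranks of
    |angle - 90|.  Doubling makes them integers, so the null distribution
    of 2*W+ is enumerable exactly even with ties.
    """
    r2 = np.round(2 * ranks).astype(int)
    total = int(r2.sum())
    dist = np.zeros(total + 1, dtype=float)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = 0.5 * (dist + shifted)
    cutoff = int(np.floor(np.round(2 * w_obs, 6)))
    return float(dist[: cutoff + 1].sum())


def wilcoxon_vs_90(angles) -> TestResult:
    """One-sample Wilcoxon signed-rank test against 90 deg, one-sided < 90.

    Zero differences are dropped (the standard reduction); ties in
    |angle - 90| receive average ranks.  For n <= 25 the null distribution
    of the positive-rank sum W+ is computed exactly by enumeration over
    sign patterns; larger samples use the normal approximation with
    continuity correction.  Small W+ (most angles below 90) gives small p.
    """
    a = _angles_array(angles)
    diffs = a - NULL_ANGLE
    diffs = diffs[diffs != 0]
    n = len(diffs)
    if n < 1:
        raise DegenerateSampleError("all angles equal 90: signed ranks undefined")
    ranks = sps.rankdata(np.abs(diffs))
    w_plus = float(ranks[diffs > 0].sum())
    if n <= 25:
        p = _signed_rank_exact_cdf(ranks, w_plus)
        mode = "exact"
    else:
        mu = n * (n + 1) / 4.0
        # tie correction to the null variance of W+
        _, tie_counts = np.unique(np.abs(diffs), return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 \
            - (tie_counts ** 3 - tie_counts).sum() / 48.0
        z = (w_plus + 0.5 - mu) / np.sqrt(var)
        p = float(sps.norm.cdf(z))
        mode = "normal_approx"
    return TestResult(method="wilcoxon_vs_90", statistic=w_plus,
                      p_value=min(p, 1.0), n=n,
                      extras={"mean_angle": float(a.mean()), "mode": mode})


def _mean_pairwise_angle_batches(k: int, d: int, iterations: int,
                                 rng: np.random.Generator,
                                 batch: int = 20000) -> np.ndarray:
    """Per-iteration mean of all C(k,2) pairwise angles among k random
    unit directions in d dimensions (normalized standard normals)."""
    iu = np.triu_indices(k, 1)
    out = np.empty(iterations)
    done = 0
    while done < iterations:
        b = min(batch, iterations - done)
        x = rng.standard_normal((b, k, d))
        x /= np.linalg.norm(x, axis=2, keepdims=True)
        gram = np.clip(np.einsum("bkd,bld->bkl", x, x), -1.0, 1.0)
        ang = np.degrees(np.arccos(gram[:, iu[0], iu[1]]))
        out[done:done + b] = ang.mean(axis=1)
        done += b
    return out


def random_angle_null(k: int, d: int, iterations: int = 100_000,
                      seed: int = 0) -> RandomAngleNull:
    """Monte-Carlo null distribution of the mean pairwise angle.

    Each iteration draws k independent uniformly-random unit directions in
    d dimensions and averages all C(k,2) pairwise angles.  Simulating
    whole sets (rather than independent single angles) preserves the
    dependence structure among angles that share a vector.
    """
    if k < 2:
        raise ValueError("need k >= 2 vectors per draw")
    if d < 2:
        raise ValueError("need d >= 2 dimensions")
    if iterations < 1000:
        logger.warning("random_angle_null: %d iterations is low; p-value "
                       "resolution is only %.2g", iterations,
                       1 / (iterations + 1))
    rng = np.random.default_rng(seed)
    samples = _mean_pairwise_angle_batches(k, d, iterations, rng)
    return RandomAngleNull(d=d, k=k, iterations=iterations, seed=seed,
                           samples=samples)


def monte_carlo_parallelism(vs=None, *, k: int | None = None,
                            d: int | None = None,
                            observed_mean: float | None = None,
                            iterations: int = 100_000,
                            seed: int = 0) -> TestResult:
    """Monte-Carlo parallelism test against the random-direction null.

    Pass either a ChangeVectorSet (k, d and the observed mean pairwise
    angle are derived from it) or explicit ``k``, ``d`` and
    ``observed_mean``.  p = (1 + #{null mean <= observed mean}) /
    (iterations + 1): small mean angles that no random draw undercuts give
    the minimal attainable p of 1/(iterations+1), never exactly zero.
    """
    if vs is not None:
        if not isinstance(vs, ChangeVectorSet):
            raise TypeError("vs must be a ChangeVectorSet")
        from .vectors import pairwise_angles
        observed_mean = float(pairwise_angles(vs)["theta_deg"].mean())
        k, d = vs.k, vs.d
    if k is None or d is None or observed_mean is None:
        raise ValueError("provide a ChangeVectorSet or k, d and observed_mean")
    null = random_angle_null(k, d, iterations, seed)
    count = int((null.samples <= observed_mean).sum())
    p = (1 + count) / (iterations + 1)
    return TestResult(method="monte_carlo", statistic=float(observed_mean),
                      p_value=p, n=k * (k - 1) // 2,
                      extras={"mean_angle": float(observed_mean), "d": d,
                              "k": k, "iterations": iterations, "seed": seed,
                              "null_mean": float(null.samples.mean())})


def rayleigh_test(vs: ChangeVectorSet) -> TestResult:
    """Rayleigh test of unimodal concentration of vector directions.

    The unit directions u_i = v_i/|v_i| have mean resultant length
    Rbar = |mean(u_i)|; S = k * d * Rbar^2 is referred to the upper tail
    of a chi-square with d degrees of freedom.  Only directions matter —
    vector lengths never enter.
    """
    if vs.k < 2:
        raise ValueError("Rayleigh test needs at least 2 vectors")
    u = vs.unit_vectors()
    rbar = float(np.linalg.norm(u.mean(axis=0)))
    s = vs.k * vs.d * rbar ** 2
    p = float(sps.chi2.sf(s, df=vs.d))
    return TestResult(method="rayleigh", statistic=s, p_value=p, n=vs.k,
                      extras={"rbar": rbar, "d": vs.d, "S": s})


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p for Spearman's rho (n <= 10).

    Enumerates all n! permutations of one variable's ranks in chunks and
    counts |rho_perm| >= |rho_obs|.  Ties are handled by average ranks, so
    rho is the Pearson correlation of the rank vectors.
    """
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = np.sqrt((rx_c ** 2).sum() * (ry_c ** 2).sum())
    n = len(rx)
    target = abs(rho_obs) - 1e-12
    count = 0
    total = 0
    chunk: list[tuple] = []
    chunk_size = 100_000

    def flush(chunk):
        perm = np.array(chunk)
        rhos = (ry_c[perm] @ rx_c) / denom
        return int((np.abs(rhos) >= target).sum())

    for p in permutations(range(n)):
        chunk.append(p)
        total += 1
        if len(chunk) == chunk_size:
            count += flush(chunk)
            chunk = []
    if chunk:
        count += flush(chunk)
    return count / total


def spearman(x, y) -> TestResult:
    """Spearman rank correlation with exact small-sample p-values.

    Average-rank tie handling.  For n <= 10 the two-sided p comes from
    exact enumeration of rank permutations; larger samples use the
    t-approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise DegenerateSampleError("Spearman needs at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateSampleError("constant input: ranks carry no information")
    rho, p_t = sps.spearmanr(x, y)
    rho = float(rho)
    if n <= 10:
        p = _spearman_exact_p(x, y, rho)
        mode = "exact_permutation"
    else:
        p = float(p_t)
        mode = "t_approx"
    return TestResult(method="spearman", statistic=rho, p_value=p, n=n,
                      extras={"rho": rho, "mode": mode})


def compare_angle_sets(angles_a, angles_b,
                       restrict_below_90: bool = False) -> TestResult:
    """Paired two-sided t-test between two matched angle sets.

    The two sets must index the same comparisons (e.g. composition vs
    inferred function for identical population pairs).  With
    ``restrict_below_90`` only pairs where *both* angles fall below 90 deg
    — i.e. both analyses show parallelism — are kept before testing.
    A positive t means set A has larger angles (is less parallel) than B.
    """
    a = _angles_array(angles_a)
    b = _angles_array(angles_b)
    if len(a) != len(b):
        raise ValueError("paired angle sets must have equal length")
    if restrict_below_90:
        keep = (a < 90) & (b < 90)
        a, b = a[keep], b[keep]
    if len(a) < 2:
        raise DegenerateSampleError("fewer than 2 surviving pairs")
    diff = a - b
    if np.ptp(diff) == 0:
        if diff[0] == 0:
            t_stat, p = 0.0, 1.0
        else:
            # constant nonzero shift: t diverges; report a saturated value
            t_stat, p = float(np.sign(diff[0])) * np.finfo(float).max, 0.0
    else:
        res = sps.ttest_rel(a, b)
        t_stat, p = float(res.statistic), float(res.pvalue)
    return TestResult(method="paired_set", statistic=t_stat, p_value=p,
                      n=len(a),
                      extras={"mean_a": float(a.mean()),
                              "mean_b": float(b.mean()),
                              "restricted": bool(restrict_below_90)})


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional across-system FDR)."""
    _, adj, _, _ = multipletests(np.asarray(p_values, dtype=float),
                                 method="fdr_bh")
    return adj
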