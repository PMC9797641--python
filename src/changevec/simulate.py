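"""Synthetic fixtures with known ground truth.

Three generators, from most to least abstract:

* :func:`make_vector_fan` — change-vector sets whose pairwise angles are
  known *exactly* (planar fan embedded in d dimensions); the oracle for
  the angle operator.
* :func:`simulate_ordination_groups` — Gaussian sample clouds around
  centroids placed so that the true change-vector angles follow a chosen
  parallelism mode; tests centroid/angle estimation without any
  distance-matrix distortion.
* :func:`simulate_count_tables` — Dirichlet-multinomial count tables with
  a 7-rank taxonomy and controlled parallel structure, emulating the
  processed 16S products (feature table + taxonomy + metadata) that the
  real pipeline consumes; tests the full counts -> Bray-Curtis -> PCoA ->
  vectors -> tests chain end to end.

True angle geometry is defined at the centroid level in the latent space.
Bray-Curtis and PCoA distort angles in ways that depend on the data, so
end-to-end checks assert rank-order recovery of the parallelism modes,
not exact angle values.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .io import (ComparisonDesign, DesignEntry, FeatureTable, SampleMetadata,
                 TaxonomyMap)
from .vectors import ChangeVectorSet

__all__ = ["ScenarioSpec", "make_vector_fan", "simulate_ordination_groups",
           "simulate_count_tables", "pair_design"]

MODES = ("parallel", "orthogonal", "antiparallel", "random")


@dataclass
class ScenarioSpec:
    """Parameters of one synthetic study system.

    Defaults describe a well-powered but realistic 16S-style study: six
    population pairs of 50 samples each, 200 features at sequencing depth
    10,000, a centroid shift five times the within-group spread.
    """

    n_systems: int = 1
    pairs_per_system: int = 6
    n_per_group: int = 50
    d: int = 10                     # latent dimensionality (ordination sims)
    n_features: int = 200           # count-table sims
    shift_magnitude: float = 5.0    # centroid displacement (latent units /
                                    # log-fold for counts)
    parallelism_mode: str = "parallel"
    dispersion: float = 1.0         # within-group sd (latent units / lognormal
                                    # sd of per-pair baseline wobble for counts)
    overlap: float = 1.0            # fraction of shifted features shared
    shift_fraction: float = 0.1     # fraction of features shifted per pair
    depth: int = 10_000             # sequencing depth per sample
    concentration: float = 0.5      # per-feature Dirichlet concentration
    seed: int = 0

    def __post_init__(self) -> None:
        if self.parallelism_mode not in MODES:
            raise ValueError(f"parallelism_mode must be one of {MODES}")
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.shift_magnitude < 0:
            raise ValueError("shift_magnitude must be >= 0")
        if not (0.0 <= self.overlap <= 1.0):
            raise ValueError("overlap must lie in [0, 1]")


def pair_design(n_pairs: int) -> ComparisonDesign:
    """The pair design matching the simulators' group labels."""
    entries = [DesignEntry(f"v{i}", f"pair{i}_from", f"pair{i}_to")
               for i in range(n_pairs)]
    return ComparisonDesign(kind="pair", entries=entries)


def _planar_angle(p: float, q: float) -> float:
    """Angle in [0, 180] between planar directions at positions p, q (deg)."""
    a = abs(p - q) % 360.0
    return 360.0 - a if a > 180.0 else a


def make_vector_fan(k: int, d: int, target_angles, seed: int = 0,
                    rotate: bool = False) -> ChangeVectorSet:
    """Unit vectors in d dimensions with exactly the given pairwise angles.

    ``target_angles`` lists the C(k,2) pairwise angles in pair order
    (1,2), (1,3), ..., (k-1,k), each in [0, 180] degrees.  The vectors are
    placed on a planar fan (positions solved by sign search against the
    target table), embedded in the first two coordinates of the d-space.
    With ``rotate=True`` a seeded random orthogonal map is applied; angles
    are preserved to floating-point precision but no longer exact at the
    1e-9-degree level, so the default leaves the fan in-plane.

    Raises
    ------
    ValueError
        If no planar fan reproduces the target table (inconsistent set),
        or angles fall outside [0, 180].
    """
    if d < 2:
        raise ValueError("need d >= 2")
    targets = np.asarray(target_angles, dtype=float).ravel()
    n_pairs = k * (k - 1) // 2
    if len(targets) != n_pairs:
        raise ValueError(f"expected {n_pairs} target angles for k={k}, "
                         f"got {len(targets)}")
    if ((targets < 0) | (targets > 180)).any():
        raise ValueError("target angles must lie in [0, 180]")
    tgt = {}
    for (i, j), t in zip(combinations(range(k), 2), targets):
        tgt[(i, j)] = float(t)

    # fan position search: vector 0 at 0 deg, each later vector at +/- its
    # angle to vector 0; 2^(k-1) sign assignments, checked against all pairs
    positions = None
    for mask in range(1 << (k - 1)):
        pos = [0.0]
        for j in range(1, k):
            sign = -1.0 if (mask >> (j - 1)) & 1 else 1.0
            pos.append(sign * tgt[(0, j)])
        ok = all(abs(_planar_angle(pos[i], pos[j]) - tgt[(i, j)]) <= 1e-9
                 for i, j in combinations(range(k), 2))
        if ok:
            positions = pos
            break
    if positions is None:
        raise ValueError("target angle set is not realizable by any planar fan")

    vecs = np.zeros((k, d))
    rad = np.radians(positions)
    vecs[:, 0] = np.cos(rad)
    vecs[:, 1] = np.sin(rad)
    # bitwise-identical directions for coincident positions => exact 0 deg
    for i, j in combinations(range(k), 2):
        if abs(_planar_angle(positions[i], positions[j])) == 0.0:
            vecs[j] = vecs[i]
    if rotate:
        rng = np.random.default_rng(seed)
        q, r = np.linalg.qr(rng.standard_normal((d, d)))
        q *= np.sign(np.diag(r))
        vecs = vecs @ q.T
    ids = [f"fan{i}" for i in range(k)]
    return ChangeVectorSet(ids, vecs, ["origin"] * k, [f"tip{i}" for i in range(k)])


def _mode_directions(mode: str, n_pairs: int, d: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Unit shift directions per pair realizing the parallelism mode.

    parallel: all pairs shift along the same axis (all angles 0).
    orthogonal: mutually orthogonal axes (all angles 90; needs d >= pairs).
    antiparallel: alternating +/- along one axis (angles 0 or 180; for
    k > 2 every pair of opposite-sign vectors contributes 180).
    random: independent uniformly-random directions.
    """
    if mode == "parallel":
        dirs = np.zeros((n_pairs, d))
        dirs[:, 0] = 1.0
    elif mode == "orthogonal":
        if d < n_pairs:
            raise ValueError(f"orthogonal mode needs d >= pairs ({n_pairs}), got d={d}")
        dirs = np.eye(n_pairs, d)
    elif mode == "antiparallel":
        dirs = np.zeros((n_pairs, d))
        dirs[:, 0] = [1.0 if i % 2 == 0 else -1.0 for i in range(n_pairs)]
    else:  # random
        dirs = rng.standard_normal((n_pairs, d))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    return dirs


def simulate_ordination_groups(spec: ScenarioSpec):
    """Gaussian sample clouds with known true change-vectors.

    Each population pair gets a "from" centroid (pairs spaced apart on an
    axis unused by the shift directions) and a "to" centroid displaced by
    ``shift_magnitude`` along the mode's direction.  Samples are spherical
    Gaussian with sd ``dispersion`` around their centroid.

    Returns
    -------
    (coordinates, metadata, true_vectors) :
        coordinates — DataFrame (samples x d) usable directly by
        :func:`changevec.vectors.group_centroids`; metadata — sample
        system/population/ecotype labels; true_vectors — the noise-free
        ChangeVectorSet for recovery checks.
    """
    rng = np.random.default_rng(spec.seed)
    n_pairs = spec.pairs_per_system
    d = spec.d
    dirs = _mode_directions(spec.parallelism_mode, n_pairs, d, rng)
    # base centroids spaced on the last axis, which no mode's shift uses
    # (orthogonal mode requires d > n_pairs for this to hold strictly; the
    # separation axis only sets where pairs sit, not their vectors)
    sep_axis = d - 1
    rows, meta_rows, index = [], [], []
    true_vecs = []
    for i in range(n_pairs):
        base = np.zeros(d)
        base[sep_axis] = 4.0 * max(spec.shift_magnitude, 1.0) * i
        shift = spec.shift_magnitude * dirs[i]
        true_vecs.append(shift)
        for eco, centroid in (("from", base), ("to", base + shift)):
            pts = centroid + spec.dispersion * rng.standard_normal(
                (spec.n_per_group, d))
            for s in range(spec.n_per_group):
                sid = f"S{i}_{eco}_{s}"
                index.append(sid)
                rows.append(pts[s])
                meta_rows.append({"sample-id": sid, "system": "system0",
                                  "population": f"pair{i}_{eco}",
                                  "ecotype": eco})
    coords = pd.DataFrame(np.array(rows), index=index,
                          columns=[f"PC{j+1}" for j in range(d)])
    meta = SampleMetadata(pd.DataFrame(meta_rows).set_index("sample-id"))
    design = pair_design(n_pairs)
    true_set = ChangeVectorSet([e.vector_id for e in design.entries],
                               np.array(true_vecs),
                               [e.from_group for e in design.entries],
                               [e.to_group for e in design.entries]) \
        if spec.shift_magnitude > 0 else None
    return coords, meta, true_set


def _nested_taxonomy(n_features: int) -> TaxonomyMap:
    """Deterministic 7-rank hierarchy; child rank determines every parent.

    Widths double per rank (12 phyla, 24 classes, ... 192 genera), roughly
    matching the taxonomic richness of a denoised 16S data set, so that
    collapsing retains meaningful structure even at phylum level.
    """
    lineages = {}
    for f in range(n_features):
        genus = f % 192
        family = genus % 96
        order = family % 48
        klass = order % 24
        phylum = klass % 12
        lineages[f"F{f}"] = ("Bacteria", f"Phylum{phylum}", f"Class{klass}",
                             f"Order{order}", f"Family{family}",
                             f"Genus{genus}", f"Species{f}")
    return TaxonomyMap(lineages)


def simulate_count_tables(spec: ScenarioSpec):
    """Dirichlet-multinomial count tables with controlled parallel structure.

    A shared base composition is drawn once; each pair receives a mild
    lognormal baseline wobble (so pairs occupy distinct regions of
    community space), and its "to" group additionally gets log-fold shifts
    of size ``shift_magnitude`` on a subset of ``shift_fraction`` of the
    features.  Across pairs the shifted subset is shared per-feature with
    probability ``overlap`` (parallel), disjoint (orthogonal), or shared
    with alternating shift sign (antiparallel).  Counts are
    Dirichlet-multinomial: per sample, proportions ~ Dirichlet(alpha * p)
    with total mass alpha = concentration * n_features, then counts ~
    Multinomial(depth).

    Returns (FeatureTable, TaxonomyMap, SampleMetadata).
    """
    if spec.n_features < 10:
        raise ValueError("need n_features >= 10")
    if spec.depth < spec.n_features:
        raise ValueError(f"depth {spec.depth} too small for "
                         f"{spec.n_features} features")
    rng = np.random.default_rng(spec.seed)
    nf = spec.n_features
    n_pairs = spec.pairs_per_system
    base = rng.dirichlet(np.full(nf, 1.0))
    m = max(1, int(round(spec.shift_fraction * nf)))

    first_subset = rng.choice(nf, size=m, replace=False)
    subsets, signs = [], []
    used = set(first_subset.tolist())
    for i in range(n_pairs):
        if spec.parallelism_mode == "parallel":
            keep = rng.random(m) < spec.overlap
            subset = first_subset.copy()
            pool = np.setdiff1d(np.arange(nf), first_subset)
            n_swap = int((~keep).sum())
            if n_swap:
                subset[~keep] = rng.choice(pool, size=n_swap, replace=False)
            sign = np.ones(m)
        elif spec.parallelism_mode == "antiparallel":
            subset = first_subset.copy()
            sign = np.ones(m) * (1.0 if i % 2 == 0 else -1.0)
        elif spec.parallelism_mode == "orthogonal":
            pool = np.setdiff1d(np.arange(nf), np.array(sorted(used)))
            if len(pool) < m:
                raise ValueError("not enough features for disjoint subsets; "
                                 "lower shift_fraction or pairs_per_system")
            subset = rng.choice(pool, size=m, replace=False)
            used.update(subset.tolist())
            sign = np.ones(m)
        else:  # random
            subset = rng.choice(nf, size=m, replace=False)
            sign = np.ones(m)
        subsets.append(subset)
        signs.append(sign)

    alpha_mass = spec.concentration * nf
    cols, col_ids, meta_rows = [], [], []
    for i in range(n_pairs):
        wobble = np.exp(spec.dispersion * 0.3 * rng.standard_normal(nf))
        p_from = base * wobble
        p_from /= p_from.sum()
        logfold = np.zeros(nf)
        logfold[subsets[i]] = signs[i] * spec.shift_magnitude
        p_to = p_from * np.exp(logfold)
        p_to /= p_to.sum()
        for eco, p in (("from", p_from), ("to", p_to)):
            for s in range(spec.n_per_group):
                props = rng.dirichlet(alpha_mass * p)
                counts = rng.multinomial(spec.depth, props)
                sid = f"S{i}_{eco}_{s}"
                cols.append(counts)
                col_ids.append(sid)
                meta_rows.append({"sample-id": sid, "system": "system0",
                                  "population": f"pair{i}_{eco}",
                                  "ecotype": eco})
    table = FeatureTable(pd.DataFrame(
        np.array(cols).T.astype(float),
        index=[f"F{f}" for f in range(nf)], columns=col_ids))
    meta = SampleMetadata(pd.DataFrame(meta_rows).set_index("sample-id"))
    return table, _nested_taxonomy(nf), meta
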