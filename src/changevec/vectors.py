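"""Centroid change-vectors and the angles between them.

A change-vector connects two group centroids inside one shared ordination.
Its length L measures the magnitude of community divergence; the angle
theta between two change-vectors measures how parallel the two divergences
are: theta < 90 deg is the parallel side, theta around 90 deg is orthogonal
(independent) change, theta > 90 deg is anti-parallel change.  Direction
comes from the comparison design (e.g. always benthic -> limnetic) and is
never auto-flipped: a consistent direction convention is what makes angles
comparable across population pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .io import ComparisonDesign, DesignError, SampleMetadata
from .ordination import Ordination

__all__ = ["ChangeVectorSet", "group_centroids", "change_vectors",
           "pairwise_angles", "angle_between"]

#: Vectors shorter than this are degenerate: their direction (hence any
#: angle involving them) is undefined.
DEGENERATE_NORM = 1e-12


@dataclass
class ChangeVectorSet:
    """Labelled centroid-difference vectors sharing one coordinate basis."""

    vector_ids: list[str]
    vectors: np.ndarray          # k x d
    from_groups: list[str]
    to_groups: list[str]

    def __post_init__(self) -> None:
        self.vectors = np.atleast_2d(np.asarray(self.vectors, dtype=float))
        k = self.vectors.shape[0]
        if not (len(self.vector_ids) == len(self.from_groups) == len(self.to_groups) == k):
            raise ValueError("vector ids/groups do not match vector count")
        if len(set(self.vector_ids)) != k:
            raise ValueError("duplicate vector ids")
        norms = np.linalg.norm(self.vectors, axis=1)
        bad = [vid for vid, nrm in zip(self.vector_ids, norms) if nrm < DEGENERATE_NORM]
        if bad:
            raise DesignError(
                f"degenerate (zero-length) change vector(s): {bad}; "
                "the 'from' and 'to' centroids coincide and the angle is undefined"
            )

    @property
    def k(self) -> int:
        return self.vectors.shape[0]

    @property
    def d(self) -> int:
        return self.vectors.shape[1]

    @property
    def lengths(self) -> np.ndarray:
        return np.linalg.norm(self.vectors, axis=1)

    def unit_vectors(self) -> np.ndarray:
        return self.vectors / self.lengths[:, None]


def group_centroids(ordn: Ordination | pd.DataFrame, meta: SampleMetadata,
                    grouping: str = "population") -> dict[str, np.ndarray]:
    """Arithmetic-mean centroid of each group's samples, on all retained axes.

    `grouping` names a metadata column (usually "population").  `ordn` is
    either a PCoA Ordination or a plain samples x axes DataFrame of
    coordinates (e.g. NMDS scores from another tool).  Only samples
    present in the ordination contribute; a group with no such sample is
    a design error.
    """
    if isinstance(ordn, pd.DataFrame):
        sample_ids = [str(s) for s in ordn.index]
        coords = ordn.to_numpy(dtype=float)
    else:
        sample_ids = ordn.sample_ids
        coords = ordn.coordinates
    pos = {sid: i for i, sid in enumerate(sample_ids)}
    centroids: dict[str, np.ndarray] = {}
    for group, members in meta.group_members(grouping).items():
        idx = [pos[s] for s in members if s in pos]
        if not idx:
            raise DesignError(f"group {group!r} has no samples in the ordination")
        centroids[group] = coords[idx].mean(axis=0)
    return centroids


def change_vectors(centroids: dict[str, np.ndarray],
                   design: ComparisonDesign) -> ChangeVectorSet:
    """Build v = centroid(to) - centroid(from) for every design entry.

    All centroids must come from the same shared ordination (enforced here
    only as dimension consistency; mixing ordinations is the caller's bug
    and produces meaningless angles).
    """
    dims = {np.asarray(c).shape[0] for c in centroids.values()}
    if len(dims) > 1:
        raise ValueError(f"centroids have inconsistent dimensionality: {sorted(dims)}; "
                         "all vectors must come from a single shared ordination")
    ids, vecs, froms, tos = [], [], [], []
    for e in design.entries:
        for g in (e.from_group, e.to_group):
            if g not in centroids:
                raise DesignError(f"vector {e.vector_id!r}: group {g!r} has no centroid")
        ids.append(e.vector_id)
        vecs.append(np.asarray(centroids[e.to_group], dtype=float)
                    - np.asarray(centroids[e.from_group], dtype=float))
        froms.append(e.from_group)
        tos.append(e.to_group)
    return ChangeVectorSet(ids, np.array(vecs), froms, tos)


def angle_between(v: np.ndarray, w: np.ndarray) -> float:
    """Angle between two vectors in degrees, in [0, 180].

    The normalized dot product is clamped to [-1, 1] before arccos so that
    exactly (anti)parallel vectors are safe against floating-point overshoot.
    """
    v = np.asarray(v, dtype=float)
    w = np.asarray(w, dtype=float)
    nv, nw = np.linalg.norm(v), np.linalg.norm(w)
    if nv < DEGENERATE_NORM or nw < DEGENERATE_NORM:
        raise ValueError("angle undefined for zero-length vector")
    cosine = np.clip(np.dot(v, w) / (nv * nw), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosine)))


def pairwise_angles(vs: ChangeVectorSet) -> pd.DataFrame:
    """Angle table over all C(k,2) unordered vector pairs.

    Columns: vector_id_1, vector_id_2, theta_deg, L1, L2, meanL, where
    meanL is the unweighted mean of the two lengths — the magnitude
    covariate paired with each angle.
    """
    if vs.k < 2:
        raise ValueError("pairwise angles need at least 2 vectors")
    U = vs.unit_vectors()
    L = vs.lengths
    G = np.clip(U @ U.T, -1.0, 1.0)
    rows = []
    for i, j in combinations(range(vs.k), 2):
        rows.append({
            "vector_id_1": vs.vector_ids[i],
            "vector_id_2": vs.vector_ids[j],
            "theta_deg": float(np.degrees(np.arccos(G[i, j]))),
            "L1": float(L[i]),
            "L2": float(L[j]),
            "meanL": float((L[i] + L[j]) / 2.0),
        })
    return pd.DataFrame(rows)
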