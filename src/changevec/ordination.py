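"""Distances and principal coordinates: the space where change-vectors live.

The analysis chain is: (optional) rarefaction of a count table to even
depth, (optional) collapse of features to a named taxonomic rank,
Bray-Curtis dissimilarity, and principal coordinates analysis (PCoA) of
the resulting distance matrix.  Precomputed distance matrices (e.g.
UniFrac exported from other tools) can enter the chain directly at the
PCoA step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist
from skbio import DistanceMatrix

from .io import FeatureTable, TaxonomyMap, RANK_NAMES

__all__ = ["Ordination", "rarefy", "collapse_taxonomy", "bray_curtis", "pcoa",
           "write_ordination", "read_ordination", "COLLAPSIBLE_LEVELS"]

logger = logging.getLogger(__name__)

#: Ranks at which `collapse_taxonomy` may pool features (domain excluded:
#: collapsing to domain leaves nothing to ordinate).
COLLAPSIBLE_LEVELS = RANK_NAMES[1:]  # phylum .. species

#: Relative eigenvalue tolerance: axes with eigenvalue <= tol * max are noise.
EIG_REL_TOL = 1e-8


@dataclass
class Ordination:
    """Sample coordinates on the retained PCoA axes.

    Attributes
    ----------
    sample_ids : list of str
    coordinates : ndarray, samples x d
        Axis k is the k-th principal coordinate, scaled by sqrt(eigenvalue).
    eigenvalues : ndarray, length d
        Strictly positive, nonincreasing.
    negative_mass : float
        Sum of |negative eigenvalues| discarded (Bray-Curtis is
        non-Euclidean, so some negative mass is normal).
    """

    sample_ids: list[str]
    coordinates: np.ndarray
    eigenvalues: np.ndarray
    negative_mass: float = 0.0

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        n, d = self.coordinates.shape
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match coordinate rows")
        if len(self.eigenvalues) != d:
            raise ValueError("eigenvalues length does not match coordinate columns")
        if d < 1:
            raise ValueError("ordination must retain at least one axis")
        if (self.eigenvalues <= 0).any():
            raise ValueError("retained eigenvalues must be strictly positive")
        if (np.diff(self.eigenvalues) > 1e-12).any():
            raise ValueError("eigenvalues must be nonincreasing")

    @property
    def d(self) -> int:
        return self.coordinates.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PC{k+1}" for k in range(self.d)]
        return pd.DataFrame(self.coordinates, index=self.sample_ids, columns=cols)


def rarefy(table: FeatureTable, depth: int, seed: int) -> FeatureTable:
    """Subsample each sample without replacement to exactly `depth` counts.

    Samples whose total is below `depth` are dropped (and logged); a sample
    whose total equals `depth` is returned unchanged.  One integer seed
    governs all samples through deterministic per-sample substreams, so
    results are reproducible and independent of sample order.

    Raises
    ------
    ValueError
        If depth <= 0, counts are non-integral, or no sample survives.
    """
    if depth <= 0:
        raise ValueError(f"rarefaction depth must be positive, got {depth}")
    counts = table.counts
    if not np.allclose(counts, np.round(counts)):
        raise ValueError("rarefaction requires integer counts")
    counts = np.round(counts).astype(np.int64)

    root = np.random.SeedSequence(seed)
    kept_cols: list[int] = []
    out = np.zeros_like(counts)
    dropped: list[str] = []
    # spawn one substream per sample position; dropping a sample does not
    # shift the streams of the others
    streams = root.spawn(table.n_samples)
    for j, sid in enumerate(table.sample_ids):
        total = int(counts[:, j].sum())
        if total < depth:
            dropped.append(sid)
            continue
        if total == depth:
            out[:, j] = counts[:, j]
        else:
            rng = np.random.default_rng(streams[j])
            out[:, j] = rng.multivariate_hypergeometric(counts[:, j], depth)
        kept_cols.append(j)
    if dropped:
        logger.info("rarefy: dropped %d sample(s) below depth %d: %s",
                    len(dropped), depth, ", ".join(dropped))
    if not kept_cols:
        raise ValueError(f"all samples fall below rarefaction depth {depth}")
    df = pd.DataFrame(out[:, kept_cols],
                      index=table.feature_ids,
                      columns=[table.sample_ids[j] for j in kept_cols])
    return FeatureTable(df.astype(float))


def collapse_taxonomy(table: FeatureTable, tax: TaxonomyMap, level: str,
                      missing: str = "error") -> FeatureTable:
    """Sum features sharing the same lineage truncated at `level`.

    `level` is one of phylum, class, order, family, genus, species.
    Features whose lineage is too short to reach `level` are pooled into a
    single ``unclassified_<level>`` bin.  Features absent from the taxonomy
    are an error by default; pass ``missing="pool"`` to send them to the
    unclassified bin instead.  Per-sample totals are conserved exactly.
    """
    if level not in COLLAPSIBLE_LEVELS:
        raise ValueError(f"level must be one of {COLLAPSIBLE_LEVELS}, got {level!r}")
    if missing not in ("error", "pool"):
        raise ValueError("missing must be 'error' or 'pool'")
    depth = RANK_NAMES.index(level) + 1  # lineage prefix length at this rank
    unclassified = f"unclassified_{level}"
    labels: list[str] = []
    for fid in table.feature_ids:
        if fid not in tax:
            if missing == "error":
                raise KeyError(f"feature {fid!r} absent from taxonomy")
            labels.append(unclassified)
            continue
        ranks = tax[fid]
        if len(ranks) < depth or ranks[depth - 1] == "":
            labels.append(unclassified)
        else:
            labels.append(";".join(ranks[:depth]))
    grouped = table.data.groupby(labels, sort=False).sum()
    grouped.index.name = table.data.index.name
    return FeatureTable(grouped)


def bray_curtis(table: FeatureTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between all sample pairs.

    BC(i, j) = sum_k |x_ki - x_kj| / sum_k (x_ki + x_kj), in [0, 1].
    """
    if table.n_samples < 2:
        raise ValueError("Bray-Curtis requires at least 2 samples")
    totals = table.sample_totals()
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero total abundance: {list(zero.index)}")
    profiles = table.counts.T  # samples x features
    dm = squareform(pdist(profiles, metric="braycurtis"))
    return DistanceMatrix(dm, ids=table.sample_ids)


def pcoa(dm: DistanceMatrix, n_axes: int | None = None) -> Ordination:
    """Principal coordinates analysis by Gower double-centering.

    B = -1/2 J D^2 J with J = I - 11'/n; the coordinates are the
    eigenvectors of B scaled by sqrt(eigenvalue).  Negative eigenvalues
    (non-Euclidean input) are discarded and their absolute mass recorded;
    positive axes below a relative tolerance of the leading eigenvalue are
    treated as numerical noise.  Axis signs are fixed deterministically by
    making the largest-|loading| entry of each axis positive.
    """
    D = np.asarray(dm.data, dtype=float)
    n = D.shape[0]
    if n < 2:
        raise ValueError("PCoA requires at least 2 samples")
    D2 = D ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * (J @ D2 @ J)
    B = (B + B.T) / 2.0  # enforce exact symmetry for eigh
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]

    negative_mass = float(-eigvals[eigvals < 0].sum())
    tol = EIG_REL_TOL * max(eigvals[0], 0.0)
    keep = eigvals > max(tol, 0.0)
    if not keep.any():
        raise ValueError("degenerate input: no positive PCoA eigenvalue "
                         "(all samples coincide?)")
    eigvals, eigvecs = eigvals[keep], eigvecs[:, keep]
    if n_axes is not None:
        if n_axes < 1:
            raise ValueError("n_axes must be >= 1")
        eigvals, eigvecs = eigvals[:n_axes], eigvecs[:, :n_axes]
    if negative_mass > 0:
        logger.info("pcoa: discarded negative eigenvalue mass %.6g "
                    "(%.2f%% of positive mass)", negative_mass,
                    100 * negative_mass / eigvals.sum())

    coords = eigvecs * np.sqrt(eigvals)
    # deterministic sign: largest-|loading| entry of each axis positive
    pivot = np.abs(coords).argmax(axis=0)
    signs = np.sign(coords[pivot, np.arange(coords.shape[1])])
    signs[signs == 0] = 1.0
    coords = coords * signs
    return Ordination(sample_ids=list(dm.ids), coordinates=coords,
                      eigenvalues=eigvals, negative_mass=negative_mass)


def write_ordination(ordn: Ordination, path) -> None:
    """Write eigenvalues header block plus sample x axis coordinates."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#eigenvalues\t" +
                 "\t".join(f"{v:.12g}" for v in ordn.eigenvalues) + "\n")
        fh.write("#negative_mass\t" + f"{ordn.negative_mass:.12g}" + "\n")
        ordn.to_frame().rename_axis("sample-id").to_csv(fh, sep="\t",
                                                        float_format="%.12g")


def read_ordination(path) -> Ordination:
    eigenvalues = None
    negative_mass = 0.0
    header_lines = 0
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            header_lines += 1
            fields = line.rstrip("\n").split("\t")
            if fields[0] == "#eigenvalues":
                eigenvalues = np.array([float(x) for x in fields[1:]])
            elif fields[0] == "#negative_mass":
                negative_mass = float(fields[1])
    df = pd.read_csv(path, sep="\t", index_col=0, skiprows=header_lines)
    if eigenvalues is None:
        raise ValueError(f"{path}: missing #eigenvalues header")
    return Ordination(sample_ids=[str(x) for x in df.index],
                      coordinates=df.to_numpy(dtype=float),
                      eigenvalues=eigenvalues, negative_mass=negative_mass)
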