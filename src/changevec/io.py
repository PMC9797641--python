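"""Reading and writing the tabular artifacts of community change-vector analysis.

All interchange is plain tab-delimited text: BIOM-style TSV feature tables
(features as rows, samples as columns), QIIME2-style taxonomy tables,
sample metadata, LSMAT-style square distance matrices, comparison designs,
and the angle/test result tables this package writes.  Parsing is strict:
missing values, duplicate identifiers and asymmetric matrices are errors,
never silently repaired (beyond averaging distance asymmetries inside the
1e-8 floating-point tolerance).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

__all__ = [
    "FeatureTable",
    "TaxonomyMap",
    "SampleMetadata",
    "ComparisonDesign",
    "DesignEntry",
    "FormatError",
    "DesignError",
    "RANK_NAMES",
    "read_feature_table",
    "read_taxonomy",
    "read_metadata",
    "read_design",
    "read_distance_matrix",
    "write_feature_table",
    "write_distance_matrix",
    "write_results",
]

#: Canonical rank names, coarsest to finest.  Index 0 is domain/kingdom.
RANK_NAMES = ("domain", "phylum", "class", "order", "family", "genus", "species")

#: Tolerance for distance-matrix asymmetry (absolute).
SYMMETRY_TOL = 1e-8


class FormatError(ValueError):
    """A file violates the expected tabular dialect."""


class DesignError(ValueError):
    """A comparison design is internally inconsistent."""


@dataclass
class FeatureTable:
    """Nonnegative feature-by-sample count/abundance matrix.

    Parameters
    ----------
    data : pandas.DataFrame
        Features as rows (index), samples as columns.  Order is meaningful
        and preserved through every operation.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        idx, cols = self.data.index, self.data.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise FormatError(f"duplicate feature ids: {dups}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups}")
        values = self.data.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise FormatError("feature table contains non-numeric entries")
        if np.isnan(values).any():
            raise ValueError("feature table contains missing values")
        if (values < 0).any():
            raise ValueError("feature table contains negative counts")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        """Counts as a features x samples float array."""
        return self.data.to_numpy(dtype=float)

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def sample_totals(self) -> pd.Series:
        return self.data.sum(axis=0)


@dataclass
class TaxonomyMap:
    """Feature id -> tuple of rank names, coarsest first, possibly truncated."""

    lineages: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        for fid, ranks in self.lineages.items():
            if len(ranks) > len(RANK_NAMES):
                raise FormatError(
                    f"lineage for {fid!r} has {len(ranks)} ranks; max is {len(RANK_NAMES)}"
                )

    def __getitem__(self, feature_id: str) -> tuple[str, ...]:
        return self.lineages[feature_id]

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self.lineages

    def __len__(self) -> int:
        return len(self.lineages)


@dataclass
class SampleMetadata:
    """Per-sample system / population / ecotype labels."""

    data: pd.DataFrame  # index: sample id; columns: system, population, ecotype

    REQUIRED = ("system", "population", "ecotype")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise FormatError(f"metadata missing required columns: {missing}")
        if self.data.index.has_duplicates:
            raise FormatError("duplicate sample ids in metadata")
        if self.data[list(self.REQUIRED)].isna().any().any():
            raise ValueError("metadata contains missing labels")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def group_members(self, column: str) -> dict[str, list[str]]:
        """Map each label in `column` to the samples carrying it (input order)."""
        out: dict[str, list[str]] = {}
        for sid, label in self.data[column].items():
            out.setdefault(str(label), []).append(sid)
        return out


@dataclass(frozen=True)
class DesignEntry:
    vector_id: str
    from_group: str
    to_group: str


@dataclass
class ComparisonDesign:
    """An ordered list of directed centroid comparisons.

    ``kind`` is "pair" (one vector per population pair) or "outgroup"
    (every vector starts at a common outgroup centroid).  Direction is part
    of the design and is never auto-flipped downstream.
    """

    kind: str
    entries: list[DesignEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in ("pair", "outgroup"):
            raise DesignError(f"unknown design kind {self.kind!r}")
        seen: set[str] = set()
        for e in self.entries:
            if e.from_group == e.to_group:
                raise DesignError(
                    f"vector {e.vector_id!r}: from_group == to_group ({e.from_group!r})"
                )
            if e.vector_id in seen:
                raise DesignError(f"duplicate vector id {e.vector_id!r}")
            seen.add(e.vector_id)
        if self.kind == "outgroup" and self.entries:
            froms = {e.from_group for e in self.entries}
            if len(froms) > 1:
                raise DesignError(
                    f"outgroup design must share a single from_group, got {sorted(froms)}"
                )

    @property
    def vector_ids(self) -> list[str]:
        return [e.vector_id for e in self.entries]


def _read_tsv_lines(path) -> list[list[str]]:
    rows: list[list[str]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for raw in fh:
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            rows.append(line.split("\t"))
    if not rows:
        raise FormatError(f"{path}: empty file")
    return rows


def read_feature_table(path, transposed: bool = False) -> FeatureTable:
    """Read a BIOM-style TSV feature table.

    The first column holds feature ids, remaining columns are samples.  A
    leading comment line (``# Constructed from biom file``) and/or a header
    starting with ``#OTU ID`` are tolerated, matching QIIME2 TSV exports.
    Set ``transposed=True`` when samples are rows.
    """
    rows = _read_tsv_lines(path)
    # drop pure comment lines, keep the "#OTU ID" header
    while rows and rows[0][0].startswith("#") and not rows[0][0].lower().startswith("#otu"):
        rows.pop(0)
    if not rows:
        raise FormatError(f"{path}: no header row")
    header = rows[0]
    width = len(header)
    sample_ids = header[1:]
    feature_ids: list[str] = []
    values: list[list[float]] = []
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != width:
            raise FormatError(
                f"{path}:{lineno}: ragged row ({len(row)} fields, expected {width})"
            )
        feature_ids.append(row[0])
        try:
            values.append([float(x) for x in row[1:]])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric value ({exc})") from exc
    df = pd.DataFrame(values, index=feature_ids, columns=sample_ids, dtype=float)
    if transposed:
        df = df.T
    return FeatureTable(df)


_PREFIX_RE = re.compile(r"^[A-Za-z]_?_?\d*_{0,2}")


def _strip_rank_prefix(token: str) -> str:
    """Strip Silva/Greengenes-style prefixes: ``D_1__``, ``p__``, ``k__`` etc."""
    token = token.strip()
    m = re.match(r"^(D_\d+__|[a-zA-Z]__)", token)
    return token[m.end():].strip() if m else token


def read_taxonomy(path) -> TaxonomyMap:
    """Read a two-column taxonomy TSV (feature id, semicolon-joined lineage).

    A header line whose first field is ``Feature ID`` / ``#OTU ID`` (any
    case) is skipped.  Rank prefixes are stripped and empty trailing ranks
    dropped, so ``D_0__Bacteria; D_1__Firmicutes`` becomes
    ``("Bacteria", "Firmicutes")``.
    """
    rows = _read_tsv_lines(path)
    if rows and rows[0][0].lower() in ("feature id", "#otu id", "feature-id", "featureid"):
        rows = rows[1:]
    lineages: dict[str, tuple[str, ...]] = {}
    for lineno, row in enumerate(rows, start=1):
        fid = row[0]
        if fid in lineages:
            raise FormatError(f"{path}: feature {fid!r} listed twice")
        lineage = row[1] if len(row) > 1 else ""
        ranks = [_strip_rank_prefix(tok) for tok in lineage.split(";")]
        while ranks and ranks[-1] == "":
            ranks.pop()
        lineages[fid] = tuple(ranks)
    return TaxonomyMap(lineages)


def read_metadata(path) -> SampleMetadata:
    """Read sample metadata TSV with columns sample-id, system, population, ecotype."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    id_col = df.columns[0]
    if id_col.lower().replace("_", "-") not in ("sample-id", "sampleid", "#sample-id"):
        raise FormatError(
            f"{path}: first column must be sample-id, got {id_col!r}"
        )
    df = df.set_index(id_col)
    df.index.name = "sample-id"
    return SampleMetadata(df)


def read_design(path) -> ComparisonDesign:
    """Read a comparison-design TSV (columns vector_id, from_group, to_group).

    Design kind is declared either with a ``#kind: outgroup`` comment line
    or inferred: a shared from_group across >1 entries means outgroup,
    otherwise pair.
    """
    kind = None
    rows = _read_tsv_lines(path)
    body: list[list[str]] = []
    for row in rows:
        if row[0].startswith("#kind:"):
            kind = row[0].split(":", 1)[1].strip()
        elif not row[0].startswith("#"):
            body.append(row)
    if not body:
        raise FormatError(f"{path}: no design rows")
    header = [h.strip() for h in body[0]]
    required = ["vector_id", "from_group", "to_group"]
    if header[:3] != required:
        raise FormatError(f"{path}: design header must be {required}, got {header[:3]}")
    entries = []
    for row in body[1:]:
        if len(row) < 3:
            raise FormatError(f"{path}: design row too short: {row}")
        entries.append(DesignEntry(row[0].strip(), row[1].strip(), row[2].strip()))
    if kind is None:
        froms = {e.from_group for e in entries}
        kind = "outgroup" if len(entries) > 1 and len(froms) == 1 else "pair"
    return ComparisonDesign(kind=kind, entries=entries)


def read_distance_matrix(path) -> DistanceMatrix:
    """Read an LSMAT-style square labelled distance matrix.

    The matrix must be symmetric within 1e-8 (asymmetries inside the
    tolerance are averaged away) and have a zero diagonal.  Suitable for
    precomputed UniFrac exports as well as matrices written by this package.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise FormatError(f"{path}: header row and header column labels differ")
    if df.index.has_duplicates:
        raise FormatError(f"{path}: duplicate sample labels")
    mat = df.to_numpy(dtype=float)
    if np.isnan(mat).any():
        raise ValueError(f"{path}: missing values in distance matrix")
    asym = np.abs(mat - mat.T).max() if mat.size else 0.0
    if asym > SYMMETRY_TOL:
        raise ValueError(
            f"{path}: matrix asymmetric beyond tolerance (max |d_ij - d_ji| = {asym:.3g})"
        )
    mat = (mat + mat.T) / 2.0
    if mat.size and np.abs(np.diag(mat)).max() > SYMMETRY_TOL:
        raise ValueError(f"{path}: nonzero diagonal")
    np.fill_diagonal(mat, 0.0)
    return DistanceMatrix(mat, ids=[str(x) for x in df.index])


def write_feature_table(table: FeatureTable, path) -> None:
    df = table.data.copy()
    df.index.name = "#OTU ID"
    df.to_csv(path, sep="\t", float_format="%.12g")


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    df = pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids)
    df.index.name = ""
    df.to_csv(path, sep="\t", float_format="%.12g")


def write_results(angles: pd.DataFrame, tests, angles_path, tests_path) -> None:
    """Write the per-comparison angle table and the test-summary table.

    ``angles`` is an AngleTable DataFrame (vector_id_1, vector_id_2,
    theta_deg, L1, L2, meanL).  ``tests`` is an iterable of TestResult-like
    objects exposing ``method``, ``n``, ``statistic``, ``p_value`` and
    ``extras``.  Values round-trip through 12 significant digits.
    """
    angles.to_csv(angles_path, sep="\t", index=False, float_format="%.12g")
    rows = []
    for t in tests:
        row = {"method": t.method, "n": t.n, "statistic": t.statistic, "p_value": t.p_value}
        row.update(t.extras)
        rows.append(row)
    pd.DataFrame(rows).to_csv(tests_path, sep="\t", index=False, float_format="%.12g")
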