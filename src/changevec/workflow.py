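"""End-to-end orchestration: feature table (or distance matrix) to test report.

`run_pipeline` executes the full analysis for one study system —
(optional) rarefaction, (optional) taxonomy collapse, Bray-Curtis, PCoA,
centroid change-vectors, pairwise angles, and the selected parallelism
tests — and writes every intermediate artifact plus a run manifest.
`taxon_level_sweep` repeats it at each taxonomic rank to ask whether the
direction and magnitude of community change depend on taxonomic
resolution.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from . import __version__
from .io import (ComparisonDesign, FeatureTable, SampleMetadata, TaxonomyMap,
                 read_design, read_distance_matrix, read_feature_table,
                 read_metadata, read_taxonomy, write_distance_matrix,
                 write_feature_table, write_results)
from .ordination import (COLLAPSIBLE_LEVELS, Ordination, bray_curtis,
                         collapse_taxonomy, pcoa, rarefy, write_ordination)
from .stats import (TestResult, monte_carlo_parallelism, rayleigh_test,
                    shapiro_gate, t_test_vs_90, wilcoxon_vs_90)
from .vectors import ChangeVectorSet, change_vectors, group_centroids, \
    pairwise_angles

__all__ = ["RunConfig", "AnalysisResult", "analyze", "run_pipeline",
           "taxon_level_sweep"]

logger = logging.getLogger(__name__)

METHODS = ("auto", "t", "wilcoxon", "mc", "rayleigh", "all")


@dataclass
class RunConfig:
    """Configuration of one pipeline run (file-path level)."""

    feature_table: str | None = None
    distance_matrix: str | None = None
    metadata: str = ""
    design: str = ""
    output_dir: str = "changevec_out"
    metric: str = "bray_curtis"          # or "precomputed"
    n_axes: int | None = None
    methods: tuple = ("auto", "mc", "rayleigh")
    iterations: int = 100_000
    seed: int | None = None
    taxonomy: str | None = None
    taxonomy_level: str | None = None
    rarefaction_depth: int | None = None
    grouping: str = "population"

    def validate(self) -> None:
        if self.metric not in ("bray_curtis", "precomputed"):
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.metric == "precomputed":
            if not self.distance_matrix:
                raise ValueError("metric=precomputed requires distance_matrix")
        elif not self.feature_table:
            raise ValueError("metric=bray_curtis requires feature_table")
        for p in (self.feature_table, self.distance_matrix, self.metadata,
                  self.design, self.taxonomy):
            if p and not Path(p).exists():
                raise FileNotFoundError(f"configured input does not exist: {p}")
        bad = [m for m in self.methods if m not in METHODS]
        if bad:
            raise ValueError(f"unknown method(s) {bad}; choose from {METHODS}")
        if any(m in ("mc", "all") for m in self.methods) and self.seed is None:
            raise ValueError("seed is required when the Monte-Carlo test is selected")
        if self.rarefaction_depth is not None and self.seed is None:
            raise ValueError("seed is required when rarefaction is enabled")


@dataclass
class AnalysisResult:
    ordination: Ordination
    vectors: ChangeVectorSet
    angles: pd.DataFrame
    tests: list[TestResult]
    normality: str | None = None
    table: FeatureTable | None = None
    distance: DistanceMatrix | None = None
    log: dict = field(default_factory=dict)


def _select_tests(angles: pd.DataFrame, vs: ChangeVectorSet, methods,
                  iterations: int, seed: int | None):
    theta = angles["theta_deg"].to_numpy()
    tests: list[TestResult] = []
    normality = None
    for m in methods:
        if m == "auto":
            normality = shapiro_gate(theta) if len(theta) >= 3 else "normal"
            chosen = t_test_vs_90 if normality == "normal" else wilcoxon_vs_90
            tests.append(chosen(theta))
        elif m == "t":
            tests.append(t_test_vs_90(theta))
        elif m == "wilcoxon":
            tests.append(wilcoxon_vs_90(theta))
        elif m == "mc":
            if seed is None:
                raise ValueError("Monte-Carlo test requires a seed")
            tests.append(monte_carlo_parallelism(vs, iterations=iterations,
                                                 seed=seed))
        elif m == "rayleigh":
            tests.append(rayleigh_test(vs))
        elif m == "all":
            normality = shapiro_gate(theta) if len(theta) >= 3 else "normal"
            tests.append(t_test_vs_90(theta))
            tests.append(wilcoxon_vs_90(theta))
            if seed is None:
                raise ValueError("Monte-Carlo test requires a seed")
            tests.append(monte_carlo_parallelism(vs, iterations=iterations,
                                                 seed=seed))
            tests.append(rayleigh_test(vs))
    return tests, normality


def analyze(*, table: FeatureTable | None = None,
            distance: DistanceMatrix | None = None,
            metadata: SampleMetadata,
            design: ComparisonDesign,
            taxonomy: TaxonomyMap | None = None,
            taxonomy_level: str | None = None,
            rarefaction_depth: int | None = None,
            n_axes: int | None = None,
            methods=("auto", "mc", "rayleigh"),
            iterations: int = 100_000,
            seed: int | None = None,
            grouping: str = "population") -> AnalysisResult:
    """In-memory pipeline: objects in, AnalysisResult out.

    Exactly one of ``table`` / ``distance`` must be given.  Stages that
    have no configured inputs (rarefaction, collapse) are skipped.
    """
    if (table is None) == (distance is None):
        raise ValueError("provide exactly one of table or distance")
    log: dict = {}
    if table is not None:
        if rarefaction_depth is not None:
            if seed is None:
                raise ValueError("rarefaction requires a seed")
            before = table.n_samples
            table = rarefy(table, rarefaction_depth, seed)
            log["rarefaction_dropped"] = before - table.n_samples
        if taxonomy_level is not None:
            if taxonomy is None:
                raise ValueError("taxonomy_level given without a taxonomy")
            table = collapse_taxonomy(table, taxonomy, taxonomy_level)
            log["features_after_collapse"] = table.n_features
        distance = bray_curtis(table)
    ordn = pcoa(distance, n_axes=n_axes)
    log["retained_axes"] = ordn.d
    log["negative_eigenvalue_mass"] = ordn.negative_mass
    centroids = group_centroids(ordn, metadata, grouping)
    vs = change_vectors(centroids, design)
    angles = pairwise_angles(vs)
    tests, normality = _select_tests(angles, vs, methods, iterations, seed)
    return AnalysisResult(ordination=ordn, vectors=vs, angles=angles,
                          tests=tests, normality=normality, table=table,
                          distance=distance, log=log)


def run_pipeline(config: RunConfig) -> AnalysisResult:
    """Execute a configured run and write all artifacts to the output dir.

    Outputs: ``distance_matrix.tsv``, ``ordination.tsv``, ``vectors.tsv``,
    ``angles.tsv``, ``tests.tsv`` and a ``manifest.json`` sufficient to
    re-execute the run.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    metadata = read_metadata(config.metadata)
    design = read_design(config.design)
    table = distance = taxonomy = None
    if config.metric == "precomputed":
        distance = read_distance_matrix(config.distance_matrix)
    else:
        table = read_feature_table(config.feature_table)
        if config.taxonomy:
            taxonomy = read_taxonomy(config.taxonomy)

    result = analyze(table=table, distance=distance, metadata=metadata,
                     design=design, taxonomy=taxonomy,
                     taxonomy_level=config.taxonomy_level,
                     rarefaction_depth=config.rarefaction_depth,
                     n_axes=config.n_axes, methods=tuple(config.methods),
                     iterations=config.iterations, seed=config.seed,
                     grouping=config.grouping)

    if result.table is not None:
        write_feature_table(result.table, out / "feature_table.tsv")
    write_distance_matrix(result.distance, out / "distance_matrix.tsv")
    write_ordination(result.ordination, out / "ordination.tsv")
    vec_df = pd.DataFrame(result.vectors.vectors,
                          index=result.vectors.vector_ids,
                          columns=[f"PC{j+1}" for j in
                                   range(result.vectors.d)])
    vec_df.insert(0, "to_group", result.vectors.to_groups)
    vec_df.insert(0, "from_group", result.vectors.from_groups)
    vec_df.insert(len(vec_df.columns), "L", result.vectors.lengths)
    vec_df.rename_axis("vector_id").to_csv(out / "vectors.tsv", sep="\t",
                                           float_format="%.12g")
    write_results(result.angles, result.tests,
                  out / "angles.tsv", out / "tests.tsv")

    manifest = {"config": asdict(config), "package_version": __version__,
                "numpy_version": np.__version__,
                "retained_axes": result.ordination.d,
                "normality": result.normality, "log": result.log}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    logger.info("run complete: %d samples, %d retained axes, %d vectors",
                len(result.ordination.sample_ids), result.ordination.d,
                result.vectors.k)
    return result


def taxon_level_sweep(table: FeatureTable, taxonomy: TaxonomyMap,
                      metadata: SampleMetadata, design: ComparisonDesign,
                      levels=COLLAPSIBLE_LEVELS, n_axes: int | None = None,
                      grouping: str = "population") -> pd.DataFrame:
    """Repeat the angle analysis at each taxonomic rank.

    Returns a long-format table (level, vector_id_1, vector_id_2,
    theta_deg, L1, L2, meanL) for cross-level comparison.  Levels at which
    fewer than two features survive collapse are skipped with a warning.
    """
    frames = []
    for level in levels:
        collapsed = collapse_taxonomy(table, taxonomy, level)
        if collapsed.n_features < 2:
            logger.warning("taxon_level_sweep: level %s has %d feature(s); "
                           "skipped", level, collapsed.n_features)
            continue
        result = analyze(table=collapsed, metadata=metadata, design=design,
                         n_axes=n_axes, methods=(), grouping=grouping)
        ang = result.angles.copy()
        ang.insert(0, "level", level)
        frames.append(ang)
    if not frames:
        raise ValueError("no taxonomic level produced an analyzable table")
    return pd.concat(frames, ignore_index=True)
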