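"""End-to-end comparative pipeline on synthetic multi-species data.

Orchestrates every stage: simulate the focal count matrix and comparator
tables, filter and test differential expression, cluster fold-change
profiles into the five focal temporal classes, coarse-classify both
comparators, recover the ortholog maps from the similarity tables by
reciprocal best hit, and compute every cluster-pair overlap statistic
through the ortholog bridge. The whole run is a deterministic function of
the configuration (seed included), and can be written out as per-stage TSVs
plus a JSON run summary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import synth
from .cluster import (
    ClusteringParams,
    ClusterAssignment,
    build_foldchange_matrix,
    classify_focal_clusters,
    coarse_classify_comparator,
    consolidate_clusters,
    cut_dendrogram,
    euclidean_distance,
    hierarchical_cluster,
    select_cut_height,
    zscore_transform,
)
from .expr import (
    CountMatrix,
    DEGTable,
    FilterParams,
    cpm_normalize,
    deg_filter,
    detection_filter,
    estimate_dispersions,
    summarize_deg,
    test_differential_expression,
)
from .io import write_json_summary
from .orthologs import OrthologMap, reciprocal_best_hits
from .overlap import OverlapResult, build_universe, overlap_table

log = logging.getLogger("regencomp")


@dataclass
class PipelineReport:
    config: synth.SimulationConfig
    truth: synth.SyntheticTruth
    counts: CountMatrix
    deg: DEGTable
    deg_union: pd.Index
    focal_assignment: ClusterAssignment
    comparator_assignments: dict[str, ClusterAssignment]
    ortholog_maps: dict[str, OrthologMap]
    overlaps: dict[str, pd.DataFrame]
    summary: dict = field(default_factory=dict)

    def focal_class_sets(self) -> dict[str, set]:
        return self.focal_assignment.genes_by_class()


def _overlap_frame(results: list[OverlapResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.focal_cluster, r.comparator_cluster, r.k, r.n1, r.n2, r.N, r.p, r.p_adj)
            for r in results
        ],
        columns=["focal_cluster", "comparator_cluster", "k", "n1", "n2", "N", "p", "p_adj"],
    )


def run_comparison_pipeline(
    config: synth.SimulationConfig,
    filter_params: FilterParams | None = None,
    clustering_params: ClusteringParams | None = None,
    out_dir: str | Path | None = None,
) -> PipelineReport:
    """Simulate, test, cluster, bridge, and score all cluster-pair overlaps."""
    fp = filter_params or FilterParams()
    cp = clustering_params or ClusteringParams()
    log.info("pipeline start: seed=%s n_genes=%s", config.seed, config.n_genes_per_species)
    for name, value in (
        ("min_cpm", fp.min_cpm), ("min_samples", fp.min_samples),
        ("p_threshold", fp.p_threshold), ("min_fold_change", fp.min_fold_change),
        ("linkage", cp.linkage), ("cut_height", cp.cut_height),
        ("consolidation_correlation", cp.consolidation_correlation),
        ("k_coarse", cp.k_coarse), ("delta", cp.delta),
    ):
        log.info("parameter %s = %s", name, value)

    truth = synth.generate_truth(config)
    cm = synth.simulate_focal_counts(truth, config)
    cpm = cpm_normalize(cm)
    expressed = detection_filter(cpm, fp)
    cm_f = cm.subset_genes(expressed)
    phi = estimate_dispersions(cm_f)
    deg = test_differential_expression(cm_f, phi, fp)
    deg, union = deg_filter(deg, fp)
    log.info("expressed=%d, DEG union=%d (%.2f%%)", len(expressed), len(union),
             summarize_deg(len(union), len(expressed)))

    profiles = build_foldchange_matrix(deg, union)
    Z = hierarchical_cluster(euclidean_distance(profiles), linkage=cp.linkage)
    h = cp.cut_height if isinstance(cp.cut_height, (int, float)) else \
        select_cut_height(Z, cp.plateau_window)
    focal = cut_dendrogram(Z, h, profiles)
    focal = consolidate_clusters(focal, cp.consolidation_correlation)
    classify_focal_clusters(focal, cp.delta)
    log.info("focal clusters at h=%.3g: %d after consolidation (%s)",
             h, focal.labels.nunique(), focal.classes)

    table_a, table_b = synth.simulate_comparator_tables(truth, config)
    comp_a, comp_b = config.species[1], config.species[2]
    # the normalized-count comparator mimics a dataset with its own DE call:
    # only temporally variable transcripts enter the coarse clustering
    logged_a = pd.DataFrame(
        np.log2(table_a.to_numpy(float) + 1.0), index=table_a.index, columns=table_a.columns
    )
    if cp.comparator_min_sd > 0:
        variable = table_a.index[logged_a.std(axis=1, ddof=0) > cp.comparator_min_sd]
        if len(variable) < cp.k_coarse:
            variable = table_a.index
    else:
        variable = table_a.index
    comp_assign = {
        comp_a: coarse_classify_comparator(
            zscore_transform(table_a.loc[variable]), "ward2", cp.k_coarse, cp.delta
        ),
        comp_b: coarse_classify_comparator(table_b, "average", cp.k_coarse, cp.delta),
    }

    hits = synth.simulate_similarity_tables(truth, config)
    omaps = {sp: reciprocal_best_hits(ab, ba) for sp, (ab, ba) in hits.items()}

    # focal side: the five consolidated temporal classes; comparator side:
    # the three coarse clusters themselves (their class labels ride along in
    # the cell name), matching a cluster-by-cluster overlap survey
    focal_sets = focal.genes_by_class()
    overlaps = {}
    for sp in (comp_a, comp_b):
        comp_sets = comp_assign[sp].genes_by_cluster()
        universe = build_universe(
            omaps[sp], set(union), set(comp_assign[sp].labels.index)
        )
        overlaps[sp] = _overlap_frame(
            overlap_table(focal_sets, comp_sets, omaps[sp], universe)
        )

    summary = {
        "seed": config.seed,
        "n_genes_per_species": config.n_genes_per_species,
        "n_expressed": int(len(expressed)),
        "n_deg": int(len(union)),
        "pct_deg": summarize_deg(len(union), len(expressed)),
        "cut_height": float(h),
        "n_focal_clusters": int(focal.labels.nunique()),
        "focal_classes": {str(k): v for k, v in focal.classes.items()},
        "n_ortholog_pairs": {sp: len(m) for sp, m in omaps.items()},
        "min_overlap": {
            sp: df.loc[df["p"].idxmin(),
                       ["focal_cluster", "comparator_cluster", "p"]].to_dict()
            for sp, df in overlaps.items()
        },
        "params": {
            "min_cpm": fp.min_cpm, "min_samples": fp.min_samples,
            "p_threshold": fp.p_threshold, "min_fold_change": fp.min_fold_change,
            "linkage": cp.linkage, "consolidation_correlation": cp.consolidation_correlation,
            "k_coarse": cp.k_coarse, "delta": cp.delta,
        },
    }
    report = PipelineReport(
        config=config, truth=truth, counts=cm, deg=deg, deg_union=union,
        focal_assignment=focal, comparator_assignments=comp_assign,
        ortholog_maps=omaps, overlaps=overlaps, summary=summary,
    )
    if out_dir is not None:
        write_report(report, out_dir)
    return report


def write_report(report: PipelineReport, out_dir: str | Path) -> None:
    """Per-stage TSVs plus a JSON run summary and a parameter log."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.deg.log2fc.to_csv(out / "log2fc.tsv", sep="\t")
    report.deg.p_value.to_csv(out / "p_values.tsv", sep="\t")
    if report.deg.is_de is not None:
        report.deg.is_de.to_csv(out / "is_de.tsv", sep="\t")
    focal = pd.DataFrame({
        "cluster": report.focal_assignment.labels,
        "class": report.focal_assignment.labels.map(report.focal_assignment.classes),
    })
    focal.to_csv(out / "focal_clusters.tsv", sep="\t")
    for sp, assign in report.comparator_assignments.items():
        pd.DataFrame({
            "cluster": assign.labels,
            "class": assign.labels.map(assign.classes),
        }).to_csv(out / f"{sp}_clusters.tsv", sep="\t")
    for sp, omap in report.ortholog_maps.items():
        omap.pairs.to_csv(out / f"{sp}_rbbh.tsv", sep="\t", index=False)
    for sp, df in report.overlaps.items():
        df.to_csv(out / f"{sp}_overlaps.tsv", sep="\t", index=False)
    write_json_summary(report.summary, out / "run_summary.json")
    with open(out / "run_log.txt", "w") as fh:
        for k, v in report.summary["params"].items():
            fh.write(f"{k}\t{v}\n")
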