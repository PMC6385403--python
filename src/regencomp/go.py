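"""GO-term enrichment of expression clusters against an annotated universe.

Annotations are flat gene -> term sets (typically transferred across the
rBBH map); no ontology-graph propagation is applied. Enrichment reuses the
same hypergeometric upper tail as the cross-species overlap statistics, with
Benjamini-Hochberg correction within each cluster.
"""

from __future__ import annotations

import pandas as pd

from .overlap import adjust_pvalues, hypergeometric_overlap_p


def enrich_terms(
    cluster_genes: set,
    annotations: dict[str, set],
    universe: set,
    min_term_size: int = 3,
) -> pd.DataFrame:
    """One row per term with >= ``min_term_size`` annotated universe genes.

    Counts: N = annotated universe size, n1 = cluster genes in that universe,
    n2 = term size in the universe, k = term genes in the cluster. ``fraction``
    is k / n2 (the share of the term's genes captured by the cluster).
    """
    annotated = {g for g in universe if annotations.get(g)}
    if not annotated:
        raise ValueError("annotated universe is empty")
    term_genes: dict[str, set] = {}
    for g in annotated:
        for t in annotations[g]:
            term_genes.setdefault(t, set()).add(g)
    cluster = cluster_genes & annotated
    rows = []
    for term in sorted(term_genes):
        genes = term_genes[term]
        n2 = len(genes)
        if n2 < min_term_size:
            continue
        k = len(genes & cluster)
        p = hypergeometric_overlap_p(k, len(cluster), n2, len(annotated))
        rows.append((term, k, len(cluster), n2, len(annotated), k / n2, p))
    out = pd.DataFrame(
        rows, columns=["term", "k", "n1", "n2", "N", "fraction", "p"]
    )
    out["p_corrected"] = adjust_pvalues(out["p"]) if len(out) else []
    return out.sort_values("p", kind="mergesort").reset_index(drop=True)


def compare_annotation_sources(
    results_per_source: dict[str, dict[str, pd.DataFrame]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Jaccard agreement of significant term sets between annotation sources.

    ``results_per_source`` maps source name -> {cluster -> enrichment table}.
    Returns one row per (cluster, source pair) with the Jaccard index of the
    term sets significant at ``alpha`` (corrected).
    """
    sources = sorted(results_per_source)
    if len(sources) < 2:
        raise ValueError("need at least two annotation sources to compare")
    rows = []
    clusters = sorted({c for s in sources for c in results_per_source[s]})
    for cluster in clusters:
        for i, s1 in enumerate(sources):
            for s2 in sources[i + 1:]:
                t1 = _significant_terms(results_per_source[s1].get(cluster), alpha)
                t2 = _significant_terms(results_per_source[s2].get(cluster), alpha)
                union = t1 | t2
                jac = len(t1 & t2) / len(union) if union else 1.0
                rows.append((cluster, s1, s2, jac))
    return pd.DataFrame(rows, columns=["cluster", "source_a", "source_b", "jaccard"])


def _significant_terms(table: pd.DataFrame | None, alpha: float) -> set:
    if table is None or table.empty:
        return set()
    return set(table.loc[table["p_corrected"] < alpha, "term"])
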