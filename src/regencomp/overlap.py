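"""Cross-species cluster-overlap statistics via the ortholog bridge.

The headline question: does a focal-species expression cluster share more
genes with a comparator-species cluster than chance, given the ortholog map?
The universe is restricted to focal genes that (a) were clustered, (b) have
an rBBH partner, and (c) whose partner was itself clustered in the
comparator; the overlap count is tested against the upper tail of the
hypergeometric distribution, computed in log space. Benjamini-Hochberg
adjusted p-values are always reported alongside the raw ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .orthologs import OrthologMap


@dataclass(frozen=True)
class OverlapResult:
    focal_cluster: str
    comparator_cluster: str
    k: int
    n1: int
    n2: int
    N: int
    p: float
    p_adj: float | None = None


def build_universe(
    omap: OrthologMap, focal_clustered: set, comparator_clustered: set
) -> set:
    """Focal genes that are clustered, mapped, and whose partner is clustered."""
    partner = omap.as_dict()
    universe = {
        g for g in focal_clustered
        if g in partner and partner[g] in comparator_clustered
    }
    if not universe:
        raise ValueError(
            "empty overlap universe "
            f"(|focal clustered|={len(focal_clustered)}, |pairs|={len(omap)}, "
            f"|comparator clustered|={len(comparator_clustered)})"
        )
    return universe


def bridge_contingency(
    focal_cluster_genes: set,
    comparator_cluster_genes: set,
    omap: OrthologMap,
    universe: set,
) -> tuple[int, int, int, int]:
    """(k, n1, n2, N): overlap count and marginals within the universe."""
    partner = omap.as_dict()
    in_comp = {g for g in universe if partner[g] in comparator_cluster_genes}
    n1_set = focal_cluster_genes & universe
    k = len(n1_set & in_comp)
    return k, len(n1_set), len(in_comp), len(universe)


def hypergeometric_overlap_logp(k: int, n1: int, n2: int, N: int) -> float:
    """log of the upper-tail P[X >= k] for X ~ Hypergeometric(N, n1, n2).

    Computed via the log-space survival function; the log scale is the
    stable representation for the extreme tails cluster overlaps produce.
    """
    if not (0 <= n1 <= N and 0 <= n2 <= N and 0 <= k <= min(n1, n2)):
        raise ValueError(f"invalid contingency (k={k}, n1={n1}, n2={n2}, N={N})")
    if k == 0:
        return 0.0
    return float(min(0.0, stats.hypergeom.logsf(k - 1, N, n1, n2)))


def hypergeometric_overlap_p(k: int, n1: int, n2: int, N: int) -> float:
    """Upper-tail P[X >= k] for X ~ Hypergeometric(N, n1, n2); see
    :func:`hypergeometric_overlap_logp` for the underflow-safe log form."""
    return float(np.exp(hypergeometric_overlap_logp(k, n1, n2, N)))


def adjust_pvalues(p_list, method: str = "fdr_bh") -> np.ndarray:
    """Multiple-testing adjustment (Benjamini-Hochberg by default)."""
    p = np.asarray(list(p_list), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method=method)[1]


def overlap_table(
    focal_sets: dict[str, set],
    comparator_sets: dict[str, set],
    omap: OrthologMap,
    universe: set,
) -> list[OverlapResult]:
    """All cluster-pair overlap tests, BH-adjusted across the table."""
    results = []
    for fc, fgenes in sorted(focal_sets.items()):
        for cc, cgenes in sorted(comparator_sets.items()):
            k, n1, n2, N = bridge_contingency(fgenes, cgenes, omap, universe)
            p = hypergeometric_overlap_p(k, n1, n2, N)
            results.append(OverlapResult(fc, cc, k, n1, n2, N, p))
    padj = adjust_pvalues([r.p for r in results])
    return [
        OverlapResult(r.focal_cluster, r.comparator_cluster, r.k, r.n1, r.n2,
                      r.N, r.p, float(a))
        for r, a in zip(results, padj)
    ]


def permute_partners(omap: OrthologMap, rng: np.random.Generator) -> OrthologMap:
    """Shuffle which partner each focal gene maps to (a null ortholog bridge)."""
    pairs = omap.pairs.copy()
    perm = rng.permutation(len(pairs))
    pairs["gene_b"] = pairs["gene_b"].to_numpy()[perm]
    pairs["bitscore_ba"] = pairs["bitscore_ba"].to_numpy()[perm]
    return OrthologMap(pairs=pairs)
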