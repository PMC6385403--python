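"""Reciprocal-best-hit ortholog identification and annotation transfer.

Consumes pairwise similarity tables in BLAST tabular (outfmt-6) layout; a
gene pair (a, b) is called an ortholog when b is a's best-scoring subject and
a is b's, with a deterministic tie-breaking chain (bitscore desc, then evalue
asc, then subject id asc). A toy shared-k-mer scorer is provided so synthetic
FASTA sequences can feed the same path end to end.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

OUTFMT6_COLUMNS = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)
_NUMERIC = {
    "pident": float, "length": int, "mismatch": int, "gapopen": int,
    "qstart": int, "qend": int, "sstart": int, "send": int,
    "evalue": float, "bitscore": float,
}


@dataclass
class OrthologMap:
    """One-to-one gene pairs with the supporting bidirectional bitscores."""

    pairs: pd.DataFrame  # columns gene_a, gene_b, bitscore_ab, bitscore_ba

    def __post_init__(self):
        if self.pairs.empty:
            self.pairs = pd.DataFrame(
                columns=["gene_a", "gene_b", "bitscore_ab", "bitscore_ba"]
            )
        if self.pairs["gene_a"].duplicated().any() or self.pairs["gene_b"].duplicated().any():
            raise ValueError("ortholog map is not one-to-one")

    def __len__(self) -> int:
        return len(self.pairs)

    def as_dict(self) -> dict[str, str]:
        return dict(zip(self.pairs["gene_a"], self.pairs["gene_b"]))

    def as_set(self) -> set[tuple[str, str]]:
        return set(zip(self.pairs["gene_a"], self.pairs["gene_b"]))


def read_hit_table(path: str | Path) -> pd.DataFrame:
    """Parse a 12-column tab-separated outfmt-6 file.

    Malformed rows (wrong column count or non-numeric fields) raise a
    ValueError naming the offending 1-based line numbers.
    """
    rows, bad = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                bad.append(f"line {lineno}: expected 12 columns, got {len(parts)}")
                continue
            try:
                rows.append([
                    conv(v) if (conv := _NUMERIC.get(col)) else v
                    for col, v in zip(OUTFMT6_COLUMNS, parts)
                ])
            except ValueError:
                bad.append(f"line {lineno}: non-numeric field")
    if bad:
        raise ValueError("malformed hit table: " + "; ".join(bad))
    return pd.DataFrame(rows, columns=list(OUTFMT6_COLUMNS))


def best_hit_per_query(hits: pd.DataFrame) -> pd.Series:
    """Best subject per query: max bitscore, ties by min evalue, then by
    lexicographically smallest subject id. Duplicate (query, subject) rows
    are collapsed to their max-bitscore row first."""
    if hits.empty:
        return pd.Series(dtype=object, name="sseqid")
    dedup = (
        hits.sort_values(["bitscore", "evalue"], ascending=[False, True])
        .drop_duplicates(["qseqid", "sseqid"], keep="first")
    )
    ranked = dedup.sort_values(
        ["qseqid", "bitscore", "evalue", "sseqid"],
        ascending=[True, False, True, True],
        kind="mergesort",
    )
    best = ranked.drop_duplicates("qseqid", keep="first")
    return pd.Series(best["sseqid"].to_numpy(), index=best["qseqid"].to_numpy(),
                     name="sseqid")


def reciprocal_best_hits(hits_ab: pd.DataFrame, hits_ba: pd.DataFrame) -> OrthologMap:
    """Pairs (a, b) with best(a->) == b and best(b->) == a."""
    best_ab = best_hit_per_query(hits_ab)
    best_ba = best_hit_per_query(hits_ba)
    rows = []
    score_ab = hits_ab.groupby(["qseqid", "sseqid"])["bitscore"].max() if not hits_ab.empty else {}
    score_ba = hits_ba.groupby(["qseqid", "sseqid"])["bitscore"].max() if not hits_ba.empty else {}
    for a, b in best_ab.items():
        if best_ba.get(b) == a:
            rows.append((a, b, score_ab.get((a, b)), score_ba.get((b, a))))
    pairs = pd.DataFrame(rows, columns=["gene_a", "gene_b", "bitscore_ab", "bitscore_ba"])
    return OrthologMap(pairs=pairs)


def kmer_similarity(seq_a: str, seq_b: str, k: int = 8) -> int:
    """Count of distinct k-mers shared by two sequences (symmetric)."""
    if k < 1:
        raise ValueError("k must be positive")
    if len(seq_a) < k or len(seq_b) < k:
        raise ValueError(f"sequences must be at least {k} long")
    kmers = lambda s: {s[i:i + k] for i in range(len(s) - k + 1)}
    return len(kmers(seq_a) & kmers(seq_b))


def score_fasta_pairwise(fasta_a: str | Path, fasta_b: str | Path,
                         k: int = 8) -> pd.DataFrame:
    """All-vs-all shared-k-mer scores between two FASTA files, as a hit table.

    A stand-in for a real aligner on synthetic sequences: each (a, b) pair
    with at least one shared k-mer becomes an outfmt-6-shaped row whose
    bitscore is the shared-k-mer count, so the result can feed
    :func:`reciprocal_best_hits` directly.
    """
    from Bio import SeqIO

    seqs_a = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(fasta_a), "fasta")]
    seqs_b = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(fasta_b), "fasta")]
    rows = []
    for qid, qseq in seqs_a:
        for sid, sseq in seqs_b:
            score = kmer_similarity(qseq, sseq, k)
            if score > 0:
                rows.append((qid, sid, 100.0, min(len(qseq), len(sseq)), 0, 0,
                             1, len(qseq), 1, len(sseq), 0.0, float(score)))
    return pd.DataFrame(rows, columns=list(OUTFMT6_COLUMNS))


def transfer_annotations(
    omap: OrthologMap, reference_annotations: dict[str, set]
) -> dict[str, set]:
    """Assign each mapped focal gene the union of its single rBBH partner's
    terms; unmapped genes receive the empty set (i.e. are absent)."""
    out: dict[str, set] = {}
    for a, b in zip(omap.pairs["gene_a"], omap.pairs["gene_b"]):
        terms = reference_annotations.get(b)
        if terms:
            out[a] = set(terms)
    return out


def summarize_mapping(n_mapped: int, n_total: int) -> float:
    """Percentage of loci with an rBBH match, to one decimal."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_mapped <= n_total:
        raise ValueError("need 0 <= n_mapped <= n_total")
    return round(100.0 * n_mapped / n_total, 1)
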