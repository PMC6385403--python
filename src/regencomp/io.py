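"""Readers and writers for the pipeline's plain-text interchange formats.

Counts travel as TSV (genes as rows, sample ids as header) with a CSV sample
sheet (sample, fragment, timepoint, replicate, batch); annotations as
two-column TSV (gene, term) with repeated rows per term; Nanostring panels as
CSV (probe, class, then one column per sample); similarity tables in BLAST
outfmt-6 layout (see orthologs.read_hit_table).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .expr import CountMatrix
from .nanostring import NanostringRun

SAMPLE_SHEET_COLUMNS = ("sample", "fragment", "timepoint", "replicate", "batch")


def read_count_matrix(counts_path: str | Path, samples_path: str | Path) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    sheet = pd.read_csv(samples_path)
    missing = set(SAMPLE_SHEET_COLUMNS) - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    meta = sheet.set_index("sample")[list(SAMPLE_SHEET_COLUMNS[1:])]
    return CountMatrix(counts=counts, sample_meta=meta)


def write_count_matrix(cm: CountMatrix, counts_path: str | Path, samples_path: str | Path) -> None:
    cm.counts.to_csv(counts_path, sep="\t")
    sheet = cm.sample_meta.reset_index()
    sheet.columns = list(SAMPLE_SHEET_COLUMNS)
    sheet.to_csv(samples_path, index=False)


def read_annotations(path: str | Path) -> dict[str, set]:
    """Two-column (gene, term) TSV -> gene -> set of terms."""
    table = pd.read_csv(path, sep="\t", header=None, names=["gene", "term"],
                        dtype=str, comment="#")
    out: dict[str, set] = {}
    for gene, term in zip(table["gene"], table["term"]):
        out.setdefault(gene, set()).add(term)
    return out


def write_annotations(annotations: dict[str, set], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(annotations):
            for term in sorted(annotations[gene]):
                fh.write(f"{gene}\t{term}\n")


def read_nanostring_csv(path: str | Path) -> NanostringRun:
    """CSV with columns probe, class, then one column per sample. Sample ids
    of the form FRAG_TP_rN are parsed back into metadata."""
    table = pd.read_csv(path)
    probe_class = pd.Series(table["class"].to_numpy(), index=table["probe"], name="class")
    counts = table.drop(columns=["class"]).set_index("probe")
    rows = []
    for s in counts.columns:
        frag, tp, rep = s.split("_")
        rows.append((frag, tp, int(rep.lstrip("r")), f"b{rep.lstrip('r')}"))
    meta = pd.DataFrame(rows, index=pd.Index(counts.columns, name="sample"),
                        columns=["fragment", "timepoint", "replicate", "batch"])
    return NanostringRun(counts=counts, probe_class=probe_class, sample_meta=meta)


def write_nanostring_csv(run: NanostringRun, path: str | Path) -> None:
    out = run.counts.copy()
    out.insert(0, "class", run.probe_class)
    out.to_csv(path, index_label="probe")


def write_json_summary(summary: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(summary, indent=2, sort_keys=True, default=str) + "\n")
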