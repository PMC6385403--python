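"""Synthetic multi-species regeneration data with known ground truth.

Emulates the study design the pipeline targets: a focal species sampled as an
18-sample bulk RNA-seq experiment (2 replicates x {anterior, posterior,
control} x {3 h, 3 d, 6 d post-bisection}) with negative-binomial counts, plus
two comparator species whose expression is reported the way published
regeneration time courses are — one as normalized counts over pseudo-time, one
as range-binned z-scores in {0, 1, 2}. Temporal expression "programs" are
planted per gene; programs marked shared are carried by ortholog pairs across
species, and pairwise similarity tables (BLAST outfmt-6 layout) encode those
pairs as mutual top hits amid lower-scoring decoys. Everything is a
deterministic function of the configuration seed.

Planted log2 fold-change shapes over (T0, T1, T2) for an effect size ``e``:

========== ================= =================
program     ANT               POST
========== ================= =================
up_early    (e, e/2, 0)       (e, e/2, 0)
down_early  (-e, -e/2, 0)     (-e, -e/2, 0)
anterior    (e, e, e)         (-e, -e, -e)
posterior   (-e, -e, -e)      (e, e, e)
up_late     (0, 0, e)         (0, 0, e)
neutral     (0, 0, 0)         (0, 0, 0)
========== ================= =================
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .expr import CountMatrix, FRAGMENTS, TIMEPOINTS
from .nanostring import NanostringRun

PROGRAM_NAMES = (
    "up_early",
    "down_early",
    "anterior_specific",
    "posterior_specific",
    "up_late",
    "neutral",
)

OUTFMT6_COLUMNS = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)


@dataclass(frozen=True)
class ProgramSpec:
    name: str
    n_genes: int
    effect_log2fc: float
    shared_across_species: bool = False

    def __post_init__(self):
        if self.name not in PROGRAM_NAMES:
            raise ValueError(f"unknown program {self.name!r}")
        if self.n_genes < 0 or self.effect_log2fc < 0:
            raise ValueError("n_genes and effect_log2fc must be non-negative")


def default_programs() -> tuple[ProgramSpec, ...]:
    """The default planted structure: five temporal classes, with the
    early-upregulated program shared across all three species."""
    return (
        ProgramSpec("up_early", 150, 2.0, shared_across_species=True),
        ProgramSpec("down_early", 150, 2.0),
        ProgramSpec("anterior_specific", 100, 1.5),
        ProgramSpec("posterior_specific", 100, 1.5),
        ProgramSpec("up_late", 100, 2.0),
    )


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_genes_per_species: int = 2000
    species: tuple[str, str, str] = ("focal", "comparator_a", "comparator_b")
    ortholog_fraction: float = 0.6
    programs: tuple[ProgramSpec, ...] = field(default_factory=default_programs)
    nb_dispersion: float = 0.2
    #: fraction of ortholog pairs whose comparator member carries a
    #: species-specific temporal program while the focal member stays
    #: neutral — orthologs with divergent expression, which real comparator
    #: datasets are full of
    divergent_fraction: float = 0.4
    base_mean_log_range: tuple[float, float] = (0.5, 3.0)  # log10 abundance span
    library_size_range: tuple[int, int] = (800_000, 1_200_000)
    decoy_hit_rate: float = 0.2
    batch_log2_sd: float = 0.2  # per-gene batch effect (log2 SD) on batch b2
    comparator_noise_sd: float = 0.35  # log2 noise in comparator tables
    n_comparator_timepoints: int = 4

    def validate(self) -> None:
        if self.n_genes_per_species < 50:
            raise ValueError("n_genes_per_species must be >= 50")
        if not 0.0 <= self.ortholog_fraction <= 1.0:
            raise ValueError("ortholog_fraction must lie in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if len(self.species) != 3:
            raise ValueError("exactly three species identifiers are required")
        if self.n_comparator_timepoints < 4:
            raise ValueError("comparator tables need >= 4 timepoints")
        n = self.n_genes_per_species
        n_prog = sum(p.n_genes for p in self.programs)
        if n_prog > n:
            raise ValueError("program sizes exceed n_genes_per_species")
        if not 0.0 <= self.divergent_fraction <= 1.0:
            raise ValueError("divergent_fraction must lie in [0, 1]")
        n_pairs = round(self.ortholog_fraction * n)
        n_shared = sum(p.n_genes for p in self.programs if p.shared_across_species)
        if n_shared > n_pairs:
            raise ValueError(
                "shared programs need ortholog pairs: "
                f"{n_shared} shared genes > {n_pairs} pairs"
            )

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


@dataclass
class SyntheticTruth:
    """Ground truth: gene ids, program labels, ortholog pairs, baselines."""

    gene_ids: dict[str, list[str]]
    programs: dict[str, pd.Series]  # species -> gene -> program name
    ortholog_pairs: dict[str, list[tuple[str, str]]]  # comparator -> (focal, comp)
    baseline: dict[str, pd.Series]  # species -> relative abundance (sums to 1)


def _rng_for(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


def generate_truth(config: SimulationConfig) -> SyntheticTruth:
    """Draw gene identities, program assignments, ortholog pairs, baselines."""
    config.validate()
    rng = _rng_for(config, 0)
    n = config.n_genes_per_species
    focal, comp_a, comp_b = config.species
    gene_ids = {sp: [f"{sp}_g{i:05d}" for i in range(n)] for sp in config.species}

    n_pairs = round(config.ortholog_fraction * n)
    paired_focal = list(rng.choice(n, size=n_pairs, replace=False))
    unpaired_focal = [i for i in range(n) if i not in set(paired_focal)]
    ortholog_pairs: dict[str, list[tuple[str, str]]] = {}
    partner_idx: dict[str, np.ndarray] = {}
    for comp in (comp_a, comp_b):
        partners = rng.choice(n, size=n_pairs, replace=False)
        partner_idx[comp] = partners
        ortholog_pairs[comp] = [
            (gene_ids[focal][i], gene_ids[comp][j])
            for i, j in zip(paired_focal, partners)
        ]

    programs = {
        sp: pd.Series("neutral", index=gene_ids[sp], dtype=object)
        for sp in config.species
    }
    # a gene may be an ortholog regardless of its program; only SHARED
    # programs constrain the pairing (their genes must be paired, and the
    # partner carries the same program). Non-shared program genes keep
    # whatever partner they drew; the partner stays neutral unless it picks
    # up a divergent program of its own below.
    lookup = {fi: k for k, fi in enumerate(paired_focal)}
    pool_paired = list(paired_focal)
    pool_any = list(range(n))
    for spec in config.programs:
        if spec.shared_across_species:
            pool = [i for i in pool_paired if programs[focal].iloc[i] == "neutral"]
        else:
            pool = [i for i in pool_any if programs[focal].iloc[i] == "neutral"]
        take_pos = rng.choice(len(pool), size=spec.n_genes, replace=False)
        take = {pool[i] for i in take_pos}
        for i in sorted(take):
            programs[focal].iloc[i] = spec.name
        if spec.shared_across_species:
            for comp in (comp_a, comp_b):
                for i in sorted(take):
                    programs[comp].iloc[partner_idx[comp][lookup[i]]] = spec.name

    # orthologs with divergent expression: the comparator member runs its own
    # temporal program while the focal member's program (often neutral) is
    # not mirrored
    prog_names = [p.name for p in config.programs]
    n_divergent = round(config.divergent_fraction * n_pairs)
    if prog_names and n_divergent:
        for comp in (comp_a, comp_b):
            free = [
                k for k, fi in enumerate(paired_focal)
                if programs[comp].iloc[partner_idx[comp][k]] == "neutral"
            ]
            if not free:
                continue
            pick = rng.choice(len(free), size=min(n_divergent, len(free)), replace=False)
            chosen = rng.integers(0, len(prog_names), size=len(pick))
            for pos, which in zip(pick, chosen):
                ci = partner_idx[comp][free[pos]]
                programs[comp].iloc[ci] = prog_names[which]

    lo, hi = config.base_mean_log_range
    baseline = {}
    for sp in config.species:
        ab = 10.0 ** rng.uniform(lo, hi, size=n)
        baseline[sp] = pd.Series(ab / ab.sum(), index=gene_ids[sp])
    return SyntheticTruth(gene_ids, programs, ortholog_pairs, baseline)


#: planted log2FC at (T0, T1, T2) per fragment, scaled by effect size
_FOCAL_SHAPES = {
    "up_early": {"ANT": (1.0, 0.5, 0.0), "POST": (1.0, 0.5, 0.0)},
    "down_early": {"ANT": (-1.0, -0.5, 0.0), "POST": (-1.0, -0.5, 0.0)},
    "anterior_specific": {"ANT": (1, 1, 1), "POST": (-1, -1, -1)},
    "posterior_specific": {"ANT": (-1, -1, -1), "POST": (1, 1, 1)},
    "up_late": {"ANT": (0.0, 0.0, 1.0), "POST": (0.0, 0.0, 1.0)},
    "neutral": {"ANT": (0.0, 0.0, 0.0), "POST": (0.0, 0.0, 0.0)},
}


def planted_log2fc(config: SimulationConfig, truth: SyntheticTruth) -> pd.DataFrame:
    """True focal log2FC per gene for the six fragment/timepoint contrasts."""
    focal = config.species[0]
    effects = {p.name: p.effect_log2fc for p in config.programs}
    effects["neutral"] = 0.0
    rows = {}
    for frag in ("ANT", "POST"):
        for k, tp in enumerate(TIMEPOINTS):
            col = f"{frag}-{tp}"
            rows[col] = [
                _FOCAL_SHAPES[prog][frag][k] * effects.get(prog, 0.0)
                for prog in truth.programs[focal]
            ]
    return pd.DataFrame(rows, index=truth.gene_ids[focal])


def simulate_focal_counts(truth: SyntheticTruth, config: SimulationConfig) -> CountMatrix:
    """18-sample NB count matrix with the planted fold changes.

    Per-sample expected counts are renormalized to the drawn library size, so
    column totals land in ``library_size_range`` by construction (up to NB
    noise); this reproduces the mild compositional shift real library-size
    normalization sees when strong programs are planted.
    """
    rng = _rng_for(config, 1)
    focal = config.species[0]
    genes = truth.gene_ids[focal]
    lfc_true = planted_log2fc(config, truth)
    batch_eff = rng.normal(0.0, config.batch_log2_sd, size=len(genes))

    samples, meta_rows, cols = [], [], []
    for frag in FRAGMENTS:
        for tp in TIMEPOINTS:
            for rep in (1, 2):
                sid = f"{frag}_{tp}_r{rep}"
                samples.append(sid)
                meta_rows.append((frag, tp, rep, f"b{rep}"))
                lib = rng.uniform(*config.library_size_range)
                lfc = (
                    lfc_true[f"{frag}-{tp}"].to_numpy()
                    if frag != "CONT"
                    else np.zeros(len(genes))
                )
                log2_mu = np.log2(truth.baseline[focal].to_numpy()) + lfc
                if rep == 2:
                    log2_mu = log2_mu + batch_eff
                mu = 2.0 ** log2_mu
                mu = mu / mu.sum() * lib
                r = 1.0 / config.nb_dispersion
                counts = rng.negative_binomial(r, r / (r + mu))
                cols.append(counts)
    counts = pd.DataFrame(np.column_stack(cols), index=genes, columns=samples)
    meta = pd.DataFrame(
        meta_rows, index=pd.Index(samples, name="sample"),
        columns=["fragment", "timepoint", "replicate", "batch"],
    )
    return CountMatrix(counts=counts, sample_meta=meta)


#: comparator log2 shapes over 4 pseudo-timepoints, scaled by effect size
_COMPARATOR_SHAPES = {
    "up_early": (1.0, 2.0 / 3.0, 1.0 / 3.0, 0.0),
    "down_early": (-1.0, -2.0 / 3.0, -1.0 / 3.0, 0.0),
    "anterior_specific": (0.0, 1.0, 1.0, 0.0),
    "posterior_specific": (0.5, -0.5, -0.5, 0.5),
    "up_late": (0.0, 0.0, 0.0, 1.0),
    "neutral": (0.0, 0.0, 0.0, 0.0),
}


def _comparator_latent(truth, config, species, rng) -> pd.DataFrame:
    tps = config.n_comparator_timepoints
    effects = {p.name: p.effect_log2fc for p in config.programs}
    base4 = np.array([_COMPARATOR_SHAPES[p][:4] for p in truth.programs[species]])
    shapes = np.zeros((len(base4), tps))
    # interpolate the canonical 4-point shape onto the requested pseudo-times
    xs = np.linspace(0, 3, tps)
    for j, x in enumerate(xs):
        k = int(np.floor(x))
        frac = x - k
        hi = min(k + 1, 3)
        shapes[:, j] = base4[:, k] * (1 - frac) + base4[:, hi] * frac
    eff = np.array([effects.get(p, 0.0) for p in truth.programs[species]])
    latent = shapes * eff[:, None]
    latent = latent + rng.normal(0.0, config.comparator_noise_sd, size=latent.shape)
    cols = [f"t{j}" for j in range(tps)]
    return pd.DataFrame(latent, index=truth.gene_ids[species], columns=cols)


def simulate_comparator_tables(
    truth: SyntheticTruth, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(normalized-count table for comparator A, binned z table for comparator B).

    Comparator A mimics a dataset distributed as normalized read counts:
    counts = scale * 2**(planted shape + noise). Comparator B mimics one
    distributed as per-transcript range bins in {0, 1, 2} (lower/mid/upper
    third of each transcript's expression range).
    """
    rng = _rng_for(config, 2)
    _, comp_a, comp_b = config.species
    latent_a = _comparator_latent(truth, config, comp_a, rng)
    scale = truth.baseline[comp_a].to_numpy() * 5e5
    table_a = pd.DataFrame(
        scale[:, None] * (2.0 ** latent_a.to_numpy()),
        index=latent_a.index, columns=latent_a.columns,
    )
    latent_b = _comparator_latent(truth, config, comp_b, rng)
    from .cluster import bin_zscores  # local import to avoid a cycle

    table_b = bin_zscores(latent_b)
    return table_a, table_b


def simulate_similarity_tables(
    truth: SyntheticTruth, config: SimulationConfig
) -> dict[str, tuple[pd.DataFrame, pd.DataFrame]]:
    """Per comparator species, (focal->comp, comp->focal) outfmt-6 hit tables.

    Every truth ortholog pair appears as the mutual top-scoring hit in both
    directions. Decoy hits (per-query probability ``decoy_hit_rate``) score at
    most 0.8x the query's true-pair bitscore and always point at a subject
    whose own best hit is its true partner, so decoys can never form a
    reciprocal pair.
    """
    rng = _rng_for(config, 3)
    focal = config.species[0]
    out = {}
    for comp in config.species[1:]:
        pairs = truth.ortholog_pairs[comp]
        partner_of = dict(pairs)
        partner_rev = {b: a for a, b in pairs}
        rows_ab, rows_ba = [], []

        def hit_row(q, s, bitscore, rng=rng):
            length = int(rng.integers(150, 500))
            pident = float(np.round(rng.uniform(80, 100), 1))
            mismatch = int(round(length * (100 - pident) / 100))
            evalue = float(10.0 ** (-bitscore / 10.0))
            return (q, s, pident, length, mismatch, 0, 1, length, 1, length,
                    evalue, round(float(bitscore), 1))

        true_score: dict[str, float] = {}
        for a, b in pairs:
            s_ab = rng.uniform(150, 400)
            s_ba = rng.uniform(150, 400)
            true_score[a] = s_ab
            true_score[b] = s_ba
            rows_ab.append(hit_row(a, b, s_ab))
            rows_ba.append(hit_row(b, a, s_ba))
            if rng.random() < 0.1:  # occasional duplicate lower-score HSP row
                rows_ab.append(hit_row(a, b, s_ab * rng.uniform(0.3, 0.7)))

        paired_b = [b for _, b in pairs]
        paired_a = [a for a, _ in pairs]
        if paired_b:
            for q in truth.gene_ids[focal]:
                if rng.random() < config.decoy_hit_rate:
                    s = paired_b[int(rng.integers(len(paired_b)))]
                    if partner_of.get(q) == s:
                        continue
                    cap = 0.8 * true_score.get(q, 150.0)
                    rows_ab.append(hit_row(q, s, cap * rng.uniform(0.5, 1.0)))
            for q in truth.gene_ids[comp]:
                if rng.random() < config.decoy_hit_rate:
                    s = paired_a[int(rng.integers(len(paired_a)))]
                    if partner_rev.get(q) == s:
                        continue
                    cap = 0.8 * true_score.get(q, 150.0)
                    rows_ba.append(hit_row(q, s, cap * rng.uniform(0.5, 1.0)))
        cols = list(OUTFMT6_COLUMNS)
        out[comp] = (
            pd.DataFrame(rows_ab, columns=cols),
            pd.DataFrame(rows_ba, columns=cols),
        )
    return out


def simulate_nanostring(
    truth: SyntheticTruth,
    config: SimulationConfig,
    n_targets: int = 30,
    background_mean: float = 10.0,
    background_sd: float = 3.0,
) -> NanostringRun:
    """Probe-count panel over the same 18-sample design.

    8 negative probes draw from a low-mean background distribution (no sample
    scaling — background is additive machine noise); 6 positive and 11
    housekeeping probes scale with a per-sample lognormal factor; target
    probes sample focal genes across programs and carry the planted fold
    changes. Two deliberately dim target probes sit below background.
    """
    rng = _rng_for(config, 4)
    focal = config.species[0]
    lfc_true = planted_log2fc(config, truth)

    # choose target genes cycling through programs so all classes are covered
    by_prog: dict[str, list[str]] = {}
    for g, p in truth.programs[focal].items():
        by_prog.setdefault(p, []).append(g)
    ordered = []
    progs = [p for p in PROGRAM_NAMES if p in by_prog]
    k = 0
    while len(ordered) < n_targets:
        p = progs[k % len(progs)]
        if by_prog[p]:
            ordered.append(by_prog[p].pop(0))
        k += 1

    samples, meta_rows = [], []
    for frag in FRAGMENTS:
        for tp in TIMEPOINTS:
            for rep in (1, 2):
                samples.append(f"{frag}_{tp}_r{rep}")
                meta_rows.append((frag, tp, rep, f"b{rep}"))
    factors = rng.lognormal(0.0, 0.25, size=len(samples))

    probe_rows, classes, data = [], [], []
    for i in range(8):
        probe_rows.append(f"NEG_{i+1}")
        classes.append("negative")
        data.append(np.maximum(0, rng.normal(background_mean, background_sd,
                                             len(samples))).round())
    pos_means = np.array([8000.0, 2000.0, 500.0, 125.0, 32.0, 8.0])
    for i, m in enumerate(pos_means):
        probe_rows.append(f"POS_{i+1}")
        classes.append("positive")
        data.append(rng.poisson(m * factors))
    hk_means = 10.0 ** rng.uniform(2.3, 3.3, size=11)
    for i, m in enumerate(hk_means):
        probe_rows.append(f"HK_{i+1}")
        classes.append("housekeeping")
        data.append(rng.poisson(m * factors))
    target_means = 10.0 ** rng.uniform(2.0, 3.0, size=len(ordered))
    target_means[:2] = background_mean * 0.3  # planted below-background probes
    phi = 0.05
    r = 1.0 / phi
    for g, base in zip(ordered, target_means):
        probe_rows.append(f"T_{g}")
        classes.append("target")
        mus = []
        for (frag, tp, rep, _), f in zip(meta_rows, factors):
            lfc = lfc_true.loc[g, f"{frag}-{tp}"] if frag != "CONT" else 0.0
            mus.append(base * f * 2.0 ** lfc)
        mus = np.array(mus)
        data.append(rng.negative_binomial(r, r / (r + mus)))
    counts = pd.DataFrame(
        np.vstack(data), index=pd.Index(probe_rows, name="probe"), columns=samples
    ).astype(int)
    meta = pd.DataFrame(
        meta_rows, index=pd.Index(samples, name="sample"),
        columns=["fragment", "timepoint", "replicate", "batch"],
    )
    probe_class = pd.Series(classes, index=counts.index, name="class")
    return NanostringRun(counts=counts, probe_class=probe_class, sample_meta=meta,
                         target_gene={f"T_{g}": g for g in ordered})
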