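"""Expression filtering and differential expression testing.

Implements the bulk RNA-seq portion of the comparative regeneration pipeline:
library-size (CPM) normalization, the detection filter (more than ``min_cpm``
reads per million in at least ``min_samples`` samples), negative-binomial
dispersion estimation with shrinkage toward a mean-dispersion trend, per-
contrast GLM testing of regenerating fragments against age-matched uncut
controls (with batch as an additive covariate), and the DEG thresholds
(p < 0.05 and more than twofold change in either direction).

The experimental design is fixed by the study it models: fragments
{ANT, POST, CONT} x timepoints {T0, T1, T2} (3 hours, 3 days, 6 days
post-bisection) with replicate samples per cell, 18 samples in total. The six
contrasts compare each regenerating fragment to the control at the same
timepoint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .glm import fit_nb_glm, nb_deviance

FRAGMENTS = ("ANT", "POST", "CONT")
TIMEPOINTS = ("T0", "T1", "T2")
#: fragment/timepoint contrasts vs the age-matched control, fixed column order
CONTRASTS = tuple(
    f"{frag}-{tp}" for frag in ("ANT", "POST") for tp in TIMEPOINTS
)


@dataclass
class CountMatrix:
    """Gene x sample integer counts with sample metadata.

    ``counts`` is a genes-by-samples DataFrame; ``sample_meta`` is indexed by
    sample id with columns ``fragment``, ``timepoint``, ``replicate`` and
    ``batch``.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self):
        if not self.counts.columns.equals(self.sample_meta.index):
            self.sample_meta = self.sample_meta.loc[self.counts.columns]
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.index.has_duplicates:
            raise ValueError("gene identifiers must be unique")
        bad = set(self.sample_meta["fragment"]) - set(FRAGMENTS)
        if bad:
            raise ValueError(f"unknown fragment labels: {sorted(bad)}")
        cells = self.sample_meta.groupby(["fragment", "timepoint"], observed=True).size()
        expect = {(f, t) for f in FRAGMENTS for t in TIMEPOINTS}
        have = set(cells.index)
        missing = expect - have
        if missing:
            raise ValueError(f"design cells without samples: {sorted(missing)}")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def subset_genes(self, genes) -> "CountMatrix":
        return CountMatrix(self.counts.loc[genes], self.sample_meta)


@dataclass(frozen=True)
class FilterParams:
    """Detection and DEG thresholds, plus the library normalization flavour.

    ``normalization`` selects how effective library sizes are computed for
    testing and fold-change reporting: ``"tmm"`` (default) rescales totals by
    trimmed-mean-of-M-values factors, which keeps unregulated genes at zero
    log fold change even when strongly regulated programs skew the library
    composition; ``"cpm"`` uses plain totals.
    """

    min_cpm: float = 3.0
    min_samples: int = 2
    p_threshold: float = 0.05
    min_fold_change: float = 2.0
    normalization: str = "tmm"

    def __post_init__(self):
        if self.min_cpm <= 0 or self.min_samples <= 0 or self.p_threshold <= 0:
            raise ValueError("filter parameters must be strictly positive")
        if self.min_fold_change < 1:
            raise ValueError("min_fold_change must be >= 1")
        if self.normalization not in ("cpm", "tmm"):
            raise ValueError("normalization must be 'cpm' or 'tmm'")


@dataclass
class DEGTable:
    """Per-gene, per-contrast log2 fold changes and p-values."""

    log2fc: pd.DataFrame  # genes x CONTRASTS
    p_value: pd.DataFrame  # genes x CONTRASTS
    is_de: pd.DataFrame | None = None
    params: FilterParams = field(default_factory=FilterParams)


def cpm_normalize(cm: CountMatrix) -> pd.DataFrame:
    """Counts-per-million: each sample column rescaled to sum to 1e6."""
    totals = cm.counts.sum(axis=0)
    zero = totals.index[totals == 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero total counts: {list(zero)}")
    return cm.counts / totals * 1e6


def tmm_effective_library_sizes(cm: CountMatrix, trim_m: float = 0.3,
                                trim_a: float = 0.05) -> pd.Series:
    """Per-sample effective library sizes via trimmed mean of M-values.

    The reference sample is the one whose upper-quartile CPM is closest to
    the across-sample average. Per sample, gene-wise log ratios M against
    the reference are double-trimmed (by M and by average abundance A) and
    averaged with inverse-variance weights; totals are rescaled by the
    resulting factors, normalized to geometric mean 1.
    """
    lib = cm.counts.sum(axis=0).astype(float)
    if (lib == 0).any():
        raise ValueError("sample(s) with zero total counts")
    p = cm.counts.to_numpy(float) / lib.to_numpy()
    uq = np.quantile(np.where(p > 0, p, np.nan), 0.75, axis=0)
    uq = np.nan_to_num(uq)
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    factors = np.ones(p.shape[1])
    for s in range(p.shape[1]):
        if s == ref:
            continue
        ok = (p[:, s] > 0) & (p[:, ref] > 0)
        ps, pr = p[ok, s], p[ok, ref]
        M = np.log2(ps / pr)
        A = 0.5 * np.log2(ps * pr)
        lo_m, hi_m = np.quantile(M, [trim_m, 1 - trim_m])
        lo_a, hi_a = np.quantile(A, [trim_a, 1 - trim_a])
        keep = (M >= lo_m) & (M <= hi_m) & (A >= lo_a) & (A <= hi_a)
        if not keep.any():
            continue
        ys = ps[keep] * lib.iloc[s]
        yr = pr[keep] * lib.iloc[ref]
        w = 1.0 / ((1.0 / ys - 1.0 / lib.iloc[s]) + (1.0 / yr - 1.0 / lib.iloc[ref]))
        factors[s] = 2.0 ** (np.sum(w * M[keep]) / np.sum(w))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(lib.to_numpy() * factors, index=cm.samples)


def effective_library_sizes(cm: CountMatrix, params: FilterParams) -> pd.Series:
    if params.normalization == "tmm":
        return tmm_effective_library_sizes(cm)
    return cm.counts.sum(axis=0).astype(float)


def detection_filter(cpm: pd.DataFrame, params: FilterParams) -> pd.Index:
    """Genes with CPM strictly above ``min_cpm`` in >= ``min_samples`` samples."""
    n_above = (cpm > params.min_cpm).sum(axis=1)
    return cpm.index[n_above >= params.min_samples]


def _group_key(meta: pd.DataFrame) -> pd.Series:
    return meta["fragment"].astype(str) + "_" + meta["timepoint"].astype(str)


def estimate_dispersions(cm: CountMatrix, trend_weight: float = 0.7) -> pd.Series:
    """Per-gene NB dispersion phi (var = mu + phi mu^2), trend-shrunk.

    Raw per-gene values come from a method-of-moments estimator pooled over
    the replicated (fragment, timepoint) groups on library-size-equalized
    counts. Raw values are then shrunk toward a lowess trend of dispersion on
    log mean abundance (weight ``trend_weight`` to the trend), mirroring the
    moderation used by mainstream count-model packages. Genes with no
    within-group variability anywhere are floored at exactly 0.
    """
    meta = cm.sample_meta
    groups = _group_key(meta)
    sizes = groups.value_counts()
    if (sizes < 2).all():
        raise ValueError(
            "dispersion unidentifiable: no (fragment, timepoint) group has >= 2 replicates"
        )
    totals = cm.counts.sum(axis=0)
    norm = cm.counts * (totals.mean() / totals)
    num = pd.Series(0.0, index=cm.genes)
    den = pd.Series(0.0, index=cm.genes)
    var_total = pd.Series(0.0, index=cm.genes)
    for g in sizes.index[sizes >= 2]:
        sub = norm.loc[:, groups[groups == g].index]
        n_i = sub.shape[1]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        num += (n_i - 1) * (v - m)
        den += (n_i - 1) * m**2
        var_total += v
    raw = (num / den.replace(0.0, np.nan)).clip(lower=0.0).fillna(0.0)

    log_mean = np.log10(norm.mean(axis=1) + 1.0)
    if log_mean.nunique() < 5:  # no abundance spread to fit a trend on
        smoothed = np.full(len(raw), float(raw.median()))
    else:
        smoothed = lowess(raw.to_numpy(), log_mean.to_numpy(), frac=0.4,
                          return_sorted=False)
    trend = pd.Series(np.clip(smoothed, 0.0, None), index=cm.genes)
    phi = trend_weight * trend + (1.0 - trend_weight) * raw
    phi[var_total == 0.0] = 0.0  # identical counts everywhere -> Poisson-or-less
    return phi.clip(lower=0.0)


def _design_matrices(meta: pd.DataFrame):
    """Cell-means design (9 group indicators) plus batch dummies.

    Returns the full design, the group column order, and batch dummy columns.
    Raises on a singular design, naming the confounded factors.
    """
    groups = _group_key(meta)
    group_levels = [f"{f}_{t}" for f in FRAGMENTS for t in TIMEPOINTS]
    G = np.stack([(groups == g).to_numpy(float) for g in group_levels], axis=1)
    batches = sorted(meta["batch"].astype(str).unique())
    B = np.stack(
        [(meta["batch"].astype(str) == b).to_numpy(float) for b in batches[1:]], axis=1
    ) if len(batches) > 1 else np.zeros((len(meta), 0))
    X = np.hstack([G, B])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            "singular design: batch is confounded with the fragment/timepoint groups"
        )
    return X, group_levels, batches


def test_differential_expression(
    cm: CountMatrix,
    dispersions: pd.Series,
    params: FilterParams | None = None,
    test: str = "qlf",
) -> DEGTable:
    """Per-contrast DE test of each regenerating fragment vs matched control.

    A single NB GLM per gene is fit over all samples with a cell-means group
    term (one level per fragment x timepoint) and additive batch covariate.
    Each contrast is tested by refitting with the fragment group merged into
    its age-matched control group and comparing fits, either as a chi-square
    likelihood-ratio test (``test="lrt"``) or as a quasi-likelihood F test
    (``test="qlf"``, default) in which the LR statistic is scaled by the
    per-gene residual deviance over its degrees of freedom — the same flavour
    of test used by edgeR's glmQLFTest and better calibrated at small
    replicate numbers.

    Reported log2 fold changes are computed from group-mean CPM with a 0.5
    pseudo-count (reporting only; the test uses raw counts), so the sign is
    exactly antisymmetric under swapping fragment and control labels.
    """
    if params is None:
        params = FilterParams()
    phi = dispersions.loc[cm.genes].to_numpy()
    y = cm.counts.to_numpy(float)
    lib_eff = effective_library_sizes(cm, params)
    offset = np.log(lib_eff.to_numpy(float))
    X_full, group_levels, _ = _design_matrices(cm.sample_meta)
    beta_full, ll_full = fit_nb_glm(y, X_full, phi, offset=offset)

    df_resid = y.shape[1] - X_full.shape[1]
    if test == "qlf":
        if df_resid <= 0:
            raise ValueError("no residual degrees of freedom for the QL F test")
        mu_full = np.exp(np.clip(offset + beta_full @ X_full.T, -30, 30))
        s2 = np.maximum(nb_deviance(y, mu_full, phi) / df_resid, 1e-8)

    cpm = cm.counts / lib_eff * 1e6  # CPM on the effective library scale
    groups = _group_key(cm.sample_meta)
    group_cpm = cpm.T.groupby(groups).mean().T  # genes x groups

    lfc = {}
    pval = {}
    for contrast in CONTRASTS:
        frag, tp = contrast.split("-")
        g_frag, g_cont = f"{frag}_{tp}", f"CONT_{tp}"
        # reduced design: merge the fragment group with its matched control
        idx_map = {g: i for i, g in enumerate(group_levels)}
        X_red = X_full[:, [i for g, i in idx_map.items() if g != g_frag] +
                       list(range(len(group_levels), X_full.shape[1]))].copy()
        red_levels = [g for g in group_levels if g != g_frag]
        merged_col = red_levels.index(g_cont)
        X_red[:, merged_col] += X_full[:, idx_map[g_frag]]
        _, ll_red = fit_nb_glm(y, X_red, phi, offset=offset)
        stat = np.clip(2.0 * (ll_full - ll_red), 0.0, None)
        if test == "lrt":
            p = stats.chi2.sf(stat, df=1)
        elif test == "qlf":
            p = stats.f.sf(stat / s2, 1, df_resid)
        else:
            raise ValueError(f"unknown test {test!r}")
        lfc[contrast] = np.log2(
            (group_cpm[g_frag] + 0.5) / (group_cpm[g_cont] + 0.5)
        )
        pval[contrast] = p

    log2fc = pd.DataFrame(lfc, index=cm.genes)[list(CONTRASTS)]
    p_value = pd.DataFrame(pval, index=cm.genes)[list(CONTRASTS)]
    return DEGTable(log2fc=log2fc, p_value=p_value, params=params)


def deg_filter(table: DEGTable, params: FilterParams | None = None) -> tuple[DEGTable, pd.Index]:
    """Flag DE calls (p below threshold AND fold change above threshold) and
    return the union of genes DE in at least one contrast."""
    if params is None:
        params = table.params
    is_de = (table.p_value < params.p_threshold) & (
        table.log2fc.abs() > np.log2(params.min_fold_change)
    )
    table.is_de = is_de
    table.params = params
    union = table.log2fc.index[is_de.any(axis=1)]
    return table, union


def summarize_deg(n_de: int, n_expressed: int) -> float:
    """Percentage of expressed genes called DE, to two decimals."""
    if n_expressed <= 0:
        raise ValueError("n_expressed must be positive")
    if not 0 <= n_de <= n_expressed:
        raise ValueError("need 0 <= n_de <= n_expressed")
    return round(100.0 * n_de / n_expressed, 2)
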