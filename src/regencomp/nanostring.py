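"""nCounter-style probe-count normalization, filtering, DE, and concordance.

Mirrors the standard nCounter workflow: a per-sample background threshold
from the negative-control probes (mean + 2 SD), positive-control and
housekeeping scaling vectors from geometric means, removal of probes that
never rise above background, a count-model likelihood-ratio test per probe
and condition against the uncut control, and a trend/significance concordance
classification against matched RNA-seq fold changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .glm import fit_nb_glm

PROBE_CLASSES = ("negative", "positive", "housekeeping", "target")


@dataclass
class NanostringRun:
    counts: pd.DataFrame  # probes x samples
    probe_class: pd.Series  # probe -> class
    sample_meta: pd.DataFrame  # as in CountMatrix
    target_gene: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("probe counts must be non-negative")
        bad = set(self.probe_class) - set(PROBE_CLASSES)
        if bad:
            raise ValueError(f"unknown probe classes: {sorted(bad)}")
        n = self.probe_class.value_counts()
        if n.get("negative", 0) < 2:
            raise ValueError("need at least 2 negative control probes")
        if n.get("positive", 0) < 1 or n.get("housekeeping", 0) < 1:
            raise ValueError("need positive and housekeeping control probes")

    def probes_of(self, cls: str) -> pd.Index:
        return self.probe_class.index[self.probe_class == cls]


@dataclass
class NormalizationFactors:
    background: pd.Series  # per-sample lambda
    positive: pd.Series  # per-sample positive-control scaling
    housekeeping: pd.Series  # per-sample housekeeping scaling


def background_threshold(run: NanostringRun) -> pd.Series:
    """Per-sample background: mean + 2 * sample SD of the negative probes."""
    neg = run.counts.loc[run.probes_of("negative")]
    if len(neg) < 2:
        raise ValueError("need at least 2 negative probes for a background SD")
    return neg.mean(axis=0) + 2.0 * neg.std(axis=0, ddof=1)


def _scaling(counts: pd.DataFrame) -> pd.Series:
    if (counts.sum(axis=1) == 0).any():
        raise ValueError("control probe with all-zero counts")
    # zeros are floored to 1 before the geometric mean; unlike an additive
    # pseudo-count this keeps the factors exactly inverse to a per-sample
    # rescaling whenever the control counts are positive
    gm = np.exp(np.log(counts.clip(lower=1)).mean(axis=0))
    return gm.mean() / gm


def scaling_factors(run: NanostringRun) -> NormalizationFactors:
    """Positive-control and housekeeping scaling vectors.

    Per class: factor_s = (across-sample mean of per-sample geometric means)
    / (geometric mean of sample s), with zeros floored to 1 inside the
    geometric means. The housekeeping vector is computed on counts already
    rescaled by the positive vector, so the product positive x housekeeping
    corrects the overall per-sample scale exactly once (computing both on
    raw counts would double-correct it). Multiplying a sample's counts by c
    divides its factor product by exactly c, so normalized values are scale
    invariant up to the across-sample anchor — one global constant that
    cancels in every downstream model fit.
    """
    positive = _scaling(run.counts.loc[run.probes_of("positive")])
    hk_posnorm = run.counts.loc[run.probes_of("housekeeping")] * positive
    return NormalizationFactors(
        background=background_threshold(run),
        positive=positive,
        housekeeping=_scaling(hk_posnorm),
    )


def flag_low_probes(run: NanostringRun, background: pd.Series) -> set:
    """Target probes that never exceed their sample's background threshold."""
    targets = run.counts.loc[run.probes_of("target")]
    above = targets.gt(background, axis=1)  # strict >
    return set(targets.index[~above.any(axis=1)])


def normalized_counts(run: NanostringRun, factors: NormalizationFactors) -> pd.DataFrame:
    """Counts rescaled by the product of the two scaling vectors."""
    scale = factors.positive * factors.housekeeping
    return run.counts * scale


def _estimate_common_phi(y: np.ndarray, groups: pd.Series) -> float:
    """Pooled method-of-moments NB dispersion; 0 triggers the Poisson fallback."""
    num = den = 0.0
    for g in groups.unique():
        cols = np.flatnonzero((groups == g).to_numpy())
        if len(cols) < 2:
            continue
        sub = y[:, cols]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        num += np.sum(v - m)
        den += np.sum(m**2)
    return max(0.0, num / den) if den > 0 else 0.0


def nanostring_de(
    run: NanostringRun,
    factors: NormalizationFactors,
    failed_probes: set | None = None,
    test: str = "lrt",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-probe (log2fc, p) for each fragment/timepoint contrast vs control.

    Fits a count GLM per probe over all samples with a cell-means group term
    and batch covariate, using log(positive x housekeeping scaling) offsets
    so the model works on the normalized scale; each contrast is tested with
    a 1-df likelihood-ratio test (``test="lrt"``, default); ``test="qlf"``
    scales the statistic by the per-probe residual deviance over its degrees
    of freedom and refers it to an F distribution instead. A common NB dispersion is estimated by
    moments and the model falls back to Poisson when the estimate hits zero.
    Returns (log2fc, p_value) DataFrames over the six contrasts.
    """
    from .expr import CONTRASTS, _design_matrices, _group_key
    from .glm import nb_deviance

    failed = failed_probes if failed_probes is not None else set()
    probes = [p for p in run.probes_of("target") if p not in failed]
    if not probes:
        raise ValueError("no target probes left after background filtering")
    y = run.counts.loc[probes].to_numpy(float)
    scale = (factors.positive * factors.housekeeping).to_numpy(float)
    offset = -np.log(scale)  # raw counts are normalized counts / scale
    meta = run.sample_meta
    phi = _estimate_common_phi(y * scale, _group_key(meta))
    X_full, group_levels, _ = _design_matrices(meta)
    beta_full, ll_full = fit_nb_glm(y, X_full, np.full(len(probes), phi), offset=offset)
    df_resid = y.shape[1] - X_full.shape[1]
    if test == "qlf":
        mu_full = np.exp(np.clip(offset + beta_full @ X_full.T, -30, 30))
        s2 = np.maximum(
            nb_deviance(y, mu_full, np.full(len(probes), phi)) / df_resid, 1e-8
        )

    norm = pd.DataFrame(run.counts.loc[probes].to_numpy() * scale,
                        index=probes, columns=run.counts.columns)
    groups = _group_key(meta)
    group_means = norm.T.groupby(groups).mean().T

    lfc, pval = {}, {}
    idx_map = {g: i for i, g in enumerate(group_levels)}
    for contrast in CONTRASTS:
        frag, tp = contrast.split("-")
        g_frag, g_cont = f"{frag}_{tp}", f"CONT_{tp}"
        X_red = X_full[:, [i for g, i in idx_map.items() if g != g_frag] +
                       list(range(len(group_levels), X_full.shape[1]))].copy()
        red_levels = [g for g in group_levels if g != g_frag]
        X_red[:, red_levels.index(g_cont)] += X_full[:, idx_map[g_frag]]
        _, ll_red = fit_nb_glm(y, X_red, np.full(len(probes), phi), offset=offset)
        stat = np.clip(2.0 * (ll_full - ll_red), 0.0, None)
        if test == "qlf":
            pval[contrast] = stats.f.sf(stat / s2, 1, df_resid)
        elif test == "lrt":
            pval[contrast] = stats.chi2.sf(stat, df=1)
        else:
            raise ValueError(f"unknown test {test!r}")
        lfc[contrast] = np.log2(
            (group_means[g_frag] + 0.5) / (group_means[g_cont] + 0.5)
        )
    log2fc = pd.DataFrame(lfc, index=pd.Index(probes))[list(CONTRASTS)]
    p_value = pd.DataFrame(pval, index=pd.Index(probes))[list(CONTRASTS)]
    return log2fc, p_value


def concordance_classes(
    ns_log2fc: pd.DataFrame,
    ns_is_de: pd.DataFrame,
    rnaseq_log2fc: pd.DataFrame,
    rnaseq_is_de: pd.DataFrame,
    zero_band: float = 0.25,
    majority: float = 0.5,
) -> pd.Series:
    """Per-gene platform concordance class.

    A contrast's trend agrees when the two log2FCs share a sign, or when
    either is inside the +-``zero_band`` dead zone. A gene is ``trend_only``
    when trends agree in a strict majority of the shared contrasts,
    ``trend+significance`` when additionally the DE flags match in a
    majority, and ``discordant`` otherwise.
    """
    shared = ns_log2fc.index.intersection(rnaseq_log2fc.index)
    if len(shared) == 0:
        raise ValueError("no shared genes between the two platforms")
    cols = [c for c in ns_log2fc.columns if c in rnaseq_log2fc.columns]
    a = ns_log2fc.loc[shared, cols]
    b = rnaseq_log2fc.loc[shared, cols]
    agree = (np.sign(a) == np.sign(b)) | (a.abs() < zero_band) | (b.abs() < zero_band)
    sig_match = ns_is_de.loc[shared, cols].astype(bool) == rnaseq_is_de.loc[shared, cols].astype(bool)
    trend_ok = agree.mean(axis=1) > majority
    sig_ok = sig_match.mean(axis=1) > majority
    out = pd.Series("discordant", index=shared, dtype=object)
    out[trend_ok] = "trend_only"
    out[trend_ok & sig_ok] = "trend+significance"
    return out
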