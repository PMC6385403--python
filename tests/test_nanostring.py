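"""nCounter normalization, filtering, DE calibration, and concordance."""

import numpy as np
import pandas as pd
import pytest

from regencomp.nanostring import (
    NanostringRun,
    background_threshold,
    concordance_classes,
    flag_low_probes,
    nanostring_de,
    normalized_counts,
    scaling_factors,
)

from conftest import design_meta


def make_run(seed=0, n_targets=40, planted_fold=None, factor_sd=0.25,
             neg_mean=10.0, neg_sd=3.0, phi=0.05):
    """A synthetic nCounter panel over the 18-sample design."""
    rng = np.random.default_rng(seed)
    meta = design_meta()
    factors = rng.lognormal(0.0, factor_sd, len(meta))
    rows, classes, data = [], [], []
    for i in range(8):
        rows.append(f"NEG_{i}")
        classes.append("negative")
        data.append(np.maximum(0, rng.normal(neg_mean, neg_sd, len(meta))).round())
    for i, m in enumerate([8000, 2000, 500, 125, 32, 8]):
        rows.append(f"POS_{i}")
        classes.append("positive")
        data.append(rng.poisson(m * factors))
    for i in range(11):
        rows.append(f"HK_{i}")
        classes.append("housekeeping")
        data.append(rng.poisson(500 * factors))
    r = 1.0 / phi
    is_ant = (meta["fragment"] == "ANT").to_numpy()
    for i in range(n_targets):
        m = 500.0 if planted_fold else 10 ** rng.uniform(2, 3)
        mus = m * factors.copy()
        if planted_fold:
            mus[is_ant] *= planted_fold
        rows.append(f"T_{i}")
        classes.append("target")
        data.append(rng.negative_binomial(r, r / (r + mus)))
    counts = pd.DataFrame(np.vstack(data), index=rows, columns=meta.index).astype(int)
    return NanostringRun(counts=counts,
                         probe_class=pd.Series(classes, index=counts.index),
                         sample_meta=meta)


class TestBackground:
    def test_zero_sd_negatives(self):
        run = make_run()
        run.counts.loc[run.probes_of("negative")] = 10
        assert np.allclose(background_threshold(run), 10.0)

    def test_hand_arithmetic_8_12(self):
        run = make_run()
        neg = run.probes_of("negative")
        run.counts.loc[neg] = 0
        run.counts.loc[neg[0]] = 8
        run.counts.loc[neg[1]] = 12
        run2 = NanostringRun(counts=run.counts.loc[list(neg[:2]) +
                                                   list(run.counts.index[8:])],
                             probe_class=run.probe_class.drop(neg[2:]),
                             sample_meta=run.sample_meta)
        lam = background_threshold(run2)
        assert np.allclose(lam, 10 + 2 * np.sqrt(8.0))

    def test_translation_equivariance(self):
        run = make_run(1)
        lam = background_threshold(run)
        shifted = run.counts.copy()
        shifted.loc[run.probes_of("negative")] += 7
        run2 = NanostringRun(counts=shifted, probe_class=run.probe_class,
                             sample_meta=run.sample_meta)
        assert np.allclose(background_threshold(run2), lam + 7)

    def test_background_estimator_tracks_mean_plus_2sd(self):
        run = make_run(2, neg_mean=10.0, neg_sd=3.0)
        lam = background_threshold(run)
        assert abs(lam.mean() - 16.0) < 3.0  # sampling error over 8 probes


class TestScaling:
    def test_identical_samples_give_unit_factors(self):
        run = make_run(3)
        tiled = run.counts.copy()
        tiled.loc[:, :] = np.tile(run.counts.iloc[:, [0]].to_numpy(),
                                  (1, run.counts.shape[1]))
        run2 = NanostringRun(counts=tiled, probe_class=run.probe_class,
                             sample_meta=run.sample_meta)
        f = scaling_factors(run2)
        assert np.allclose(f.positive, 1.0, atol=1e-12)
        assert np.allclose(f.housekeeping, 1.0, atol=1e-12)

    def test_doubling_positives_halves_positive_factor(self):
        run = make_run(4)
        f1 = scaling_factors(run).positive
        bumped = run.counts.copy()
        s = bumped.columns[0]
        bumped.loc[run.probes_of("positive"), s] *= 2
        run2 = NanostringRun(counts=bumped, probe_class=run.probe_class,
                             sample_meta=run.sample_meta)
        f2 = scaling_factors(run2).positive
        # inverse-scale relation, up to the small shift of the across-sample
        # mean caused by the one altered sample (1 of 18)
        assert f1[s] / f2[s] == pytest.approx(2.0, rel=0.07)

    def test_scale_invariance_up_to_the_anchor_constant(self):
        # the factors absorb a per-sample rescaling exactly; only the
        # across-sample anchor (a single global constant that cancels in
        # every downstream model fit) moves
        run = make_run(5)
        norm1 = normalized_counts(run, scaling_factors(run))
        scaled = run.counts.astype(float).copy()
        s = scaled.columns[3]
        scaled[s] *= 3.0
        run2 = NanostringRun(counts=scaled, probe_class=run.probe_class,
                             sample_meta=run.sample_meta)
        norm2 = normalized_counts(run2, scaling_factors(run2))
        ratio = norm2.to_numpy() / norm1.to_numpy()
        assert np.allclose(ratio, ratio[0, 0], rtol=1e-10)


class TestFlagging:
    def test_single_sample_above_background_retains(self):
        run = make_run(6)
        lam = background_threshold(run)
        t = run.probes_of("target")[0]
        run.counts.loc[t] = 0
        run.counts.loc[t, run.counts.columns[5]] = int(lam.iloc[5]) + 50
        assert t not in flag_low_probes(run, lam)

    def test_probe_at_exactly_background_fails(self):
        run = make_run(7)
        lam = pd.Series(20.0, index=run.counts.columns)
        t = run.probes_of("target")[0]
        run.counts.loc[t] = 20
        assert t in flag_low_probes(run, lam)

    def test_raising_background_never_unfails(self):
        run = make_run(8)
        lam = background_threshold(run)
        failed_lo = flag_low_probes(run, lam)
        failed_hi = flag_low_probes(run, lam + 100)
        assert failed_lo <= failed_hi


class TestNanostringDE:
    def test_null_type_one_error_calibrated(self):
        run = make_run(9, n_targets=1000)
        _, p = nanostring_de(run, scaling_factors(run))
        rate = float((p.to_numpy() < 0.05).mean())
        assert 0.02 <= rate <= 0.10

    def test_power_for_fourfold_change(self):
        run = make_run(10, n_targets=200, planted_fold=4.0)
        _, p = nanostring_de(run, scaling_factors(run))
        power = float((p[["ANT-T0", "ANT-T1", "ANT-T2"]].to_numpy() < 0.05).mean())
        assert power > 0.9

    def test_label_swap_flips_log2fc(self):
        run = make_run(11, n_targets=30, planted_fold=3.0)
        f = scaling_factors(run)
        lfc1, _ = nanostring_de(run, f)
        meta = run.sample_meta.copy()
        meta["fragment"] = meta["fragment"].map(
            {"ANT": "CONT", "CONT": "ANT", "POST": "POST"})
        run2 = NanostringRun(counts=run.counts, probe_class=run.probe_class,
                             sample_meta=meta)
        lfc2, _ = nanostring_de(run2, scaling_factors(run2))
        cols = ["ANT-T0", "ANT-T1", "ANT-T2"]
        assert np.allclose(lfc1[cols].to_numpy(), -lfc2[cols].to_numpy())


class TestConcordance:
    def _tables(self, seed=0, n=40):
        rng = np.random.default_rng(seed)
        cols = ["ANT-T0", "ANT-T1", "ANT-T2", "POST-T0", "POST-T1", "POST-T2"]
        lfc = pd.DataFrame(rng.normal(0, 2, (n, 6)),
                           index=[f"g{i}" for i in range(n)], columns=cols)
        de = lfc.abs() > 1
        return lfc, de

    def test_identical_tables_fully_concordant(self):
        lfc, de = self._tables()
        cls = concordance_classes(lfc, de, lfc, de)
        assert (cls == "trend+significance").all()

    def test_sign_flip_is_discordant(self):
        lfc, de = self._tables(1)
        lfc = lfc.where(lfc.abs() > 0.5, 2.0)  # keep away from the dead zone
        cls = concordance_classes(lfc, de, -lfc, de)
        assert (cls == "discordant").all()

    def test_no_shared_genes_rejected(self):
        lfc, de = self._tables(2)
        other = lfc.rename(index=lambda g: f"x{g}")
        with pytest.raises(ValueError):
            concordance_classes(lfc, de, other, de.rename(index=lambda g: f"x{g}"))

    def test_synthetic_platform_pair_mostly_concordant(self, small_config):
        from regencomp import (
            FilterParams, cpm_normalize, deg_filter, detection_filter,
            estimate_dispersions, simulate_focal_counts, simulate_nanostring,
            test_differential_expression, generate_truth,
        )

        truth = generate_truth(small_config)
        run = simulate_nanostring(truth, small_config)
        factors = scaling_factors(run)
        failed = flag_low_probes(run, background_threshold(run))
        ns_lfc, ns_p = nanostring_de(run, factors, failed)
        ns_lfc = ns_lfc.rename(index=run.target_gene)
        ns_de = (ns_p.rename(index=run.target_gene) < 0.05) & (ns_lfc.abs() > 1)

        cm = simulate_focal_counts(truth, small_config)
        fp = FilterParams()
        cm = cm.subset_genes(detection_filter(cpm_normalize(cm), fp))
        deg = test_differential_expression(cm, estimate_dispersions(cm), fp)
        deg, _ = deg_filter(deg, fp)
        shared = ns_lfc.index.intersection(deg.log2fc.index)
        cls = concordance_classes(ns_lfc.loc[shared], ns_de.loc[shared],
                                  deg.log2fc, deg.is_de)
        assert (cls != "discordant").mean() >= 0.8
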