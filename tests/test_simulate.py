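"""Ground-truth simulator: covariance design, latent Gaussian stage, depth
calibration and Poisson read sampling."""

import numpy as np
import pytest
from scipy import stats

from countsimbench import (
    SimConfig,
    SimulationError,
    build_covariance,
    calibrate_depth,
    preset_config,
    simulate_counts,
    simulate_dataset,
    simulate_log_concentrations,
)
from countsimbench.simulate import make_ground_truth


def cfg(**kw):
    defaults = dict(n_features=30, n_per_class=(8, 8), de_fraction=0.1)
    defaults.update(kw)
    return SimConfig(**defaults)


class TestBuildCovariance:
    def test_single_block_compound_symmetry(self):
        R = build_covariance(cfg(block_size=5, block_rho=0.4)).full()
        assert R.shape == (30, 30)
        np.testing.assert_allclose(np.diag(R), 1.0)
        np.testing.assert_allclose(R, R.T)
        block = [i for i, b in enumerate(
            build_covariance(cfg()).block_of()) if b == 0]
        assert len(block) == 5
        sub = R[np.ix_(block, block)]
        off = sub[~np.eye(5, dtype=bool)]
        np.testing.assert_allclose(off, 0.4)
        outside = np.delete(np.delete(R, block, 0), block, 1)
        np.testing.assert_allclose(outside, np.eye(outside.shape[0]))

    def test_zero_rho_gives_identity(self):
        R = build_covariance(cfg(block_rho=0.0)).full()
        np.testing.assert_allclose(R, np.eye(30))

    def test_block_spectrum(self):
        # compound symmetry k=5, rho=0.4: eigenvalues 1+4*rho and 1-rho (x4)
        B = build_covariance(cfg()).block_matrix(0)
        eig = np.sort(np.linalg.eigvalsh(B))
        np.testing.assert_allclose(eig, [0.6, 0.6, 0.6, 0.6, 2.6])
        assert np.all(eig > 0)

    def test_rejects_non_positive_definite_rho(self):
        with pytest.raises(SimulationError, match="positive-definite"):
            build_covariance(cfg(block_rho=-0.3))  # below -1/(k-1) = -0.25

    def test_rejects_blocks_exceeding_features(self):
        with pytest.raises(SimulationError):
            build_covariance(cfg(n_features=8, n_blocks=2, block_size=5,
                                 de_fraction=0.0))


class TestLatentStage:
    def test_sigma_zero_equals_class_means(self):
        c = cfg(sigma=0.0, lfc_de=1.0)
        latent = simulate_log_concentrations(c, seed=1)
        truth = make_ground_truth(c, seed=1)
        shift = np.log(2.0)
        for g in range(c.n_features):
            expected = np.full(c.n_samples, c.baseline_log_mean)
            if truth.de_flags[g]:
                expected[truth.class_label == 2] += shift
            np.testing.assert_allclose(latent[g], expected)

    def test_non_de_feature_class_means_agree(self):
        # large-n check: class means of a non-DE feature within 3 SE
        c = cfg(n_features=10, n_per_class=(10_000, 10_000), de_fraction=0.1)
        latent = simulate_log_concentrations(c, seed=2)
        truth = make_ground_truth(c, seed=2)
        g = int(np.flatnonzero(~truth.de_flags)[0])
        a = latent[g, truth.class_label == 1]
        b = latent[g, truth.class_label == 2]
        se = np.sqrt(a.var() / a.size + b.var() / b.size)
        assert abs(a.mean() - b.mean()) < 3 * se

    def test_block_latent_correlation_recovered(self):
        c = cfg(n_features=20, n_per_class=(2500, 2500), de_fraction=0.0,
                sigma=0.4, block_rho=0.4)
        latent = simulate_log_concentrations(c, seed=3)
        block = np.flatnonzero(make_ground_truth(c, seed=3).block_id == 0)
        corrs = [
            np.corrcoef(latent[i], latent[j])[0, 1]
            for k, i in enumerate(block)
            for j in block[k + 1:]
        ]
        assert abs(np.mean(corrs) - 0.4) < 0.03

    def test_deterministic_given_seed(self):
        a = simulate_log_concentrations(cfg(), seed=9)
        b = simulate_log_concentrations(cfg(), seed=9)
        np.testing.assert_array_equal(a, b)


class TestSimulateCounts:
    def test_pure_poisson_variance_mean_ratio(self):
        c = cfg(n_features=200, n_per_class=(500, 500), de_fraction=0.0,
                sigma=0.0)
        latent = np.full((200, 1000), np.log(50.0))
        cm = simulate_counts(latent, 1.0, c, seed=4)
        ratio = cm.counts.var(axis=1, ddof=1) / cm.counts.mean(axis=1)
        assert abs(np.median(ratio) - 1.0) < 0.1

    def test_scale_zero_gives_all_zero(self):
        c = cfg()
        latent = simulate_log_concentrations(c, seed=5)
        cm = simulate_counts(latent, 0.0, c, seed=5)
        assert cm.counts.sum() == 0

    def test_bitwise_deterministic(self):
        c = cfg()
        latent = simulate_log_concentrations(c, seed=6)
        a = simulate_counts(latent, 2.0, c, seed=6)
        b = simulate_counts(latent, 2.0, c, seed=6)
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_rate_ceiling_guard(self):
        c = cfg()
        latent = np.full((c.n_features, c.n_samples), 40.0)  # e^40 ~ 2e17
        with pytest.raises(SimulationError, match="ceiling"):
            simulate_counts(latent, 1.0, c, seed=0)

    def test_depth_jitter_scales_library_sizes(self):
        c = cfg(n_features=2000, n_per_class=(20, 20),
                depth_jitter=(0.5, 2.0))
        latent = np.full((2000, 40), np.log(100.0))
        cm = simulate_counts(latent, 1.0, c, seed=8)
        libs = cm.library_sizes()
        assert libs.max() / libs.min() > 1.5  # jitter visible


class TestCalibrateDepth:
    def test_fixed_point_when_target_equals_pilot_mean(self):
        c = cfg(n_features=500, n_per_class=(30, 30))
        latent = simulate_log_concentrations(c, seed=11)
        pilot = simulate_counts(latent, 1.0, c, seed=11 + 1000)
        c2 = cfg(n_features=500, n_per_class=(30, 30),
                 target_mean_count=float(pilot.counts.mean()))
        scale = calibrate_depth(c2, pilot_seed=11, latent=latent)
        assert scale == pytest.approx(1.0)

    def test_doubling_target_doubles_scale(self):
        base = dict(n_features=500, n_per_class=(30, 30))
        s1 = calibrate_depth(cfg(**base, target_mean_count=200.0),
                             pilot_seed=12)
        s2 = calibrate_depth(cfg(**base, target_mean_count=400.0),
                             pilot_seed=12)
        assert s2 / s1 == pytest.approx(2.0, rel=0.02)

    def test_preset_hits_target_mean(self):
        cm, _ = simulate_dataset("ngsspg1-small", seed=13)
        assert 297.0 <= cm.counts.mean() <= 303.0


class TestSimulateDataset:
    def test_preset_design_values(self):
        cm, truth = simulate_dataset("ngsspg1-small", seed=1)
        assert cm.counts.shape == (500, 20)
        assert truth.de_flags.sum() == 25  # 5% of 500
        assert (truth.class_label == 1).sum() == 10
        assert (truth.class_label == 2).sum() == 10

    def test_zero_de_fraction(self):
        c = cfg(de_fraction=0.0)
        _, truth = simulate_dataset(c, seed=2)
        assert not truth.de_flags.any()
        assert np.all(truth.true_lfc == 0.0)

    def test_true_lfc_zero_off_de(self):
        _, truth = simulate_dataset(cfg(), seed=3)
        assert np.all(truth.true_lfc[~truth.de_flags] == 0.0)

    def test_higher_sigma_increases_log_count_variance(self):
        c1 = preset_config("ngsspg1-small")
        c2 = preset_config("ngsspg2-small")
        cm1, _ = simulate_dataset(c1, seed=4)
        cm2, _ = simulate_dataset(c2, seed=4)
        v1 = np.log1p(cm1.counts).var(axis=1).mean()
        v2 = np.log1p(cm2.counts).var(axis=1).mean()
        assert v2 > v1

    def test_end_to_end_determinism(self):
        a, _ = simulate_dataset(cfg(), seed=5)
        b, _ = simulate_dataset(cfg(), seed=5)
        np.testing.assert_array_equal(a.counts, b.counts)
        assert a.feature_ids == b.feature_ids

    def test_de_lfc_converges_to_design(self):
        c = cfg(n_features=40, n_per_class=(2000, 2000), de_fraction=0.1,
                sigma=0.4, lfc_de=1.0)
        cm, truth = simulate_dataset(c, seed=6)
        m1 = cm.counts[:, truth.class_label == 1].mean(axis=1)
        m2 = cm.counts[:, truth.class_label == 2].mean(axis=1)
        emp_lfc = np.log2(m2 / m1)
        assert np.all(np.abs(emp_lfc[truth.de_flags] - 1.0) < 0.1)
        assert np.all(np.abs(emp_lfc[~truth.de_flags]) < 0.1)

    def test_null_class_distributions_exchangeable(self):
        # lfc_de = 0: per-gene two-sample KS rejects at about nominal rate
        c = cfg(n_features=400, n_per_class=(50, 50), de_fraction=0.05,
                lfc_de=0.0)
        cm, truth = simulate_dataset(c, seed=7)
        in1 = truth.class_label == 1
        pvals = np.array([
            stats.ks_2samp(row[in1], row[~in1]).pvalue for row in cm.counts
        ])
        rate = np.mean(pvals < 0.05)
        assert 0.005 <= rate <= 0.12

    def test_hetero_markers_shift_only_selected_subgroups(self):
        c = SimConfig(
            n_features=50, n_per_class=(600, 600), n_subgroups_class1=3,
            de_fraction=0.0, n_hetero_markers=5, sigma=0.1, lfc_de=2.0,
            target_mean_count=100.0,
        )
        cm, truth = simulate_dataset(c, seed=8)
        assert truth.hetero_flags.sum() == 5
        assert len(truth.hetero_subgroups) == 2  # ceil(3/2)
        g = int(np.flatnonzero(truth.hetero_flags)[0])
        cls1 = truth.class_label == 1
        shifted = cls1 & np.isin(truth.subgroup_label, truth.hetero_subgroups)
        plain = cls1 & ~np.isin(truth.subgroup_label, truth.hetero_subgroups)
        assert cm.counts[g, shifted].mean() > 2 * cm.counts[g, plain].mean()

    def test_invalid_configs_rejected(self):
        with pytest.raises(SimulationError):
            SimConfig(de_fraction=1.5).validate()
        with pytest.raises(SimulationError):
            SimConfig(depth_jitter=(2.0, 1.0)).validate()
        with pytest.raises(SimulationError):
            preset_config("nope")
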