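"""Synthetic cohort generator: neural dynamics, hemodynamics, clinical table."""

import numpy as np
import pytest

from rsgca.connectivity import pairwise_gca
from rsgca.networks import HemoSpec, NetworkSpec, RegionSpec
from rsgca.severity import pc1
from rsgca.simulate import (
    ClinicalSpec,
    CohortConfig,
    SubjectData,
    apply_hemodynamics,
    clinical_correlation_matrix,
    simulate_clinical,
    simulate_cohort,
    simulate_neural,
)


def _net(W, corr=None, lag=1, innovation_sd=1.0):
    regions = [RegionSpec(f"r{i}") for i in range(W.shape[0])]
    return NetworkSpec(regions, W, innovation_sd, influence_lag=lag,
                       innovation_corr=corr or {})


class TestSimulateNeural:
    def test_no_dynamics_gives_unit_white_noise(self, rng):
        z = simulate_neural(_net(np.zeros((3, 3))), 20_000, rng)
        assert z.shape == (20_000, 3)
        assert np.allclose(z.var(axis=0), 1.0, atol=0.05)
        # no lag-1 autocorrelation
        ac = [np.corrcoef(z[1:, i], z[:-1, i])[0, 1] for i in range(3)]
        assert np.max(np.abs(ac)) < 0.03

    def test_nonstationary_network_rejected(self):
        with pytest.raises(ValueError, match="stationary"):
            _net(np.diag([1.05, 0.2]))

    def test_lag1_coefficient_recovered(self, rng):
        """y driven only by x at lag 1 with coefficient 0.5: the estimator
        recovers 0.5 on average (Monte-Carlo oracle over 200 series).
        Innovation variances are set so both series have unit variance, the
        scale on which the standardized coefficient equals the weight."""
        W = np.array([[0.0, 0.0], [0.5, 0.0]])
        net = _net(W, innovation_sd=np.array([1.0, np.sqrt(1 - 0.25)]))
        est = [
            pairwise_gca(*(lambda z: (z[:, 0], z[:, 1]))(
                simulate_neural(net, 800, rng)))[0]
            for _ in range(200)
        ]
        assert np.mean(est) == pytest.approx(0.5, abs=0.02)

    def test_seeded_determinism(self):
        net = _net(np.array([[0.3, 0.1], [0.0, 0.3]]))
        z1 = simulate_neural(net, 100, np.random.default_rng(7))
        z2 = simulate_neural(net, 100, np.random.default_rng(7))
        assert np.array_equal(z1, z2)


class TestHemodynamics:
    def test_disabled_is_identity(self, rng):
        hemo = HemoSpec(enabled=False)
        z = rng.standard_normal((100, 2))
        assert np.array_equal(apply_hemodynamics(z, hemo), z)

    def test_impulse_peaks_later_with_larger_delay(self):
        hemo = HemoSpec(delay_jitter_sd_s=0.0)
        n = 400
        imp = np.zeros((n, 2))
        imp[100] = 1.0
        out = apply_hemodynamics(imp, hemo, delays_s=np.array([6.0, 9.0]))
        assert np.argmax(out[:, 1]) > np.argmax(out[:, 0])

    def test_negative_delay_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            apply_hemodynamics(np.zeros((100, 1)), HemoSpec(),
                               delays_s=np.array([-1.0]))

    def test_consistent_delay_offset_creates_spurious_group_effect(self, rng):
        """The hemodynamic-delay confound: with zero neural lag, a delay
        difference that is consistent across subjects yields a group-level
        spurious directed effect, while zero-mean subject-random delays do
        not."""
        hemo = HemoSpec(delay_jitter_sd_s=0.0)

        def one_group(delayer, n_sub=60):
            betas = []
            for _ in range(n_sub):
                shared = rng.standard_normal(1600)
                noise = 0.3 * rng.standard_normal((1600, 2))
                z = shared[:, None] + noise  # zero-lag coupling only
                obs = apply_hemodynamics(z, hemo, delays_s=delayer())
                betas.append(pairwise_gca(obs[:, 0], obs[:, 1])[0])
            return np.asarray(betas)

        consistent = one_group(lambda: np.array([6.0, 7.0]))
        random_sign = one_group(
            lambda: np.array([6.0, 6.0 + rng.choice([-1.0, 1.0])])
        )
        t_cons = consistent.mean() / (consistent.std(ddof=1) / np.sqrt(len(consistent)))
        t_rand = random_sign.mean() / (random_sign.std(ddof=1) / np.sqrt(len(random_sign)))
        assert abs(t_cons) > 5.0
        assert abs(t_rand) < 3.0


class TestClinical:
    def test_correlation_matrix_hits_both_targets(self):
        C = clinical_correlation_matrix(ClinicalSpec())
        pairs = np.triu_indices(6, 1)
        ev = np.linalg.eigvalsh(C)
        assert np.abs(C[pairs]).mean() == pytest.approx(0.34, abs=1e-8)
        assert ev[-1] / 6 == pytest.approx(0.40, abs=1e-8)
        assert ev[0] > 0

    def test_mean_abs_corr_only_falls_back_to_equicorrelation(self):
        C = clinical_correlation_matrix(ClinicalSpec(target_pc1_share=None))
        pairs = np.triu_indices(6, 1)
        assert np.allclose(C[pairs], 0.34)

    def test_null_coupling_decorrelates_severity_from_loop(self, rng):
        spec = ClinicalSpec(severity_loop_coupling=0.0,
                            severity_visual_coupling=0.0)
        loop = rng.standard_normal(1000)
        tab = simulate_clinical(loop, spec, rng)
        r = np.corrcoef(tab.attrs["severity_latent"], loop)[0, 1]
        assert abs(r) < 0.08

    def test_realized_mean_abs_corr(self, rng):
        tab = simulate_clinical(rng.standard_normal(1000), ClinicalSpec(), rng)
        corr = np.corrcoef(tab.to_numpy().T)
        pairs = np.triu_indices(6, 1)
        assert np.abs(corr[pairs]).mean() == pytest.approx(0.34, abs=0.05)

    def test_near_collinear_limit(self, rng):
        spec = ClinicalSpec(target_mean_abs_corr=0.999, target_pc1_share=None)
        tab = simulate_clinical(rng.standard_normal(400), spec, rng)
        f = pc1(tab)
        assert f.variance_explained > 0.99

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            ClinicalSpec(target_mean_abs_corr=1.5)
        with pytest.raises(ValueError):
            ClinicalSpec(severity_loop_coupling=0.9, severity_visual_coupling=0.6)


class TestCohort:
    def test_seeded_cohorts_are_identical(self, default_networks):
        cfg = CohortConfig(n_controls=3, n_patients=3, n_timepoints=60,
                           rng_seed=5)
        a = simulate_cohort(cfg)
        b = simulate_cohort(cfg)
        for sa, sb in zip(a, b):
            assert sa.id == sb.id and sa.group == sb.group
            assert np.array_equal(sa.series, sb.series)
            assert sa.age == sb.age and sa.dose == sb.dose

    def test_cohort_composition_and_shapes(self, small_cohort):
        groups = [s.group for s in small_cohort]
        assert groups.count("control") == 10 and groups.count("patient") == 10
        t = small_cohort[0].series.shape[0]
        assert all(s.series.shape == (t, 8) for s in small_cohort)
        assert all(np.isfinite(s.series).all() for s in small_cohort)

    def test_patients_carry_clinical_and_dose(self, small_cohort):
        for s in small_cohort:
            if s.group == "patient":
                assert len(s.clinical) == 6
                assert s.dose >= 0.0
            else:
                assert s.clinical == {}
                assert s.dose == 0.0

    def test_age_distributions_follow_printed_summaries(self, default_networks):
        subs = simulate_cohort(CohortConfig(n_controls=150, n_patients=150,
                                            n_timepoints=60, rng_seed=8))
        ages_c = [s.age for s in subs if s.group == "control"]
        ages_p = [s.age for s in subs if s.group == "patient"]
        assert np.mean(ages_c) == pytest.approx(33.5, abs=2.5)
        assert np.mean(ages_p) == pytest.approx(34.5, abs=2.5)
        assert np.std(ages_c, ddof=1) == pytest.approx(9.1, abs=2.0)

    def test_truth_records_generating_coefficients(self, small_cohort):
        s = small_cohort[0]
        assert "rAI->rDLPFC" in s.truth["edges"]
        assert len(s.truth["delays_s"]) == 8
        assert "fc_latent" in s.truth

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(n_controls=0)


def test_subject_data_validation():
    with pytest.raises(ValueError, match="missing"):
        SubjectData(id="s", group="control",
                    series=np.array([[1.0, np.nan]]), regions=["a", "b"],
                    age=30.0, gender="F", dose=0.0)
    with pytest.raises(ValueError, match="columns"):
        SubjectData(id="s", group="control", series=np.ones((5, 2)),
                    regions=["a"], age=30.0, gender="F", dose=0.0)
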