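import numpy as np
import pytest

from mabscale.allometry import (
    AllometricModel,
    AllometricModelSpec,
    ModelComparison,
    bootstrap_fit,
    compare_models,
    fold_error_summary,
    scale_human_cl,
)
from mabscale.simulate import AllometricSimConfig, simulate_allometric_dataset


@pytest.fixture(scope="module")
def synthetic20():
    """20-antibody, 3-species dataset from the generative power-law model."""
    return simulate_allometric_dataset(AllometricSimConfig(n_antibodies=20, seed=11))


@pytest.fixture(scope="module")
def monkey_human_fit(packaged):
    model = AllometricModel.from_dataset(packaged, species=("monkey", "human"))
    return model, model.fit()


class TestFit:
    def test_noiseless_power_law_equals_loglog_ols(self):
        ds, truth = simulate_allometric_dataset(
            AllometricSimConfig(n_antibodies=12, omega=0.0, sigma=0.0, seed=5)
        )
        model = AllometricModel.from_dataset(ds, species=("rat", "monkey", "human"))
        slope, intercept = np.polyfit(model.logbw, np.log(model.y), 1)
        fit = model.fit(compute_se=False)
        assert fit.beta_tv == pytest.approx(slope, abs=1e-6)
        assert np.log(fit.alpha_tv) == pytest.approx(intercept, abs=1e-6)
        assert fit.beta_tv == pytest.approx(truth["beta"], abs=1e-6)

    def test_parameter_recovery_large_n(self):
        ds, truth = simulate_allometric_dataset(AllometricSimConfig(n_antibodies=200, seed=42))
        fit = AllometricModel.from_dataset(ds, species=("rat", "monkey", "human")).fit(compute_se=False)
        assert fit.beta_tv == pytest.approx(truth["beta"], abs=0.02)
        assert fit.omega2_alpha == pytest.approx(truth["omega2"], rel=0.3)

    def test_eb_etas_center_near_zero(self, monkey_human_fit):
        _, fit = monkey_human_fit
        assert np.exp(fit.eta).mean() == pytest.approx(1.0, abs=0.15)

    def test_summary_renders(self, monkey_human_fit):
        _, fit = monkey_human_fit
        text = fit.summary()
        assert "alpha_tv" in text and "OFV" in text

    def test_too_few_antibodies_raises(self):
        with pytest.raises(ValueError, match="at least 5"):
            AllometricModel([1.0] * 4, [1.0] * 4, list("abcd"))


class TestOFV:
    def test_omega_zero_collapses_to_fixed_effects_likelihood(self, synthetic20):
        ds, _ = synthetic20
        model = AllometricModel.from_dataset(ds, species=("rat", "monkey", "human"))
        alpha, beta, sg2 = 0.007, 0.9, 0.08
        ofv0 = model.ofv(params=(alpha, beta, 0.0, sg2))
        # direct -2 log N(y; f, sigma2 f^2)
        f = alpha * model.bw**beta
        direct = np.sum(np.log(2 * np.pi * sg2 * f**2) + (model.y - f) ** 2 / (sg2 * f**2))
        assert ofv0 == pytest.approx(direct, rel=1e-12)

    def test_laplace_close_to_dense_quadrature(self, synthetic20):
        ds, _ = synthetic20
        model = AllometricModel.from_dataset(ds, species=("rat", "monkey", "human"))
        fit = model.fit(compute_se=False)
        ofv_lap = model.ofv(theta=fit.theta, method="laplace")
        ofv_63 = model.ofv(theta=fit.theta, method="agq", nodes=63)
        assert abs(ofv_lap - ofv_63) < 0.5

    def test_quadrature_converged_at_default_nodes(self, monkey_human_fit):
        model, fit = monkey_human_fit
        assert abs(fit.ofv - model.ofv(theta=fit.theta, nodes=63)) < 0.05

    def test_perturbing_beta_increases_ofv(self, monkey_human_fit):
        model, fit = monkey_human_fit
        for db in (-0.05, 0.05):
            theta = fit.theta.copy()
            theta[1] += db
            assert model.ofv(theta=theta) > fit.ofv

    def test_invalid_variances_raise(self, monkey_human_fit):
        model, _ = monkey_human_fit
        with pytest.raises(ValueError):
            model.ofv(params=(0.007, 0.9, -0.1, 0.08))
        with pytest.raises(ValueError):
            model.ofv(params=(0.007, 0.9, 0.2, 0.0))

    def test_profile_beta_within_lrt_band(self, monkey_human_fit):
        model, fit = monkey_human_fit
        prof = model.fit(fix_beta=fit.beta_tv, compute_se=False)
        assert prof.ofv - fit.ofv < 3.841
        assert prof.ofv >= fit.ofv - 1e-3


class TestModelComparison:
    def _dummy(self, model, ofv, random_on):
        from mabscale.allometry import AllometricResults

        spec = AllometricModelSpec(species=model.spec.species, random_effect_on=random_on)
        m = AllometricModel(model.y, model.bw, np.array(model.names)[model.group], spec)
        d = len(random_on)
        theta = np.r_[np.log(0.007), 0.9, np.log(0.2) * np.ones(d), np.log(0.1)]
        return AllometricResults(
            model=m, theta=theta, ofv=ofv, converged=True, cov_theta=None,
            eta=np.zeros((m.n_groups, d)), method="agq", n_nodes=31,
        )

    def test_threshold_decision(self, monkey_human_fit):
        model, _ = monkey_human_fit
        red5 = self._dummy(model, 100.0, ("alpha",))
        assert compare_models(red5, self._dummy(model, 95.0, ("alpha", "beta"))).full_selected
        assert not compare_models(red5, self._dummy(model, 96.2, ("alpha", "beta"))).full_selected

    def test_boundary_just_below_threshold_keeps_reduced(self, monkey_human_fit):
        model, _ = monkey_human_fit
        red = self._dummy(model, 100.0, ("alpha",))
        full = self._dummy(model, 100.0 - 3.8, ("alpha", "beta"))
        assert not compare_models(red, full).full_selected

    def test_non_nested_raises(self, monkey_human_fit):
        model, _ = monkey_human_fit
        a = self._dummy(model, 100.0, ("alpha",))
        b = self._dummy(model, 95.0, ("beta",))
        with pytest.raises(ValueError, match="nested"):
            compare_models(a, b)


class TestScaling:
    def test_beta_one_preserves_per_kg_cl(self):
        assert scale_human_cl(0.5, 0.3, 70.0, beta=1.0) == pytest.approx(0.5)

    @pytest.mark.parametrize(
        "cl,bw_src,beta,expected",
        [(0.488, 0.3, 0.92, 0.3155), (1.85, 3.0, 0.84, 1.118)],
    )
    def test_hand_computed_values(self, cl, bw_src, beta, expected):
        assert scale_human_cl(cl, bw_src, 70.0, beta) == pytest.approx(expected, abs=5e-4)

    def test_per_kg_form_matches_absolute_form(self):
        # CL_h,abs = CL_s,abs * (BWh/BWs)^beta  <=>  per-kg exponent beta-1
        cl_s, bw_s, bw_h, beta = 0.4, 0.3, 70.0, 0.9
        abs_scaled = (cl_s * bw_s * 24 / 1000) * (bw_h / bw_s) ** beta
        per_kg = scale_human_cl(cl_s, bw_s, bw_h, beta)
        assert per_kg == pytest.approx(abs_scaled / bw_h / 24 * 1000, rel=1e-12)

    def test_non_positive_raises(self):
        with pytest.raises(ValueError):
            scale_human_cl(-1.0, 0.3, 70.0, 0.9)


class TestFoldErrorSummary:
    def test_perfect_predictions(self, packaged):
        res = fold_error_summary(packaged, "monkey", 0.84)
        perfect = res.ratio / res.ratio  # all ones
        assert np.all((perfect >= 0.5) & (perfect <= 2.0))
        res2 = fold_error_summary(packaged, "monkey", 0.84)
        assert res2.mean_ratio == pytest.approx(res.mean_ratio)

    def test_two_fold_bounds_inclusive(self, packaged):
        res = fold_error_summary(packaged, "monkey", 0.84)
        assert np.array_equal(res.within_2fold, (res.ratio >= 0.5) & (res.ratio <= 2.0))

    def test_invariant_to_common_rescaling(self, packaged):
        r1 = fold_error_summary(packaged, "rat", 0.92)
        # rescaling both observed and scaled CL by the same factor keeps ratios
        ratio_scaled = (3.7 * r1.observed) / (3.7 * r1.scaled)
        np.testing.assert_allclose(ratio_scaled, r1.ratio)

    def test_frame_columns(self, packaged):
        df = fold_error_summary(packaged, "rat", 0.92).to_frame()
        assert list(df.columns) == [
            "antibody", "observed_human_cl", "scaled_human_cl",
            "ratio_obs_over_scaled", "within_2fold",
        ]


class TestBootstrap:
    def test_determinism_and_size(self, packaged):
        b1 = bootstrap_fit(packaged, ("monkey", "human"), n_replicates=20, seed=123)
        b2 = bootstrap_fit(packaged, ("monkey", "human"), n_replicates=20, seed=123)
        np.testing.assert_array_equal(b1.estimates, b2.estimates)
        assert b1.n_replicates == 20
        assert b1.estimates.shape[0] + b1.n_failed == 20

    def test_different_seeds_differ(self, packaged):
        b1 = bootstrap_fit(packaged, ("monkey", "human"), n_replicates=5, seed=1)
        b2 = bootstrap_fit(packaged, ("monkey", "human"), n_replicates=5, seed=2)
        assert not np.array_equal(b1.estimates, b2.estimates)

    def test_summary_and_ci(self, packaged):
        b = bootstrap_fit(packaged, ("monkey", "human"), n_replicates=20, seed=3)
        ci = b.percentile_ci()
        assert ci["beta_tv"][0] < b.point_estimates["beta_tv"] < ci["beta_tv"][1]
        assert "boot mean" in b.summary()
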