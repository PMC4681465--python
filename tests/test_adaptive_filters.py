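"""ANFIS / RBFN / FLN-RBFN training, prediction and cancellation.

The least-squares substeps are checked against an independent dense
normal-equations oracle built directly from the definition (no ridge
solver code shared with the implementation).
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import eegclean.adaptive_filters as af
from eegclean import (
    GrowthParams,
    TimeSeries,
    TrainConfig,
    build_regressors,
    cancel,
    fit_anfis,
    fit_fln_rbfn,
    fit_rbfn,
    functional_expand,
    linear_scenario,
    predict,
)
from eegclean.adaptive_filters import (
    _anfis_design,
    _gaussian_activations,
    load_model,
    model_from_dict,
    model_to_dict,
    save_model,
)
from eegclean.signal_model import apply_params


def normal_equations_oracle(Phi, y, lam):
    """Brute-force ridge solution via the explicit normal equations,
    assembled entry by entry."""
    p = Phi.shape[1]
    A = np.empty((p, p))
    b = np.empty(p)
    for i in range(p):
        b[i] = np.dot(Phi[:, i], y)
        for j in range(p):
            A[i, j] = np.dot(Phi[:, i], Phi[:, j])
        A[i, i] += lam
    return np.linalg.solve(A, b)


def small_regression(seed=0, n=30):
    rng = np.random.default_rng(seed)
    ref = TimeSeries(rng.standard_normal(n), 100.0, "EOG")
    target = TimeSeries(rng.standard_normal(n), 100.0, "EEG")
    return build_regressors(ref, 1), target


class TestFunctionalExpand:
    def test_zero_input(self):
        np.testing.assert_allclose(functional_expand(np.array([0.0]), 1), [0.0, 0.0, 1.0])

    def test_half_input(self):
        np.testing.assert_allclose(functional_expand(np.array([0.5]), 1),
                                   [0.5, 1.0, 0.0], atol=1e-15)

    def test_dimension_formula(self):
        z = functional_expand(np.zeros((4, 2)), 2)
        assert z.shape == (4, 2 * (1 + 2 * 2))

    def test_order_below_one_rejected(self):
        with pytest.raises(ValueError):
            functional_expand(np.zeros(2), 0)


class TestANFIS:
    def test_consequents_match_normal_equations_oracle(self):
        """With premises frozen (epochs make no accepted move when the
        loss is already at a stationary design), the consequent solve must
        equal the dense oracle on the same design matrix."""
        reg, target = small_regression(seed=1, n=30)
        cfg = TrainConfig(epochs=1, ridge_lambda=1e-6, seed=0)
        model = fit_anfis(reg, target, cfg)
        X = np.column_stack([
            apply_params(reg.rows[:, i], model.input_params[i]) for i in range(2)
        ])
        y = apply_params(target.samples, model.target_params)
        Phi = _anfis_design(X, model.mf_centers, model.mf_widths)
        theta = normal_equations_oracle(Phi, y, cfg.ridge_lambda)
        np.testing.assert_allclose(model.consequents.reshape(-1), theta, atol=1e-8)

    def test_zero_target_gives_zero_model(self):
        reg, _ = small_regression(seed=2, n=40)
        target = TimeSeries(np.zeros(40), 100.0)
        model = fit_anfis(reg, target, TrainConfig(epochs=2, ridge_lambda=1e-6))
        np.testing.assert_allclose(model.consequents, 0.0, atol=1e-12)
        est = predict(model, reg)
        np.testing.assert_allclose(est.samples, 0.0, atol=1e-12)

    def test_recovers_linear_function_of_inputs(self):
        """A target linear in [r(k), r(k-1)] is representable by the TS
        consequents, so training error collapses."""
        rng = np.random.default_rng(3)
        ref = TimeSeries(rng.standard_normal(400), 100.0)
        reg = build_regressors(ref, 1)
        y = 0.5 * reg.rows[:, 0] + 0.2 * reg.rows[:, 1]
        model = fit_anfis(reg, TimeSeries(y, 100.0), TrainConfig())
        resid = predict(model, reg).samples - y
        assert np.mean(resid**2) < 1e-6 * np.var(y)

    def test_training_mse_monotone_nonincreasing(self, nonlinear_scenario):
        sc = nonlinear_scenario
        reg = build_regressors(sc.reference_artifact, 1)
        model = fit_anfis(reg, sc.contaminated, TrainConfig(epochs=10))
        h = np.asarray(model.mse_history)
        assert np.all(np.diff(h) <= 1e-9)

    def test_underdetermined_without_ridge_rejected(self):
        reg, target = small_regression(seed=4, n=10)  # 10 samples < 27 params
        with pytest.raises(ValueError):
            fit_anfis(reg, target, TrainConfig(ridge_lambda=0.0))

    def test_too_few_mfs_rejected(self):
        reg, target = small_regression()
        with pytest.raises(ValueError):
            fit_anfis(reg, target, TrainConfig(), n_mfs_per_input=1)


class TestRBFN:
    def test_weights_match_normal_equations_oracle(self):
        reg, target = small_regression(seed=5, n=50)
        cfg = TrainConfig(ridge_lambda=1e-6, seed=0)
        model = fit_rbfn(reg, target, cfg, n_neurons=5)
        X = np.column_stack([
            apply_params(reg.rows[:, i], model.input_params[i]) for i in range(2)
        ])
        y = apply_params(target.samples, model.target_params)
        Phi = np.column_stack([
            _gaussian_activations(X, model.centers, model.widths), np.ones(50)
        ])
        theta = normal_equations_oracle(Phi, y, cfg.ridge_lambda)
        np.testing.assert_allclose(np.append(model.weights, model.bias), theta, atol=1e-8)

    def test_single_neuron_interpolates_constant_target(self):
        """One neuron on identical inputs with a constant target must
        reproduce that constant at the input point."""
        ref = TimeSeries(np.full(20, 2.0), 100.0)
        reg = build_regressors(ref, 0)
        target = TimeSeries(np.full(20, 7.0), 100.0)
        model = fit_rbfn(reg, target, TrainConfig(), n_neurons=1)
        est = predict(model, reg)
        np.testing.assert_allclose(est.samples, 7.0, atol=1e-4)

    def test_gaussian_activation_is_one_at_center(self):
        c = np.array([[0.3, -1.2]])
        for width in (1e-6, 0.5, 100.0):
            act = _gaussian_activations(c.copy(), c, np.array([width]))
            assert act[0, 0] == 1.0

    def test_needs_enough_samples(self):
        reg, target = small_regression(n=5)
        with pytest.raises(ValueError):
            fit_rbfn(reg, target, TrainConfig(), n_neurons=9)


class TestFLNRBFN:
    def test_first_novel_sample_allocates_one_neuron_with_error_weight(self):
        """On an empty model, the first sample with |error| above the
        novelty threshold allocates exactly one neuron whose weight is the
        error at that sample (pure sequential weights, no refit)."""
        ref = TimeSeries(np.array([1.0, 1.0, 1.0, 1.0]), 100.0)
        reg = build_regressors(ref, 0)
        target = TimeSeries(np.array([3.0, 3.0, 3.0, 3.0]), 100.0)
        # constant target standardizes to zeros -> craft a varying target
        target = TimeSeries(np.array([3.0, -1.0, 3.0, -1.0]), 100.0)
        growth = GrowthParams(novelty_distance=0.7, novelty_error=0.05, max_neurons=50)
        model = fit_fln_rbfn(reg, target, TrainConfig(epochs=1, learning_rate=1e-9),
                             growth=growth, refit=False)
        # inputs are all identical: only the very first sample is novel
        assert model.n_neurons == 1
        y0 = apply_params(np.array([3.0]), model.target_params)[0]
        assert model.weights[0] == pytest.approx(y0)

    def test_duplicate_sample_never_allocates_again(self):
        ref = TimeSeries(np.ones(50), 100.0)
        reg = build_regressors(ref, 0)
        rng = np.random.default_rng(0)
        target = TimeSeries(rng.standard_normal(50), 100.0)
        model = fit_fln_rbfn(reg, target, TrainConfig(epochs=3), refit=False)
        assert model.n_neurons == 1  # delta = 0 <= epsilon for every later sample

    def test_neuron_count_monotone_and_capped(self, nonlinear_scenario):
        sc = nonlinear_scenario
        reg = build_regressors(sc.reference_artifact, 1)
        growth = GrowthParams(max_neurons=6)
        model = fit_fln_rbfn(reg, sc.contaminated, TrainConfig(epochs=2), growth=growth)
        hist = np.asarray(model.neuron_history)
        assert np.all(np.diff(hist) >= 0)
        assert 1 <= model.n_neurons <= growth.max_neurons

    def test_growth_beats_one_neuron_ablation(self, nonlinear_scenario):
        sc = nonlinear_scenario
        reg = build_regressors(sc.reference_artifact, 1)
        full = fit_fln_rbfn(reg, sc.contaminated, TrainConfig(epochs=2))
        tiny = fit_fln_rbfn(reg, sc.contaminated, TrainConfig(epochs=2),
                            growth=GrowthParams(max_neurons=1))
        assert full.n_neurons > 1
        assert full.mse_history[-1] < tiny.mse_history[-1]

    def test_invalid_growth_params_rejected(self):
        with pytest.raises(ValueError):
            GrowthParams(novelty_distance=0.0)
        with pytest.raises(ValueError):
            GrowthParams(max_neurons=0)


class TestPredictAndCancel:
    def test_zeroed_weights_give_zero_estimate(self):
        reg, target = small_regression(seed=6, n=40)
        model = fit_rbfn(reg, target, TrainConfig(), n_neurons=3)
        model.weights = np.zeros_like(model.weights)
        model.bias = 0.0
        model.target_params = af.StandardizationParams(mean=0.0, scale=1.0)
        np.testing.assert_array_equal(predict(model, reg).samples, 0.0)

    def test_prediction_reproduces_cached_training_fit(self, nonlinear_scenario):
        """predict() on the training inputs must reproduce the fitted
        values cached at the end of training, bit-identically."""
        sc = nonlinear_scenario
        reg = build_regressors(sc.reference_artifact, 1)
        cfg = TrainConfig(epochs=3)
        for fit in (fit_anfis, fit_rbfn, fit_fln_rbfn):
            model = fit(reg, sc.contaminated, cfg)
            np.testing.assert_array_equal(
                predict(model, reg).samples, model.training_prediction)

    def test_dimension_mismatch_rejected(self):
        reg, target = small_regression(seed=7, n=30)
        model = fit_rbfn(reg, target, TrainConfig(), n_neurons=3)
        bad = af.RegressorMatrix(rows=np.zeros((5, 3)), delay_d=1, n_inputs=3)
        with pytest.raises(ValueError):
            predict(model, bad)

    def test_cancel_identity_annihilation_and_conservation(self, random_series):
        zeros = random_series.with_samples(np.zeros(len(random_series)))
        np.testing.assert_array_equal(
            cancel(random_series, zeros).samples, random_series.samples)
        np.testing.assert_array_equal(
            cancel(random_series, random_series).samples, 0.0)
        with pytest.raises(ValueError):
            cancel(random_series, TimeSeries(np.zeros(3), 256.0))

    def test_cancel_recovers_clean_on_perfect_estimate(self, linear_blink_scenario):
        sc = linear_blink_scenario
        cleaned = cancel(sc.contaminated, sc.true_contribution)
        # exact up to one rounding of the construction sum
        np.testing.assert_allclose(cleaned.samples, sc.clean_eeg.samples,
                                   rtol=0, atol=1e-10)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_conservation_bit_exact_property(self, seed):
        """cleaned + estimate == contaminated bit-exactly for arbitrary
        estimate signals."""
        rng = np.random.default_rng(seed)
        contaminated = TimeSeries(rng.standard_normal(64) * 100, 256.0)
        estimate = TimeSeries(rng.standard_normal(64) * 10, 256.0)
        cleaned = cancel(contaminated, estimate)
        np.testing.assert_array_equal(cleaned.samples,
                                      contaminated.samples - estimate.samples)


class TestDeterminismAndSerialization:
    @pytest.mark.parametrize("fit", [fit_anfis, fit_rbfn, fit_fln_rbfn])
    def test_identical_config_gives_bit_identical_models(self, fit, nonlinear_scenario):
        sc = nonlinear_scenario
        reg = build_regressors(sc.reference_artifact, 1)
        cfg = TrainConfig(epochs=2, seed=42)
        a = fit(reg, sc.contaminated, cfg)
        b = fit(reg, sc.contaminated, cfg)
        assert model_to_dict(a) == model_to_dict(b)

    @pytest.mark.parametrize("fit", [fit_anfis, fit_rbfn, fit_fln_rbfn])
    def test_json_roundtrip_predictions_bit_identical(self, fit, tmp_path,
                                                      nonlinear_scenario):
        sc = nonlinear_scenario
        reg = build_regressors(sc.reference_artifact, 1)
        model = fit(reg, sc.contaminated, TrainConfig(epochs=2))
        path = tmp_path / "model.json"
        save_model(model, path)
        restored = load_model(path)
        np.testing.assert_array_equal(predict(model, reg).samples,
                                      predict(restored, reg).samples)

    def test_roundtrip_dict_identity(self, nonlinear_scenario):
        sc = nonlinear_scenario
        reg = build_regressors(sc.reference_artifact, 1)
        model = fit_rbfn(reg, sc.contaminated, TrainConfig(), n_neurons=4)
        assert model_to_dict(model_from_dict(model_to_dict(model))) == model_to_dict(model)


class TestLinearRecovery:
    @pytest.mark.parametrize("fit", [fit_anfis, fit_rbfn, fit_fln_rbfn])
    def test_linear_pathway_estimate_close_to_truth(self, fit, linear_blink_scenario):
        """On the identity-pathway scenario every filter's artifact
        estimate lands within a few percent of the true contribution."""
        sc = linear_blink_scenario
        reg = build_regressors(sc.reference_artifact, 1)
        model = fit(reg, sc.contaminated, TrainConfig(seed=0))
        est = predict(model, reg, sc.contaminated.sampling_rate_hz)
        rel = np.mean((est.samples - sc.true_contribution.samples) ** 2) \
            / np.var(sc.true_contribution.samples)
        assert rel <= 0.05
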