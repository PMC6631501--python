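"""Perceptron surrogate: forward pass, backprop, training, early stopping."""

import warnings

import numpy as np
import pytest

import rsmann as rm
from rsmann.mlp import (
    ExtrapolationWarning,
    MLPSurrogate,
    SplitSpec,
    _forward,
    _init_weights,
    _mse_and_grad,
)


def _random_model(rng, k=4, h=6):
    return MLPSurrogate(
        n_inputs=k, n_hidden=h, theta=_init_weights(rng, k, h),
        x_min=np.zeros(k), x_max=np.ones(k), y_min=0.0, y_max=1.0,
    )


def test_zero_weights_give_constant_output_bias():
    k, h = 4, 10
    theta = np.zeros(k * h + 2 * h + 1)
    theta[-1] = 0.37  # output bias
    m = MLPSurrogate(
        n_inputs=k, n_hidden=h, theta=theta,
        x_min=np.zeros(k), x_max=np.ones(k), y_min=-1.0, y_max=1.0,
    )
    x = np.random.default_rng(0).uniform(0, 1, size=(8, k))
    np.testing.assert_allclose(m.predict(x), 0.37)


def test_tanh_oddness_with_zero_biases(rng):
    k, h = 3, 5
    W1 = rng.normal(size=(h, k))
    w2 = rng.normal(size=h)
    theta = np.concatenate([W1.ravel(), np.zeros(h), w2, [0.0]])
    z = rng.uniform(-1, 1, size=(6, k))
    out_pos = _forward(theta, z, h)
    out_neg = _forward(theta, -z, h)
    np.testing.assert_allclose(out_neg, -out_pos, atol=1e-12)


def test_batch_prediction_equals_elementwise(rng):
    m = _random_model(rng)
    x = rng.uniform(0, 1, size=(7, 4))
    batch = m.predict(x)
    singles = [m.predict(row) for row in x]
    np.testing.assert_allclose(batch, singles)


def test_extrapolation_warns(rng):
    m = _random_model(rng)
    with pytest.warns(ExtrapolationWarning):
        m.predict(np.full(4, 2.5))
    with warnings.catch_warnings():
        warnings.simplefilter("error")
        m.predict(np.full(4, 0.5))  # inside bounds: no warning


class TestGradient:
    def test_analytic_gradient_matches_finite_differences(self, rng):
        m = _random_model(rng)
        x = rng.uniform(0, 1, size=(12, 4))
        y = rng.uniform(0, 1, size=12)
        assert rm.gradient_check(m, x, y) < 1e-6

    def test_zero_residual_gives_zero_gradient(self, rng):
        m = _random_model(rng)
        x = rng.uniform(0, 1, size=(9, 4))
        targets = m.predict(x)  # targets equal outputs exactly
        Z = m.normalize_x(x)
        t = m.normalize_y(targets)
        _, g = _mse_and_grad(m.theta, Z, t, m.n_hidden)
        np.testing.assert_allclose(g, 0.0, atol=1e-12)

    def test_sign_bug_detected_by_finite_difference_oracle(self, rng):
        """Negative control: corrupting one gradient component must blow up
        the comparison that the real gradient passes."""
        m = _random_model(rng)
        x = rng.uniform(0, 1, size=(12, 4))
        y = rng.uniform(0, 1, size=12)
        Z, t = m.normalize_x(x), m.normalize_y(y)
        _, g = _mse_and_grad(m.theta, Z, t, m.n_hidden)

        eps = 1e-5
        num = np.empty_like(g)
        for i in range(len(g)):
            tp, tm = m.theta.copy(), m.theta.copy()
            tp[i] += eps
            tm[i] -= eps
            num[i] = (
                _mse_and_grad(tp, Z, t, m.n_hidden)[0]
                - _mse_and_grad(tm, Z, t, m.n_hidden)[0]
            ) / (2 * eps)
        rel = lambda a, b: np.max(np.abs(a - b) / np.maximum(np.abs(a) + np.abs(b), 1e-8))
        assert rel(g, num) < 1e-6
        buggy = g.copy()
        buggy[0] = -buggy[0] if abs(buggy[0]) > 1e-6 else buggy[0] + 1.0
        assert rel(buggy, num) > 1e-2


class TestTraining:
    def test_deterministic_given_seed(self, ccrd_data):
        a = rm.train_mlp(ccrd_data, restarts=4, seed=9)
        b = rm.train_mlp(ccrd_data, restarts=4, seed=9)
        assert np.array_equal(a.theta, b.theta)
        np.testing.assert_array_equal(
            a.predict(ccrd_data.design.actual), b.predict(ccrd_data.design.actual)
        )

    def test_noise_free_smooth_surface_learned(self, factors):
        """On exact quadratic-surface data the trainer drives normalized
        training MSE below 1e-3."""
        syn = rm.generate_synthetic(rm.SyntheticSpec(noise_sd=0.0))
        ann = rm.train_mlp(syn, restarts=8, seed=1)
        t = ann.normalize_y(syn.response)
        Z = ann.normalize_x(syn.design.actual)
        mse = float(np.mean((_forward(ann.theta, Z, ann.n_hidden) - t) ** 2))
        assert mse < 1e-3

    def test_early_stopping_returns_best_validation_epoch(self, ccrd_data):
        ann = rm.train_mlp(ccrd_data, restarts=6, seed=2)
        trace = ann.trace[ann.trace["restart"] == ann.restart_index]
        assert ann.best_val_mse <= trace["val_mse"].min() + 1e-15
        # selected restart has the lowest best-epoch validation MSE overall
        per_restart = ann.trace.groupby("restart")["val_mse"].min()
        assert ann.best_val_mse <= per_restart.min() + 1e-15

    def test_split_assignment_partitions_all_runs(self):
        labels = SplitSpec(seed=3).assign(27)
        counts = {lab: int((labels == lab).sum()) for lab in
                  ("train", "validation", "test")}
        assert sum(counts.values()) == 27
        assert counts["train"] == 19 and counts["validation"] == 4

    def test_invalid_split_fractions_rejected(self):
        with pytest.raises(ValueError):
            SplitSpec(train=0.5, validation=0.2, test=0.2)

    def test_overparameterized_net_outfits_quadratic_truth(self, factors):
        """With replicate-scale noise the network (which can interpolate)
        reaches a higher in-sample R² than the generating quadratic itself,
        reproducing the observed quadratic < network fit ordering."""
        syn = rm.generate_synthetic(
            rm.SyntheticSpec(noise_sd=rm.NOISE_SD_PURE_ERROR, seed=4)
        )
        ann = rm.train_mlp(syn, restarts=8, seed=4)
        truth = rm.fit_quadratic(syn)
        r2_ann = rm.compute_metrics(syn.response, ann.predict(syn.design.actual)).r_squared
        r2_rsm = rm.compute_metrics(syn.response, truth.predict(syn.design.actual)).r_squared
        assert r2_ann > r2_rsm

    def test_serialization_round_trip(self, ccrd_data):
        ann = rm.train_mlp(ccrd_data, restarts=3, seed=5)
        clone = MLPSurrogate.from_json(ann.to_json())
        x = ccrd_data.design.actual
        np.testing.assert_allclose(clone.predict(x), ann.predict(x), rtol=1e-12)

    def test_too_few_runs_rejected(self, factors):
        design = rm.build_ccrd(factors[:2], n_center=1)
        data = rm.ExperimentTable(design=design, response=np.ones(design.n_runs))
        with pytest.raises(ValueError):
            rm.train_mlp(data, restarts=1)
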