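"""Architecture forward passes, joint loss, and analytic gradients."""

import numpy as np
import pytest

from pdsp.model import (
    ArchitectureConfig,
    Batch,
    LossConfig,
    ModelParameters,
    den_forward,
    ddn_forward,
    loss_and_grads,
    predict,
    regression_loss,
    san_forward,
    sensitivity_loss_and_grads,
    total_loss,
    weighted_bce,
)
from pdsp.records import ValidationError


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def _set_layers(layers, values):
    for layer, (W, b) in zip(layers, values):
        layer.W[...] = W
        layer.b[...] = b


class TestForwardPasses:
    def test_zero_parameters_give_zero_latent(self, tiny_arch):
        params = ModelParameters.zeros(tiny_arch)
        h = den_forward(np.ones(2), np.ones(2), params)
        np.testing.assert_array_equal(h, np.zeros(2))

    def test_eval_mode_is_deterministic(self, tiny_params, rng):
        d, c = rng.normal(size=2), rng.normal(size=2)
        h1 = den_forward(d, c, tiny_params)
        h2 = den_forward(d, c, tiny_params)
        np.testing.assert_array_equal(h1, h2)

    def test_den_matches_hand_computed_relu_chain(self, tiny_arch):
        params = ModelParameters.zeros(tiny_arch)
        W0 = np.arange(12).reshape(4, 3) / 10.0 - 0.5
        b0 = np.array([0.1, -0.2, 0.3])
        W1 = np.arange(6).reshape(3, 2) / 5.0 - 0.4
        b1 = np.array([-0.1, 0.2])
        _set_layers(params.den, [(W0, b0), (W1, b1)])
        d, c = np.array([1.0, -2.0]), np.array([0.5, 3.0])
        # independent manual arithmetic
        x = np.array([1.0, -2.0, 0.5, 3.0])
        expected = np.maximum(x @ W0 + b0, 0.0) @ W1 + b1
        np.testing.assert_allclose(den_forward(d, c, params), expected, rtol=1e-12)

    def test_ddn_matches_hand_computed_logit(self, tiny_arch):
        params = ModelParameters.zeros(tiny_arch)
        W0 = np.array([[0.5, -1.0], [2.0, 0.25]])
        b0 = np.array([0.0, 0.1])
        W1 = np.array([[1.5], [-0.5]])
        b1 = np.array([0.2])
        _set_layers(params.ddn, [(W0, b0), (W1, b1)])
        h = np.array([1.0, -1.0])
        expected = (np.maximum(h @ W0 + b0, 0.0) @ W1 + b1).item()
        assert ddn_forward(h, params) == pytest.approx(expected, rel=1e-12)

    def test_san_matches_hand_computed_scalar(self, tiny_arch):
        params = ModelParameters.zeros(tiny_arch)
        W0 = np.arange(12).reshape(4, 3) / 6.0 - 0.8
        b0 = np.zeros(3)
        W1 = np.array([[1.0], [-1.0], [0.5]])
        b1 = np.array([0.3])
        _set_layers(params.san, [(W0, b0), (W1, b1)])
        h1, h2 = np.array([1.0, 0.0]), np.array([0.0, 1.0])
        x = np.concatenate([h1, h2])
        expected = (np.maximum(x @ W0 + b0, 0.0) @ W1 + b1).item()
        assert san_forward(h1, h2, params) == pytest.approx(expected, rel=1e-12)

    def test_san_is_order_dependent_for_generic_weights(self, tiny_params, rng):
        h1, h2 = rng.normal(size=2), rng.normal(size=2)
        assert san_forward(h1, h2, tiny_params) != san_forward(h2, h1, tiny_params)

    def test_dim_mismatch_rejected(self, tiny_params):
        with pytest.raises(ValidationError):
            den_forward(np.ones(3), np.ones(2), tiny_params)
        with pytest.raises(ValidationError):
            san_forward(np.ones(2), np.ones(3), tiny_params)


class TestPredict:
    def test_symmetrized_prediction_is_exactly_order_invariant(self, tiny_params, rng):
        for _ in range(100):
            d_i, d_j, c = rng.normal(size=2), rng.normal(size=2), rng.normal(size=2)
            ij = predict(d_i, d_j, c, tiny_params)
            ji = predict(d_j, d_i, c, tiny_params)
            assert float(ij.y_hat) == float(ji.y_hat)  # bitwise
            assert float(ij.s_hat_i) == float(ji.s_hat_j)
            assert float(ij.s_hat_j) == float(ji.s_hat_i)

    def test_identical_drugs_share_sensitivity(self, tiny_params, rng):
        d, c = rng.normal(size=2), rng.normal(size=2)
        res = predict(d, d.copy(), c, tiny_params)
        assert float(res.s_hat_i) == float(res.s_hat_j)

    def test_zero_parameter_model(self, tiny_arch):
        params = ModelParameters.zeros(tiny_arch)
        res = predict(np.ones(2), -np.ones(2), np.ones(2), params)
        assert float(res.y_hat) == 0.0
        assert float(res.s_hat_i) == float(res.s_hat_j) == 0.5


class TestWeightSharing:
    def test_single_encoder_storage(self, tiny_params):
        parts = tiny_params.parts()
        # there is exactly one den/ddn stack; mutating it moves both positions
        assert tiny_params.den is parts["den"]
        before = predict(np.ones(2), np.zeros(2), np.ones(2), tiny_params)
        tiny_params.den[0].W += 0.5
        after = predict(np.ones(2), np.zeros(2), np.ones(2), tiny_params)
        assert float(before.y_hat) != float(after.y_hat)
        # the swapped call sees the identical mutation
        swapped = predict(np.zeros(2), np.ones(2), np.ones(2), tiny_params)
        assert float(after.y_hat) == float(swapped.y_hat)


class TestLosses:
    def test_regression_loss_examples(self):
        assert regression_loss([1.0, 2.0], [1.0, 2.0]) == 0.0
        assert regression_loss([0.0, 2.0], [1.0, 1.0]) == 1.0
        assert regression_loss([3.0], [1.0]) == 4.0

    def test_regression_loss_validates(self):
        with pytest.raises(ValidationError):
            regression_loss([1.0], [1.0, 2.0])
        with pytest.raises(ValidationError):
            regression_loss([], [])

    def test_weighted_bce_closed_forms(self):
        assert weighted_bce([1.0], [0.5], 1.0, 1.0) == pytest.approx(np.log(2), rel=1e-9)
        base = weighted_bce([1.0, 1.0], [0.3, 0.8], 1.0, 1.0)
        assert weighted_bce([1.0, 1.0], [0.3, 0.8], 2.0, 1.0) == pytest.approx(2 * base)
        assert weighted_bce([1.0], [1.0 - 1e-9], 1.0, 1.0) < 1e-6

    def test_weighted_bce_rejects_bad_probs(self):
        with pytest.raises(ValidationError):
            weighted_bce([1.0], [1.2], 1.0, 1.0)

    def test_lambda_arithmetic(self, tiny_arch):
        # L = Lreg + lambda * Lcls with hand-chosen pieces: 1.0 + 10 * 0.5 = 6.0
        assert 1.0 + LossConfig().lambda_task * 0.5 == 6.0

    def test_all_masked_sensitivity_reduces_to_regression(self, tiny_params, rng):
        n = 4
        batch = Batch(
            d_i=rng.normal(size=(n, 2)), d_j=rng.normal(size=(n, 2)),
            c=rng.normal(size=(n, 2)), y=rng.normal(size=n),
            s_i=np.zeros(n), m_i=np.zeros(n, bool),
            s_j=np.zeros(n), m_j=np.zeros(n, bool),
        )
        loss = total_loss(batch, tiny_params, LossConfig(lambda_sensitive=1, lambda_resistant=1))
        res = predict(batch.d_i, batch.d_j, batch.c, tiny_params)
        # unsymmetrized forward: recompute the ordered SAN output
        h_i = den_forward(batch.d_i, batch.c, tiny_params)
        h_j = den_forward(batch.d_j, batch.c, tiny_params)
        y_hat = san_forward(h_i, h_j, tiny_params)
        assert loss == pytest.approx(float(np.mean((batch.y - y_hat) ** 2)), rel=1e-12)

    def test_total_loss_matches_scalar_loop_oracle(self, tiny_arch, rng):
        cfg = LossConfig(lambda_task=10.0, lambda_sensitive=1.3, lambda_resistant=0.7)
        for trial in range(200):
            params = ModelParameters.initialize(tiny_arch, seed=trial)
            n = int(rng.integers(1, 6))
            batch = Batch(
                d_i=rng.normal(size=(n, 2)), d_j=rng.normal(size=(n, 2)),
                c=rng.normal(size=(n, 2)), y=rng.normal(size=n),
                s_i=rng.integers(0, 2, n).astype(float), m_i=rng.random(n) < 0.7,
                s_j=rng.integers(0, 2, n).astype(float), m_j=rng.random(n) < 0.7,
            )
            got = total_loss(batch, params, cfg)

            # independent element-by-element recomputation
            sq, bce_i, bce_j = [], [], []
            for k in range(n):
                h_i = den_forward(batch.d_i[k], batch.c[k], params)
                h_j = den_forward(batch.d_j[k], batch.c[k], params)
                sq.append((batch.y[k] - san_forward(h_i, h_j, params)) ** 2)
                for logits, s, m, acc in (
                    (ddn_forward(h_i, params), batch.s_i[k], batch.m_i[k], bce_i),
                    (ddn_forward(h_j, params), batch.s_j[k], batch.m_j[k], bce_j),
                ):
                    if m:
                        p = min(max(_sigmoid(logits), 1e-7), 1 - 1e-7)
                        acc.append(
                            -(cfg.lambda_sensitive * s * np.log(p)
                              + cfg.lambda_resistant * (1 - s) * np.log(1 - p))
                        )
            expected = float(np.mean(sq))
            for acc in (bce_i, bce_j):
                if acc:
                    expected += cfg.lambda_task * float(np.mean(acc))
            assert got == pytest.approx(expected, rel=1e-6)

    def test_empty_batch_rejected(self, tiny_params):
        empty = Batch(*(np.empty((0, 2)),) * 3, *(np.empty(0),) * 5)
        with pytest.raises(ValidationError):
            total_loss(empty, tiny_params, LossConfig())


def _flatten(params_like):
    out = []
    for name in ("den", "ddn", "san"):
        for layer in params_like[name] if isinstance(params_like, dict) else getattr(params_like, name):
            out.extend([layer.W, layer.b])
    return out


class TestGradients:
    def _tiny(self):
        arch = ArchitectureConfig(
            d_drug=2, d_expr=2, latent_dim=2,
            den_hidden=(2,), ddn_hidden=(2,), san_hidden=(2,), dropout_rate=0.0,
        )
        params = ModelParameters.initialize(arch, seed=1)
        # jitter every parameter (incl. zero-initialized biases) so no
        # pre-activation sits exactly on the ReLU kink, where a central
        # finite difference disagrees with the subgradient
        jrng = np.random.default_rng(42)
        for arr in params.flat_arrays():
            arr += jrng.normal(0.0, 0.3, size=arr.shape)
        return arch, params

    def test_joint_loss_gradient_matches_finite_differences(self, rng):
        arch, params = self._tiny()
        cfg = LossConfig(lambda_task=10.0, lambda_sensitive=1.2, lambda_resistant=0.8)
        n = 3
        batch = Batch(
            d_i=rng.normal(size=(n, 2)), d_j=rng.normal(size=(n, 2)),
            c=rng.normal(size=(n, 2)), y=rng.normal(size=n),
            s_i=rng.integers(0, 2, n).astype(float), m_i=np.array([True, True, False]),
            s_j=rng.integers(0, 2, n).astype(float), m_j=np.array([True, False, True]),
        )
        _, grads = loss_and_grads(batch, params, cfg, mode="eval")
        eps = 1e-6
        for arr, g in zip(_flatten(params), _flatten(grads)):
            flat, gflat = arr.ravel(), g.ravel()
            for idx in range(flat.size):
                orig = flat[idx]
                flat[idx] = orig + eps
                up = total_loss(batch, params, cfg)
                flat[idx] = orig - eps
                dn = total_loss(batch, params, cfg)
                flat[idx] = orig
                fd = (up - dn) / (2 * eps)
                assert gflat[idx] == pytest.approx(fd, rel=1e-4, abs=1e-7)

    def test_sensitivity_loss_gradient_matches_finite_differences(self, rng):
        arch, params = self._tiny()
        cfg = LossConfig(lambda_sensitive=1.0, lambda_resistant=1.0)
        d, c = rng.normal(size=(4, 2)), rng.normal(size=(4, 2))
        labels = rng.integers(0, 2, 4).astype(float)
        _, grads = sensitivity_loss_and_grads(d, c, labels, params, cfg, mode="eval")
        eps = 1e-6
        for name in ("den", "ddn"):
            for layer, glayer in zip(getattr(params, name), grads[name]):
                flat, gflat = layer.W.ravel(), glayer.W.ravel()
                for idx in range(flat.size):
                    orig = flat[idx]
                    flat[idx] = orig + eps
                    up, _ = sensitivity_loss_and_grads(d, c, labels, params, cfg, mode="eval")
                    flat[idx] = orig - eps
                    dn, _ = sensitivity_loss_and_grads(d, c, labels, params, cfg, mode="eval")
                    flat[idx] = orig
                    assert gflat[idx] == pytest.approx((up - dn) / (2 * eps), rel=1e-4, abs=1e-7)


class TestLossConfigResolution:
    def test_inverse_frequency_weights_mean_one(self):
        labels = np.array([1, 1, 1, 0])  # 75% positive
        cfg = LossConfig().resolved(labels)
        w1, w0 = cfg.lambda_sensitive, cfg.lambda_resistant
        assert (w1 + w0) / 2 == pytest.approx(1.0)
        assert w0 / w1 == pytest.approx(3.0)  # rarer class weighted up

    def test_explicit_weights_pass_through(self):
        cfg = LossConfig(lambda_sensitive=2.0, lambda_resistant=0.5).resolved([1, 0])
        assert (cfg.lambda_sensitive, cfg.lambda_resistant) == (2.0, 0.5)
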