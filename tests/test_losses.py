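"""Loss algebra: worked examples in double precision, and gradient sanity."""

import numpy as np
import pytest

from destripenet._nn import CorrectionNet
from destripenet.haar_wavelet import WaveletCoefficients
from destripenet.losses import (LossConfig, mse, regular_loss, total_loss,
                                total_loss_and_grad, wavelet_loss,
                                calibrate_lambda)


def _coeffs(*bands):
    return WaveletCoefficients(*[np.asarray(b, dtype=float) for b in bands])


class TestMSE:
    def test_identical_is_zero(self, rng):
        x = rng.normal(size=(5, 7))
        assert mse(x, x) == 0.0

    def test_hand_computed_half(self):
        assert mse(np.array([[0.0, 0.0], [1.0, 1.0]]), np.zeros((2, 2))) == 0.5

    def test_symmetry(self, rng):
        a, b = rng.normal(size=(2, 4, 4))
        assert mse(a, b) == mse(b, a)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mse(np.zeros((2, 2)), np.zeros((2, 3)))


class TestWaveletLoss:
    def test_equal_prediction_is_zero(self, rng):
        c = _coeffs(*rng.normal(size=(4, 3, 3)))
        assert wavelet_loss(c, c) == 0.0

    def test_single_band_difference(self, rng):
        label = _coeffs(*rng.normal(size=(4, 4, 4)))
        pred = _coeffs(label.wa + 0.5, label.wh, label.wv, label.wd)
        assert wavelet_loss(pred, label) == pytest.approx(0.25, abs=1e-14)

    def test_prescribed_per_band_mses_sum_to_one(self):
        """Bands constructed with per-band MSE 0.1/0.2/0.3/0.4 -> L_M = 1.0."""
        zeros = np.zeros((2, 2))
        label = _coeffs(zeros, zeros, zeros, zeros)
        pred = _coeffs(*(np.full((2, 2), np.sqrt(m)) for m in (0.1, 0.2, 0.3, 0.4)))
        assert wavelet_loss(pred, label) == pytest.approx(1.0, abs=1e-14)


class TestRegularLoss:
    def test_axis_constant_estimate_is_zero(self):
        """Ideal full-length stripes are constant along the stripe direction."""
        col = np.tile(np.arange(5.0), (6, 1))  # constant down each column
        pred = _coeffs(col, 2 * col, col, col)
        assert regular_loss(pred, LossConfig()) == 0.0

    def test_zero_estimate_is_zero(self):
        pred = _coeffs(*(np.zeros((4, 4)),) * 4)
        assert regular_loss(pred) == 0.0

    def test_unit_step_in_one_column(self):
        """Single unit step along the stripe axis -> 1 / ((m-1) * n)."""
        m, n = 6, 5
        wa = np.zeros((m, n))
        wa[3:, 2] = 1.0  # one step of height 1 in one column
        pred = _coeffs(wa, np.zeros((m, n)), np.zeros((m, n)), np.zeros((m, n)))
        assert regular_loss(pred) == pytest.approx(1.0 / ((m - 1) * n), abs=1e-15)

    def test_l1_norm_option(self):
        m, n = 4, 3
        wa = np.zeros((m, n))
        wa[2:, 0] = 2.0
        pred = _coeffs(wa, np.zeros((m, n)), np.zeros((m, n)), np.zeros((m, n)))
        assert regular_loss(pred, LossConfig(smoothness_norm="l1")) == \
            pytest.approx(2.0 / ((m - 1) * n), abs=1e-15)

    def test_only_selected_bands_contribute(self, rng):
        rough = rng.normal(size=(6, 6))
        pred = _coeffs(np.zeros((6, 6)), np.zeros((6, 6)), rough, rough)
        assert regular_loss(pred, LossConfig(smooth_bands=("wa", "wh"))) == 0.0
        assert regular_loss(pred, LossConfig(smooth_bands=("wv", "wd"))) > 0.0


class TestTotalLoss:
    def test_lambda_zero_equals_wavelet_loss(self, rng):
        pred = _coeffs(*rng.normal(size=(4, 5, 5)))
        label = _coeffs(*rng.normal(size=(4, 5, 5)))
        cfg = LossConfig(lambda_reg=0.0)
        assert total_loss(pred, label, cfg) == wavelet_loss(pred, label)

    def test_affine_in_lambda(self, rng):
        pred = _coeffs(*rng.normal(size=(4, 5, 5)))
        label = _coeffs(*rng.normal(size=(4, 5, 5)))
        l0 = total_loss(pred, label, LossConfig(lambda_reg=0.0))
        l2 = total_loss(pred, label, LossConfig(lambda_reg=2.0))
        assert l2 - l0 == pytest.approx(2.0 * regular_loss(pred), rel=1e-12)

    def test_combined_worked_example(self):
        """L_M = 1.0 construction plus regular_loss = 0.5 and lambda = 0.1 -> 1.05."""
        m, n = 2, 2
        zeros = np.zeros((m, n))
        label = _coeffs(zeros, zeros, zeros, zeros)
        pred_bands = [np.full((m, n), np.sqrt(v)) for v in (0.1, 0.2, 0.3, 0.4)]
        # give WA a step that makes L_W = 0.5 without changing its MSE:
        # elements (+-sqrt(0.1)) have mse 0.1; one column's worth of steps
        wa = np.array([[np.sqrt(0.1), np.sqrt(0.1)],
                       [-np.sqrt(0.1), -np.sqrt(0.1)]])
        pred = _coeffs(wa, *pred_bands[1:])
        lw = regular_loss(pred, LossConfig())
        lm = wavelet_loss(pred, label)
        cfg = LossConfig(lambda_reg=0.1)
        assert lm == pytest.approx(1.0, abs=1e-14)
        assert total_loss(pred, label, cfg) == pytest.approx(1.0 + 0.1 * lw, abs=1e-14)

    def test_nonnegative_for_random_inputs(self, rng):
        for _ in range(20):
            pred = _coeffs(*rng.normal(size=(4, 3, 4)))
            label = _coeffs(*rng.normal(size=(4, 3, 4)))
            for cfg in (LossConfig(), LossConfig(smoothness_norm="l1"),
                        LossConfig(lambda_reg=5.0)):
                assert total_loss(pred, label, cfg) >= 0.0
                assert wavelet_loss(pred, label) >= 0.0
                assert regular_loss(pred, cfg) >= 0.0


class TestGradients:
    def test_stack_loss_matches_scalar_api(self, rng):
        pred = rng.normal(size=(4, 6, 5))
        label = rng.normal(size=(4, 6, 5))
        cfg = LossConfig(lambda_reg=0.3)
        val, _ = total_loss_and_grad(pred, label, cfg)
        ref = total_loss(WaveletCoefficients.from_stack(pred),
                         WaveletCoefficients.from_stack(label), cfg)
        assert val == pytest.approx(ref, rel=1e-12)

    def test_training_gradient_matches_finite_differences(self):
        """Analytic parameter gradient vs central differences, double precision."""
        rng = np.random.default_rng(0)
        net = CorrectionNet(4, 6, 4, 1, rng).astype(np.float64)
        x = rng.normal(size=(2, 4, 6, 5))
        label = rng.normal(size=(2, 4, 6, 5))
        cfg = LossConfig(lambda_reg=0.3)

        net.zero_grad()
        out = net.forward(x, keep=True)
        _, dy = total_loss_and_grad(out, label, cfg)
        net.backward(dy)

        eps = 1e-6
        for obj, name, gname in net.params()[:4]:
            w, g = getattr(obj, name), getattr(obj, gname)
            flat_idx = rng.choice(w.size, size=min(4, w.size), replace=False)
            for fi in flat_idx:
                idx = np.unravel_index(fi, w.shape)
                orig = w[idx]
                w[idx] = orig + eps
                lp, _ = total_loss_and_grad(net.forward(x, keep=False), label, cfg)
                w[idx] = orig - eps
                lm, _ = total_loss_and_grad(net.forward(x, keep=False), label, cfg)
                w[idx] = orig
                numeric = (lp - lm) / (2 * eps)
                denom = max(1e-8, abs(numeric) + abs(g[idx]))
                assert abs(numeric - g[idx]) / denom < 1e-4


def test_calibrate_lambda_balances_terms(rng):
    preds = [_coeffs(*rng.normal(size=(4, 6, 6))) for _ in range(3)]
    labels = [_coeffs(*rng.normal(size=(4, 6, 6))) for _ in range(3)]
    lam = calibrate_lambda(preds, labels, LossConfig())
    lm = np.mean([wavelet_loss(p, l) for p, l in zip(preds, labels)])
    lw = np.mean([regular_loss(p) for p in preds])
    assert lam == pytest.approx(lm / lw, rel=1e-12)
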