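"""Loss oracles: SSIM against a direct-from-definition computation, BCE and
regression losses against closed forms."""

import numpy as np
import pytest

from fegnet.autograd import Tensor
from fegnet.losses import (LossConfig, SSIMConfig, alt_density_loss, bce_loss,
                           ssim_loss, total_loss)
from fegnet.network import ForwardOutput


def reference_ssim_mean(pred: np.ndarray, gt: np.ndarray, cfg: SSIMConfig) -> float:
    """Independent windowed SSIM: explicit per-window L*C*S with loops.

    Same conventions as the implementation under test (gaussian window,
    reflection padding, c1=(0.01R)^2, c2=(0.03R)^2, c3=c2/2, weighted local
    moments) but computed position by position from the definition.
    """
    k = cfg.window_side
    half = k // 2
    ax = np.arange(k) - half
    g = np.exp(-(ax ** 2) / (2.0 * cfg.sigma ** 2))
    win = np.outer(g, g)
    win /= win.sum()

    r = float(gt.max()) if cfg.data_range == "auto" else float(cfg.data_range)
    r = max(r, 1e-12)
    c1, c2 = (0.01 * r) ** 2, (0.03 * r) ** 2
    c3 = c2 / 2.0

    xp = np.pad(pred.astype(np.float64), half, mode="reflect")
    yp = np.pad(gt.astype(np.float64), half, mode="reflect")
    h, w = pred.shape
    vals = np.empty((h, w))
    for i in range(h):
        for j in range(w):
            px = xp[i:i + k, j:j + k]
            py = yp[i:i + k, j:j + k]
            mx, my = (win * px).sum(), (win * py).sum()
            vx = (win * px * px).sum() - mx * mx
            vy = (win * py * py).sum() - my * my
            cov = (win * px * py).sum() - mx * my
            vx, vy = max(vx, 0.0), max(vy, 0.0)
            sx, sy = np.sqrt(vx), np.sqrt(vy)
            lum = (2 * mx * my + c1) / (mx * mx + my * my + c1)
            con = (2 * sx * sy + c2) / (vx + vy + c2)
            stru = (cov + c3) / (sx * sy + c3)
            vals[i, j] = lum * con * stru
    return float(vals.mean())


class TestSSIM:
    def test_identical_maps_give_zero(self):
        rng = np.random.default_rng(0)
        x = rng.random((24, 24))
        assert abs(float(ssim_loss(x, x).data)) <= 1e-9

    def test_constant_offset_increases_loss(self):
        rng = np.random.default_rng(1)
        x = rng.random((20, 20))
        losses = [float(ssim_loss(x + c, x, SSIMConfig(data_range=1.0)).data)
                  for c in (0.0, 0.05, 0.15)]
        assert losses[0] < losses[1] < losses[2]
        assert all(-1e-9 <= v <= 2 + 1e-9 for v in losses)

    def test_matches_direct_definition_on_fixed_maps(self):
        # checkerboard vs a flat map at the checkerboard's mean
        cb = np.indices((16, 16)).sum(axis=0) % 2 * 0.02
        flat = np.full((16, 16), cb.mean())
        cfg = SSIMConfig()
        got = float(ssim_loss(Tensor(cb.astype(np.float64)),
                              Tensor(flat.astype(np.float64)), cfg).data)
        want = 1.0 - reference_ssim_mean(cb, flat, cfg)
        assert abs(got - want) <= 1e-6

    def test_matches_direct_definition_on_random_maps(self):
        rng = np.random.default_rng(7)
        pred = rng.random((16, 16)) * 0.01
        gt = rng.random((16, 16)) * 0.01
        cfg = SSIMConfig()
        got = float(ssim_loss(Tensor(pred), Tensor(gt), cfg).data)
        want = 1.0 - reference_ssim_mean(pred, gt, cfg)
        assert abs(got - want) <= 1e-6

    def test_symmetric_with_fixed_data_range(self):
        rng = np.random.default_rng(3)
        a, b = rng.random((12, 12)), rng.random((12, 12))
        cfg = SSIMConfig(data_range=1.0)
        assert abs(float(ssim_loss(Tensor(a.astype(np.float64)), Tensor(b.astype(np.float64)), cfg).data)
                   - float(ssim_loss(Tensor(b.astype(np.float64)), Tensor(a.astype(np.float64)), cfg).data)) <= 1e-12

    def test_explicit_c3_path_agrees_at_default_ratio(self):
        rng = np.random.default_rng(4)
        a, b = rng.random((12, 12)), rng.random((12, 12))
        collapsed = ssim_loss(a, b, SSIMConfig(data_range=1.0))
        explicit = ssim_loss(a, b, SSIMConfig(data_range=1.0, c1=1e-4, c2=9e-4,
                                              c3=9e-4 / 2 + 1e-12))
        assert abs(float(collapsed.data) - float(explicit.data)) <= 1e-4

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ssim_loss(np.zeros((4, 4)), np.zeros((5, 5)))

    def test_gradient_flows(self):
        rng = np.random.default_rng(5)
        pred = Tensor(rng.random((1, 1, 16, 16)), requires_grad=True)
        loss = ssim_loss(pred, rng.random((1, 1, 16, 16)))
        loss.backward()
        assert pred.grad is not None and np.isfinite(pred.grad).all()


class TestBCE:
    def test_perfect_prediction_near_zero(self):
        y = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert float(bce_loss(y, y).data) <= 1e-6

    def test_half_probability_is_ln2(self):
        y = (np.random.default_rng(0).random((8, 8)) > 0.5).astype(float)
        p = np.full((8, 8), 0.5)
        assert abs(float(bce_loss(p, y).data) - np.log(2)) <= 1e-6

    def test_quarter_probability_all_ones(self):
        y = np.ones((4, 4))
        p = np.full((4, 4), 0.25)
        assert abs(float(bce_loss(p, y).data) + np.log(0.25)) <= 1e-6

    def test_minimized_by_mean_over_constant_predictions(self):
        rng = np.random.default_rng(2)
        y = (rng.random((10, 10)) > 0.7).astype(float)
        mean = y.mean()
        best = float(bce_loss(np.full_like(y, mean), y).data)
        for p in np.linspace(0.05, 0.95, 19):
            if abs(p - mean) < 1e-9:
                continue
            assert float(bce_loss(np.full_like(y, p), y).data) >= best

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bce_loss(np.full((2, 2), 0.5), np.zeros((3, 3)))


class TestAltLosses:
    @pytest.mark.parametrize("kind", ["l1", "mse", "smooth_l1"])
    def test_zero_at_equality(self, kind):
        x = np.random.default_rng(0).random((6, 6))
        assert float(alt_density_loss(x, x, kind).data) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("kind,offset,expected", [
        ("l1", 0.5, 0.5),
        ("mse", 0.5, 0.25),
        ("smooth_l1", 0.5, 0.125),
        ("smooth_l1", 2.0, 1.5),
    ])
    def test_closed_forms_at_constant_offset(self, kind, offset, expected):
        gt = np.zeros((5, 5))
        assert float(alt_density_loss(gt + offset, gt, kind).data) == pytest.approx(expected, abs=1e-6)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            alt_density_loss(np.zeros((2, 2)), np.zeros((2, 2)), "huber9000")


class TestTotalLoss:
    @staticmethod
    def _output(density, probability=None):
        return ForwardOutput(density=Tensor(density), raw_density=Tensor(density),
                             attention=None,
                             probability=None if probability is None else Tensor(probability))

    def test_variant_without_mask_path_is_density_loss_only(self):
        rng = np.random.default_rng(0)
        pred = rng.random((1, 1, 16, 16))
        gt = rng.random((1, 1, 16, 16))
        cfg = LossConfig()
        total, comps = total_loss(self._output(pred), gt, None, cfg)
        assert float(total.data) == pytest.approx(comps["density"], abs=1e-9)
        assert comps["mask"] == 0.0

    def test_weighted_sum_of_components(self):
        rng = np.random.default_rng(1)
        pred = rng.random((1, 1, 16, 16))
        gt = rng.random((1, 1, 16, 16))
        prob = np.full((1, 1, 2, 2), 0.5)
        mask = np.zeros((1, 1, 2, 2))
        cfg = LossConfig(loss_weights=(2.0, 3.0))
        total, comps = total_loss(self._output(pred, prob), gt, mask, cfg)
        assert float(total.data) == pytest.approx(
            2.0 * comps["density"] + 3.0 * comps["mask"], rel=1e-6)

    def test_perfect_prediction_near_zero(self):
        gt = np.random.default_rng(2).random((1, 1, 16, 16))
        prob = np.ones((1, 1, 2, 2)) * (1 - 1e-7)
        mask = np.ones((1, 1, 2, 2))
        total, _ = total_loss(self._output(gt, prob), gt, mask, LossConfig())
        assert float(total.data) <= 1e-6

    def test_supervised_variant_missing_mask_raises(self):
        pred = np.zeros((1, 1, 8, 8))
        prob = np.full((1, 1, 1, 1), 0.5)
        with pytest.raises(ValueError):
            total_loss(self._output(pred, prob), pred, None, LossConfig())
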