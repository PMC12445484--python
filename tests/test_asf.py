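"""Scale-sequence fusion neck blocks: kernels, shapes, linearity, wiring."""

import numpy as np
import pytest

from canedet.asf import (SSFF, TFE, AttnAdd, gaussian_kernel, gaussian_smooth,
                         hybrid_downsample)
from canedet.assembly import ASFP2Neck, NeckConfig, StemNodeNet, build_model
from canedet.nn.autograd import Tensor
from canedet.nn.modules import seed_rng


def t(arr):
    return Tensor(np.asarray(arr, dtype=np.float32))


class TestGaussian:
    @pytest.mark.parametrize("sigma,k", [(0.5, 3), (1.0, 5), (2.0, 7)])
    def test_kernel_sums_to_one(self, sigma, k):
        assert gaussian_kernel(sigma, k).sum() == pytest.approx(1.0, abs=1e-6)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            gaussian_kernel(1.0, 4)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            gaussian_kernel(0.0, 3)

    def test_constant_map_unchanged(self):
        x = np.full((16, 16), 3.25)
        out = gaussian_smooth(x, sigma=1.0, kernel_size=5)
        # interior only: same-padding uses zero borders
        assert np.allclose(out[2:-2, 2:-2], 3.25, atol=1e-5)

    def test_impulse_reproduces_kernel(self):
        x = np.zeros((11, 11))
        x[5, 5] = 1.0
        out = gaussian_smooth(x, sigma=1.0, kernel_size=5)
        assert np.allclose(out[3:8, 3:8], gaussian_kernel(1.0, 5), atol=1e-6)

    def test_smoothing_reduces_noise_variance(self, rng):
        x = rng.standard_normal((64, 64))
        out = gaussian_smooth(x, sigma=1.0, kernel_size=5)
        assert out[4:-4, 4:-4].var() < 0.5 * x.var()

    def test_commutes_with_translation_on_interior(self, rng):
        x = rng.standard_normal((20, 20))
        a = gaussian_smooth(np.roll(x, 3, axis=1), 1.0, 5)
        b = np.roll(gaussian_smooth(x, 1.0, 5), 3, axis=1)
        assert np.allclose(a[4:-4, 6:-6], b[4:-4, 6:-6], atol=1e-5)


class TestSSFF:
    def _pyramid(self, rng, c=(8, 12, 12, 16), hw=32):
        return [t(rng.standard_normal((1, ci, hw // (2 ** i), hw // (2 ** i))))
                for i, ci in enumerate(c)]

    def test_output_matches_fuse_level_shape(self, rng):
        seed_rng(0)
        m = SSFF((8, 12, 12, 16), 10)
        out = m(self._pyramid(rng))
        assert out.shape == (1, 10, 16, 16)

    def test_zero_pyramid_zero_bias_gives_zero(self, rng):
        seed_rng(0)
        m = SSFF((8, 12, 12, 16), 10, sigmas=(None,) * 4)
        m.eval()
        for p in m.modules():
            for _, q in p._params.items():
                q.data[...] = 0.0
        feats = [t(np.zeros((1, ci, 32 // 2 ** i, 32 // 2 ** i)))
                 for i, ci in enumerate((8, 12, 12, 16))]
        out = m(feats)
        assert np.allclose(out.data, 0.0)

    def test_identity_kernel_mean_oracle(self, rng):
        """With identity projections and a unit 3-D kernel, the block
        reduces to max over the resized levels (hand-set weights)."""
        seed_rng(0)
        c = 6
        m = SSFF((c, c, c, c), c, sigmas=(None,) * 4)
        m.eval()
        for proj in m.proj:
            proj.conv.weight.data[...] = np.eye(c)[:, :, None, None]
            proj.bn.weight.data[...] = 1.0
            proj.bn.bias.data[...] = 0.0
            proj.bn.running_mean[...] = 0.0
            proj.bn.running_var[...] = 1.0 - proj.bn.eps
        m.fuse3d.conv.weight.data[...] = np.eye(c)[:, :, None, None]
        m.fuse3d.conv.bias.data[...] = 0.0
        m.fuse3d.bn.weight.data[...] = 1.0
        m.fuse3d.bn.bias.data[...] = 0.0
        m.fuse3d.bn.running_mean[...] = 0.0
        m.fuse3d.bn.running_var[...] = 1.0 - m.fuse3d.bn.eps
        feats = [t(np.abs(rng.standard_normal((1, c, 16 // 2 ** i, 16 // 2 ** i))))
                 for i in range(4)]
        out = m(feats).data
        # silu(x) on projections then lrelu on positives is monotone; the
        # depth pool must pick the max across resized levels
        resized = []
        for i, f in enumerate(feats):
            a = f.data
            if i == 0:
                # hybrid (max + avg) / 2 halving of the stride-4 level
                win = a.reshape(1, c, 8, 2, 8, 2)
                a = 0.5 * (win.max(axis=(3, 5)) + win.mean(axis=(3, 5)))
            else:
                a = a.repeat(2 ** (i - 1), axis=2).repeat(2 ** (i - 1), axis=3)
            s = a / (1 + np.exp(-a))
            resized.append(s)
        want = np.max(np.stack(resized, 0), axis=0)
        assert np.allclose(out, want, atol=1e-4)

    def test_missing_level_rejected(self, rng):
        seed_rng(0)
        m = SSFF((8, 12, 12, 16), 10)
        with pytest.raises(ValueError):
            m(self._pyramid(rng)[:3])


class TestTFE:
    def test_output_matches_mid_shape(self, rng):
        seed_rng(0)
        m = TFE(8, 12, 16, 10)
        out = m(t(rng.standard_normal((1, 8, 32, 32))),
                t(rng.standard_normal((1, 12, 16, 16))),
                t(rng.standard_normal((1, 16, 8, 8))))
        assert out.shape == (1, 10, 16, 16)

    def test_wrong_resolution_triple_rejected(self, rng):
        seed_rng(0)
        m = TFE(8, 12, 16, 10)
        with pytest.raises(ValueError):
            m(t(rng.standard_normal((1, 8, 16, 16))),
              t(rng.standard_normal((1, 12, 16, 16))),
              t(rng.standard_normal((1, 16, 8, 8))))

    def test_input_order_matters(self, rng):
        seed_rng(3)
        c = 8
        m = TFE(c, c, c, c)
        fl = t(rng.standard_normal((1, c, 16, 16)))
        fm = t(rng.standard_normal((1, c, 8, 8)))
        fs = t(rng.standard_normal((1, c, 4, 4)))
        a = m(fl, fm, fs).data
        # swap mid/small content (after resizing they share the grid)
        fm2 = t(fm.data.copy())
        fs2 = t(fs.data.copy())
        b = m(fl, t(fs.data.repeat(2, 2).repeat(2, 3)),
              t(fm2.data[:, :, ::2, ::2])).data
        assert not np.allclose(a, b, atol=1e-4)

    def test_hybrid_downsample_combines_max_and_mean(self):
        x = t(np.arange(16, dtype=np.float32).reshape(1, 1, 4, 4))
        out = hybrid_downsample(x).data
        want_max = np.array([[5, 7], [13, 15]], dtype=np.float32)
        want_avg = np.array([[2.5, 4.5], [10.5, 12.5]], dtype=np.float32)
        assert np.allclose(out[0, 0], want_max + want_avg)


class TestNeck:
    def test_four_outputs_at_expected_strides(self, rng):
        seed_rng(0)
        net = build_model("ours")
        x = t(rng.standard_normal((1, 3, 128, 128)))
        net.eval()
        outs = net(x)
        assert len(outs) == 4
        assert [o.shape[2] for o in outs] == [32, 16, 8, 4]
        assert net.strides == (4, 8, 16, 32)

    def test_baseline_has_three_outputs(self, rng):
        seed_rng(0)
        net = build_model("yolo11n")
        net.eval()
        outs = net(t(rng.standard_normal((1, 3, 128, 128))))
        assert len(outs) == 3
        assert [o.shape[2] for o in outs] == [16, 8, 4]

    def test_forward_deterministic_under_seed(self, rng):
        x = rng.standard_normal((1, 3, 64, 64)).astype(np.float32)
        outs = []
        for _ in range(2):
            net = build_model("ours")
            net.eval()
            outs.append(net(t(x))[0].data)
        assert np.array_equal(outs[0], outs[1])

    def test_gradients_reach_every_backbone_tap(self, rng):
        seed_rng(0)
        net = StemNodeNet("ours")
        net.train()
        x = Tensor(rng.standard_normal((1, 3, 64, 64)).astype(np.float32))
        outs = net(x)
        total = None
        for o in outs:
            s = o.sum()
            total = s if total is None else total + s
        total.backward()
        for name in ("l0", "l2", "l4", "l6", "l10"):
            conv = getattr(net.backbone, name)
            p = next(iter(conv.parameters()))
            assert p.grad is not None and np.abs(p.grad).max() > 0, name
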