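"""Engine correctness: autograd gradients, conv semantics, normalization."""

import numpy as np
import pytest

from canedet.nn import functional as F
from canedet.nn.autograd import Tensor, concat, stack
from canedet.nn.modules import (BatchNorm2d, Conv2d, ConvBN, GroupNorm,
                                seed_rng)

from oracles import numerical_grad


def check_grad(fn_tensor, fn_np, shape, rng, tol=2e-2, scale=1.0):
    """Compare backward() gradients with central differences."""
    x = (rng.standard_normal(shape) * scale).astype(np.float32)
    t = Tensor(x.copy(), requires_grad=True)
    out = fn_tensor(t)
    out.sum().backward()
    got = t.grad.astype(np.float64)
    want = numerical_grad(lambda a: float(fn_np(a).sum()),
                          x.astype(np.float64), eps=1e-3)
    assert np.abs(got - want).max() <= tol * max(1.0, np.abs(want).max())


class TestElementwiseGrads:
    @pytest.mark.parametrize("name", ["silu", "sigmoid", "exp", "sqrt_abs",
                                      "leaky", "softmax"])
    def test_unary_ops(self, name, rng):
        fns = {
            "silu": (lambda t: t.silu(),
                     lambda a: a / (1 + np.exp(-a))),
            "sigmoid": (lambda t: t.sigmoid(),
                        lambda a: 1 / (1 + np.exp(-a))),
            "exp": (lambda t: t.exp(), np.exp),
            "sqrt_abs": (lambda t: (t * t + 1.0).sqrt(),
                         lambda a: np.sqrt(a * a + 1.0)),
            "leaky": (lambda t: t.leaky_relu(0.1),
                      lambda a: np.where(a > 0, a, 0.1 * a)),
            "softmax": (lambda t: (t.softmax(axis=1) * np.arange(5)),
                        lambda a: (np.exp(a - a.max(1, keepdims=True))
                                   / np.exp(a - a.max(1, keepdims=True)).sum(1, keepdims=True)
                                   ) * np.arange(5)),
        }
        ft, fn = fns[name]
        check_grad(ft, fn, (3, 5), rng)

    def test_broadcast_binary_grad(self, rng):
        b = rng.standard_normal((1, 4)).astype(np.float32)

        def ft(t):
            return (t * b + t / 2.0 - t.maximum(0.3)) * t

        def fn(a):
            return (a * b + a / 2.0 - np.maximum(a, 0.3)) * a

        x = rng.standard_normal((3, 4)).astype(np.float32) + 1.0
        t = Tensor(x.copy(), requires_grad=True)
        ft(t).sum().backward()
        want = numerical_grad(lambda a: float(fn(a).sum()), x.astype(np.float64))
        assert np.allclose(t.grad, want, atol=2e-2)

    def test_getitem_concat_stack_grads(self, rng):
        x = rng.standard_normal((2, 6)).astype(np.float32)
        t = Tensor(x.copy(), requires_grad=True)
        out = concat([t[:, :2] * 3.0, t[:, 2:]], axis=1)
        out = stack([out, out * 2.0], axis=0)
        out.sum().backward()
        want = np.ones_like(x) * 3.0
        want[:, :2] = 9.0
        assert np.allclose(t.grad, want)

    def test_max_reduction_splits_ties(self):
        t = Tensor(np.array([[1.0, 1.0, 0.0]], dtype=np.float32),
                   requires_grad=True)
        t.max(axis=1).sum().backward()
        assert np.allclose(t.grad, [[0.5, 0.5, 0.0]])


class TestConv:
    def test_conv2d_matches_direct_computation(self, rng):
        x = rng.standard_normal((2, 3, 6, 6)).astype(np.float32)
        w = rng.standard_normal((4, 3, 3, 3)).astype(np.float32)
        out = F.conv2d(Tensor(x), Tensor(w), padding=1).data
        # direct nested-loop cross-correlation on one output position
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        want = np.einsum("ncij,ocij->no", xp[:, :, 3:6, 4:7], w)
        assert np.allclose(out[:, :, 3, 4], want, atol=1e-4)

    def test_conv2d_gradients(self, rng):
        x = rng.standard_normal((1, 2, 5, 5)).astype(np.float32)
        w = rng.standard_normal((3, 2, 3, 3)).astype(np.float32)
        b = rng.standard_normal(3).astype(np.float32)
        tx, tw, tb = (Tensor(a.copy(), requires_grad=True) for a in (x, w, b))
        F.conv2d(tx, tw, tb, stride=2, padding=1).sum().backward()
        for t, arr, f in (
            (tx, x, lambda a: _np_conv(a, w, b, 2, 1)),
            (tw, w, lambda a: _np_conv(x, a, b, 2, 1)),
            (tb, b, lambda a: _np_conv(x, w, a, 2, 1)),
        ):
            want = numerical_grad(lambda v: float(f(v).sum()),
                                  arr.astype(np.float64), eps=1e-3)
            assert np.allclose(t.grad, want, atol=5e-2), t.shape

    def test_depthwise_groups(self, rng):
        x = rng.standard_normal((1, 4, 5, 5)).astype(np.float32)
        w = rng.standard_normal((4, 1, 3, 3)).astype(np.float32)
        out = F.conv2d(Tensor(x), Tensor(w), padding=1, groups=4).data
        for c in range(4):
            ref = F.conv2d(Tensor(x[:, c:c + 1]), Tensor(w[c:c + 1]),
                           padding=1).data
            assert np.allclose(out[:, c:c + 1], ref, atol=1e-5)

    def test_maxpool_forward_and_grad(self, rng):
        x = rng.standard_normal((1, 2, 6, 6)).astype(np.float32)
        t = Tensor(x.copy(), requires_grad=True)
        out = F.max_pool2d(t, 2, 2)
        assert np.allclose(out.data, x.reshape(1, 2, 3, 2, 3, 2).max((3, 5)))
        out.sum().backward()
        assert t.grad.sum() == pytest.approx(out.data.size)

    def test_upsample_nearest_inverts_avgpool_energy(self, rng):
        x = rng.standard_normal((1, 3, 4, 4)).astype(np.float32)
        up = F.upsample_nearest(Tensor(x), 2).data
        assert up.shape == (1, 3, 8, 8)
        assert np.allclose(up[:, :, ::2, ::2], x)


def _np_conv(x, w, b, stride, pad):
    out = F.conv2d(Tensor(np.asarray(x, dtype=np.float32)),
                   Tensor(np.asarray(w, dtype=np.float32)),
                   Tensor(np.asarray(b, dtype=np.float32)),
                   stride=stride, padding=pad)
    return out.data.astype(np.float64)


class TestNorms:
    def test_groupnorm_invariant_to_batch_shuffle(self, rng):
        gn = GroupNorm(4, 8)
        x = rng.standard_normal((6, 8, 5, 5)).astype(np.float32)
        out = gn(Tensor(x)).data
        perm = rng.permutation(6)
        out_p = gn(Tensor(x[perm])).data
        assert np.allclose(out[perm], out_p, atol=1e-6)

    def test_batchnorm_depends_on_batch_composition(self, rng):
        bn = BatchNorm2d(8)
        x = rng.standard_normal((6, 8, 5, 5)).astype(np.float32)
        y = x.copy()
        y[3:] *= 4.0  # change the other images in the batch
        a = bn(Tensor(x)).data[:3]
        b = bn(Tensor(y)).data[:3]
        assert not np.allclose(a, b, atol=1e-3)

    def test_groupnorm_normalizes_per_group(self, rng):
        gn = GroupNorm(2, 4)
        x = rng.standard_normal((2, 4, 7, 7)).astype(np.float32) * 5 + 3
        out = gn(Tensor(x)).data
        g0 = out[:, :2].reshape(2, -1)
        assert np.allclose(g0.mean(1), 0.0, atol=1e-4)
        assert np.allclose(g0.std(1), 1.0, atol=1e-3)

    def test_batchnorm_train_eval_consistency(self, rng):
        bn = BatchNorm2d(3, momentum=1.0)  # running stats = batch stats
        x = rng.standard_normal((8, 3, 4, 4)).astype(np.float32)
        y_train = bn(Tensor(x)).data
        bn.train(False)
        y_eval = bn(Tensor(x)).data
        assert np.allclose(y_train, y_eval, atol=1e-4)

    def test_indivisible_groups_rejected(self):
        with pytest.raises(ValueError):
            GroupNorm(3, 8)


class TestModules:
    def test_seeded_build_is_deterministic(self):
        seed_rng(7)
        a = Conv2d(3, 8, 3).weight.data.copy()
        seed_rng(7)
        b = Conv2d(3, 8, 3).weight.data.copy()
        assert np.array_equal(a, b)

    def test_convbn_fused_count_convention(self):
        m = ConvBN(8, 16, 3)
        assert m.param_count(fused=False) == 8 * 16 * 9 + 32
        assert m.param_count(fused=True) == 8 * 16 * 9 + 16

    def test_state_dict_roundtrip(self, rng):
        seed_rng(1)
        m = ConvBN(4, 6, 3)
        sd = m.state_dict()
        seed_rng(2)
        m2 = ConvBN(4, 6, 3)
        m2.load_state_dict(sd)
        x = Tensor(rng.standard_normal((1, 4, 5, 5)).astype(np.float32))
        m.eval(), m2.eval()
        assert np.allclose(m(x).data, m2(x).data)
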