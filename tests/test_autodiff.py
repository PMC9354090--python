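"""Gradient correctness of the autodiff engine via central finite differences."""

import numpy as np
import pytest

from mlee.autodiff import Adam, Tensor, concat, crf_forward_step, stack


def _numgrad(f, x, eps=1e-6):
    g = np.zeros_like(x)
    flat = x.ravel()
    gf = g.ravel()
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        hi = f()
        flat[i] = orig - eps
        lo = f()
        flat[i] = orig
        gf[i] = (hi - lo) / (2 * eps)
    return g


@pytest.mark.parametrize(
    "name, builder",
    [
        ("matmul", lambda a, b: (a @ b).sum()),
        ("add_broadcast", lambda a, b: (a + b[0:1, :]).tanh().sum()),
        ("mul", lambda a, b: ((a @ b) * a * 0.5).sum()),
        ("softmax", lambda a, b: ((a @ b).softmax(axis=-1) * np.arange(3.0)).sum()),
        ("logsumexp", lambda a, b: (a @ b).logsumexp(axis=-1).sum()),
        ("layernorm", lambda a, b: ((a @ b).layernorm() * np.arange(3.0)).sum()),
        ("relu", lambda a, b: (a @ b).relu().sum()),
        ("getitem", lambda a, b: (a[1:, :] @ b).sum()),
    ],
)
def test_gradients_match_finite_differences(name, builder):
    rng = np.random.default_rng(7)
    a = Tensor(rng.normal(size=(4, 3)), requires_grad=True)
    b = Tensor(rng.normal(size=(3, 3)), requires_grad=True)
    out = builder(a, b)
    out.backward()
    for t in (a, b):
        num = _numgrad(lambda: float(builder(a, b).data), t.data)
        assert np.allclose(t.grad, num, atol=1e-5), name


def test_gather_scatter_accumulates_repeats():
    emb = Tensor(np.arange(12.0).reshape(4, 3), requires_grad=True)
    ids = np.array([[0, 2, 0]])
    out = emb[ids].sum()
    out.backward()
    expected = np.zeros((4, 3))
    expected[0] = 2.0  # index 0 gathered twice
    expected[2] = 1.0
    assert np.array_equal(emb.grad, expected)


def test_concat_stack_where_gradients():
    rng = np.random.default_rng(8)
    a = Tensor(rng.normal(size=(2, 3)), requires_grad=True)
    b = Tensor(rng.normal(size=(2, 3)), requires_grad=True)

    def f():
        c = concat([a, b], axis=1)
        s = stack([a, b], axis=0).sum()
        w = a.where_static(np.array([[True, False, True]] * 2), b)
        return (c.sum() + s + w.sum()).data.item()

    out = concat([a, b], axis=1).sum() + stack([a, b], axis=0).sum() + a.where_static(
        np.array([[True, False, True]] * 2), b
    ).sum()
    out.backward()
    for t in (a, b):
        num = _numgrad(f, t.data)
        assert np.allclose(t.grad, num, atol=1e-5)


def test_crf_forward_step_matches_composed_ops():
    rng = np.random.default_rng(9)
    alpha = Tensor(rng.normal(size=(3, 4)), requires_grad=True)
    trans = Tensor(rng.normal(size=(4, 4)), requires_grad=True)
    fused = crf_forward_step(alpha, trans)
    composed = (alpha.reshape(3, 4, 1) + trans.reshape(1, 4, 4)).logsumexp(axis=1)
    assert np.allclose(fused.data, composed.data, atol=1e-12)
    fused.sum().backward()
    ga, gt = alpha.grad.copy(), trans.grad.copy()
    alpha.zero_grad(), trans.zero_grad()
    composed2 = (alpha.reshape(3, 4, 1) + trans.reshape(1, 4, 4)).logsumexp(axis=1)
    composed2.sum().backward()
    assert np.allclose(ga, alpha.grad, atol=1e-10)
    assert np.allclose(gt, trans.grad, atol=1e-10)


def test_shared_subexpression_accumulates_once_per_use():
    x = Tensor(np.array([2.0]), requires_grad=True)
    y = x * 3.0
    out = y + y  # two uses of the same node
    out.backward()
    assert x.grad[0] == pytest.approx(6.0)


def test_adam_reduces_quadratic():
    x = Tensor(np.array([5.0, -3.0]), requires_grad=True)
    opt = Adam([x], lr=0.1)
    for _ in range(200):
        loss = (x * x).sum()
        opt.zero_grad()
        loss.backward()
        opt.step()
    assert np.all(np.abs(x.data) < 1e-2)
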