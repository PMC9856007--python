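"""Gradient correctness of the autodiff primitives.

Every spatial primitive is checked against central finite differences on
small float32 tensors; elementwise ops are exercised through composite
expressions. Tolerances reflect float32 arithmetic.
"""

import numpy as np
import pytest

from axialseg import grad


def finite_difference(f, tensor, indices, eps=1e-2):
    """Central finite differences of the scalar f() w.r.t. tensor entries."""
    out = []
    for idx in indices:
        orig = tensor.data[idx]
        tensor.data[idx] = orig + eps
        lp = f().item()
        tensor.data[idx] = orig - eps
        lm = f().item()
        tensor.data[idx] = orig
        out.append((lp - lm) / (2 * eps))
    return np.array(out)


def assert_grads_match(f, tensors, rng, n_probe=25, rtol=0.05, atol=5e-3):
    loss = f()
    loss.backward()
    analytic = [t.grad.copy() for t in tensors]
    for t, g_an in zip(tensors, analytic):
        idx_list = [tuple(rng.integers(0, s) for s in t.data.shape)
                    for _ in range(min(n_probe, t.data.size))]
        g_fd = finite_difference(f, t, idx_list)
        g_at = np.array([g_an[i] for i in idx_list])
        np.testing.assert_allclose(g_at, g_fd, rtol=rtol, atol=atol)


@pytest.mark.parametrize("stride", [1, 2])
def test_conv3d_gradients(rng, stride):
    x = grad.Tensor(rng.normal(size=(2, 3, 6, 5, 4)).astype(np.float32), requires_grad=True)
    w = grad.Tensor(0.3 * rng.normal(size=(4, 3, 3, 3, 3)).astype(np.float32),
                    requires_grad=True)
    weight = grad.Tensor(rng.normal(size=(1,)).astype(np.float32))

    def f():
        return (grad.conv3d(x, w, stride=stride, padding=1) * weight).sum()

    assert_grads_match(f, [x, w], rng)


def test_conv3d_matches_scipy_oracle(rng):
    """Forward cross-correlation agrees with scipy.ndimage.correlate per
    output channel (stride 1, zero padding)."""
    from scipy import ndimage
    x = rng.normal(size=(1, 2, 5, 6, 4)).astype(np.float32)
    w = rng.normal(size=(3, 2, 3, 3, 3)).astype(np.float32)
    out = grad.conv3d(grad.Tensor(x), grad.Tensor(w), stride=1, padding=1).data
    for o in range(3):
        expected = sum(
            ndimage.correlate(x[0, c].astype(np.float64), w[o, c].astype(np.float64),
                              mode="constant", cval=0.0)
            for c in range(2))
        np.testing.assert_allclose(out[0, o], expected, atol=1e-4)


def test_conv_transpose_doubles_and_backprops(rng):
    x = grad.Tensor(rng.normal(size=(2, 3, 3, 4, 2)).astype(np.float32), requires_grad=True)
    w = grad.Tensor(0.3 * rng.normal(size=(3, 5, 2, 2, 2)).astype(np.float32),
                    requires_grad=True)
    out = grad.conv_transpose3d_2x(x, w)
    assert out.shape == (2, 5, 6, 8, 4)
    assert_grads_match(lambda: (grad.conv_transpose3d_2x(x, w) ** 2.0).sum(), [x, w], rng)


def test_instance_norm_matches_composite(rng):
    x0 = rng.normal(size=(2, 3, 4, 4, 4)).astype(np.float32)
    g0 = rng.normal(size=(1, 3, 1, 1, 1)).astype(np.float32)
    b0 = rng.normal(size=(1, 3, 1, 1, 1)).astype(np.float32)
    proj = rng.normal(size=(2, 3, 4, 4, 4)).astype(np.float32)

    def run(fused):
        x = grad.Tensor(x0, requires_grad=True)
        ga = grad.Tensor(g0, requires_grad=True)
        be = grad.Tensor(b0, requires_grad=True)
        if fused:
            out = grad.instance_norm(x, ga, be)
        else:
            mu = x.mean(axis=(2, 3, 4), keepdims=True)
            cen = x - mu
            var = (cen ** 2.0).mean(axis=(2, 3, 4), keepdims=True)
            out = cen * (var + 1e-5) ** -0.5 * ga + be
        (out * grad.Tensor(proj)).sum().backward()
        return out.data, x.grad, ga.grad, be.grad

    for a, b in zip(run(True), run(False)):
        np.testing.assert_allclose(a, b, atol=2e-5)


def test_softmax_rows_stochastic_and_grad(rng):
    a = grad.Tensor(rng.normal(size=(3, 4, 5)).astype(np.float32), requires_grad=True)
    s = grad.softmax(a, axis=-1)
    np.testing.assert_allclose(s.data.sum(axis=-1), 1.0, atol=1e-6)
    assert (s.data >= 0).all()
    assert_grads_match(lambda: (grad.softmax(a, axis=-1) ** 2.0).sum(), [a], rng)


def test_matmul_broadcast_grad(rng):
    a = grad.Tensor(rng.normal(size=(2, 3, 4)).astype(np.float32), requires_grad=True)
    b = grad.Tensor(rng.normal(size=(4, 5)).astype(np.float32), requires_grad=True)
    assert_grads_match(lambda: ((a @ b) ** 2.0).sum(), [a, b], rng)


def test_upsample_nearest_grad_is_sum_pool(rng):
    x = grad.Tensor(rng.normal(size=(1, 2, 3, 3, 3)).astype(np.float32), requires_grad=True)
    out = grad.upsample_nearest(x, 2)
    assert out.shape == (1, 2, 6, 6, 6)
    out.sum().backward()
    np.testing.assert_allclose(x.grad, 8.0)


def test_clip_blocks_gradient_outside_bounds():
    x = grad.Tensor(np.array([0.0, 0.5, 1.0], dtype=np.float32), requires_grad=True)
    grad.clip(x, 0.1, 0.9).sum().backward()
    np.testing.assert_array_equal(x.grad, [0.0, 1.0, 0.0])


def test_no_grad_suppresses_tape(rng):
    x = grad.Tensor(rng.normal(size=(2, 2)).astype(np.float32), requires_grad=True)
    with grad.no_grad():
        y = (x * 2.0).sum()
    assert y._parents == () and not y.requires_grad


def test_broadcast_add_accumulates_over_broadcast_axes(rng):
    x = grad.Tensor(rng.normal(size=(2, 3, 4)).astype(np.float32), requires_grad=True)
    b = grad.Tensor(rng.normal(size=(3, 1)).astype(np.float32), requires_grad=True)
    ((x + b) * grad.Tensor(np.ones((2, 3, 4), np.float32))).sum().backward()
    np.testing.assert_allclose(b.grad, 8.0)
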