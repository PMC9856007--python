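"""Axial attention against an independent loop-based oracle.

The oracle implements the attention arithmetic directly: for every 1-D line
of voxels along the attended axis it forms q, k, v by explicit matrix
products, builds the correlation matrix entry by entry as inner products,
softmax-normalises rows, and accumulates the weighted values — no shared
code with the vectorised implementation.
"""

import numpy as np
import pytest

import axialseg as ax
from axialseg import grad
from axialseg.attention import (AXES, AxialAttentionFusion, AxisSelfAttention,
                                FeatureMap, attention_matrix_elements,
                                head_schedule)


def oracle_axis_attention(x, axis_idx, wq, wk, wv, wo, bo, pos):
    """Single-head axial attention, explicit loops over lines and positions.

    x: (C, D, H, W); wq/wk: (C, Chat); wv/wo: (C, C); pos: (C, L) or None.
    """
    c = x.shape[0]
    x = x.astype(np.float64).copy()
    if pos is not None:
        shape = [c, 1, 1, 1]
        shape[axis_idx + 1] = pos.shape[1]
        x = x + pos.reshape(shape)
    out = np.zeros_like(x)
    spatial = x.shape[1:]
    length = spatial[axis_idx]
    others = [a for a in range(3) if a != axis_idx]
    for u in range(spatial[others[0]]):
        for v in range(spatial[others[1]]):
            idx = [None, None, None]
            idx[others[0]], idx[others[1]] = u, v
            line = np.empty((length, c))
            for j in range(length):
                idx[axis_idx] = j
                line[j] = x[(slice(None),) + tuple(idx)]
            q = line @ wq
            k = line @ wk
            vv = line @ wv
            delta = np.empty((length, length))
            for j in range(length):
                for i in range(length):
                    delta[j, i] = float(q[i] @ k[j])
            r = np.exp(delta - delta.max(axis=1, keepdims=True))
            r /= r.sum(axis=1, keepdims=True)
            res = np.zeros((length, c))
            for j in range(length):
                for i in range(length):
                    res[j] += r[j, i] * vv[i]
            res = res @ wo + bo
            for j in range(length):
                idx[axis_idx] = j
                out[(slice(None),) + tuple(idx)] = res[j]
    return out


@pytest.mark.parametrize("axis", AXES)
@pytest.mark.parametrize("channels,shape", [(8, (6, 5, 4)), (4, (3, 4, 5))])
def test_axis_attention_matches_loop_oracle(rng, axis, channels, shape):
    axis_idx = AXES.index(axis)
    attn = AxisSelfAttention(channels, axis, shape[axis_idx], heads=1,
                             head_dim=channels // 2, rng=rng)
    x = rng.normal(size=(1, channels) + shape).astype(np.float32)
    got = attn(grad.Tensor(x)).data[0]
    expected = oracle_axis_attention(
        x[0], axis_idx,
        attn.q_proj.weight.data, attn.k_proj.weight.data,
        attn.v_proj.weight.data, attn.out_proj.weight.data,
        attn.out_proj.bias.data, attn.pos_embed.data)
    np.testing.assert_allclose(got, expected, atol=1e-5)


def test_attention_matrices_row_stochastic(rng):
    attn = AxisSelfAttention(8, "height", 5, heads=2, head_dim=4, rng=rng)
    x = rng.normal(size=(1, 8, 3, 5, 4)).astype(np.float32)
    mats = attn.attention_matrix(grad.Tensor(x))
    assert mats.shape[-2:] == (5, 5)
    assert (mats >= 0).all()
    np.testing.assert_allclose(mats.sum(axis=-1), 1.0, atol=1e-5)


def test_length_one_axis_reduces_to_projection(rng):
    """Softmax over a single element is 1, so the output is the output
    projection of v regardless of q/k weights."""
    attn = AxisSelfAttention(6, "depth", 1, heads=1, head_dim=4, rng=rng)
    attn.pos_embed.data[:] = 0
    x = rng.normal(size=(1, 6, 1, 4, 3)).astype(np.float32)
    got = attn(grad.Tensor(x)).data
    seq = np.moveaxis(x[0], 0, -1)  # (1,4,3,C)
    expected = (seq @ attn.v_proj.weight.data) @ attn.out_proj.weight.data \
        + attn.out_proj.bias.data
    np.testing.assert_allclose(got[0], np.moveaxis(expected, -1, 0), atol=1e-5)


def test_no_mixing_across_lines(rng):
    """Permuting positions along an orthogonal axis permutes the output
    identically: lines attend independently."""
    attn = AxisSelfAttention(4, "depth", 6, heads=2, head_dim=3, rng=rng)
    x = rng.normal(size=(1, 4, 6, 5, 3)).astype(np.float32)
    out = attn(grad.Tensor(x)).data
    perm = rng.permutation(5)
    out_perm = attn(grad.Tensor(x[:, :, :, perm, :])).data
    np.testing.assert_allclose(out[:, :, :, perm, :], out_perm, atol=1e-5)


def test_position_embedding_breaks_translation_symmetry(rng):
    """Two voxels with identical intensities at different positions become
    distinguishable once the position embedding is added."""
    attn = AxisSelfAttention(4, "depth", 4, heads=1, head_dim=4, rng=rng)
    attn.pos_embed.data = rng.normal(0, 1, size=(4, 4)).astype(np.float32)
    x = np.zeros((1, 4, 4, 1, 1), dtype=np.float32)
    x[0, :, :, 0, 0] = 1.0  # all positions identical
    with_pos = attn(grad.Tensor(x)).data[0, :, :, 0, 0]
    attn.pos_embed.data[:] = 0
    without_pos = attn(grad.Tensor(x)).data[0, :, :, 0, 0]
    # without embeddings every position gets the same output vector
    assert np.allclose(without_pos, without_pos[:, :1], atol=1e-6)
    assert not np.allclose(with_pos, with_pos[:, :1], atol=1e-4)


def test_constant_embedding_shifts_slices(rng):
    attn = AxisSelfAttention(3, "width", 4, heads=1, head_dim=2, rng=rng)
    attn.pos_embed.data[:] = 0.7
    x = rng.normal(size=(1, 3, 2, 2, 4)).astype(np.float32)
    np.testing.assert_allclose(attn.add_position(grad.Tensor(x)).data,
                               x + 0.7, atol=1e-6)


class TestFusionBlock:
    def _block(self, rng, **kw):
        return AxialAttentionFusion(skip_channels=6, pre_channels=10,
                                    spatial_shape=(4, 6, 8), heads=2, head_dim=4,
                                    rng=rng, **kw)

    def test_upsample_doubles_and_matches_channels(self, rng):
        block = self._block(rng)
        f_pre = FeatureMap(grad.Tensor(rng.normal(size=(1, 10, 2, 3, 4)).astype(np.float32)),
                           level=3)
        f = block.upsample_previous(f_pre)
        assert f.data.shape == (1, 6, 4, 6, 8)
        assert f.level == 2

    def test_zero_weights_degenerate_identity(self, rng):
        """With all attention projections and embeddings zeroed the attention
        chain vanishes, forcing F_out = F + F_sc exactly."""
        block = self._block(rng)
        for attn in block.attentions:
            for lin in (attn.q_proj, attn.k_proj, attn.v_proj, attn.out_proj):
                lin.weight.data[:] = 0
                if lin.bias is not None:
                    lin.bias.data[:] = 0
            attn.pos_embed.data[:] = 0
        f_sc = grad.Tensor(rng.normal(size=(1, 6, 4, 6, 8)).astype(np.float32))
        f_pre = grad.Tensor(rng.normal(size=(1, 10, 2, 3, 4)).astype(np.float32))
        out = block(f_sc, f_pre)
        f = block.upsample(f_pre)
        np.testing.assert_array_equal(out.data, f.data + f_sc.data)

    def test_residual_ablation_changes_output(self, rng):
        f_sc = rng.normal(size=(1, 6, 4, 6, 8)).astype(np.float32)
        f_pre = rng.normal(size=(1, 10, 2, 3, 4)).astype(np.float32)
        with_res = self._block(np.random.default_rng(3), use_residual=True)
        without = self._block(np.random.default_rng(3), use_residual=False)
        out_a = with_res(grad.Tensor(f_sc), grad.Tensor(f_pre)).data
        out_b = without(grad.Tensor(f_sc), grad.Tensor(f_pre)).data
        assert np.abs(out_a - out_b).max() > 1e-4

    def test_level_contract(self, rng):
        block = self._block(rng)
        f_sc = FeatureMap(grad.Tensor(np.zeros((1, 6, 4, 6, 8), np.float32)), level=2)
        f_pre = FeatureMap(grad.Tensor(np.zeros((1, 10, 2, 3, 4), np.float32)), level=2)
        with pytest.raises(ValueError, match="coarser"):
            block.aam_forward(f_sc, f_pre)

    def test_end_to_end_gradient(self, rng):
        """Finite-difference gradient through the whole fusion block."""
        from test_grad import assert_grads_match
        block = self._block(rng)
        f_sc = grad.Tensor(rng.normal(size=(1, 6, 4, 6, 8)).astype(np.float32),
                           requires_grad=True)
        f_pre = grad.Tensor(rng.normal(size=(1, 10, 2, 3, 4)).astype(np.float32),
                            requires_grad=True)
        assert_grads_match(lambda: (block(f_sc, f_pre) ** 2.0).sum(),
                           [f_pre], rng, n_probe=10, rtol=0.08, atol=2e-2)


def test_head_schedule_doubles_with_depth():
    levels = (1, 2, 3, 4)
    assert head_schedule(1, levels) == (4, 16)
    assert head_schedule(2, levels) == (8, 32)
    assert head_schedule(3, levels) == (16, 64)
    assert head_schedule(4, levels) == (32, 128)
    with pytest.raises(ValueError):
        head_schedule(0, levels)


def test_complexity_factorization():
    """Axial factorisation stores D^2+H^2+W^2 entries per line-batch versus
    (DHW)^2 for dense 3-D attention."""
    counts = attention_matrix_elements((16, 16, 16))
    assert counts["axial"] == 3 * 16 ** 2 * 16 ** 2
    assert counts["dense"] == 16 ** 6
    assert counts["dense"] // counts["axial"] == 16 ** 2 // 3
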