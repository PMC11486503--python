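"""Cross-attention with hard lambda thresholding."""

import numpy as np
import pytest

import oracles
from dualddi.autodiff import Tensor
from dualddi.crossattn import CrossAttention, cross_attend


def relu(x):
    return np.maximum(x, 0.0)


@pytest.fixture
def module(rng):
    return CrossAttention(d=4, n_patterns=3, lam=0.5, rng=rng)


def test_lambda_zero_reproduces_unmasked_attention(rng):
    q = Tensor(rng.normal(size=(3, 4)))
    k = Tensor(rng.normal(size=(5, 4)))
    v = Tensor(rng.normal(size=(5, 4)))
    w_o = Tensor(rng.normal(size=(4, 4)))
    raw, mask, out = cross_attend(q, k, v, 0.0, w_o, 2.0)
    assert np.all(mask == 1.0)
    expected = relu((q.data + raw.data @ v.data) @ w_o.data)
    np.testing.assert_allclose(out.data, expected, atol=1e-12)


def test_lambda_above_one_collapses_to_query_only(rng):
    q = Tensor(rng.normal(size=(3, 4)))
    k = Tensor(rng.normal(size=(5, 4)))
    v = Tensor(rng.normal(size=(5, 4)))
    w_o = Tensor(rng.normal(size=(4, 4)))
    raw, mask, out = cross_attend(q, k, v, 1.1, w_o, 2.0)
    assert np.all(mask == 0.0)
    np.testing.assert_allclose(out.data, relu(q.data @ w_o.data), atol=1e-12)


def test_single_key_keeps_full_weight_for_any_lambda_below_one(rng):
    q = Tensor(rng.normal(size=(2, 4)))
    k = Tensor(rng.normal(size=(1, 4)))
    v = Tensor(rng.normal(size=(1, 4)))
    w_o = Tensor(rng.normal(size=(4, 4)))
    raw, mask, out = cross_attend(q, k, v, 1.0, w_o, 2.0)
    np.testing.assert_allclose(raw.data, 1.0)
    assert np.all(mask == 1.0)
    expected = relu((q.data + np.broadcast_to(v.data, q.data.shape)) @ w_o.data)
    np.testing.assert_allclose(out.data, expected, atol=1e-12)


def test_matches_explicit_loop_oracle_with_thresholding(rng):
    d, m, n = 2, 2, 3
    q = rng.normal(size=(m, d))
    k = rng.normal(size=(n, d))
    v = rng.normal(size=(n, d))
    w_o = rng.normal(size=(d, d))
    raw, mask, out = cross_attend(
        Tensor(q), Tensor(k), Tensor(v), 0.5, Tensor(w_o), np.sqrt(d)
    )
    o_raw, o_mask, o_out = oracles.cross_attend(
        q.tolist(), k.tolist(), v.tolist(), 0.5, w_o.tolist(), np.sqrt(d)
    )
    np.testing.assert_allclose(raw.data, o_raw, atol=1e-6)
    np.testing.assert_array_equal(mask, o_mask)
    np.testing.assert_allclose(out.data, o_out, atol=1e-6)


def test_negative_lambda_rejected(rng):
    q = Tensor(np.ones((1, 2)))
    with pytest.raises(ValueError, match="lambda"):
        cross_attend(q, q, q, -0.1, Tensor(np.eye(2)), 1.0)


def test_mask_monotone_in_lambda(rng):
    q = Tensor(rng.normal(size=(4, 6)))
    k = Tensor(rng.normal(size=(7, 6)))
    v = Tensor(rng.normal(size=(7, 6)))
    w_o = Tensor(np.eye(6))
    masks = [
        cross_attend(q, k, v, lam, w_o, np.sqrt(6))[1]
        for lam in (0.0, 0.1, 0.3, 0.75, 1.01)
    ]
    for lo, hi in zip(masks, masks[1:]):
        assert np.all(hi <= lo)  # raising lambda can only shrink the mask


def test_attention_rows_sum_to_one_and_padding_gets_zero_weight(module, rng):
    nodes_1 = Tensor(rng.normal(size=(2, 5, 4)))
    nodes_2 = Tensor(rng.normal(size=(2, 6, 4)))
    valid_1 = np.array([[[1, 1, 1, 0, 0]], [[1, 1, 1, 1, 1]]], dtype=float)
    valid_2 = np.array([[[1, 1, 1, 1, 1, 1]], [[1, 1, 0, 0, 0, 0]]], dtype=float)
    _, _, diag = module(nodes_1, nodes_2, valid_1, valid_2)
    for key, valid in (("attention_1", valid_2), ("attention_2", valid_1)):
        raw = diag[key]
        np.testing.assert_allclose(raw.sum(axis=-1), 1.0, atol=1e-5)
        assert np.all(raw[np.broadcast_to(valid, raw.shape) == 0] == 0)


def test_zero_valid_nodes_rejected(module, rng):
    nodes = Tensor(rng.normal(size=(1, 3, 4)))
    empty = np.zeros((1, 1, 3))
    with pytest.raises(ValueError, match="zero valid"):
        module(nodes, nodes, empty, np.ones((1, 1, 3)))


def test_outputs_invariant_to_node_permutation(module, rng):
    h1 = rng.normal(size=(5, 4))
    h2 = rng.normal(size=(6, 4))
    o1, o2, _ = module(Tensor(h1), Tensor(h2))
    perm1, perm2 = rng.permutation(5), rng.permutation(6)
    o1p, o2p, _ = module(Tensor(h1[perm1]), Tensor(h2[perm2]))
    np.testing.assert_allclose(o1.data, o1p.data, atol=1e-5)
    np.testing.assert_allclose(o2.data, o2p.data, atol=1e-5)


def test_pair_results_independent_of_batch_padding(module, rng):
    h1a, h2a = rng.normal(size=(4, 4)), rng.normal(size=(3, 4))
    h1b, h2b = rng.normal(size=(7, 4)), rng.normal(size=(6, 4))
    o1_solo, o2_solo, _ = module(Tensor(h1a), Tensor(h2a))

    def pad(h, n):
        out = np.zeros((n, 4))
        out[: len(h)] = h
        return out

    n1, n2 = 7, 6
    batch1 = Tensor(np.stack([pad(h1a, n1), h1b]))
    batch2 = Tensor(np.stack([pad(h2a, n2), h2b]))
    valid1 = np.array([[[1] * 4 + [0] * 3], [[1] * 7]], dtype=float)
    valid2 = np.array([[[1] * 3 + [0] * 3], [[1] * 6]], dtype=float)
    o1_batch, o2_batch, _ = module(batch1, batch2, valid1, valid2)
    np.testing.assert_allclose(o1_solo.data, o1_batch.data[0], atol=1e-6)
    np.testing.assert_allclose(o2_solo.data, o2_batch.data[0], atol=1e-6)


def test_tiled_queries_identical_across_batch(module):
    tiled = module.tiled_queries(3)
    assert tiled.shape == (3, 3, 4)
    np.testing.assert_array_equal(tiled.data[0], tiled.data[1])
    np.testing.assert_allclose(
        tiled.data[2], module.patterns.data @ module.w_q.data, atol=1e-12
    )


def test_identity_and_zero_projections(rng):
    mod = CrossAttention(d=3, n_patterns=2, lam=0.0, rng=rng)
    h = Tensor(rng.normal(size=(4, 3)))
    mod.w_k1.data = np.eye(3)
    mod.w_v1.data = np.eye(3)
    k, v = mod.project_keys_values(h, 1)
    np.testing.assert_array_equal(k.data, h.data)
    np.testing.assert_array_equal(v.data, h.data)
    mod.w_k2.data = np.zeros((3, 3))
    k2, _ = mod.project_keys_values(h, 2)
    assert np.all(k2.data == 0)
    with pytest.raises(ValueError, match="slot"):
        mod.project_keys_values(h, 3)


def test_mask_density_reflects_lambda_extremes(rng):
    open_gate = CrossAttention(d=4, n_patterns=3, lam=0.0, rng=rng)
    closed_gate = CrossAttention(d=4, n_patterns=3, lam=1.5, rng=rng)
    h1, h2 = Tensor(rng.normal(size=(5, 4))), Tensor(rng.normal(size=(4, 4)))
    assert open_gate(h1, h2)[2]["mask_density"] == 1.0
    assert closed_gate(h1, h2)[2]["mask_density"] == 0.0
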