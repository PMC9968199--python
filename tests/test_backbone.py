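"""Graph convolution against brute-force oracles; adjacency and affinity."""

import numpy as np
import pytest

import gaitgcn as gg
from gaitgcn import nn
from gaitgcn.backbone import (AGCNLayer, Backbone, BackboneConfig, graph_conv,
                              input_affinity, normalize_adjacency)


def eq7_triple_loop(fin, W, A, B, C):
    """Naive elementwise statement of the three-term graph convolution."""
    Cin, T, N = fin.shape
    Cout = W[0].shape[0]
    out = np.zeros((Cout, T, N))
    for k in range(len(W)):
        M = A[k] + B[k] + C[k]
        for o in range(Cout):
            for t in range(T):
                for n in range(N):
                    acc = 0.0
                    for c in range(Cin):
                        for m in range(N):
                            acc += W[k][o, c] * fin[c, t, m] * M[m, n]
                    out[o, t, n] += acc
    return out


# ---------------------------------------------------------------------- #
# adjacency normalization
# ---------------------------------------------------------------------- #
def test_normalize_adjacency_chain_hand_value():
    A_bar = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
    A = normalize_adjacency(A_bar)
    assert A[0, 1] == pytest.approx(1 / np.sqrt(1.001 * 2.001), abs=1e-6)
    np.testing.assert_allclose(np.diag(A), 0.0)


def test_normalize_adjacency_empty_rows_guarded():
    A = normalize_adjacency(np.zeros((4, 4)))
    assert np.all(np.isfinite(A))
    np.testing.assert_array_equal(A, 0.0)


def test_normalize_adjacency_preserves_symmetry():
    rng = np.random.default_rng(0)
    for _ in range(20):
        n = rng.integers(2, 8)
        A_bar = rng.integers(0, 2, size=(n, n)).astype(float)
        A_bar = np.triu(A_bar, 1)
        A_bar = A_bar + A_bar.T
        A = normalize_adjacency(A_bar)
        np.testing.assert_allclose(A, A.T, atol=1e-12)


# ---------------------------------------------------------------------- #
# embedded-Gaussian affinity
# ---------------------------------------------------------------------- #
def test_affinity_uniform_for_identical_embeddings():
    fin = nn.Tensor(np.ones((2, 5, 3), dtype=np.float32))  # (B, N, C)
    th = nn.Tensor(np.ones((4, 3), dtype=np.float32))
    ph = nn.Tensor(np.ones((4, 3), dtype=np.float32))
    C = input_affinity(fin, th, ph)
    np.testing.assert_allclose(C.data, 1.0 / 5, atol=1e-6)


def test_affinity_softmax_closed_form():
    """N=2 with row logits differing by ln 3 -> softmax row (0.25, 0.75)."""
    # scalar embeddings: theta(v_i)^T phi(v_j) = x_i * x_j, so node values
    # (1, 1 + ln 3) give first-row logits (1, 1 + ln 3), a ln 3 gap
    fin = nn.Tensor(np.array([[[1.0], [1.0 + np.log(3.0)]]], dtype=np.float32))
    th = nn.Tensor(np.array([[1.0]], dtype=np.float32))
    ph = nn.Tensor(np.array([[1.0]], dtype=np.float32))
    C = input_affinity(fin, th, ph)
    np.testing.assert_allclose(C.data[0, 0], [0.25, 0.75], atol=1e-5)


def test_affinity_rows_sum_to_one_random():
    rng = np.random.default_rng(1)
    fin = nn.Tensor(rng.standard_normal((3, 7, 5)).astype(np.float32))
    th = nn.Tensor(rng.standard_normal((4, 5)).astype(np.float32))
    ph = nn.Tensor(rng.standard_normal((4, 5)).astype(np.float32))
    C = input_affinity(fin, th, ph)
    np.testing.assert_allclose(C.data.sum(axis=-1), 1.0, atol=1e-6)
    assert np.all(C.data >= 0) and np.all(C.data <= 1)  # open in exact arith.


# ---------------------------------------------------------------------- #
# graph convolution vs oracle
# ---------------------------------------------------------------------- #
def test_graph_conv_identity_configuration():
    rng = np.random.default_rng(2)
    fin = rng.standard_normal((3, 4, 5))
    out = graph_conv(fin, W=[np.eye(3)], A=[np.eye(5)])
    np.testing.assert_allclose(out, fin, atol=1e-12)


def test_graph_conv_matches_triple_loop_oracle():
    """100 random small instances agree with the naive loops to 1e-6."""
    rng = np.random.default_rng(3)
    for _ in range(100):
        N = int(rng.integers(2, 5))
        Cin = int(rng.integers(1, 4))
        Cout = int(rng.integers(1, 4))
        T = int(rng.integers(1, 4))
        Kv = int(rng.integers(1, 4))
        fin = rng.standard_normal((Cin, T, N))
        W = [rng.standard_normal((Cout, Cin)) for _ in range(Kv)]
        A = [rng.standard_normal((N, N)) for _ in range(Kv)]
        B = [rng.standard_normal((N, N)) for _ in range(Kv)]
        C = [rng.standard_normal((N, N)) for _ in range(Kv)]
        got = graph_conv(fin, W, A, B, C)
        expect = eq7_triple_loop(fin, W, A, B, C)
        np.testing.assert_allclose(got, expect, atol=1e-6)


def test_graph_conv_linear_in_attention_map():
    rng = np.random.default_rng(4)
    fin = rng.standard_normal((2, 3, 4))
    W = [rng.standard_normal((2, 2))]
    A = [rng.standard_normal((4, 4))]
    B0 = [rng.standard_normal((4, 4))]
    delta = [rng.standard_normal((4, 4))]
    out0 = graph_conv(fin, W, A, B0)
    out1 = graph_conv(fin, W, A, [B0[0] + delta[0]])
    out_d = graph_conv(fin, W, [np.zeros((4, 4))], delta)
    np.testing.assert_allclose(out1 - out0, out_d, atol=1e-9)


def test_layer_spatial_matches_reference_view(chain3):
    """The fast node-major layer equals the canonical (C,T,N) formulation."""
    cfg = BackboneConfig(n_layers=1, feature_maps=4, kv=3, kt=3, embed_dim=2)
    A_bar = chain3.subset_adjacencies()
    A = np.stack([normalize_adjacency(a) for a in A_bar]).astype(np.float32)
    rng = np.random.default_rng(5)
    layer = AGCNLayer(2, cfg, A, rng)
    B, N, C, T = 2, 3, 2, 6
    f = rng.standard_normal((B, N, C, T)).astype(np.float32)
    out = layer.spatial(nn.Tensor(f.reshape(B * N, C, T)), B)
    out_np = out.data.reshape(B, N, -1, T)
    for b in range(B):
        fin = f[b].transpose(1, 2, 0)  # (C, T, N)
        Cmaps = [c[b] for c in layer.last_C]
        expect = graph_conv(
            fin,
            [w.data.astype(np.float64) for w in layer.W],
            [a.data.astype(np.float64) for a in layer.A],
            [bk.data.astype(np.float64) for bk in layer.B],
            Cmaps,
        ) + layer.bias.data[:, None, None]
        np.testing.assert_allclose(
            out_np[b].transpose(1, 2, 0), expect.transpose(0, 1, 2), atol=1e-4
        )


# ---------------------------------------------------------------------- #
# temporal convolution
# ---------------------------------------------------------------------- #
def test_temporal_conv_delta_kernel_is_identity():
    x = np.random.default_rng(6).standard_normal((2, 3, 8)).astype(np.float32)
    W = np.zeros((3, 3, 5), dtype=np.float32)
    for c in range(3):
        W[c, c, 2] = 1.0  # centered delta
    out = nn.conv1d(nn.Tensor(x), nn.Tensor(W))
    np.testing.assert_allclose(out.data, x, atol=1e-6)


def test_temporal_conv_preserves_dc_with_averaging_kernel():
    x = np.full((1, 2, 9), 3.0, dtype=np.float32)
    W = np.zeros((2, 2, 3), dtype=np.float32)
    for c in range(2):
        W[c, c, :] = 1.0 / 3.0
    out = nn.conv1d(nn.Tensor(x), nn.Tensor(W))
    np.testing.assert_allclose(out.data[:, :, 1:-1], 3.0, atol=1e-6)


# ---------------------------------------------------------------------- #
# whole backbone
# ---------------------------------------------------------------------- #
def test_backbone_temporal_length_before_tap(skeleton):
    """T_c=240 through 4 halving layers -> 15 samples before pooling."""
    cfg = BackboneConfig()
    rng = np.random.default_rng(0)
    bb = Backbone(skeleton, 3, 240, cfg, rng)
    f = nn.Tensor(np.random.default_rng(1).standard_normal(
        (1, skeleton.n_markers, 3, 240)).astype(np.float32))
    h = f.reshape(skeleton.n_markers, 3, 240)
    lengths = [240]
    for layer in bb.layers:
        h = layer.forward(h, 1)
        lengths.append(h.shape[-1])
    assert lengths == [240, 120, 60, 30, 15]
    out = bb.forward(f)
    assert out.shape == (1, 64)


def test_backbone_zero_input_zero_biases_gives_zero(skeleton):
    cfg = BackboneConfig(n_layers=2, feature_maps=8)
    rng = np.random.default_rng(0)
    bb = Backbone(skeleton, 3, 16, cfg, rng)
    f = nn.Tensor(np.zeros((2, skeleton.n_markers, 3, 16), dtype=np.float32))
    out = bb.forward(f)
    np.testing.assert_allclose(out.data, 0.0, atol=1e-7)


def test_backbone_node_permutation_invariance_of_pooled_output(chain3):
    """Relabeling markers (and their adjacencies) leaves the node-mean
    pooled feature unchanged."""
    perm = [2, 0, 1]
    skel_p = gg.SkeletonGraph(
        marker_names=[chain3.marker_names[p] for p in perm],
        edges=[(perm.index(i), perm.index(j)) for i, j in chain3.edges],
        root="ROOT",
    )
    cfg = BackboneConfig(n_layers=2, feature_maps=8, kv=3, kt=3, embed_dim=4)
    rng_seedling = 7
    f = np.random.default_rng(8).standard_normal((1, 3, 3, 16)).astype(np.float32)

    bb1 = Backbone(chain3, 3, 16, cfg, np.random.default_rng(rng_seedling))
    bb2 = Backbone(skel_p, 3, 16, cfg, np.random.default_rng(rng_seedling))
    out1 = bb1.forward(nn.Tensor(f))
    out2 = bb2.forward(nn.Tensor(f[:, perm]))
    np.testing.assert_allclose(out1.data, out2.data, atol=1e-4)
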