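"""Adaptive temporal-spatial graph-convolutional backbone.

Each of the four layers mixes marker features over the skeleton graph

    f_out = sum_k  W_k f_in (A_k + B_k + C_k),

where, per partition kernel k (Kv = 3 spatial-configuration subsets:
self/equal-distance, centripetal, centrifugal):

* A_k is the fixed normalized adjacency
  A_k = Lambda^{-1/2} Abar_k Lambda^{-1/2} with
  Lambda_ii = sum_j Abar_k_ij + alpha (alpha = 0.001 guards empty rows);
* B_k is a learned, input-independent attention map (initialized zero,
  unconstrained, not forced left/right symmetric);
* C_k is an input-dependent embedded-Gaussian affinity: node embeddings
  theta_k, phi_k are compared by softmax-normalized inner products, so
  every row of C_k sums to 1.

The spatial step is followed by a per-node temporal convolution
(Kt = 5, same padding), ReLU and temporal halving max-pool; after the
last layer, temporal average pooling plus a node mean summarize the
sequence into one 64-dimensional feature vector.  Configuration toggles
degrade the model to the plain-GCN (B_k, C_k off) and TCN (no node
mixing) baselines.

Features flow through the layers in a node-major (B*N, C, T) layout so
the node mixing, the 1x1 channel convolution and the temporal
convolution are all contiguous batched GEMMs; `graph_conv` exposes the
canonical (C, T', N) single-window view of the spatial step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .data_model import SkeletonGraph

GRAPH_MODES = ("none", "fixed", "adaptive")


@dataclass
class BackboneConfig:
    n_layers: int = 4
    feature_maps: int = 64
    kv: int = 3
    kt: int = 5
    embed_dim: int = 16
    graph: str = "adaptive"  # none -> TCN, fixed -> GCN, adaptive -> AGCN

    def __post_init__(self):
        if self.kt % 2 == 0:
            raise ValueError("Kt must be odd (same padding)")
        if self.n_layers < 1:
            raise ValueError("need at least one layer")
        if self.graph not in GRAPH_MODES:
            raise ValueError(f"graph must be one of {GRAPH_MODES}")


def normalize_adjacency(A_bar: np.ndarray, alpha: float = 0.001) -> np.ndarray:
    """A_k = Lambda^{-1/2} Abar_k Lambda^{-1/2}, Lambda_ii = sum_j Abar_ij + alpha."""
    A_bar = np.asarray(A_bar, dtype=np.float64)
    deg = A_bar.sum(axis=1) + alpha
    d = 1.0 / np.sqrt(deg)
    return (A_bar * d[:, None]) * d[None, :]


def input_affinity(
    fin: nn.Tensor, theta_W: nn.Tensor, phi_W: nn.Tensor
) -> nn.Tensor:
    """Embedded-Gaussian affinity C_k: softmax over j of theta(v_i)^T phi(v_j).

    fin: (B, N, C) time-averaged node features; theta_W, phi_W: (E, C)
    embedding projections.  Rows of the returned (B, N, N) map sum to 1.
    """
    th = fin @ theta_W.transpose(1, 0)  # (B, N, E)
    ph = fin @ phi_W.transpose(1, 0)
    logits = th @ ph.transpose(0, 2, 1)  # (B, N, N)
    return nn.softmax(logits, axis=-1)


class AGCNLayer:
    """One graph-conv + temporal-conv block on (B*N, C, T) features."""

    def __init__(
        self,
        c_in: int,
        cfg: BackboneConfig,
        A: np.ndarray,  # (Kv, N, N) fixed normalized adjacencies
        rng: np.random.Generator,
    ):
        self.cfg = cfg
        self.graph = cfg.graph
        self.n_nodes = A.shape[1]
        c_out = cfg.feature_maps
        self.params: list[nn.Parameter] = []
        self.A = [nn.Tensor(a) for a in A]
        self.At = [nn.Tensor(np.ascontiguousarray(a.T)) for a in A]
        kv = cfg.kv if cfg.graph != "none" else 1
        self.kv = kv
        self.W = []
        self.B = []
        self.theta = []
        self.phi = []
        # deliberately conservative 1x1-conv init: the kv summed kernels and
        # the worst-case ~2x gain of the (A + B + C) mixing (C row-stochastic,
        # A near-stochastic) enter the He fan-in as (gain)^2, damping the
        # graph pathway below the variance-correct value. The smaller start
        # trades convergence speed for markedly smoother optimization in a
        # normalization-free stack; Adam recovers the scale.
        gain = {"none": 1, "fixed": kv, "adaptive": 2 * kv}[cfg.graph]
        for _ in range(kv):
            Wk = nn.Parameter(nn.he_init(rng, (c_out, c_in), c_in * gain**2))
            self.W.append(Wk)
            self.params.append(Wk)
            if cfg.graph == "adaptive":
                Bk = nn.Parameter(np.zeros(A.shape[1:], dtype=nn.DTYPE))
                th = nn.Parameter(nn.he_init(rng, (cfg.embed_dim, c_in), c_in))
                ph = nn.Parameter(nn.he_init(rng, (cfg.embed_dim, c_in), c_in))
                self.B.append(Bk)
                self.theta.append(th)
                self.phi.append(ph)
                self.params += [Bk, th, ph]
        self.bias = nn.Parameter(np.zeros(c_out, dtype=nn.DTYPE))
        self.params.append(self.bias)
        self.Wt = nn.Parameter(
            nn.he_init(rng, (c_out, c_out, cfg.kt), c_out * cfg.kt)
        )
        self.bt = nn.Parameter(np.zeros(c_out, dtype=nn.DTYPE))
        self.params += [self.Wt, self.bt]
        self.last_C: list[np.ndarray] = []  # input-dependent maps, for Eq-14 readout

    def spatial(self, f: nn.Tensor, B: int) -> nn.Tensor:
        """f: (B*N, C, T) -> (B*N, C_out, T) by the three-term graph convolution."""
        BN, C, T = f.shape
        N = self.n_nodes
        self.last_C = []
        if self.graph == "adaptive":
            fbar = f.reshape(B, N, C, T).mean(axis=3)  # (B, N, C)
        out = None
        for k in range(self.kv):
            if self.graph == "none":
                mixed = f  # no node mixing: pure per-node (TCN) pathway
            else:
                if self.graph == "adaptive":
                    Ck = input_affinity(fbar, self.theta[k], self.phi[k])
                    self.last_C.append(Ck.data.copy())
                    M = self.A[k] + self.B[k] + Ck  # (B, N, N)
                    Mt = M.transpose(0, 2, 1)
                else:
                    Mt = self.At[k]
                # mixed[b, n] = sum_m f[b, m] M[m, n]  (contraction of nodes)
                mixed = (Mt @ f.reshape(B, N, C * T)).reshape(BN, C, T)
            out_k = self.W[k] @ mixed  # 1x1 conv: (Cout, C) @ (B*N, C, T)
            out = out_k if out is None else out + out_k
        return out + self.bias.reshape(1, -1, 1)

    def temporal(self, f: nn.Tensor) -> nn.Tensor:
        """Per-node Kt x 1 temporal convolution, ReLU, temporal halving pool."""
        return nn.max_pool1d(nn.relu(nn.conv1d(f, self.Wt, self.bt)), 2)

    def forward(self, f: nn.Tensor, B: int) -> nn.Tensor:
        return self.temporal(self.spatial(f, B))


def graph_conv(
    fin: np.ndarray,
    W: list[np.ndarray],
    A: list[np.ndarray],
    Bmaps: list[np.ndarray] | None = None,
    Cmaps: list[np.ndarray] | None = None,
) -> np.ndarray:
    """Canonical spatial graph convolution on one window.

    fin: (C_in, T', N); per kernel k, node features are mixed by
    (A_k + B_k + C_k) and channel-mapped by W_k (C_out, C_in); the Kv
    terms are summed.  This is the reference (C, T', N) view of
    `AGCNLayer.spatial`.
    """
    fin = np.asarray(fin)
    out = None
    for k, Wk in enumerate(W):
        M = np.asarray(A[k], dtype=fin.dtype)
        if Bmaps is not None:
            M = M + Bmaps[k]
        if Cmaps is not None:
            M = M + Cmaps[k]
        mixed = fin @ M  # (C, T', N) @ (N, N)
        term = np.tensordot(Wk, mixed, axes=(1, 0))  # (C_out, T', N)
        out = term if out is None else out + term
    return out


class Backbone:
    """Stack of AGCN layers followed by temporal average pooling."""

    def __init__(
        self,
        skeleton: SkeletonGraph,
        c_in: int,
        T_in: int,
        cfg: BackboneConfig,
        rng: np.random.Generator,
    ):
        if T_in % (2**cfg.n_layers):
            raise ValueError(
                f"input length {T_in} not divisible by 2^{cfg.n_layers} pooling"
            )
        self.cfg = cfg
        self.n_nodes = skeleton.n_markers
        A_bar = skeleton.subset_adjacencies()[: cfg.kv]
        A = np.stack([normalize_adjacency(a) for a in A_bar]).astype(nn.DTYPE)
        self.layers: list[AGCNLayer] = []
        self.params: list[nn.Parameter] = []
        for li in range(cfg.n_layers):
            layer = AGCNLayer(c_in if li == 0 else cfg.feature_maps, cfg, A, rng)
            self.layers.append(layer)
            self.params += layer.params

    def forward(self, f: nn.Tensor) -> nn.Tensor:
        """f: (B, N, C, T) -> pooled feature (B, feature_maps)."""
        B, N, C, T = f.shape
        h = f.reshape(B * N, C, T)
        for layer in self.layers:
            h = layer.forward(h, B)
        C_out = h.shape[1]
        # TAP over time, then mean over nodes
        return h.mean(axis=2).reshape(B, N, C_out).mean(axis=1)
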