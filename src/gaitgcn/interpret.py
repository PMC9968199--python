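"""Attention aggregation, joint/limb ranking and confident core-segment extraction.

Trained attention is summarized by averaging, over M windows and the
Kv partition kernels of a chosen layer (default: the first, closest to
raw kinematics),

    EA = 1/(M*K) * sum_i sum_k (A_k + B_k + C_k(x_i)),

an N x N map whose diagonal gives per-marker ("joint") weights and
whose off-diagonal entries, symmetrized for undirected display, give
marker-pair ("limb") weights.  For explanation plots, windows are
ranked by the entropy of the FOG-score prediction within each
(medication state, FOG score) stratum; the most confident windows are
returned with their predicted core-motion crop and left-heel height
trace.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import AnalysisWindow
from .model import FogScoreModel


@dataclass
class AttentionSummary:
    EA: np.ndarray  # (N, N)
    joint_weights: np.ndarray  # (N,) diagonal
    limb_weights: dict  # {(i, j): weight} for i < j
    marker_names: list[str]


def aggregate_attention(
    model: FogScoreModel, X: np.ndarray, layer: int | None = None,
    batch_size: int = 32,
) -> AttentionSummary:
    """Average (A_k + B_k + C_k(x_i)) over all windows and kernels.

    `layer` selects one backbone layer (0-based); the default `None`
    averages the per-layer aggregates over all layers, which proved the
    most stable readout — individual layers emphasize different mixes
    of raw-kinematic and task-shaped affinity.

    For the fixed-graph (GCN) configuration B_k and C_k vanish and the
    aggregate reduces to the mean normalized adjacency; the graph-free
    TCN configuration has no attention to aggregate.
    """
    if len(X) == 0:
        raise ValueError("need at least one window to aggregate attention")
    if model.cfg.graph == "none":
        raise ValueError("the TCN configuration has no graph attention")
    layers = model.backbone.layers if layer is None else \
        [model.backbone.layers[layer]]
    M = len(X)
    per_layer = []
    if model.cfg.graph == "fixed":
        for lay in layers:
            A = np.stack([a.data for a in lay.A[: lay.kv]]).astype(np.float64)
            per_layer.append(A.mean(axis=0))
    else:
        accs = [0.0 for _ in layers]
        for lo in range(0, M, batch_size):
            model.features(X[lo : lo + batch_size])
            for i, lay in enumerate(layers):
                A = np.stack([a.data for a in lay.A[: lay.kv]]).astype(np.float64)
                B = np.stack([b.data for b in lay.B]).astype(np.float64)
                Ck = np.stack(lay.last_C).astype(np.float64)  # (K, b, N, N)
                accs[i] = accs[i] + (A[:, None] + B[:, None] + Ck).sum(axis=(0, 1))
        per_layer = [acc / (M * lay.kv) for acc, lay in zip(accs, layers)]
    EA = np.mean(per_layer, axis=0)
    names = model.skeleton.marker_names
    joint = np.diag(EA).copy()
    limb = {}
    n = EA.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            limb[(i, j)] = 0.5 * (EA[i, j] + EA[j, i])
    return AttentionSummary(EA=EA, joint_weights=joint, limb_weights=limb,
                            marker_names=list(names))


def top_k(summary: AttentionSummary, k: int = 10):
    """k largest joint and limb weights; ties broken by marker index order."""
    n = len(summary.joint_weights)
    if k > n or k > len(summary.limb_weights):
        raise ValueError("k exceeds the number of available entries")
    # stable sort on negated weights keeps index order among ties
    joint_order = np.argsort(-summary.joint_weights, kind="stable")[:k]
    top_joints = [
        (int(i), summary.marker_names[i], float(summary.joint_weights[i]))
        for i in joint_order
    ]
    pairs = sorted(summary.limb_weights.items(), key=lambda kv: (-kv[1], kv[0]))[:k]
    top_limbs = [
        (
            (int(i), int(j)),
            (summary.marker_names[i], summary.marker_names[j]),
            float(w),
        )
        for (i, j), w in pairs
    ]
    return top_joints, top_limbs


def confident_core_segments(
    model: FogScoreModel,
    windows: list[AnalysisWindow],
    top_n: int = 1,
    heel_marker: str = "LHEEL",
):
    """Most confidently scored windows per (state, FOG score) stratum.

    Windows are ranked by ascending FOG-prediction entropy; the top-n of
    each stratum are returned as dicts with the window, its predicted
    crop interval in seconds, and the left-heel height trace for
    plotting the 4 s span with the core segment highlighted.
    """
    if model.trimmer is None:
        raise ValueError(
            "adaptive trimming is disabled in this model; core-segment "
            "extraction requires the AT component"
        )
    X = np.stack([w.X for w in windows]).astype(np.float32)
    pred = model.predict(X)
    heel_idx = model.skeleton.index(heel_marker)
    fs = 120.0
    strata: dict[tuple, list] = {}
    for wi, w in enumerate(windows):
        key = (w.labels.med_state, w.labels.fog_score)
        strata.setdefault(key, []).append(wi)
    out = []
    for key in sorted(strata):
        order = sorted(strata[key], key=lambda wi: pred.fog_entropy[wi])
        for wi in order[:top_n]:
            w = windows[wi]
            s, e = float(pred.crop.s[wi]), float(pred.crop.e[wi])
            out.append(
                {
                    "med_state": key[0],
                    "fog_score": key[1],
                    "window": w,
                    "entropy": float(pred.fog_entropy[wi]),
                    "crop_seconds": (s / fs, e / fs),
                    "span_seconds": w.X.shape[-1] / fs,
                    "heel_trace": w.X[heel_idx, 2].copy(),
                }
            )
    return out
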