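"""Adaptive Trimming: learned differentiable extraction of the core motion segment.

A small temporal convolutional network reads the full analysis window
(markers x channels flattened into input channels) and two fully
connected heads predict a center c = sigmoid(.) and a width
w = exp(.) of the core motion segment, mapped to continuous start/end
sample indices

    s = T * sigmoid(c - w/2),   e = T * sigmoid(c + w/2),

which always satisfy 0 < s < e < T.  The segment [s, e] is then
resampled to a fixed length by linear interpolation (a 1-D
spatial-transformer sampler), keeping the whole operation
differentiable so the trimmer trains end-to-end with the backbone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn


@dataclass
class CropSpec:
    """Continuous core-motion segment descriptor for one window."""

    c: np.ndarray  # (B,) center in (0,1)
    w: np.ndarray  # (B,) width, positive
    s: np.ndarray  # (B,) start index in (0,T)
    e: np.ndarray  # (B,) end index in (0,T)
    T: int

    def __post_init__(self):
        if np.any(self.s >= self.e):
            raise ValueError("crop invariant violated: s must be < e")
        if np.any(self.s <= 0) or np.any(self.e >= self.T):
            raise ValueError("crop indices must lie strictly inside (0, T)")


def crop_endpoints(c: nn.Tensor, w: nn.Tensor, T: int) -> tuple[nn.Tensor, nn.Tensor]:
    """Map (c, w) to start/end indices: s = T*sigmoid(c - w/2), e = T*sigmoid(c + w/2)."""
    half = w * 0.5
    s = nn.sigmoid(c - half) * float(T)
    e = nn.sigmoid(c + half) * float(T)
    return s, e


class AdaptiveTrimmer:
    """Four-layer temporal CNN plus center/width heads predicting the crop."""

    def __init__(
        self,
        in_channels: int,
        T: int,
        rng: np.random.Generator,
        feature_maps: int = 64,
        kernel: int = 3,
        n_layers: int = 4,
        fc_units: int = 128,
    ):
        if T % (2**n_layers):
            raise ValueError(f"window length {T} not divisible by 2^{n_layers}")
        self.T = T
        self.n_layers = n_layers
        self.params: list[nn.Parameter] = []
        self.convs = []
        c_in = in_channels
        for _ in range(n_layers):
            W = nn.Parameter(nn.he_init(rng, (feature_maps, c_in, kernel), c_in * kernel))
            b = nn.Parameter(np.zeros(feature_maps, dtype=nn.DTYPE))
            self.convs.append((W, b))
            self.params += [W, b]
            c_in = feature_maps
        flat = feature_maps * (T // 2**n_layers)

        def fc_head(out_bias: float):
            W1 = nn.Parameter(nn.he_init(rng, (flat, fc_units), flat))
            b1 = nn.Parameter(np.zeros(fc_units, dtype=nn.DTYPE))
            W2 = nn.Parameter(nn.he_init(rng, (fc_units, 1), fc_units))
            b2 = nn.Parameter(np.full(1, out_bias, dtype=nn.DTYPE))
            self.params += [W1, b1, W2, b2]
            return (W1, b1, W2, b2)

        # zero biases: initial c = sigmoid(0) = 0.5, w = exp(0) = 1
        self.center_head = fc_head(0.0)
        self.width_head = fc_head(0.0)

    def _features(self, x: nn.Tensor) -> nn.Tensor:
        h = x
        for W, b in self.convs:
            h = nn.max_pool1d(nn.relu(nn.conv1d(h, W, b)), 2)
        B = h.shape[0]
        return h.reshape(B, -1)

    @staticmethod
    def _head(feat: nn.Tensor, head) -> nn.Tensor:
        W1, b1, W2, b2 = head
        h = nn.relu(nn.linear(feat, W1, b1))
        out = nn.linear(h, W2, b2)
        return out.reshape(out.shape[0])

    def predict_crop(self, x: nn.Tensor):
        """x: (B, N*C, T) -> (c, w, s, e) tensors plus a CropSpec snapshot."""
        feat = self._features(x)
        c = nn.sigmoid(self._head(feat, self.center_head))
        # width logits are smoothly saturated so s, e stay strictly inside
        # (0, T) in float32 (w up to ~12 already spans essentially the full
        # window) while gradients never freeze at the bounds
        w = nn.exp(nn.soft_bound(self._head(feat, self.width_head), -4.0, 2.5))
        if not np.all(np.isfinite(c.data)) or not np.all(np.isfinite(w.data)):
            raise FloatingPointError("non-finite activation in trimming heads")
        s, e = crop_endpoints(c, w, self.T)
        spec = CropSpec(c=c.data.copy(), w=w.data.copy(), s=s.data.copy(),
                        e=e.data.copy(), T=self.T)
        return c, w, s, e, spec

    def forward(self, x: nn.Tensor, out_len: int):
        """Predict the crop and resample the window to `out_len` samples."""
        c, w, s, e, spec = self.predict_crop(x)
        xc = nn.crop_resample(x, s, e, out_len)
        return xc, spec
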