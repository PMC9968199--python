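"""Full model assembly: adaptive trimming -> AGCN backbone -> multi-task heads."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .adaptive_trimming import AdaptiveTrimmer, CropSpec
from .backbone import Backbone, BackboneConfig
from .data_model import SkeletonGraph
from .heads import GMMParams, MultiTaskHeads, TargetScaler, multitask_loss, \
    point_estimate, prediction_entropy


@dataclass
class ModelConfig:
    """Architecture toggles spanning the model family.

    `at=False, graph='none'`  -> TCN baseline;
    `at=False, graph='fixed'` -> GCN;
    `at=False, graph='adaptive'` -> AGCN;
    `at=True,  graph='adaptive', regression='mse'` -> AT+AGCN;
    `at=True,  graph='adaptive', regression='gmm'` -> full model.
    """

    at: bool = True
    graph: str = "adaptive"
    n_layers: int = 4
    feature_maps: int = 64
    kv: int = 3
    kt: int = 5
    embed_dim: int = 16
    crop_len: int = 240
    gmm_components: int = 3
    regression: str = "gmm"
    head_hidden: tuple = (256, 128)
    loss_weights: tuple = (1.0, 1.0, 1.0)

    @property
    def name(self) -> str:
        base = {"none": "TCN", "fixed": "GCN", "adaptive": "AGCN"}[self.graph]
        if self.at:
            base = "AT+" + base
        if self.regression == "gmm" and self.loss_weights[2]:
            base += "+GMM"
        return base


@dataclass
class PredictionRecord:
    """Per-window outputs of the three heads."""

    p_med: np.ndarray  # (B, 2)
    p_fog: np.ndarray  # (B, 5)
    updrs_mixture: GMMParams | None
    updrs_point: np.ndarray  # (B,) on the 0-120 scale
    fog_entropy: np.ndarray  # (B,) nats, in [0, ln 5]
    crop: CropSpec | None = None


class FogScoreModel:
    """Trainable multi-task model over analysis windows (B, N, C, T)."""

    def __init__(
        self,
        skeleton: SkeletonGraph,
        window_len: int,
        cfg: ModelConfig,
        seed: int = 0,
    ):
        self.skeleton = skeleton
        self.cfg = cfg
        self.window_len = window_len
        rng = np.random.default_rng(seed)
        self.params: list[nn.Parameter] = []
        N = skeleton.n_markers
        if cfg.at:
            self.trimmer = AdaptiveTrimmer(N * 3, window_len, rng)
            self.params += self.trimmer.params
            t_backbone = cfg.crop_len
        else:
            self.trimmer = None
            t_backbone = window_len
        bcfg = BackboneConfig(
            n_layers=cfg.n_layers,
            feature_maps=cfg.feature_maps,
            kv=cfg.kv,
            kt=cfg.kt,
            embed_dim=cfg.embed_dim,
            graph=cfg.graph,
        )
        self.backbone = Backbone(skeleton, 3, t_backbone, bcfg, rng)
        self.params += self.backbone.params
        self.heads = MultiTaskHeads(
            cfg.feature_maps,
            rng,
            hidden=cfg.head_hidden,
            gmm_components=cfg.gmm_components,
            regression=cfg.regression,
        )
        self.params += self.heads.params
        self.scaler: TargetScaler | None = None

    # ------------------------------------------------------------------ #
    def features(self, X: np.ndarray):
        """X: (B, N, C, T) -> (pooled feature tensor, CropSpec | None)."""
        B, N, C, T = X.shape
        x = nn.Tensor(X.reshape(B, N * C, T))
        spec = None
        if self.trimmer is not None:
            x, spec = self.trimmer.forward(x, self.cfg.crop_len)
            T = self.cfg.crop_len
        f = x.reshape(B, N, C, T)  # node-major layout for the backbone
        feat = self.backbone.forward(f)
        if not np.all(np.isfinite(feat.data)):
            raise FloatingPointError("non-finite activation in backbone output")
        return feat, spec

    def loss(self, X, med, fog, updrs) -> nn.Tensor:
        if self.scaler is None:
            raise RuntimeError("fit the TargetScaler before computing the loss")
        feat, _ = self.features(X)
        return multitask_loss(
            self.heads, feat, med, fog, self.scaler.transform(updrs),
            weights=self.cfg.loss_weights,
        )

    def predict(self, X: np.ndarray, batch_size: int = 32) -> PredictionRecord:
        """Forward pass without gradients, batched over windows."""
        outs = []
        for lo in range(0, len(X), batch_size):
            outs.append(self._predict_batch(X[lo : lo + batch_size]))
        crop = None
        if outs[0].crop is not None:
            crop = CropSpec(
                c=np.concatenate([o.crop.c for o in outs]),
                w=np.concatenate([o.crop.w for o in outs]),
                s=np.concatenate([o.crop.s for o in outs]),
                e=np.concatenate([o.crop.e for o in outs]),
                T=outs[0].crop.T,
            )
        mix = None
        if outs[0].updrs_mixture is not None:
            mix = GMMParams(
                alpha=np.concatenate([o.updrs_mixture.alpha for o in outs]),
                mu=np.concatenate([o.updrs_mixture.mu for o in outs]),
                sigma=np.concatenate([o.updrs_mixture.sigma for o in outs]),
            )
        return PredictionRecord(
            p_med=np.concatenate([o.p_med for o in outs]),
            p_fog=np.concatenate([o.p_fog for o in outs]),
            updrs_mixture=mix,
            updrs_point=np.concatenate([o.updrs_point for o in outs]),
            fog_entropy=np.concatenate([o.fog_entropy for o in outs]),
            crop=crop,
        )

    def _predict_batch(self, X: np.ndarray) -> PredictionRecord:
        feat, spec = self.features(X)
        med_logits, fog_logits = self.heads.classify_logits(feat)
        p_med = nn.softmax(med_logits, axis=-1).data.astype(np.float64)
        p_fog = nn.softmax(fog_logits, axis=-1).data.astype(np.float64)
        scaler = self.scaler or TargetScaler(mean=0.0, sd=1.0)
        if self.heads.regression == "gmm":
            mix = self.heads.gmm_params(feat)
            pt = point_estimate(mix, scaler)
        else:
            from .heads import _mlp_forward

            mix = None
            z = _mlp_forward(feat, self.heads.f_point).data[:, 0].astype(np.float64)
            pt = scaler.inverse(z)
        return PredictionRecord(
            p_med=p_med,
            p_fog=p_fog,
            updrs_mixture=mix,
            updrs_point=pt,
            fog_entropy=prediction_entropy(p_fog),
            crop=spec,
        )

    # ------------------------------------------------------------------ #
    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.params]

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        if len(state) != len(self.params):
            raise ValueError("state does not match model parameters")
        for p, s in zip(self.params, state):
            p.data = s.copy().astype(nn.DTYPE)

    def save(self, path) -> None:
        np.savez(
            path,
            **{f"p{i}": p.data for i, p in enumerate(self.params)},
            scaler=np.array(
                [self.scaler.mean, self.scaler.sd] if self.scaler else [0.0, 1.0]
            ),
        )

    def load(self, path) -> None:
        z = np.load(path)
        self.load_state_dict([z[f"p{i}"] for i in range(len(self.params))])
        mean, sd = z["scaler"]
        self.scaler = TargetScaler(mean=float(mean), sd=float(sd))
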