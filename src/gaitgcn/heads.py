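"""Multi-task prediction heads and the joint loss.

Three heads share the pooled 64-dimensional backbone feature:

* medication state — two-layer MLP (256, 128 units, ReLU) + 2-way
  softmax, binary cross-entropy;
* FOG score — same stack with a 5-way softmax, cross-entropy;
* MDS-UPDRS-III minus the FOG item — a Gaussian-mixture regression
  head.  Three projection stacks produce, per mixture component i,
  alpha = softmax(f_alpha(x)), mu = f_mu(x), sigma = exp(f_sigma(x)),
  and the loss is the negative log-likelihood of the z-scored target
  under p(y|x) = sum_i alpha_i N(mu_i, sigma_i^2), stabilized by
  log-sum-exp.  A plain MSE head is available as an ablation toggle.

Targets are z-scored with statistics of the training split only; point
predictions for RMSE are the mixture mean mapped back to the 0-120
scale (dominant-component mean available as an option).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn

LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class TargetScaler:
    """Z-scoring of the regression target, fitted on the training split."""

    mean: float
    sd: float

    def __post_init__(self):
        if self.sd <= 0:
            raise ValueError("target SD must be positive")

    @classmethod
    def fit(cls, y: np.ndarray) -> "TargetScaler":
        sd = float(np.std(y))
        return cls(mean=float(np.mean(y)), sd=sd if sd > 0 else 1.0)

    def transform(self, y):
        return (np.asarray(y, dtype=np.float64) - self.mean) / self.sd

    def inverse(self, z):
        return np.asarray(z, dtype=np.float64) * self.sd + self.mean


@dataclass
class GMMParams:
    """Mixture parameters on the z-score scale, one row per window."""

    alpha: np.ndarray  # (B, m) simplex
    mu: np.ndarray  # (B, m)
    sigma: np.ndarray  # (B, m) positive

    @property
    def m(self) -> int:
        return self.alpha.shape[-1]


def _mlp_params(rng, d_in, hidden, d_out, store, final_scale=1.0):
    """Two-layer head stack with optional down-scaling of the output layer
    (used so the mixture opens at mu ~ 0, sigma ~ 1 regardless of the
    backbone feature scale, instead of starting saturated)."""
    dims = [d_in, *hidden, d_out]
    layers = []
    for i, (a, b) in enumerate(zip(dims[:-1], dims[1:])):
        W = nn.Parameter(nn.he_init(rng, (a, b), a))
        if i == len(dims) - 2:
            W.data *= final_scale
        bb = nn.Parameter(np.zeros(b, dtype=nn.DTYPE))
        layers.append((W, bb))
        store += [W, bb]
    return layers


def _mlp_forward(x: nn.Tensor, layers) -> nn.Tensor:
    h = x
    for i, (W, b) in enumerate(layers):
        h = nn.linear(h, W, b)
        if i < len(layers) - 1:
            h = nn.relu(h)
    return h


class MultiTaskHeads:
    """Medication-state, FOG-score and severity-regression heads."""

    def __init__(
        self,
        d_in: int,
        rng: np.random.Generator,
        hidden: tuple = (256, 128),
        gmm_components: int = 3,
        regression: str = "gmm",
    ):
        if gmm_components < 1:
            raise ValueError("need at least one mixture component")
        if regression not in ("gmm", "mse"):
            raise ValueError("regression must be 'gmm' or 'mse'")
        self.m = gmm_components
        self.regression = regression
        self.params: list[nn.Parameter] = []
        self.med = _mlp_params(rng, d_in, hidden, 2, self.params)
        self.fog = _mlp_params(rng, d_in, hidden, 5, self.params)
        if regression == "gmm":
            self.f_alpha = _mlp_params(rng, d_in, hidden, self.m, self.params)
            self.f_mu = _mlp_params(rng, d_in, hidden, self.m, self.params,
                                    final_scale=0.01)
            self.f_sigma = _mlp_params(rng, d_in, hidden, self.m, self.params,
                                       final_scale=0.01)
        else:
            self.f_point = _mlp_params(rng, d_in, hidden, 1, self.params,
                                       final_scale=0.01)

    # ------------------------------------------------------------------ #
    def classify_logits(self, feat: nn.Tensor):
        return _mlp_forward(feat, self.med), _mlp_forward(feat, self.fog)

    def gmm_tensors(self, feat: nn.Tensor):
        """Return (log_alpha, mu, log_sigma) tensors, each (B, m)."""
        log_alpha = nn.log_softmax(_mlp_forward(feat, self.f_alpha), axis=-1)
        mu = _mlp_forward(feat, self.f_mu)
        log_sigma = nn.soft_bound(_mlp_forward(feat, self.f_sigma), -4.0, 4.0)
        return log_alpha, mu, log_sigma

    def gmm_params(self, feat: nn.Tensor) -> GMMParams:
        log_alpha, mu, log_sigma = self.gmm_tensors(feat)
        return GMMParams(
            alpha=np.exp(log_alpha.data.astype(np.float64)),
            mu=mu.data.astype(np.float64),
            sigma=np.exp(log_sigma.data.astype(np.float64)),
        )


# ---------------------------------------------------------------------- #
# losses (tensor-graph versions used in training)
# ---------------------------------------------------------------------- #
def cross_entropy(logits: nn.Tensor, y: np.ndarray) -> nn.Tensor:
    """Mean cross-entropy of integer labels under softmax(logits)."""
    B, K = logits.shape
    onehot = np.zeros((B, K), dtype=nn.DTYPE)
    onehot[np.arange(B), y] = 1.0
    logp = nn.log_softmax(logits, axis=-1)
    return -(logp * nn.Tensor(onehot)).sum() * (1.0 / B)


def gmm_nll_tensor(
    y_z: np.ndarray, log_alpha: nn.Tensor, mu: nn.Tensor, log_sigma: nn.Tensor
) -> nn.Tensor:
    """Mean negative log-likelihood of z-scored targets under the mixture."""
    yt = nn.Tensor(np.asarray(y_z, dtype=nn.DTYPE).reshape(-1, 1))
    inv_sigma = nn.exp(-log_sigma)
    z = (yt - mu) * inv_sigma
    comp = log_alpha - (z * z) * 0.5 - log_sigma - 0.5 * LOG_2PI
    return -(nn.logsumexp(comp, axis=-1).mean())


def mse_tensor(y_z: np.ndarray, pred: nn.Tensor) -> nn.Tensor:
    yt = nn.Tensor(np.asarray(y_z, dtype=nn.DTYPE).reshape(-1, 1))
    d = pred - yt
    return (d * d).mean()


def multitask_loss(
    heads: MultiTaskHeads,
    feat: nn.Tensor,
    med: np.ndarray,
    fog: np.ndarray,
    y_z: np.ndarray,
    weights: tuple = (1.0, 1.0, 1.0),
) -> nn.Tensor:
    """lambda1*BCE(med) + lambda2*CE(fog) + lambda3*NLL(updrs), batch-averaged.

    Zeroing a weight removes that task (single-task ablation hook); the
    corresponding head is then not evaluated at all.
    """
    l_med, l_fog, l_reg = weights
    med_logits, fog_logits = heads.classify_logits(feat)
    total = None

    def acc(term):
        nonlocal total
        total = term if total is None else total + term

    if l_med:
        acc(cross_entropy(med_logits, med) * float(l_med))
    if l_fog:
        acc(cross_entropy(fog_logits, fog) * float(l_fog))
    if l_reg:
        if heads.regression == "gmm":
            la, mu, ls = heads.gmm_tensors(feat)
            acc(gmm_nll_tensor(y_z, la, mu, ls) * float(l_reg))
        else:
            pred = _mlp_forward(feat, heads.f_point)
            acc(mse_tensor(y_z, pred) * float(l_reg))
    if total is None:
        raise ValueError("all task weights are zero")
    return total


# ---------------------------------------------------------------------- #
# numpy-side utilities (evaluation path)
# ---------------------------------------------------------------------- #
def gmm_nll(y_z: float | np.ndarray, params: GMMParams) -> float:
    """NLL of z-scored target(s) under the mixture (log-sum-exp stabilized)."""
    y = np.atleast_1d(np.asarray(y_z, dtype=np.float64)).reshape(-1, 1)
    z = (y - params.mu) / params.sigma
    comp = (
        np.log(params.alpha)
        - 0.5 * z**2
        - np.log(params.sigma)
        - 0.5 * LOG_2PI
    )
    m = comp.max(axis=-1, keepdims=True)
    logp = m.squeeze(-1) + np.log(np.exp(comp - m).sum(axis=-1))
    return float(np.mean(-logp))


def gmm_density(y_grid: np.ndarray, params: GMMParams, row: int = 0) -> np.ndarray:
    """Mixture density evaluated on a grid (for quadrature checks)."""
    a = params.alpha[row]
    mu = params.mu[row]
    sd = params.sigma[row]
    y = np.asarray(y_grid)[:, None]
    return (a / (sd * np.sqrt(2 * np.pi)) * np.exp(-0.5 * ((y - mu) / sd) ** 2)).sum(
        axis=1
    )


def point_estimate(
    params: GMMParams, scaler: TargetScaler, mode: str = "mean"
) -> np.ndarray:
    """Scalar severity prediction on the original 0-120 scale.

    mode 'mean': mixture mean sum_i alpha_i mu_i; mode 'dominant': mean
    of the highest-weight component.
    """
    if mode == "mean":
        z = (params.alpha * params.mu).sum(axis=-1)
    elif mode == "dominant":
        idx = params.alpha.argmax(axis=-1)
        z = params.mu[np.arange(len(idx)), idx]
    else:
        raise ValueError("mode must be 'mean' or 'dominant'")
    return scaler.inverse(z)


def prediction_entropy(probs: np.ndarray) -> np.ndarray:
    """Entropy (nats) of class prediction distributions, rows on a simplex."""
    p = np.clip(np.asarray(probs, dtype=np.float64), 1e-12, 1.0)
    return -(p * np.log(p)).sum(axis=-1)
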