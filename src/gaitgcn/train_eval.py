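"""Training loop, cross-validated evaluation, metrics, ablations and bias analysis.

Training follows the fixed protocol: Adam at learning rate 1e-3, batch
size 16, early stopping when the validation loss stops improving; the
best-validation weights are kept for testing.  Classification is scored
with per-class F1 and its macro mean (a 5-class mean for FOG score),
regression with RMSE on the 0-120 scale.  F1-type metrics carry 95%
Wilson score intervals with n = number of test windows; RMSE carries a
normal-approximation interval.  An ablation harness re-trains the model
family (TCN / GCN / AGCN / AT+AGCN / AT+AGCN+GMM) from configuration
toggles, optionally in single-task (FOG-only) mode, and a linear-model
bias analysis regresses per-subject F1 on study group, dichotomized age
(>= 69 years) and sex with Wald tests.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.metrics import precision_recall_fscore_support

from .data_model import FoldSplit, MED_STATES
from .heads import TargetScaler
from .model import FogScoreModel, ModelConfig, PredictionRecord
from .nn import Adam

logger = logging.getLogger("gaitgcn")

AGE_CUTOFF_YEARS = 69.0


# ---------------------------------------------------------------------- #
# configuration
# ---------------------------------------------------------------------- #
@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    batch_size: int = 16
    max_epochs: int = 100
    patience: int = 10
    max_grad_norm: float = 10.0  # global-norm clip guarding early steps
    seed: int = 0

    def __post_init__(self):
        if min(self.learning_rate, self.batch_size, self.max_epochs,
               self.patience) <= 0:
            raise ValueError("training hyperparameters must be positive")


def _clip_grad_norm(params, max_norm: float) -> None:
    total = np.sqrt(sum(float((p.grad.astype(np.float64) ** 2).sum())
                        for p in params if p.grad is not None))
    if total > max_norm > 0:
        scale = max_norm / total
        for p in params:
            if p.grad is not None:
                p.grad = p.grad * scale


# ---------------------------------------------------------------------- #
# metrics
# ---------------------------------------------------------------------- #
def per_class_f1(y_true, y_pred, n_classes: int):
    """Per-class precision/recall/F1 with fixed class set 0..n_classes-1.

    Classes absent from both truth and prediction contribute F1 = 0
    (conservative macro averaging).
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("empty label vectors")
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=np.arange(n_classes), zero_division=0
    )
    return prec, rec, f1


def mean_f1(y_true, y_pred, n_classes: int) -> float:
    """Macro mean of per-class F1 over the fixed class set."""
    _, _, f1 = per_class_f1(y_true, y_pred, n_classes)
    return float(f1.mean())


def rmse(y_true, y_pred) -> float:
    y_true = np.asarray(y_true, dtype=np.float64)
    y_pred = np.asarray(y_pred, dtype=np.float64)
    if y_true.size == 0:
        raise ValueError("empty input")
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch")
    return float(np.sqrt(np.mean((y_true - y_pred) ** 2)))


def wilson_ci(p_hat: float, n: int, z: float = 1.96) -> tuple[float, float]:
    """Wilson score interval for a proportion (95% at the default z).

    Computed in closed form so it accepts non-integer successes (F1
    values are treated as proportions of the n test windows); on exact
    binomial counts it coincides with
    `statsmodels.stats.proportion.proportion_confint(method="wilson")`.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= p_hat <= 1.0:
        raise ValueError("p_hat must be in [0, 1]")
    z2 = z * z
    denom = 1.0 + z2 / n
    center = (p_hat + z2 / (2 * n)) / denom
    half = z * np.sqrt(p_hat * (1 - p_hat) / n + z2 / (4 * n * n)) / denom
    return float(max(center - half, 0.0)), float(min(center + half, 1.0))


@dataclass
class MetricsReport:
    """Evaluation summary for one test split."""

    med_f1: float
    fog_f1_per_class: list[float]
    fog_mean_f1: float
    updrs_rmse: float
    n_windows: int
    med_f1_ci: tuple[float, float]
    fog_mean_f1_ci: tuple[float, float]
    updrs_rmse_ci: tuple[float, float]

    def to_dict(self) -> dict:
        return {
            "med_f1": self.med_f1,
            "fog_f1_per_class": list(self.fog_f1_per_class),
            "fog_mean_f1": self.fog_mean_f1,
            "updrs_rmse": self.updrs_rmse,
            "n_windows": self.n_windows,
            "med_f1_ci": list(self.med_f1_ci),
            "fog_mean_f1_ci": list(self.fog_mean_f1_ci),
            "updrs_rmse_ci": list(self.updrs_rmse_ci),
        }


def evaluate_predictions(
    pred: PredictionRecord, med, fog, updrs
) -> MetricsReport:
    """Score one prediction batch against its labels."""
    med = np.asarray(med)
    fog = np.asarray(fog)
    updrs = np.asarray(updrs, dtype=np.float64)
    n = len(med)
    med_hat = pred.p_med.argmax(axis=1)
    fog_hat = pred.p_fog.argmax(axis=1)
    m_f1 = mean_f1(med, med_hat, 2)
    _, _, fog_f1 = per_class_f1(fog, fog_hat, 5)
    f_f1 = float(fog_f1.mean())
    r = rmse(updrs, pred.updrs_point)
    err2 = (updrs - pred.updrs_point) ** 2
    half = 1.96 * np.std(err2) / np.sqrt(n) if n > 1 else 0.0
    rm_lo = float(np.sqrt(max(np.mean(err2) - half, 0.0)))
    rm_hi = float(np.sqrt(np.mean(err2) + half))
    return MetricsReport(
        med_f1=m_f1,
        fog_f1_per_class=[float(v) for v in fog_f1],
        fog_mean_f1=f_f1,
        updrs_rmse=r,
        n_windows=n,
        med_f1_ci=wilson_ci(m_f1, n),
        fog_mean_f1_ci=wilson_ci(f_f1, n),
        updrs_rmse_ci=(rm_lo, rm_hi),
    )


# ---------------------------------------------------------------------- #
# training
# ---------------------------------------------------------------------- #
def _plateau_floor(model: FogScoreModel) -> float:
    """Training loss of a model stuck at uniform/marginal predictions.

    Cross-entropy floors are ln2 and ln5; the regression floor is the
    NLL (~1.42) or MSE (=1) of z-scored targets under their marginal.
    """
    l_med, l_fog, l_reg = model.cfg.loss_weights
    reg_floor = 1.42 if model.heads.regression == "gmm" else 1.0
    return (l_med * float(np.log(2.0)) + l_fog * float(np.log(5.0))
            + l_reg * reg_floor)


# a run whose training loss is still at >88% of the uniform-prediction
# floor after this many epochs has failed to leave the chance plateau
# (typically a dead-feature collapse after an early loss spike) and will
# not recover; it is abandoned and re-initialized
PLATEAU_CHECK_EPOCH = 6
PLATEAU_FRACTION = 0.88


def train_model(
    model: FogScoreModel,
    X: np.ndarray,
    med: np.ndarray,
    fog: np.ndarray,
    updrs: np.ndarray,
    fold: FoldSplit,
    cfg: TrainConfig,
) -> dict:
    """Train on one fold, early-stopping on validation loss.

    Returns a history dict with per-epoch train/val losses and leaves
    the best-validation weights loaded in `model`.  If the run is still
    at the chance plateau after `PLATEAU_CHECK_EPOCH` epochs the history
    carries ``plateaued=True`` so the caller can re-initialize (see
    `run_fold`).
    """
    rng = np.random.default_rng(cfg.seed)
    tr, va = np.asarray(fold.train), np.asarray(fold.val)
    model.scaler = TargetScaler.fit(updrs[tr])
    opt = Adam(model.params, lr=cfg.learning_rate)
    best_val = np.inf
    best_state = model.state_dict()
    best_epoch = -1
    history = {"train_loss": [], "val_loss": [], "plateaued": False}
    plateau_bar = PLATEAU_FRACTION * _plateau_floor(model)
    t0 = time.time()
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(tr))
        losses = []
        for lo in range(0, len(order), cfg.batch_size):
            idx = tr[order[lo : lo + cfg.batch_size]]
            loss = model.loss(X[idx], med[idx], fog[idx], updrs[idx])
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch} (non-finite loss)"
                )
            opt.zero_grad()
            loss.backward()
            _clip_grad_norm(model.params, cfg.max_grad_norm)
            opt.step()
            losses.append(float(loss.data))
        val_losses = []
        for lo in range(0, len(va), cfg.batch_size):
            idx = va[lo : lo + cfg.batch_size]
            vloss = model.loss(X[idx], med[idx], fog[idx], updrs[idx])
            val_losses.append(float(vloss.data) * len(idx))
        val = float(np.sum(val_losses) / len(va))
        history["train_loss"].append(float(np.mean(losses)))
        history["val_loss"].append(val)
        logger.info(
            "epoch %d train %.4f val %.4f (%.1fs)",
            epoch, history["train_loss"][-1], val, time.time() - t0,
        )
        if val < best_val - 1e-6:
            best_val = val
            best_state = model.state_dict()
            best_epoch = epoch
        elif epoch - best_epoch >= cfg.patience:
            break
        if (epoch + 1 == PLATEAU_CHECK_EPOCH
                and cfg.max_epochs > PLATEAU_CHECK_EPOCH + 3
                and history["train_loss"][-1] > plateau_bar):
            logger.warning(
                "training stuck at the chance plateau (loss %.2f > %.2f) "
                "after %d epochs; abandoning this initialization",
                history["train_loss"][-1], plateau_bar, epoch + 1,
            )
            history["plateaued"] = True
            break
    model.load_state_dict(best_state)
    history["best_epoch"] = best_epoch
    history["best_val"] = best_val
    return history


def run_fold(
    model_cfg: ModelConfig,
    skeleton,
    X, med, fog, updrs,
    fold: FoldSplit,
    train_cfg: TrainConfig,
    max_restarts: int = 2,
):
    """Train on one fold and evaluate on its held-out test windows.

    An initialization whose training collapses onto the chance plateau
    (see `train_model`) is abandoned and re-drawn, up to `max_restarts`
    times — the same restart-on-failed-initialization policy used when
    fitting mixture models.
    """
    for attempt in range(max_restarts + 1):
        seed = train_cfg.seed + 7919 * attempt  # fresh init per attempt
        model = FogScoreModel(skeleton, X.shape[-1], model_cfg, seed=seed)
        cfg_a = TrainConfig(
            learning_rate=train_cfg.learning_rate,
            batch_size=train_cfg.batch_size,
            max_epochs=train_cfg.max_epochs,
            patience=train_cfg.patience,
            max_grad_norm=train_cfg.max_grad_norm,
            seed=seed,
        )
        history = train_model(model, X, med, fog, updrs, fold, cfg_a)
        if not history["plateaued"]:
            break
        logger.warning("re-initializing after plateaued attempt %d", attempt)
    te = np.asarray(fold.test)
    pred = model.predict(X[te])
    report = evaluate_predictions(pred, med[te], fog[te], updrs[te])
    return model, report, history


# ---------------------------------------------------------------------- #
# ablation harness
# ---------------------------------------------------------------------- #
MODEL_FAMILY = ("TCN", "GCN", "AGCN", "AT+AGCN", "AT+AGCN+GMM")


def family_config(name: str, base: ModelConfig | None = None) -> ModelConfig:
    """Model-family member as configuration toggles on the full model."""
    base = base or ModelConfig()
    kw = dict(
        n_layers=base.n_layers, feature_maps=base.feature_maps, kv=base.kv,
        kt=base.kt, embed_dim=base.embed_dim, crop_len=base.crop_len,
        gmm_components=base.gmm_components, head_hidden=base.head_hidden,
        loss_weights=base.loss_weights,
    )
    table = {
        "TCN": dict(at=False, graph="none", regression="mse"),
        "GCN": dict(at=False, graph="fixed", regression="mse"),
        "AGCN": dict(at=False, graph="adaptive", regression="mse"),
        "AT+AGCN": dict(at=True, graph="adaptive", regression="mse"),
        "AT+AGCN+GMM": dict(at=True, graph="adaptive", regression="gmm"),
    }
    if name not in table:
        raise ValueError(f"unknown model family member {name!r}")
    kw.update(table[name])
    return ModelConfig(**kw)


def ablation_harness(
    skeleton,
    X, med, fog, updrs,
    fold: FoldSplit,
    train_cfg: TrainConfig,
    family=MODEL_FAMILY,
    seeds=(0,),
    single_task: bool = False,
    base: ModelConfig | None = None,
) -> pd.DataFrame:
    """Re-train the model family and tabulate med F1 / fog mean F1 / RMSE.

    With `single_task=True` models are re-trained on FOG score only
    (loss weights (0,1,0)); the full GMM model is skipped there because
    without the regression task it coincides with AT+AGCN.
    """
    rows = []
    for name in family:
        if single_task and name == "AT+AGCN+GMM":
            continue
        cfg = family_config(name, base)
        if single_task:
            cfg.loss_weights = (0.0, 1.0, 0.0)
        for seed in seeds:
            tc = TrainConfig(
                learning_rate=train_cfg.learning_rate,
                batch_size=train_cfg.batch_size,
                max_epochs=train_cfg.max_epochs,
                patience=train_cfg.patience,
                seed=int(seed),
            )
            _, rep, _ = run_fold(cfg, skeleton, X, med, fog, updrs, fold, tc)
            rows.append(
                {
                    "model": name,
                    "seed": int(seed),
                    "single_task": single_task,
                    "med_f1": rep.med_f1 if not single_task else np.nan,
                    "fog_mean_f1": rep.fog_mean_f1,
                    "updrs_rmse": rep.updrs_rmse if not single_task else np.nan,
                    "med_f1_lo": rep.med_f1_ci[0],
                    "med_f1_hi": rep.med_f1_ci[1],
                    "fog_f1_lo": rep.fog_mean_f1_ci[0],
                    "fog_f1_hi": rep.fog_mean_f1_ci[1],
                    "n_windows": rep.n_windows,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "model", "seed", "single_task", "med_f1", "fog_mean_f1",
            "updrs_rmse", "med_f1_lo", "med_f1_hi", "fog_f1_lo", "fog_f1_hi",
            "n_windows",
        ],
    )


# ---------------------------------------------------------------------- #
# per-subject F1 and demographic bias
# ---------------------------------------------------------------------- #
def per_subject_f1(
    pred_fog: np.ndarray, fog: np.ndarray, subjects, meta: dict
) -> pd.DataFrame:
    """Mean F1 per subject, classes restricted to those the subject presents.

    `meta` maps subject id -> dict(group=..., age_years=..., sex=...).
    """
    subjects = np.asarray(subjects)
    rows = []
    for sid in sorted(set(subjects)):
        sel = subjects == sid
        present = np.unique(fog[sel])
        _, _, f1, _ = precision_recall_fscore_support(
            fog[sel], pred_fog[sel], labels=present, zero_division=0
        )
        info = meta[sid]
        rows.append(
            {
                "subject_id": sid,
                "f1": float(f1.mean()),
                "group": info["group"],
                "age_years": float(info["age_years"]),
                "sex": info["sex"],
            }
        )
    return pd.DataFrame(rows)


def bias_analysis(df: pd.DataFrame, age_cutoff: float = AGE_CUTOFF_YEARS):
    """OLS of per-subject F1 on group, dichotomized age and sex, with Wald tests.

    Returns (coefficient table DataFrame, fitted results).  Predictors
    with a single level (or collinear columns) are dropped with a
    warning.
    """
    work = df.copy()
    work["age_ge_cutoff"] = (work["age_years"] >= age_cutoff).astype(float)
    work["sex_M"] = (work["sex"] == "M").astype(float)
    cols = {}
    for g in sorted(work["group"].unique())[1:]:  # reference = first level
        cols[f"group[{g}]"] = (work["group"] == g).astype(float)
    cols["age_ge_cutoff"] = work["age_ge_cutoff"]
    cols["sex_M"] = work["sex_M"]
    Xd = pd.DataFrame(cols, index=work.index)
    keep = []
    for c in Xd.columns:
        if Xd[c].nunique() < 2:
            logger.warning("bias_analysis: dropping constant predictor %s", c)
            continue
        keep.append(c)
    Xd = Xd[keep]
    Xmat = sm.add_constant(Xd)
    if np.linalg.matrix_rank(Xmat.to_numpy()) < Xmat.shape[1]:
        # drop collinear columns one by one
        for c in list(Xd.columns):
            trial = sm.add_constant(Xd.drop(columns=c))
            if np.linalg.matrix_rank(trial.to_numpy()) == trial.shape[1]:
                logger.warning("bias_analysis: dropping collinear predictor %s", c)
                Xd = Xd.drop(columns=c)
                Xmat = trial
                break
    res = sm.OLS(work["f1"].to_numpy(), Xmat.to_numpy()).fit()
    pvals = np.asarray(res.pvalues, dtype=float)
    if np.ptp(work["f1"].to_numpy()) < 1e-12:
        # constant outcome: every effect is exactly zero and the Wald
        # statistic is 0/0 float noise; report no evidence of any effect
        pvals = np.where([t != "const" for t in Xmat.columns], 1.0, pvals)
    table = pd.DataFrame(
        {
            "term": list(Xmat.columns),
            "coef": res.params,
            "se": res.bse,
            "wald_p": pvals,
        }
    ).reset_index(drop=True)
    return table, res
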