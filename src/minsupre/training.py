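"""Risk estimators and training for pointwise classification from
pairwise-comparison data.

All estimators are built on the logistic loss l(z, y) = ln(1 + e^{-yz}).
With noisy-positive scores z_i (from D̃+) and noisy-negative scores z'_i
(from D̃-), the estimators are:

Binary-Biased     pooled mean of l(z,+1) over D̃+ and l(z',-1) over D̃-,
                  pretending the noisy sets are clean.
Pcomp-Unbiased    (1/n) Σ [l(z_i,+1) + l(z'_i,-1) − π+ l(z_i,-1)
                          − π- l(z'_i,+1)] — unbiased for the clean risk
                  but can go negative.
Pcomp-ReLU/ABS    the corrected form g(mean[l(z,+1) − π- l(z',+1)]) +
                  g(mean[l(z',-1) − π+ l(z,-1)]) with g = max(0,·) or |·|;
                  g = identity recovers Pcomp-Unbiased exactly.
Noisy-Unbiased    Natarajan-style loss correction with the contamination
                  rates (ρ+, ρ-) implied by the pairwise mixtures.
RankPruning       fit, prune the presumed-mislabeled fraction of each set
                  by rank, refit.
Pcomp-Teacher     RankPruning plus mean-teacher consistency: an EMA copy
                  of the scorer penalises disagreement on perturbed inputs.

Training follows a fixed protocol: Adam (lr 1e-3), mini-batches of 256
pairs (alignment of (s_i, s'_i) preserved within a batch), 50 epochs,
dropout 0.3 where the scorer uses it, a 15% development split, and the
best epoch selected by development F1.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np

from .corpus import Metrics, evaluate_predictions
from .weak import PriorConfig, derive_noise_rates

__all__ = [
    "LossConfig",
    "TrainConfig",
    "LinearScorer",
    "TrainedModel",
    "logistic_loss",
    "supervised_risk",
    "binary_biased_risk",
    "pcomp_unbiased_risk",
    "pcomp_corrected_risk",
    "noisy_unbiased_risk",
    "train",
    "fit",
    "rank_pruning_fit",
    "pcomp_teacher_fit",
    "TeacherConfig",
]

_METHODS = (
    "binary_biased",
    "noisy_unbiased",
    "rank_pruning",
    "pcomp_unbiased",
    "pcomp_relu",
    "pcomp_abs",
    "pcomp_teacher",
)


@dataclass(frozen=True)
class LossConfig:
    """Risk-estimator selection plus the class prior it needs."""

    method: str
    prior: PriorConfig = PriorConfig(0.5)
    correction: str = "identity"

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ValueError(f"unknown method {self.method!r}; choose from {_METHODS}")
        fixed = {"pcomp_relu": "relu", "pcomp_abs": "abs", "pcomp_unbiased": "identity"}
        if self.method in fixed and self.correction != fixed[self.method]:
            object.__setattr__(self, "correction", fixed[self.method])
        if self.correction not in ("relu", "abs", "identity"):
            raise ValueError(f"unknown correction {self.correction!r}")


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-3
    batch_size: int = 256
    epochs: int = 50
    dropout: float = 0.3
    dev_fraction: float = 0.15
    seed: int = 0
    selection_metric: str = "f1"

    def __post_init__(self) -> None:
        if not (0.0 < self.dev_fraction < 1.0):
            raise ValueError("dev_fraction must be in (0, 1)")
        if self.epochs < 0 or self.batch_size < 1:
            raise ValueError("epochs must be >= 0 and batch_size >= 1")


@dataclass(frozen=True)
class TeacherConfig:
    """Mean-teacher settings: EMA decay, consistency weight, perturbation σ."""

    ema_decay: float = 0.99
    consistency_weight: float = 1.0
    perturbation_scale: float = 0.1

    def __post_init__(self) -> None:
        if not (0.0 < self.ema_decay < 1.0):
            raise ValueError(f"ema_decay must be in (0, 1), got {self.ema_decay}")
        if self.consistency_weight < 0 or self.perturbation_scale < 0:
            raise ValueError("consistency_weight and perturbation_scale must be >= 0")


# ---------------------------------------------------------------- losses


def logistic_loss(z: np.ndarray | float, y: int) -> np.ndarray | float:
    """ln(1 + exp(-y z)), overflow-safe (equals softplus(-y z))."""
    if y not in (+1, -1):
        raise ValueError(f"y must be +1 or -1, got {y}")
    m = -y * np.asarray(z, dtype=float)
    # softplus(m) = max(m, 0) + log1p(exp(-|m|))
    out = np.maximum(m, 0.0) + np.log1p(np.exp(-np.abs(m)))
    return float(out) if np.isscalar(z) else out


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _dloss(z: np.ndarray, y: int) -> np.ndarray:
    """d/dz ln(1 + exp(-y z)) = -y σ(-y z)."""
    return -y * _sigmoid(-y * np.asarray(z, dtype=float))


# ---------------------------------------------------------------- risks


def supervised_risk(scores: np.ndarray, labels: np.ndarray) -> float:
    """Empirical classification risk: mean logistic loss over labeled data."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.size == 0:
        raise ValueError("empty input")
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    return float(np.mean(np.where(labels == 1, logistic_loss(scores, +1),
                                  logistic_loss(scores, -1))))


def binary_biased_risk(pos_scores: np.ndarray, neg_scores: np.ndarray) -> float:
    """Pooled mean loss treating the noisy sets as clean."""
    zp = np.asarray(pos_scores, dtype=float)
    zn = np.asarray(neg_scores, dtype=float)
    if zp.size == 0 or zn.size == 0:
        raise ValueError("both score sets must be non-empty")
    total = logistic_loss(zp, +1).sum() + logistic_loss(zn, -1).sum()
    return float(total / (zp.size + zn.size))


def pcomp_unbiased_risk(
    pos_scores: np.ndarray, neg_scores: np.ndarray, prior: PriorConfig
) -> float:
    """Unbiased pairwise-comparison risk estimator; may be negative."""
    zp = np.asarray(pos_scores, dtype=float)
    zn = np.asarray(neg_scores, dtype=float)
    if zp.size != zn.size or zp.size == 0:
        raise ValueError("paired score sets must be non-empty and equal-sized")
    pp, pm = prior.pi_plus, prior.pi_minus
    terms = (
        logistic_loss(zp, +1) + logistic_loss(zn, -1)
        - pp * logistic_loss(zp, -1) - pm * logistic_loss(zn, +1)
    )
    return float(terms.mean())


def _apply_g(x: float, g: str) -> float:
    if g == "relu":
        return max(x, 0.0)
    if g == "abs":
        return abs(x)
    if g == "identity":
        return x
    raise ValueError(f"unknown correction function {g!r}")


def pcomp_corrected_risk(
    pos_scores: np.ndarray, neg_scores: np.ndarray, prior: PriorConfig, g: str = "relu"
) -> float:
    """Correction-function variant; non-negative for g in {relu, abs} and
    identical to :func:`pcomp_unbiased_risk` for g = identity."""
    zp = np.asarray(pos_scores, dtype=float)
    zn = np.asarray(neg_scores, dtype=float)
    if zp.size != zn.size or zp.size == 0:
        raise ValueError("paired score sets must be non-empty and equal-sized")
    pp, pm = prior.pi_plus, prior.pi_minus
    bracket_pos = float((logistic_loss(zp, +1) - pm * logistic_loss(zn, +1)).mean())
    bracket_neg = float((logistic_loss(zn, -1) - pp * logistic_loss(zp, -1)).mean())
    return _apply_g(bracket_pos, g) + _apply_g(bracket_neg, g)


def noisy_unbiased_risk(
    pos_scores: np.ndarray,
    neg_scores: np.ndarray,
    prior: PriorConfig,
    *,
    noise_rates: Optional[tuple[float, float]] = None,
) -> float:
    """Natarajan-corrected pooled risk; the contamination rates default to
    the mixture-implied (ρ+, ρ-) but can be overridden (ρ = 0 recovers the
    plain binary risk)."""
    zp = np.asarray(pos_scores, dtype=float)
    zn = np.asarray(neg_scores, dtype=float)
    if zp.size == 0 or zn.size == 0:
        raise ValueError("both score sets must be non-empty")
    rho_p, rho_m = noise_rates if noise_rates is not None else derive_noise_rates(prior)
    denom = 1.0 - rho_p - rho_m
    if denom <= 0:
        raise ValueError(f"noise rates {rho_p:.3f} + {rho_m:.3f} >= 1: unidentifiable")
    lt_pos = ((1 - rho_m) * logistic_loss(zp, +1) - rho_p * logistic_loss(zp, -1)) / denom
    lt_neg = ((1 - rho_p) * logistic_loss(zn, -1) - rho_m * logistic_loss(zn, +1)) / denom
    return float((lt_pos.sum() + lt_neg.sum()) / (zp.size + zn.size))


def _risk_and_grads(
    method: str, zp: np.ndarray, zn: np.ndarray, prior: PriorConfig
) -> tuple[float, np.ndarray, np.ndarray]:
    """Risk value plus its gradients w.r.t. the two score vectors."""
    pp, pm = prior.pi_plus, prior.pi_minus
    n_p, n_n = zp.size, zn.size
    if method == "binary_biased":
        risk = binary_biased_risk(zp, zn)
        return risk, _dloss(zp, +1) / (n_p + n_n), _dloss(zn, -1) / (n_p + n_n)
    if method == "noisy_unbiased":
        rho_p, rho_m = derive_noise_rates(prior)
        denom = 1.0 - rho_p - rho_m
        risk = noisy_unbiased_risk(zp, zn, prior)
        gp = ((1 - rho_m) * _dloss(zp, +1) - rho_p * _dloss(zp, -1)) / denom / (n_p + n_n)
        gn = ((1 - rho_p) * _dloss(zn, -1) - rho_m * _dloss(zn, +1)) / denom / (n_p + n_n)
        return risk, gp, gn
    if method == "pcomp_unbiased":
        risk = pcomp_unbiased_risk(zp, zn, prior)
        gp = (_dloss(zp, +1) - pp * _dloss(zp, -1)) / n_p
        gn = (_dloss(zn, -1) - pm * _dloss(zn, +1)) / n_n
        return risk, gp, gn
    if method in ("pcomp_relu", "pcomp_abs"):
        g = "relu" if method == "pcomp_relu" else "abs"
        bracket_pos = float((logistic_loss(zp, +1) - pm * logistic_loss(zn, +1)).mean())
        bracket_neg = float((logistic_loss(zn, -1) - pp * logistic_loss(zp, -1)).mean())
        risk = _apply_g(bracket_pos, g) + _apply_g(bracket_neg, g)
        # subgradient of g at the bracket value
        def dg(x: float) -> float:
            if g == "relu":
                return 1.0 if x > 0 else 0.0
            return 1.0 if x >= 0 else -1.0
        dp, dn = dg(bracket_pos), dg(bracket_neg)
        gp = (dp * _dloss(zp, +1) - dn * pp * _dloss(zp, -1)) / n_p
        gn = (dn * _dloss(zn, -1) - dp * pm * _dloss(zn, +1)) / n_n
        return risk, gp, gn
    raise ValueError(f"method {method!r} has no per-batch risk gradient")


# ---------------------------------------------------------------- scorer


class LinearScorer:
    """Affine scorer z = w·x + b with optional inverted input dropout.

    This is the trainable surface when the encoder is frozen and features
    are precomputed pair representations (or raw synthetic features).
    """

    def __init__(self, dim: int, *, dropout_p: float = 0.0,
                 rng: Optional[np.random.Generator] = None):
        if not (0.0 <= dropout_p < 1.0):
            raise ValueError("dropout_p must be in [0, 1)")
        self.w = np.zeros(dim)
        self.b = 0.0
        self.dropout_p = dropout_p
        self._rng = rng or np.random.default_rng(0)

    def scores(self, X: np.ndarray, *, train: bool = False) -> tuple[np.ndarray, np.ndarray]:
        """Return (z, X_effective); X_effective feeds the backward pass."""
        X = np.asarray(X, dtype=float)
        if train and self.dropout_p > 0.0:
            mask = self._rng.random(X.shape) >= self.dropout_p
            X = X * mask / (1.0 - self.dropout_p)
        return X @ self.w + self.b, X

    def grads(self, X_eff: np.ndarray, dz: np.ndarray) -> tuple[np.ndarray, float]:
        return X_eff.T @ dz, float(dz.sum())

    def get_params(self) -> dict:
        return {"w": self.w.copy(), "b": self.b}

    def set_params(self, params: dict) -> None:
        self.w = np.asarray(params["w"], dtype=float).copy()
        self.b = float(params["b"])

    def predict(self, X: np.ndarray) -> np.ndarray:
        z, _ = self.scores(X, train=False)
        return np.where(z >= 0, 1, -1)


class _Adam:
    def __init__(self, shapes: dict, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(np.asarray(v, dtype=float)) for k, v in shapes.items()}
        self.v = {k: np.zeros_like(np.asarray(v, dtype=float)) for k, v in shapes.items()}

    def step(self, params: dict, grads: dict) -> dict:
        self.t += 1
        out = {}
        for k in params:
            g = np.asarray(grads[k], dtype=float)
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            out[k] = params[k] - self.lr * mhat / (np.sqrt(vhat) + self.eps)
        return out


@dataclass
class TrainedModel:
    """A fitted scorer plus its per-epoch history and best-epoch snapshot."""

    params: dict
    best_params: dict
    best_epoch: int
    history: list[dict]
    loss_cfg: LossConfig
    train_cfg: TrainConfig
    extras: dict = field(default_factory=dict)

    def predict(self, X: np.ndarray) -> np.ndarray:
        w = np.asarray(self.best_params["w"], dtype=float)
        b = float(self.best_params["b"])
        return np.where(np.asarray(X, dtype=float) @ w + b >= 0, 1, -1)

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        w = np.asarray(self.best_params["w"], dtype=float)
        return np.asarray(X, dtype=float) @ w + float(self.best_params["b"])


# ---------------------------------------------------------------- training


def _dev_metric(model: LinearScorer, Xp: np.ndarray, Xn: np.ndarray,
                metric: str) -> float:
    pred = np.concatenate([model.predict(Xp), model.predict(Xn)])
    gold = np.concatenate([np.ones(len(Xp), dtype=int), -np.ones(len(Xn), dtype=int)])
    m = evaluate_predictions(pred.tolist(), gold.tolist())
    if metric == "f1":
        return m.f1
    if metric == "accuracy":
        return (m.tp + m.tn) / m.n
    raise ValueError(f"unknown selection metric {metric!r}")


def train(
    X_pos: np.ndarray,
    X_neg: np.ndarray,
    loss_cfg: LossConfig,
    train_cfg: TrainConfig = TrainConfig(),
    *,
    model: Optional[LinearScorer] = None,
) -> TrainedModel:
    """Minimize the selected empirical risk with Adam.

    ``X_pos``/``X_neg`` are the feature matrices of D̃+ and D̃-; for the
    pairwise estimators row i of each is the pair (s_i, s'_i) and batches
    keep that alignment.  Development data (15% of pairs by default) is
    held out for best-epoch selection against the noisy labels.
    """
    Xp = np.asarray(X_pos, dtype=float)
    Xn = np.asarray(X_neg, dtype=float)
    if Xp.ndim != 2 or Xn.ndim != 2 or Xp.shape[1] != Xn.shape[1]:
        raise ValueError("feature matrices must be 2-D with equal width")
    paired = loss_cfg.method in ("pcomp_unbiased", "pcomp_relu", "pcomp_abs")
    if paired and Xp.shape[0] != Xn.shape[0]:
        raise ValueError("pairwise estimators need equal-sized, aligned sets")
    if loss_cfg.method in ("rank_pruning", "pcomp_teacher"):
        raise ValueError(f"use the dedicated fit function for {loss_cfg.method!r}")

    rng = np.random.default_rng(train_cfg.seed)
    if model is None:
        model = LinearScorer(Xp.shape[1], dropout_p=0.0, rng=rng)

    # dev split over pairs (aligned) or over each set independently
    def split(X: np.ndarray, perm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        n_dev = max(1, int(round(train_cfg.dev_fraction * len(X)))) if len(X) > 1 else 0
        return X[perm[n_dev:]], X[perm[:n_dev]]

    if paired:
        perm = rng.permutation(Xp.shape[0])
        Xp_tr, Xp_dev = split(Xp, perm)
        Xn_tr, Xn_dev = split(Xn, perm)
    else:
        Xp_tr, Xp_dev = split(Xp, rng.permutation(Xp.shape[0]))
        Xn_tr, Xn_dev = split(Xn, rng.permutation(Xn.shape[0]))

    opt = _Adam(model.get_params(), lr=train_cfg.learning_rate)
    history: list[dict] = []
    best_metric, best_epoch = -math.inf, -1
    best_params = copy.deepcopy(model.get_params())
    init_params = copy.deepcopy(model.get_params())

    n_pairs_tr = Xp_tr.shape[0]
    for epoch in range(train_cfg.epochs):
        order_p = rng.permutation(n_pairs_tr)
        order_n = order_p if paired else rng.permutation(Xn_tr.shape[0])
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, n_pairs_tr, train_cfg.batch_size):
            bi = order_p[start : start + train_cfg.batch_size]
            bj = order_n[start : start + train_cfg.batch_size] if not paired else bi
            if bi.size == 0 or bj.size == 0:
                continue
            zp, Xp_eff = model.scores(Xp_tr[bi], train=True)
            zn, Xn_eff = model.scores(Xn_tr[bj], train=True)
            risk, gzp, gzn = _risk_and_grads(loss_cfg.method, zp, zn, loss_cfg.prior)
            if not np.isfinite(risk):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: method={loss_cfg.method}, "
                    f"|w|={np.linalg.norm(model.w):.3g}"
                )
            gw_p, gb_p = model.grads(Xp_eff, gzp)
            gw_n, gb_n = model.grads(Xn_eff, gzn)
            params = model.get_params()
            params = opt.step(params, {"w": gw_p + gw_n, "b": gb_p + gb_n})
            model.set_params(params)
            epoch_loss += risk
            n_batches += 1
        dev_val = (
            _dev_metric(model, Xp_dev, Xn_dev, train_cfg.selection_metric)
            if len(Xp_dev) and len(Xn_dev)
            else -epoch_loss / max(n_batches, 1)
        )
        history.append(
            {"epoch": epoch, "train_loss": epoch_loss / max(n_batches, 1), "dev_metric": dev_val}
        )
        if dev_val > best_metric:
            best_metric, best_epoch = dev_val, epoch
            best_params = copy.deepcopy(model.get_params())

    if train_cfg.epochs == 0:
        best_params, best_epoch = init_params, -1
    return TrainedModel(
        params=model.get_params(),
        best_params=best_params,
        best_epoch=best_epoch,
        history=history,
        loss_cfg=loss_cfg,
        train_cfg=train_cfg,
    )


def rank_pruning_fit(
    X_pos: np.ndarray,
    X_neg: np.ndarray,
    prior: PriorConfig,
    train_cfg: TrainConfig = TrainConfig(),
    *,
    noise_rates: Optional[tuple[float, float]] = None,
) -> TrainedModel:
    """Two-phase noisy-label fit: rank, prune the presumed contaminants,
    refit with the plain binary loss.

    The pruning fractions default to the mixture-implied (ρ+, ρ-):  the
    ρ+ fraction of D̃+ with the lowest preliminary scores and the ρ-
    fraction of D̃- with the highest are dropped before refitting.
    """
    Xp = np.asarray(X_pos, dtype=float)
    Xn = np.asarray(X_neg, dtype=float)
    rho_p, rho_m = noise_rates if noise_rates is not None else derive_noise_rates(prior)
    if rho_p >= 1.0 or rho_m >= 1.0:
        raise ValueError("pruning fraction must be < 1")
    phase1 = train(Xp, Xn, LossConfig("binary_biased", prior), train_cfg)
    zp = phase1.decision_scores(Xp)
    zn = phase1.decision_scores(Xn)
    k_p = int(round(rho_p * len(zp)))
    k_m = int(round(rho_m * len(zn)))
    keep_p = np.argsort(zp)[k_p:] if k_p else np.arange(len(zp))
    keep_n = np.argsort(zn)[: len(zn) - k_m] if k_m else np.arange(len(zn))
    cfg2 = replace(train_cfg, seed=train_cfg.seed + 1)
    phase2 = train(Xp[keep_p], Xn[keep_n], LossConfig("binary_biased", prior), cfg2)
    phase2.loss_cfg = LossConfig("rank_pruning", prior)
    phase2.extras = {
        "pruned_pos": np.setdiff1d(np.arange(len(zp)), keep_p),
        "pruned_neg": np.setdiff1d(np.arange(len(zn)), keep_n),
        "phase1_history": phase1.history,
    }
    return phase2


def pcomp_teacher_fit(
    X_pos: np.ndarray,
    X_neg: np.ndarray,
    prior: PriorConfig,
    train_cfg: TrainConfig = TrainConfig(),
    teacher_cfg: TeacherConfig = TeacherConfig(),
) -> TrainedModel:
    """RankPruning-style fit with mean-teacher consistency regularization.

    After pruning, the refit objective adds λ · mean[(f_s(x+ε) − f_t(x+ε))²]
    over Gaussian input perturbations ε, where f_t's parameters track f_s
    as an exponential moving average after every optimizer step.
    """
    Xp = np.asarray(X_pos, dtype=float)
    Xn = np.asarray(X_neg, dtype=float)
    rho_p, rho_m = derive_noise_rates(prior)
    phase1 = train(Xp, Xn, LossConfig("binary_biased", prior), train_cfg)
    zp = phase1.decision_scores(Xp)
    zn = phase1.decision_scores(Xn)
    k_p = int(round(rho_p * len(zp)))
    k_m = int(round(rho_m * len(zn)))
    keep_p = np.argsort(zp)[k_p:] if k_p else np.arange(len(zp))
    keep_n = np.argsort(zn)[: len(zn) - k_m] if k_m else np.arange(len(zn))
    Xp_k, Xn_k = Xp[keep_p], Xn[keep_n]

    rng = np.random.default_rng(train_cfg.seed + 1)
    model = LinearScorer(Xp.shape[1], rng=rng)
    teacher = {"w": model.w.copy(), "b": model.b}
    opt = _Adam(model.get_params(), lr=train_cfg.learning_rate)

    n_dev_p = max(1, int(round(train_cfg.dev_fraction * len(Xp_k))))
    n_dev_n = max(1, int(round(train_cfg.dev_fraction * len(Xn_k))))
    pp = rng.permutation(len(Xp_k))
    pn = rng.permutation(len(Xn_k))
    Xp_tr, Xp_dev = Xp_k[pp[n_dev_p:]], Xp_k[pp[:n_dev_p]]
    Xn_tr, Xn_dev = Xn_k[pn[n_dev_n:]], Xn_k[pn[:n_dev_n]]

    history: list[dict] = []
    best_metric, best_epoch = -math.inf, -1
    best_params = copy.deepcopy(model.get_params())
    lam = teacher_cfg.consistency_weight
    sig = teacher_cfg.perturbation_scale

    for epoch in range(train_cfg.epochs):
        order_p = rng.permutation(len(Xp_tr))
        order_n = rng.permutation(len(Xn_tr))
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, len(Xp_tr), train_cfg.batch_size):
            bi = order_p[start : start + train_cfg.batch_size]
            bj = order_n[start : start + train_cfg.batch_size]
            if bi.size == 0 or bj.size == 0:
                continue
            Xb = np.vstack([Xp_tr[bi], Xn_tr[bj]])
            zp, _ = model.scores(Xp_tr[bi])
            zn, _ = model.scores(Xn_tr[bj])
            risk, gzp, gzn = _risk_and_grads("binary_biased", zp, zn, prior)
            gw, gb = model.grads(Xp_tr[bi], gzp)
            gw2, gb2 = model.grads(Xn_tr[bj], gzn)
            gw, gb = gw + gw2, gb + gb2
            if lam > 0:
                Xpert = Xb + (sig * rng.standard_normal(Xb.shape) if sig > 0 else 0.0)
                zs = Xpert @ model.w + model.b
                zt = Xpert @ teacher["w"] + teacher["b"]
                diff = zs - zt
                risk += lam * float(np.mean(diff**2))
                dz = lam * 2.0 * diff / diff.size
                gw += Xpert.T @ dz
                gb += float(dz.sum())
            params = opt.step(model.get_params(), {"w": gw, "b": gb})
            model.set_params(params)
            a = teacher_cfg.ema_decay
            teacher["w"] = a * teacher["w"] + (1 - a) * model.w
            teacher["b"] = a * teacher["b"] + (1 - a) * model.b
            epoch_loss += risk
            n_batches += 1
        dev_val = _dev_metric(model, Xp_dev, Xn_dev, train_cfg.selection_metric)
        history.append(
            {"epoch": epoch, "train_loss": epoch_loss / max(n_batches, 1), "dev_metric": dev_val}
        )
        if dev_val > best_metric:
            best_metric, best_epoch = dev_val, epoch
            best_params = copy.deepcopy(model.get_params())

    return TrainedModel(
        params=model.get_params(),
        best_params=best_params,
        best_epoch=best_epoch,
        history=history,
        loss_cfg=LossConfig("pcomp_teacher", prior),
        train_cfg=train_cfg,
        extras={"teacher": teacher, "phase1_history": phase1.history},
    )


def fit(
    X_pos: np.ndarray,
    X_neg: np.ndarray,
    loss_cfg: LossConfig,
    train_cfg: TrainConfig = TrainConfig(),
    teacher_cfg: TeacherConfig = TeacherConfig(),
) -> TrainedModel:
    """Dispatch to the right trainer for any of the seven methods."""
    if loss_cfg.method == "rank_pruning":
        return rank_pruning_fit(X_pos, X_neg, loss_cfg.prior, train_cfg)
    if loss_cfg.method == "pcomp_teacher":
        return pcomp_teacher_fit(X_pos, X_neg, loss_cfg.prior, train_cfg, teacher_cfg)
    return train(X_pos, X_neg, loss_cfg, train_cfg)
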