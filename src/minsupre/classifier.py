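"""Entity-pair scorer: pooled entity embeddings → normalized, dropped-out
concatenation → affine score.

The encoder is treated as a frozen black box: this module consumes
precomputed hidden states (n_tokens × d) plus the subtoken spans of the
two entities.  Each entity is average-pooled, the two vectors are
concatenated into r ∈ R^{2d}, batch-normalized, passed through inverted
dropout (train mode only) and scored as y = w·r + b.  The predicted label
is sign(y) with y = 0 mapped to +1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "HiddenStates",
    "BatchNormState",
    "PairClassifierParams",
    "pool_entity",
    "pair_representation",
    "pair_score",
    "score_batch",
    "predict_label",
]


@dataclass(frozen=True)
class HiddenStates:
    """Last-layer token embeddings with the two entity subtoken spans."""

    H: np.ndarray
    span_e1: tuple[int, int]
    span_e2: tuple[int, int]

    def __post_init__(self) -> None:
        H = np.asarray(self.H, dtype=float)
        object.__setattr__(self, "H", H)
        if H.ndim != 2 or H.shape[0] < 1 or H.shape[1] < 1:
            raise ValueError(f"H must be n×d with n,d >= 1, got shape {H.shape}")
        for name, (s, e) in (("e1", self.span_e1), ("e2", self.span_e2)):
            if not (0 <= s < e <= H.shape[0]):
                raise ValueError(f"{name} span [{s}, {e}) invalid for n={H.shape[0]}")

    @property
    def d(self) -> int:
        return self.H.shape[1]


@dataclass
class BatchNormState:
    """Scale/shift plus running moments for 1-D batch normalization.

    At train time moments come from the batch (and the running moments are
    updated); at eval time the running moments are used.  ``identity=True``
    bypasses normalization entirely.
    """

    gamma: np.ndarray
    beta: np.ndarray
    running_mean: np.ndarray
    running_var: np.ndarray
    momentum: float = 0.1
    eps: float = 1e-5
    identity: bool = False

    @classmethod
    def create(cls, dim: int, *, identity: bool = False) -> "BatchNormState":
        return cls(
            gamma=np.ones(dim),
            beta=np.zeros(dim),
            running_mean=np.zeros(dim),
            running_var=np.ones(dim),
            identity=identity,
        )

    def apply(self, R: np.ndarray, *, train: bool) -> np.ndarray:
        if self.identity:
            return R
        if train:
            mean = R.mean(axis=0)
            var = R.var(axis=0)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        return self.gamma * (R - mean) / np.sqrt(var + self.eps) + self.beta


@dataclass
class PairClassifierParams:
    """Affine head over the normalized pair representation."""

    w_l: np.ndarray
    b_l: float = 0.0
    dropout_p: float = 0.3
    norm: Optional[BatchNormState] = None
    mode: str = "eval"

    def __post_init__(self) -> None:
        self.w_l = np.asarray(self.w_l, dtype=float)
        if self.w_l.ndim != 1:
            raise ValueError("w_l must be a vector")
        if not (0.0 <= self.dropout_p < 1.0):
            raise ValueError(f"dropout_p must be in [0, 1), got {self.dropout_p}")
        if self.mode not in ("train", "eval"):
            raise ValueError(f"mode must be 'train' or 'eval', got {self.mode!r}")

    @classmethod
    def create(cls, d: int, *, dropout_p: float = 0.3, identity_norm: bool = False,
               mode: str = "eval", rng: Optional[np.random.Generator] = None) -> "PairClassifierParams":
        rng = rng or np.random.default_rng(0)
        w = rng.normal(scale=1.0 / np.sqrt(2 * d), size=2 * d)
        return cls(w_l=w, b_l=0.0, dropout_p=dropout_p,
                   norm=BatchNormState.create(2 * d, identity=identity_norm), mode=mode)


def pool_entity(hidden: HiddenStates, which: str) -> np.ndarray:
    """Average-pool the hidden states of one entity's subtokens."""
    if which not in ("e1", "e2"):
        raise ValueError(f"which must be 'e1' or 'e2', got {which!r}")
    s, e = hidden.span_e1 if which == "e1" else hidden.span_e2
    return hidden.H[s:e].mean(axis=0)


def pair_representation(hidden: HiddenStates) -> np.ndarray:
    """Concatenation of the two pooled entity vectors (length 2d)."""
    return np.concatenate([pool_entity(hidden, "e1"), pool_entity(hidden, "e2")])


def _dropout(R: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    # inverted dropout: kept units are scaled by 1/(1-p) so eval needs no rescale
    mask = rng.random(R.shape) >= p
    return R * mask / (1.0 - p)


def pair_score(
    hidden: HiddenStates,
    params: PairClassifierParams,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Score one entity pair; deterministic in eval mode."""
    r = pair_representation(hidden)
    if params.w_l.size != r.size:
        raise ValueError(f"w_l has length {params.w_l.size}, representation has {r.size}")
    train = params.mode == "train"
    if params.norm is not None:
        r = params.norm.apply(r[None, :], train=train)[0]
    if train and params.dropout_p > 0.0:
        if rng is None:
            raise ValueError("train-mode scoring with dropout needs an rng")
        r = _dropout(r, params.dropout_p, rng)
    return float(params.w_l @ r + params.b_l)


def score_batch(
    batch: Sequence[HiddenStates],
    params: PairClassifierParams,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Score a batch; batch-norm moments come from the batch in train mode."""
    R = np.stack([pair_representation(h) for h in batch])
    if params.w_l.size != R.shape[1]:
        raise ValueError(f"w_l has length {params.w_l.size}, representation has {R.shape[1]}")
    train = params.mode == "train"
    if params.norm is not None:
        R = params.norm.apply(R, train=train)
    if train and params.dropout_p > 0.0:
        if rng is None:
            raise ValueError("train-mode scoring with dropout needs an rng")
        R = _dropout(R, params.dropout_p, rng)
    return R @ params.w_l + params.b_l


def predict_label(score: float) -> int:
    """sign(score) with the deterministic tie rule score == 0 → +1."""
    return +1 if score >= 0 else -1
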