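"""Attention-based unsupervised relation detectors.

Given the head-averaged self-attention matrix ``A`` of one encoder layer,
the localized context distribution for an entity pair (e1, e2) is

    L = (a_e1 ∘ a_e2) / (a_e1 · a_e2)

where a_e is the mean of the attention rows of the entity's subtokens and
∘ is the Hadamard product.  L is a probability vector over sentence
positions; its shape is the detectors' only input:

PicMI     thresholds max(L) — a single dominant token signals a relation.
PicMI-Up  thresholds the entities' own attention to L's argmax token.
ConEx     thresholds KL(L ‖ U) against the uniform distribution U —
          any divergence from uniform attention counts as signal.

All detectors predict +1 when the score is >= the threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Protocol, Sequence

import numpy as np

__all__ = [
    "AttentionMatrix",
    "LocalizedContextDistribution",
    "AttnThreshold",
    "EncoderAdapter",
    "entity_attention",
    "localized_context",
    "kl_to_uniform",
    "picmi_predict",
    "picmi_up_predict",
    "conex_predict",
]

_ROW_TOL = 1e-6


@dataclass(frozen=True)
class AttentionMatrix:
    """Row-stochastic n×n head-averaged attention of one encoder layer."""

    A: np.ndarray
    layer_id: int = 0

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=float)
        object.__setattr__(self, "A", A)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError(f"attention must be square, got shape {A.shape}")
        if np.any(A < 0):
            raise ValueError("attention entries must be non-negative")
        rowsums = A.sum(axis=1)
        if np.any(np.abs(rowsums - 1.0) > _ROW_TOL):
            worst = float(np.max(np.abs(rowsums - 1.0)))
            raise ValueError(f"attention rows must sum to 1 (max deviation {worst:.2e})")

    @property
    def n(self) -> int:
        return self.A.shape[0]


@dataclass(frozen=True)
class LocalizedContextDistribution:
    """Per-token relevance vector for an entity pair; a probability vector.

    ``degenerate`` is set when the two entity attention vectors had zero
    overlap and the distribution fell back to uniform.
    """

    L: np.ndarray
    degenerate: bool = False

    def __post_init__(self) -> None:
        L = np.asarray(self.L, dtype=float)
        object.__setattr__(self, "L", L)
        if L.ndim != 1 or L.size == 0:
            raise ValueError("L must be a non-empty vector")
        if np.any(L < -1e-12) or np.any(L > 1 + 1e-12):
            raise ValueError("L entries must lie in [0, 1]")
        if abs(float(L.sum()) - 1.0) > 1e-9:
            raise ValueError(f"L must sum to 1, got {float(L.sum())!r}")

    @property
    def n(self) -> int:
        return self.L.size


@dataclass(frozen=True)
class AttnThreshold:
    """Decision threshold for the attention detectors (score >= t → +1)."""

    t: float

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValueError(f"threshold must be >= 0, got {self.t}")


class EncoderAdapter(Protocol):
    """Contract a transformer-encoder plug-in must satisfy.

    ``encode(tokens, layer_id)`` returns ``(subtokens, span_map, H, attn)``
    where ``span_map`` maps a corpus token span ``(start, end)`` to the
    corresponding subtoken span, ``H`` is the n×d hidden-state matrix of the
    requested layer and ``attn`` the head-averaged :class:`AttentionMatrix`.
    Whether special boundary tokens are kept is the adapter's documented
    choice; the bundled synthetic encoder excludes them.
    """

    def encode(
        self, tokens: Sequence[str], layer_id: int
    ) -> tuple[list[str], dict[tuple[int, int], tuple[int, int]], np.ndarray, AttentionMatrix]:
        ...


def entity_attention(attn: AttentionMatrix, span: tuple[int, int]) -> np.ndarray:
    """Collective attention of an entity: the mean of its subtoken rows."""
    start, end = span
    if not (0 <= start < end <= attn.n):
        raise ValueError(f"span [{start}, {end}) invalid for n={attn.n}")
    return attn.A[start:end].mean(axis=0)


def localized_context(a1: np.ndarray, a2: np.ndarray) -> LocalizedContextDistribution:
    """Normalized Hadamard product of two entity attention vectors.

    When the vectors share no mass (dot product 0) the distribution is
    undefined; we fall back to uniform, flag it, and warn — downstream
    detectors then see no signal.
    """
    a1 = np.asarray(a1, dtype=float)
    a2 = np.asarray(a2, dtype=float)
    if a1.shape != a2.shape or a1.ndim != 1:
        raise ValueError(f"shape mismatch: {a1.shape} vs {a2.shape}")
    prod = a1 * a2
    denom = float(prod.sum())  # == a1 · a2
    if denom <= 0.0:
        warnings.warn("entity attention vectors have zero overlap; using uniform distribution")
        n = a1.size
        return LocalizedContextDistribution(L=np.full(n, 1.0 / n), degenerate=True)
    return LocalizedContextDistribution(L=prod / denom)


def kl_to_uniform(dist: LocalizedContextDistribution) -> float:
    """KL(L ‖ U) in nats: ln(n) minus the Shannon entropy of L.

    Finite for sparse L (0·ln 0 := 0); zero iff L is uniform.
    """
    L = dist.L
    nz = L[L > 0]
    entropy = float(-(nz * np.log(nz)).sum())
    return max(float(np.log(L.size)) - entropy, 0.0)


def picmi_predict(dist: LocalizedContextDistribution, t: AttnThreshold | float) -> int:
    """+1 iff the largest localized-context weight reaches the threshold."""
    t = t.t if isinstance(t, AttnThreshold) else float(t)
    return +1 if float(dist.L.max()) >= t else -1


def picmi_up_predict(
    attn: AttentionMatrix,
    span1: tuple[int, int],
    span2: tuple[int, int],
    t: AttnThreshold | float,
) -> int:
    """+1 iff the entities' mean attention to L's argmax token reaches ``t``.

    Ties in the argmax resolve to the lowest index; a degenerate L (uniform
    fallback) therefore scores token 0 rather than raising.
    """
    t = t.t if isinstance(t, AttnThreshold) else float(t)
    a1 = entity_attention(attn, span1)
    a2 = entity_attention(attn, span2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dist = localized_context(a1, a2)
    idx = int(np.argmax(dist.L))  # np.argmax takes the first maximum
    score = 0.5 * (float(a1[idx]) + float(a2[idx]))
    return +1 if score >= t else -1


def conex_predict(dist: LocalizedContextDistribution, t: AttnThreshold | float) -> int:
    """+1 iff KL(L ‖ uniform) reaches the threshold."""
    t = t.t if isinstance(t, AttnThreshold) else float(t)
    return +1 if kl_to_uniform(dist) >= t else -1
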