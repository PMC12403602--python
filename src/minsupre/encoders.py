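"""Encoder adapters.

The detectors and the pair classifier consume hidden states and attention
matrices through the :class:`~minsupre.attention.EncoderAdapter` contract,
never a transformer library directly, so every algorithm is testable
without model downloads.  This module ships one adapter: a seeded
random-weights "tiny encoder" (synthetic — it has no trained linguistic
knowledge) that produces well-formed hidden states and row-stochastic
head-averaged attention for any token sequence.  Real transformer
encoders plug in by implementing the same ``encode`` signature.
"""

from __future__ import annotations

import zlib
from typing import Sequence

import numpy as np

from .attention import AttentionMatrix

__all__ = ["TinyRandomEncoder"]


class TinyRandomEncoder:
    """Synthetic stand-alone encoder fixture implementing the adapter contract.

    Token "subword" splitting is simulated by splitting on hyphens, so
    multi-subtoken entity spans exercise the span map.  Hidden states and
    attention are deterministic functions of (vocabulary hash, seed,
    layer_id); attention rows are softmax-normalized and head-averaged
    over ``n_heads`` random heads.  Special boundary tokens are excluded.
    """

    def __init__(self, d: int = 16, n_layers: int = 12, n_heads: int = 4, seed: int = 0):
        self.d = d
        self.n_layers = n_layers
        self.n_heads = n_heads
        self.seed = seed

    def _token_vec(self, sub: str, rng_salt: int) -> np.ndarray:
        key = f"{sub}|{self.seed}|{rng_salt}".encode()
        h = zlib.crc32(key)  # stable across processes, unlike hash()
        return np.random.default_rng(h).standard_normal(self.d)

    def encode(
        self, tokens: Sequence[str], layer_id: int
    ) -> tuple[list[str], dict[tuple[int, int], tuple[int, int]], np.ndarray, AttentionMatrix]:
        if not (0 <= layer_id < self.n_layers):
            raise ValueError(f"layer_id {layer_id} outside [0, {self.n_layers})")
        subtokens: list[str] = []
        span_map: dict[tuple[int, int], tuple[int, int]] = {}
        starts: list[int] = []
        for tok in tokens:
            starts.append(len(subtokens))
            subtokens.extend(tok.split("-") or [tok])
        starts.append(len(subtokens))
        for i in range(len(tokens)):
            for j in range(i + 1, len(tokens) + 1):
                span_map[(i, j)] = (starts[i], starts[j])
        H = np.stack([self._token_vec(s, layer_id) for s in subtokens])
        n = len(subtokens)
        rng = np.random.default_rng((self.seed, layer_id, n))
        heads = []
        for _ in range(self.n_heads):
            logits = (H @ rng.standard_normal((self.d, self.d)) @ H.T) / np.sqrt(self.d)
            logits -= logits.max(axis=1, keepdims=True)
            P = np.exp(logits)
            heads.append(P / P.sum(axis=1, keepdims=True))
        A = np.mean(heads, axis=0)
        A = A / A.sum(axis=1, keepdims=True)
        return subtokens, span_map, H, AttentionMatrix(A=A, layer_id=layer_id)
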