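"""Pairwise-comparison weak supervision: data generation and mixture theory.

A labeler (gold labels, or silver labels from an unsupervised detector)
accepts an ordered pair of instances (s, s') when their labels (y, y')
fall in {(+1,-1), (+1,+1), (-1,-1)} — i.e. s is at least as likely
positive as s'.  Accepted pairs split into a noisy-positive set D̃+ (the
first elements) and a noisy-negative set D̃- (the second elements).  With
i.i.d. labels at class prior π+ the acceptance probability is

    π̃ = π+² + π-

and the pointwise sets are mixtures of the clean class-conditionals:

    p̃+(s)  = [π+ p+(s)  + π-² p-(s)]  / (π-² + π+)
    p̃-(s') = [π+² p+(s') + π-  p-(s')] / (π+² + π-)

These mixture weights drive the noise rates used by the noisy-label risk
estimators and the pruning fractions of RankPruning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = [
    "PriorConfig",
    "LabelerSpec",
    "PairwiseDataset",
    "PointwiseWeakDataset",
    "pair_is_valid",
    "draw_pairs",
    "generate_pairwise",
    "split_pointwise",
    "mixture_weights",
    "estimate_prior_from_acceptance",
    "derive_noise_rates",
]


@dataclass(frozen=True)
class PriorConfig:
    """Positive class prior π+ (and its complement π-)."""

    pi_plus: float

    def __post_init__(self) -> None:
        if not (0.0 < self.pi_plus < 1.0):
            raise ValueError(f"pi_plus must be in (0, 1), got {self.pi_plus}")

    @property
    def pi_minus(self) -> float:
        return 1.0 - self.pi_plus


@dataclass(frozen=True)
class LabelerSpec:
    """How the pair labeler obtains its labels.

    ``gold`` uses annotated labels (weak supervision); the silver modes use
    an unsupervised detector's predictions (no supervision at all).
    ``config`` carries the detector configuration (a SardConfig, or a
    ConEx layer/threshold pair) and is opaque to this module.
    """

    mode: str = "gold"
    config: object = None

    _MODES = ("gold", "silver_sard", "silver_conex")

    def __post_init__(self) -> None:
        if self.mode not in self._MODES:
            raise ValueError(f"mode must be one of {self._MODES}, got {self.mode!r}")


@dataclass(frozen=True)
class PairwiseDataset:
    """Accepted ordered pairs of instance ids plus sampling statistics."""

    pairs: tuple[tuple[str, str], ...]
    pairs_sampled: int
    pairs_accepted: int
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.pairs_accepted != len(self.pairs):
            raise ValueError("pairs_accepted must equal len(pairs)")
        if self.pairs_sampled < self.pairs_accepted:
            raise ValueError("sampled count cannot be below accepted count")

    @property
    def acceptance_rate(self) -> float:
        return self.pairs_accepted / self.pairs_sampled if self.pairs_sampled else 0.0


@dataclass(frozen=True)
class PointwiseWeakDataset:
    """The noisy-positive / noisy-negative id sets from a pairwise split."""

    d_plus: tuple[str, ...]
    d_minus: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.d_plus) != len(self.d_minus):
            raise ValueError("d_plus and d_minus must have equal size")


def pair_is_valid(y: int, y_prime: int) -> bool:
    """Whether an ordered pair with labels (y, y') is a valid comparison.

    Valid: (+1,-1), (+1,+1), (-1,-1).  Invalid: (-1,+1) — the second
    instance would be more likely positive than the first.
    """
    for v in (y, y_prime):
        if v not in (+1, -1):
            raise ValueError(f"labels must be +1 or -1, got {v}")
    return not (y == -1 and y_prime == +1)


def _as_labels(labels: Sequence[int]) -> np.ndarray:
    arr = np.asarray(labels, dtype=int)
    if arr.size == 0:
        raise ValueError("empty label sequence")
    if not np.all(np.isin(arr, (-1, 1))):
        raise ValueError("labels must be +1 or -1")
    return arr


def draw_pairs(
    ids: Sequence[str],
    labels: Sequence[int],
    n_draws: int,
    seed: int | np.random.Generator,
) -> PairwiseDataset:
    """Draw exactly ``n_draws`` ordered pairs (uniform, with replacement)
    and keep the valid ones.  Used to measure the acceptance rate."""
    labels_arr = _as_labels(labels)
    if len(ids) != labels_arr.size:
        raise ValueError("ids and labels must align")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ii = rng.integers(0, len(ids), size=n_draws)
    jj = rng.integers(0, len(ids), size=n_draws)
    keep = ~((labels_arr[ii] == -1) & (labels_arr[jj] == +1))
    pairs = tuple((ids[int(i)], ids[int(j)]) for i, j in zip(ii[keep], jj[keep]))
    return PairwiseDataset(
        pairs=pairs,
        pairs_sampled=n_draws,
        pairs_accepted=len(pairs),
        seed=seed if isinstance(seed, int) else None,
    )


def generate_pairwise(
    ids: Sequence[str],
    labels: Sequence[int],
    n_pairs: int,
    seed: int,
    *,
    max_draws: Optional[int] = None,
) -> PairwiseDataset:
    """Sample ordered pairs with replacement until ``n_pairs`` are accepted.

    ``labels`` are whatever the labeler sees — gold labels for GoDaG,
    cached silver labels for SoDaG; validity follows :func:`pair_is_valid`.
    ``max_draws`` (default ``100 * n_pairs + 10_000``) guards against a
    corpus with no valid pairs.
    """
    if n_pairs <= 0:
        raise ValueError("n_pairs must be positive")
    labels_arr = _as_labels(labels)
    if len(ids) != labels_arr.size:
        raise ValueError("ids and labels must align")
    if max_draws is None:
        max_draws = 100 * n_pairs + 10_000
    rng = np.random.default_rng(seed)
    accepted: list[tuple[str, str]] = []
    sampled = 0
    chunk = max(1024, n_pairs)
    while len(accepted) < n_pairs:
        if sampled >= max_draws:
            raise RuntimeError(
                f"accepted only {len(accepted)}/{n_pairs} pairs after {sampled} draws; "
                "the corpus may admit too few valid comparisons"
            )
        m = min(chunk, max_draws - sampled)
        ii = rng.integers(0, len(ids), size=m)
        jj = rng.integers(0, len(ids), size=m)
        sampled += m
        keep = np.nonzero(~((labels_arr[ii] == -1) & (labels_arr[jj] == +1)))[0]
        need = n_pairs - len(accepted)
        if keep.size > need:
            # only the draws up to the last accepted pair count as sampled
            sampled -= m - (int(keep[need - 1]) + 1)
            keep = keep[:need]
        accepted.extend((ids[int(ii[k])], ids[int(jj[k])]) for k in keep)
    return PairwiseDataset(
        pairs=tuple(accepted[:n_pairs]),
        pairs_sampled=sampled,
        pairs_accepted=n_pairs,
        seed=seed,
    )


def split_pointwise(pairs: PairwiseDataset) -> PointwiseWeakDataset:
    """First elements become the noisy-positive set, second the noisy-negative."""
    if not pairs.pairs:
        raise ValueError("empty pairwise dataset")
    return PointwiseWeakDataset(
        d_plus=tuple(p for p, _ in pairs.pairs),
        d_minus=tuple(q for _, q in pairs.pairs),
    )


def mixture_weights(prior: PriorConfig) -> tuple[float, float, float, float]:
    """Mixture weights (w⁺₊, w⁺₋, w⁻₊, w⁻₋) of the pointwise densities.

    w⁺₊/w⁺₋ are the true-positive/true-negative fractions of D̃+, and
    w⁻₊/w⁻₋ those of D̃-.
    """
    pp, pm = prior.pi_plus, prior.pi_minus
    denom_plus = pm**2 + pp
    denom_minus = pp**2 + pm
    return (pp / denom_plus, pm**2 / denom_plus, pp**2 / denom_minus, pm / denom_minus)


def estimate_prior_from_acceptance(pi_tilde_hat: float, dominant: str = "positive") -> float:
    """Invert the acceptance law π̃ = π+² + 1 − π+ for π+.

    The law is symmetric around π+ = 0.5, so ``dominant`` picks the branch:
    ``"positive"`` returns the root above 0.5, ``"negative"`` below.
    """
    if dominant not in ("positive", "negative"):
        raise ValueError(f"dominant must be 'positive' or 'negative', got {dominant!r}")
    if not (0.75 - 1e-12 <= pi_tilde_hat <= 1.0 + 1e-12):
        raise ValueError(
            f"acceptance rate {pi_tilde_hat} inconsistent with the pairwise model "
            "(pi**2 + 1 - pi has minimum 0.75)"
        )
    disc = max(4.0 * pi_tilde_hat - 3.0, 0.0)
    root = math.sqrt(disc)
    return (1.0 + root) / 2.0 if dominant == "positive" else (1.0 - root) / 2.0


def derive_noise_rates(prior: PriorConfig) -> tuple[float, float]:
    """Contamination fractions (ρ+, ρ-) of the noisy sets.

    ρ+ is the true-negative fraction of D̃+, ρ- the true-positive fraction
    of D̃-; both follow from the mixture weights.
    """
    _, w_plus_neg, w_minus_pos, _ = mixture_weights(prior)
    return (w_plus_neg, w_minus_pos)
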