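"""Seeded synthetic-data generators for every input the detectors and
trainers consume.

Three generators cover the three signal channels:

* :func:`gen_parse_corpus` — sentences with constructively built
  dependency trees whose SDP-level structure (verb on path, root on path,
  direct entity link, conjunction on path) is sampled per label from
  configurable conditional probabilities, so the expected behaviour of the
  dependency detector is computable in closed form.
* :func:`gen_attention_corpus` — row-stochastic attention matrices where
  related pairs plant a shared "trigger-token" peak in both entity rows
  and unrelated pairs stay near-uniform (symmetric-Dirichlet background).
* :func:`gen_feature_corpus` — two spherical class-conditional Gaussians
  with a configurable class prior; the Bayes accuracy of the configuration
  is reported in closed form.

Every generator is a pure function of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm

from .attention import AttentionMatrix
from .corpus import EntitySpan, RelationInstance
from .dependency import DependencyParse

__all__ = [
    "ParseGenConfig",
    "AttnGenConfig",
    "FeatureGenConfig",
    "ParseRecord",
    "AttnRecord",
    "FeatureCorpus",
    "build_parse_fixture",
    "random_tree",
    "bayes_accuracy",
    "gen_parse_corpus",
    "gen_attention_corpus",
    "gen_feature_corpus",
]

_FLAG_NAMES = ("root_on_sdp", "root_is_verb", "verb_on_sdp", "direct_link", "conj_on_sdp")


# ------------------------------------------------------------- parse data


@dataclass(frozen=True)
class ParseGenConfig:
    """Structural-flag probabilities per label for the parse generator.

    Each ``p_*`` entry maps label (+1/-1) to the probability that the flag
    is set for an instance of that label.  The defaults make related pairs
    syntactically connected (verb on the SDP, few conjunctions) and
    unrelated pairs the opposite — the regularity the SDP assumptions
    exploit.
    """

    n: int = 100
    pi_plus: float = 0.5
    p_verb_on_sdp: dict = field(default_factory=lambda: {+1: 0.9, -1: 0.2})
    p_root_on_sdp: dict = field(default_factory=lambda: {+1: 0.8, -1: 0.4})
    p_root_is_verb: dict = field(default_factory=lambda: {+1: 0.8, -1: 0.5})
    p_direct_link: dict = field(default_factory=lambda: {+1: 0.2, -1: 0.05})
    p_conj_on_sdp: dict = field(default_factory=lambda: {+1: 0.1, -1: 0.5})
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.pi_plus < 1.0):
            raise ValueError("pi_plus must be in (0, 1)")
        for name in ("p_verb_on_sdp", "p_root_on_sdp", "p_root_is_verb",
                     "p_direct_link", "p_conj_on_sdp"):
            probs = getattr(self, name)
            for y in (+1, -1):
                if not (0.0 <= probs[y] <= 1.0):
                    raise ValueError(f"{name}[{y}] must be a probability")


@dataclass(frozen=True)
class ParseRecord:
    instance: RelationInstance
    parse: DependencyParse
    flags: dict


def build_parse_fixture(
    root_on_sdp: bool,
    root_is_verb: bool,
    verb_on_sdp: bool,
    direct_link: bool,
    conj_on_sdp: bool,
    *,
    instance_id: str = "fix",
) -> ParseRecord:
    """Construct a parse realizing exactly the requested SDP structure.

    ``verb_on_sdp`` requests a *non-root* verb on the path; the root's own
    verbhood is ``root_is_verb``.  With a direct entity link the path has
    only the two entity tokens, so the combination (root on path, root is
    verb, extra verb, conjunction) cannot be realized — it is rejected with
    an error naming the flags.
    """
    if direct_link:
        if root_on_sdp and root_is_verb and verb_on_sdp and conj_on_sdp:
            raise ValueError(
                "infeasible flag combination (root_on_sdp, root_is_verb, verb_on_sdp, "
                "direct_link, conj_on_sdp) = (True, True, True, True, True): a two-node "
                "path cannot host a verb root, a second verb and a conjunction"
            )
        if root_on_sdp:
            # e1 (token 0) is the root, e2 (token 1) hangs off it
            head = [-1, 0]
            upos = ["VERB" if root_is_verb else "NOUN", "NOUN"]
            if verb_on_sdp and conj_on_sdp:
                upos = ["CCONJ", "VERB"]  # root not a verb here (checked above)
            elif verb_on_sdp:
                upos[1] = "VERB"
            elif conj_on_sdp:
                upos[1] = "CCONJ"
            e1_idx, e2_idx = 0, 1
        else:
            # off-path root (token 2) dominates e1; e2 hangs off e1
            head = [2, 0, -1]
            upos = ["NOUN", "NOUN", "VERB" if root_is_verb else "NOUN"]
            if verb_on_sdp:
                upos[0] = "VERB"
            if conj_on_sdp:
                upos[1] = "CCONJ"
            e1_idx, e2_idx = 0, 1
    else:
        # chain e1(0) - 1 - apex(2) - 3 - e2(4); apex is the root when on path
        head = [1, 2, -1, 2, 3]
        upos = ["NOUN", "NOUN", "NOUN", "NOUN", "NOUN"]
        if root_on_sdp:
            upos[2] = "VERB" if root_is_verb else "NOUN"
        else:
            head = [1, 2, 5, 2, 3, -1]
            upos.append("VERB" if root_is_verb else "NOUN")
        if verb_on_sdp:
            upos[1] = "VERB"
        if conj_on_sdp:
            upos[3] = "CCONJ"
        e1_idx, e2_idx = 0, 4

    tokens = tuple(f"w{i}" for i in range(len(head)))
    inst = RelationInstance(
        id=instance_id,
        tokens=tokens,
        e1=EntitySpan(e1_idx, e1_idx + 1, tokens[e1_idx]),
        e2=EntitySpan(e2_idx, e2_idx + 1, tokens[e2_idx]),
    )
    parse = DependencyParse(head=tuple(head), upos=tuple(upos))
    flags = dict(zip(_FLAG_NAMES, (root_on_sdp, root_is_verb, verb_on_sdp,
                                   direct_link, conj_on_sdp)))
    return ParseRecord(instance=inst, parse=parse, flags=flags)


def gen_parse_corpus(cfg: ParseGenConfig) -> list[ParseRecord]:
    """Sample a labeled parse corpus from the structural-flag model.

    The single infeasible flag combination (see :func:`build_parse_fixture`)
    is resolved by clearing the redundant non-root-verb flag — the derived
    SDP predicates are unchanged — and the resolved flags are recorded.
    """
    rng = np.random.default_rng(cfg.seed)
    records: list[ParseRecord] = []
    for i in range(cfg.n):
        y = +1 if rng.random() < cfg.pi_plus else -1
        flags = {
            "root_on_sdp": rng.random() < cfg.p_root_on_sdp[y],
            "root_is_verb": rng.random() < cfg.p_root_is_verb[y],
            "verb_on_sdp": rng.random() < cfg.p_verb_on_sdp[y],
            "direct_link": rng.random() < cfg.p_direct_link[y],
            "conj_on_sdp": rng.random() < cfg.p_conj_on_sdp[y],
        }
        if all(flags.values()):
            flags["verb_on_sdp"] = False  # predicate-equivalent resolution
        rec = build_parse_fixture(**flags, instance_id=f"p{i}")
        inst = RelationInstance(
            id=rec.instance.id,
            tokens=rec.instance.tokens,
            e1=rec.instance.e1,
            e2=rec.instance.e2,
            gold_label=y,
        )
        records.append(ParseRecord(instance=inst, parse=rec.parse, flags=rec.flags))
    return records


def random_tree(n: int, rng: np.random.Generator) -> DependencyParse:
    """A uniform-ish random rooted tree over n tokens (for path oracles)."""
    if n < 1:
        raise ValueError("need at least one token")
    order = rng.permutation(n)
    head = [0] * n
    head[order[0]] = -1
    for k in range(1, n):
        head[order[k]] = int(order[rng.integers(0, k)])
    upos = tuple(rng.choice(["NOUN", "VERB", "ADJ", "CCONJ"]) for _ in range(n))
    return DependencyParse(head=tuple(head), upos=upos)


# --------------------------------------------------------- attention data


@dataclass(frozen=True)
class AttnGenConfig:
    """Planted-peak attention generator.

    Related pairs (y=+1) place ``kappa`` of each entity row's mass on one
    shared trigger token with probability ``peak_prob_pos`` (otherwise the
    row stays background); unrelated pairs peak with probability
    ``peak_prob_neg``.  Background rows are symmetric Dirichlet with
    concentration ``background_conc`` (``exact_uniform`` replaces them with
    the exact uniform distribution, for null tests).
    """

    n: int = 100
    pi_plus: float = 0.5
    kappa: float = 0.6
    peak_prob_pos: float = 1.0
    peak_prob_neg: float = 0.0
    background_conc: float = 200.0
    exact_uniform: bool = False
    length_range: tuple[int, int] = (8, 16)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.kappa <= 1.0):
            raise ValueError("kappa must be in [0, 1]")
        if not (0.0 < self.pi_plus < 1.0):
            raise ValueError("pi_plus must be in (0, 1)")
        lo, hi = self.length_range
        if lo < 3 or hi < lo:
            raise ValueError("length range needs at least 3 tokens (two entities + context)")


@dataclass(frozen=True)
class AttnRecord:
    instance: RelationInstance
    attention: AttentionMatrix
    span_e1: tuple[int, int]
    span_e2: tuple[int, int]
    trigger: int
    peaked: bool


def gen_attention_corpus(
    cfg: AttnGenConfig, labels: Optional[Sequence[int]] = None
) -> list[AttnRecord]:
    """Sample a labeled attention corpus with planted relational peaks.

    ``labels`` overrides the sampled gold labels (used to couple this
    corpus to a feature corpus over the same instances).
    """
    rng = np.random.default_rng(cfg.seed)
    if labels is not None and len(labels) != cfg.n:
        raise ValueError("labels must have length cfg.n")
    records: list[AttnRecord] = []
    lo, hi = cfg.length_range
    for i in range(cfg.n):
        y = int(labels[i]) if labels is not None else (+1 if rng.random() < cfg.pi_plus else -1)
        n_tok = int(rng.integers(lo, hi + 1))
        e1_idx = 0
        e2_idx = n_tok - 1
        trigger = int(rng.integers(1, n_tok - 1))  # a non-entity position

        def background() -> np.ndarray:
            if cfg.exact_uniform:
                return np.full(n_tok, 1.0 / n_tok)
            return rng.dirichlet(np.full(n_tok, cfg.background_conc))

        A = np.stack([background() for _ in range(n_tok)])
        p_peak = cfg.peak_prob_pos if y == +1 else cfg.peak_prob_neg
        peaked = bool(rng.random() < p_peak) and cfg.kappa > 0
        if peaked:
            for row in (e1_idx, e2_idx):
                base = background()
                vec = (1.0 - cfg.kappa) * base
                vec[trigger] += cfg.kappa
                A[row] = vec
        A = A / A.sum(axis=1, keepdims=True)  # exact row-stochasticity
        tokens = tuple(f"t{j}" for j in range(n_tok))
        inst = RelationInstance(
            id=f"a{i}",
            tokens=tokens,
            e1=EntitySpan(e1_idx, e1_idx + 1, tokens[e1_idx]),
            e2=EntitySpan(e2_idx, e2_idx + 1, tokens[e2_idx]),
            gold_label=y,
        )
        records.append(
            AttnRecord(
                instance=inst,
                attention=AttentionMatrix(A=A, layer_id=10),
                span_e1=(e1_idx, e1_idx + 1),
                span_e2=(e2_idx, e2_idx + 1),
                trigger=trigger,
                peaked=peaked,
            )
        )
    return records


# ----------------------------------------------------------- feature data


@dataclass(frozen=True)
class FeatureGenConfig:
    """Two spherical Gaussian class-conditionals with prior ``pi_plus``."""

    n: int = 1000
    pi_plus: float = 0.5
    mu_plus: tuple[float, ...] = (2.0, 0.0)
    mu_minus: tuple[float, ...] = (-2.0, 0.0)
    sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if len(self.mu_plus) != len(self.mu_minus):
            raise ValueError("class means must share a dimension")
        if not (0.0 < self.pi_plus < 1.0):
            raise ValueError("pi_plus must be in (0, 1)")

    @property
    def dim(self) -> int:
        return len(self.mu_plus)


@dataclass(frozen=True)
class FeatureCorpus:
    X: np.ndarray
    y: np.ndarray
    bayes_accuracy: float
    config: FeatureGenConfig


def bayes_accuracy(cfg: FeatureGenConfig) -> float:
    """Closed-form Bayes accuracy for equal spherical covariances.

    With Δ = |μ+ − μ-|/σ and c = ln(π-/π+)/Δ the optimal rule errs with
    probability π+ Φ(−Δ/2 − c·sign...) — concretely
    err = π+ Φ(−Δ/2 + c) + π- Φ(−Δ/2 − c); for π+ = 0.5 this is Φ(−Δ/2).
    """
    mu_p = np.asarray(cfg.mu_plus, dtype=float)
    mu_m = np.asarray(cfg.mu_minus, dtype=float)
    delta = float(np.linalg.norm(mu_p - mu_m)) / cfg.sigma
    if delta == 0.0:
        return max(cfg.pi_plus, 1.0 - cfg.pi_plus)
    c = math.log((1.0 - cfg.pi_plus) / cfg.pi_plus) / delta
    err = cfg.pi_plus * norm.cdf(-delta / 2.0 + c) + (1.0 - cfg.pi_plus) * norm.cdf(
        -delta / 2.0 - c
    )
    return 1.0 - float(err)


def gen_feature_corpus(
    cfg: FeatureGenConfig, labels: Optional[Sequence[int]] = None
) -> FeatureCorpus:
    """Sample labeled feature vectors; Bayes accuracy reported in closed form."""
    rng = np.random.default_rng(cfg.seed)
    if labels is not None:
        y = np.asarray(labels, dtype=int)
        if y.size != cfg.n:
            raise ValueError("labels must have length cfg.n")
    else:
        y = np.where(rng.random(cfg.n) < cfg.pi_plus, 1, -1)
    mu_p = np.asarray(cfg.mu_plus, dtype=float)
    mu_m = np.asarray(cfg.mu_minus, dtype=float)
    X = rng.standard_normal((cfg.n, cfg.dim)) * cfg.sigma
    X += np.where((y == 1)[:, None], mu_p, mu_m)
    return FeatureCorpus(X=X, y=y, bayes_accuracy=bayes_accuracy(cfg), config=cfg)
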