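"""Experiment orchestration: threshold sweeps and weak-supervision runs.

The sweep grids default to the detectors' standard ranges — PicMI
[0.30, 0.70] and PicMI-Up [0.20, 0.60] in steps of 0.05, ConEx
[0.05, 0.14] in steps of 0.01 — and every report row is reproducible from
the recorded configuration and seed.  Weak-supervision experiments train
one model per (method, class prior, seed) cell on pairs generated from a
pool that is structurally guaranteed to be disjoint from the test split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .attention import (
    AttnThreshold,
    conex_predict,
    entity_attention,
    kl_to_uniform,
    localized_context,
    picmi_predict,
    picmi_up_predict,
)
from .corpus import Metrics, evaluate_predictions
from .dependency import SardConfig, sard_predict
from .synthetic import AttnRecord, ParseRecord
from .training import LossConfig, TeacherConfig, TrainConfig, fit
from .weak import LabelerSpec, PriorConfig, generate_pairwise, split_pointwise

__all__ = [
    "SweepSpec",
    "ExperimentReport",
    "DEFAULT_GRIDS",
    "attention_scores",
    "attention_predict",
    "sard_labels",
    "conex_labels",
    "threshold_sweep",
    "run_weaksup_experiment",
]

DEFAULT_GRIDS = {
    "picmi": np.round(np.arange(0.30, 0.70 + 1e-9, 0.05), 2),
    "picmi_up": np.round(np.arange(0.20, 0.60 + 1e-9, 0.05), 2),
    "conex": np.round(np.arange(0.05, 0.14 + 1e-9, 0.01), 2),
}

_METHODS = ("picmi", "picmi_up", "conex")


@dataclass(frozen=True)
class SweepSpec:
    """A detector plus the threshold grid to sweep it over."""

    method: str
    grid: tuple[float, ...] = ()
    layer_id: int = 10

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ValueError(f"method must be one of {_METHODS}, got {self.method!r}")
        grid = tuple(self.grid) or tuple(float(t) for t in DEFAULT_GRIDS[self.method])
        if not grid:
            raise ValueError("empty threshold grid")
        object.__setattr__(self, "grid", grid)


@dataclass
class ExperimentReport:
    """A tidy table of per-configuration metrics plus provenance."""

    rows: list[dict]
    provenance: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def attention_scores(records: Sequence[AttnRecord], method: str) -> np.ndarray:
    """Detector score per instance (the quantity each detector thresholds)."""
    scores = np.empty(len(records))
    for k, rec in enumerate(records):
        a1 = entity_attention(rec.attention, rec.span_e1)
        a2 = entity_attention(rec.attention, rec.span_e2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dist = localized_context(a1, a2)
        if method == "picmi":
            scores[k] = float(dist.L.max())
        elif method == "conex":
            scores[k] = kl_to_uniform(dist)
        elif method == "picmi_up":
            idx = int(np.argmax(dist.L))
            scores[k] = 0.5 * (float(a1[idx]) + float(a2[idx]))
        else:
            raise ValueError(f"unknown method {method!r}")
    return scores


def attention_predict(records: Sequence[AttnRecord], method: str, t: float) -> np.ndarray:
    """±1 predictions of one attention detector at threshold ``t``."""
    if method == "picmi_up":
        return np.array(
            [picmi_up_predict(r.attention, r.span_e1, r.span_e2, t) for r in records]
        )
    preds = np.empty(len(records), dtype=int)
    for k, rec in enumerate(records):
        a1 = entity_attention(rec.attention, rec.span_e1)
        a2 = entity_attention(rec.attention, rec.span_e2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dist = localized_context(a1, a2)
        preds[k] = picmi_predict(dist, t) if method == "picmi" else conex_predict(dist, t)
    return preds


def sard_labels(records: Sequence[ParseRecord], cfg: SardConfig = SardConfig()) -> np.ndarray:
    """Silver labels from the dependency detector, one per parse record."""
    return np.array(
        [sard_predict(r.parse, r.instance.e1, r.instance.e2, cfg) for r in records]
    )


def conex_labels(records: Sequence[AttnRecord], threshold: float) -> np.ndarray:
    """Silver labels from ConEx at a fixed threshold."""
    return attention_predict(records, "conex", threshold)


def threshold_sweep(records: Sequence[AttnRecord], spec: SweepSpec) -> ExperimentReport:
    """One metrics row per grid threshold, ordered by threshold.

    Because every detector predicts +1 exactly when its score reaches the
    threshold, the predicted-positive set shrinks as t grows and recall is
    non-increasing down the table.
    """
    gold = [r.instance.gold_label for r in records]
    if any(g is None for g in gold):
        raise ValueError("threshold_sweep needs gold labels on every record")
    scores = attention_scores(records, spec.method)
    rows = []
    for t in spec.grid:
        pred = np.where(scores >= t, 1, -1)
        m = evaluate_predictions(pred.tolist(), gold)
        rows.append(
            {
                "method": spec.method,
                "threshold": float(t),
                "precision": m.precision,
                "recall": m.recall,
                "f1": m.f1,
                "tp": m.tp, "fp": m.fp, "fn": m.fn, "tn": m.tn,
            }
        )
    return ExperimentReport(
        rows=rows, provenance={"spec": spec, "n_instances": len(records)}
    )


def run_weaksup_experiment(
    X: np.ndarray,
    gold: np.ndarray,
    labeler_labels: np.ndarray,
    test_idx: np.ndarray,
    methods: Sequence[str],
    pi_grid: Sequence[float] = (0.3, 0.4, 0.5, 0.6),
    seeds: Sequence[int] = (0, 1, 2, 3, 4),
    n_pairs: int = 2000,
    train_cfg: TrainConfig = TrainConfig(),
) -> ExperimentReport:
    """Generate pairs, split pointwise, train, and score on held-out data.

    ``labeler_labels`` are what the pair labeler sees (gold for GoDaG,
    silver for SoDaG); evaluation always uses ``gold`` on ``test_idx``.
    Pairs are drawn only from the complement of ``test_idx``; any overlap
    between the pair pool and the test split is a hard error.
    """
    X = np.asarray(X, dtype=float)
    gold = np.asarray(gold, dtype=int)
    labeler_labels = np.asarray(labeler_labels, dtype=int)
    test_idx = np.asarray(test_idx, dtype=int)
    if np.unique(test_idx).size != test_idx.size:
        raise ValueError("duplicate test indices")
    pool_idx = np.setdiff1d(np.arange(len(gold)), test_idx)
    if np.intersect1d(pool_idx, test_idx).size:
        raise RuntimeError("test-set leakage: pair pool intersects the test split")
    ids = [str(i) for i in pool_idx]
    test_set = {str(i) for i in test_idx}
    pool_labels = labeler_labels[pool_idx]
    rows = []
    for method in methods:
        for pi in pi_grid:
            prior = PriorConfig(pi)
            per_seed = []
            for seed in seeds:
                pairs = generate_pairwise(ids, pool_labels, n_pairs, seed)
                used = {p for pair in pairs.pairs for p in pair}
                if used & test_set:
                    raise RuntimeError("test-set leakage in generated pairs")
                point = split_pointwise(pairs)
                Xp = X[[int(i) for i in point.d_plus]]
                Xn = X[[int(i) for i in point.d_minus]]
                cfg = TrainConfig(
                    learning_rate=train_cfg.learning_rate,
                    batch_size=train_cfg.batch_size,
                    epochs=train_cfg.epochs,
                    dropout=train_cfg.dropout,
                    dev_fraction=train_cfg.dev_fraction,
                    seed=seed,
                    selection_metric=train_cfg.selection_metric,
                )
                model = fit(Xp, Xn, LossConfig(method, prior), cfg)
                pred = model.predict(X[test_idx])
                m = evaluate_predictions(pred.tolist(), gold[test_idx].tolist())
                per_seed.append(m)
            rows.append(
                {
                    "method": method,
                    "pi_plus": pi,
                    "precision": float(np.mean([m.precision for m in per_seed])),
                    "recall": float(np.mean([m.recall for m in per_seed])),
                    "f1": float(np.mean([m.f1 for m in per_seed])),
                    "f1_median": float(np.median([m.f1 for m in per_seed])),
                    "n_seeds": len(seeds),
                }
            )
    return ExperimentReport(
        rows=rows,
        provenance={
            "methods": list(methods),
            "pi_grid": list(pi_grid),
            "seeds": list(seeds),
            "n_pairs": n_pairs,
            "n_test": int(test_idx.size),
        },
    )
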