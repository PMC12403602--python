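"""Core data types for sentence-level relation instances and evaluation.

A relation instance is one sentence, tokenised, with two marked entity
spans and an optional binary label: ``+1`` means the two entities stand in
a semantic relation, ``-1`` means they do not.  Corpora are stored as
JSONL, one instance per line, so they diff and stream cleanly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

__all__ = [
    "EntitySpan",
    "RelationInstance",
    "Metrics",
    "read_corpus",
    "write_corpus",
    "evaluate_predictions",
]

_KNOWN_KEYS = {"id", "tokens", "e1", "e2", "gold_label", "silver_label"}
_SPAN_KEYS = {"start", "end", "surface", "etype"}


@dataclass(frozen=True)
class EntitySpan:
    """A token span ``[start, end)`` (0-based, half-open) with its surface text."""

    start: int
    end: int
    surface: str
    etype: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid span [{self.start}, {self.end}): need 0 <= start < end"
            )

    def indices(self) -> range:
        return range(self.start, self.end)

    def __len__(self) -> int:
        return self.end - self.start


def _normalize_ws(text: str) -> str:
    return " ".join(text.split())


@dataclass(frozen=True)
class RelationInstance:
    """One sentence with two non-overlapping entity spans.

    ``gold_label`` is the annotated label; ``silver_label`` is a noisy label
    produced by an unsupervised detector.  Both are in {+1, -1} or absent.
    """

    id: str
    tokens: tuple[str, ...]
    e1: EntitySpan
    e2: EntitySpan
    gold_label: Optional[int] = None
    silver_label: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "tokens", tuple(self.tokens))
        if not self.tokens:
            raise ValueError(f"instance {self.id!r}: tokens must be non-empty")
        n = len(self.tokens)
        for name, span in (("e1", self.e1), ("e2", self.e2)):
            if span.end > n:
                raise ValueError(
                    f"instance {self.id!r}: {name} span [{span.start}, {span.end}) "
                    f"outside token range (n={n})"
                )
            joined = _normalize_ws(" ".join(self.tokens[span.start : span.end]))
            if joined != _normalize_ws(span.surface):
                raise ValueError(
                    f"instance {self.id!r}: {name} surface {span.surface!r} does not "
                    f"match tokens {joined!r}"
                )
        if max(self.e1.start, self.e2.start) < min(self.e1.end, self.e2.end):
            raise ValueError(f"instance {self.id!r}: entity spans overlap")
        for name, lab in (("gold_label", self.gold_label), ("silver_label", self.silver_label)):
            if lab is not None and lab not in (+1, -1):
                raise ValueError(f"instance {self.id!r}: {name} must be +1 or -1, got {lab}")


def _span_to_dict(span: EntitySpan) -> dict:
    return {"start": span.start, "end": span.end, "surface": span.surface, "etype": span.etype}


def _span_from_dict(obj: dict, *, where: str) -> EntitySpan:
    unknown = set(obj) - _SPAN_KEYS
    if unknown:
        warnings.warn(f"{where}: ignoring unknown span keys {sorted(unknown)}")
    return EntitySpan(
        start=int(obj["start"]),
        end=int(obj["end"]),
        surface=str(obj["surface"]),
        etype=obj.get("etype"),
    )


def read_corpus(path: str | Path) -> list[RelationInstance]:
    """Read a JSONL corpus; returns instances in file order.

    Labels absent (or ``null``) in the file stay absent on the instance.
    Malformed lines raise ``ValueError`` naming the line number; invalid
    spans raise naming the instance id.
    """
    path = Path(path)
    instances: list[RelationInstance] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"{path}:{lineno}: malformed JSON line: {exc}") from exc
            if not isinstance(obj, dict):
                raise ValueError(f"{path}:{lineno}: expected a JSON object")
            unknown = set(obj) - _KNOWN_KEYS
            if unknown:
                warnings.warn(f"{path}:{lineno}: ignoring unknown keys {sorted(unknown)}")
            iid = str(obj.get("id", f"line{lineno}"))
            try:
                inst = RelationInstance(
                    id=iid,
                    tokens=tuple(str(t) for t in obj["tokens"]),
                    e1=_span_from_dict(obj["e1"], where=f"{path}:{lineno}"),
                    e2=_span_from_dict(obj["e2"], where=f"{path}:{lineno}"),
                    gold_label=obj.get("gold_label"),
                    silver_label=obj.get("silver_label"),
                )
            except KeyError as exc:
                raise ValueError(f"{path}:{lineno}: missing key {exc}") from exc
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno} (instance {iid!r}): {exc}") from exc
            instances.append(inst)
    return instances


def write_corpus(instances: Sequence[RelationInstance], path: str | Path) -> int:
    """Write instances as JSONL with a fixed field order; returns the count."""
    path = Path(path)
    n = 0
    with path.open("w", encoding="utf-8") as fh:
        for inst in instances:
            obj = {
                "id": inst.id,
                "tokens": list(inst.tokens),
                "e1": _span_to_dict(inst.e1),
                "e2": _span_to_dict(inst.e2),
                "gold_label": inst.gold_label,
                "silver_label": inst.silver_label,
            }
            fh.write(json.dumps(obj, ensure_ascii=False) + "\n")
            n += 1
    return n


@dataclass(frozen=True)
class Metrics:
    """Binary precision/recall/F1 with the underlying confusion counts.

    ``+1`` is the positive class.  Zero-denominator precision, recall and
    F1 are defined as 0 so that threshold sweeps are total functions.
    """

    precision: float
    recall: float
    f1: float
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def evaluate_predictions(pred: Sequence[int], gold: Sequence[int]) -> Metrics:
    """Precision/recall/F1 of ±1 predictions against ±1 gold labels."""
    if len(pred) != len(gold):
        raise ValueError(f"length mismatch: {len(pred)} predictions vs {len(gold)} gold labels")
    tp = fp = fn = tn = 0
    for p, g in zip(pred, gold):
        if p not in (+1, -1) or g not in (+1, -1):
            raise ValueError(f"labels must be +1 or -1, got pred={p}, gold={g}")
        if p == +1 and g == +1:
            tp += 1
        elif p == +1:
            fp += 1
        elif g == +1:
            fn += 1
        else:
            tn += 1
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return Metrics(precision=precision, recall=recall, f1=f1, tp=tp, fp=fp, fn=fn, tn=tn)
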