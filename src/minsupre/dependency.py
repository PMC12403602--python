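"""Dependency-tree relation detection (SARD).

The detector reads the shortest dependency path (SDP) between the two
entity tokens off the sentence's dependency tree and applies one of three
syntactic assumptions plus one of two heuristics:

assumption 1  the root word is a verb and lies on the SDP
assumption 2  the root word lies on the SDP
assumption 3  a verb lies on the SDP

heuristic 1   predict "related" if the assumption holds or the entities
              are directly linked (a single tree edge between them)
heuristic 2   as heuristic 1, but additionally require that no
              conjunction tag appears on the SDP

The conjunction tag set defaults to {CCONJ, SCONJ} and the verb tag set
to {VERB} in the Universal POS inventory; both are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import networkx as nx

from .corpus import EntitySpan

__all__ = [
    "DependencyParse",
    "SDPResult",
    "SardConfig",
    "CONJUNCTION_TAGS",
    "VERB_TAGS",
    "entity_head",
    "shortest_dependency_path",
    "check_assumption",
    "path_has_conjunction",
    "sard_predict",
    "read_conllu",
]

CONJUNCTION_TAGS = frozenset({"CCONJ", "SCONJ"})
VERB_TAGS = frozenset({"VERB"})


@dataclass(frozen=True)
class DependencyParse:
    """A rooted dependency tree over ``n`` tokens.

    ``head[i]`` is the head token of token ``i``; the single root has head
    ``-1``.  The head array must form a tree (acyclic, connected).
    """

    head: tuple[int, ...]
    deplabel: tuple[str, ...] = ()
    upos: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "head", tuple(int(h) for h in self.head))
        object.__setattr__(self, "deplabel", tuple(self.deplabel) or ("dep",) * self.n)
        object.__setattr__(self, "upos", tuple(self.upos) or ("X",) * self.n)
        n = self.n
        if n == 0:
            raise ValueError("empty parse")
        if len(self.upos) != n or len(self.deplabel) != n:
            raise ValueError("upos/deplabel length mismatch with head array")
        roots = [i for i, h in enumerate(self.head) if h == -1]
        if len(roots) != 1:
            raise ValueError(f"parse must have exactly one root, found {len(roots)}")
        for i, h in enumerate(self.head):
            if h == i:
                raise ValueError(f"token {i} is its own head")
            if h != -1 and not (0 <= h < n):
                raise ValueError(f"token {i} has head {h} outside [0, {n})")
        # connectivity: every token must reach the root without cycles
        for i in range(n):
            seen = set()
            j = i
            while j != -1:
                if j in seen:
                    raise ValueError(f"cycle in head array through token {j}")
                seen.add(j)
                j = self.head[j]

    @property
    def n(self) -> int:
        return len(self.head)

    @property
    def root(self) -> int:
        return self.head.index(-1)

    def as_graph(self) -> "nx.Graph":
        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        g.add_edges_from((i, h) for i, h in enumerate(self.head) if h != -1)
        return g


@dataclass(frozen=True)
class SDPResult:
    """The SDP between two tokens plus the predicates SARD reads off it."""

    nodes: tuple[int, ...]
    upos_on_path: tuple[str, ...]
    contains_root: bool
    contains_verb: bool
    root_is_verb_on_path: bool
    direct_link: bool
    has_conjunction: bool


@dataclass(frozen=True)
class SardConfig:
    """Which assumption (1-3) and heuristic (1-2) SARD applies."""

    a_id: int = 3
    h_id: int = 1

    def __post_init__(self) -> None:
        if self.a_id not in (1, 2, 3):
            raise ValueError(f"a_id must be 1, 2 or 3, got {self.a_id}")
        if self.h_id not in (1, 2):
            raise ValueError(f"h_id must be 1 or 2, got {self.h_id}")


def entity_head(parse: DependencyParse, span: EntitySpan) -> int:
    """Syntactic head token of an entity span: the leftmost token whose own
    head lies outside the span (falling back to the span start)."""
    if span.end > parse.n:
        raise ValueError(f"span [{span.start}, {span.end}) outside parse (n={parse.n})")
    inside = set(span.indices())
    for i in span.indices():
        if parse.head[i] not in inside:  # -1 is never inside
            return i
    return span.start


def shortest_dependency_path(
    parse: DependencyParse,
    i: int,
    j: int,
    *,
    conj_tags: frozenset[str] = CONJUNCTION_TAGS,
    verb_tags: frozenset[str] = VERB_TAGS,
) -> SDPResult:
    """The unique simple path between tokens ``i`` and ``j`` in the
    undirected tree, with the derived SARD predicates filled in."""
    n = parse.n
    if not (0 <= i < n and 0 <= j < n):
        raise ValueError(f"token indices ({i}, {j}) outside [0, {n})")
    try:
        nodes = tuple(nx.shortest_path(parse.as_graph(), i, j))
    except nx.NetworkXNoPath as exc:  # unreachable for a valid tree
        raise ValueError(f"no path between tokens {i} and {j}") from exc
    upos = tuple(parse.upos[k] for k in nodes)
    root = parse.root
    contains_root = root in nodes
    contains_verb = any(t in verb_tags for t in upos)
    root_is_verb = parse.upos[root] in verb_tags
    return SDPResult(
        nodes=nodes,
        upos_on_path=upos,
        contains_root=contains_root,
        contains_verb=contains_verb,
        root_is_verb_on_path=contains_root and root_is_verb,
        direct_link=len(nodes) == 2,
        has_conjunction=any(t in conj_tags for t in upos),
    )


def check_assumption(a_id: int, sdp: SDPResult) -> bool:
    """Evaluate one of the three SDP assumptions on a path."""
    if a_id == 1:
        return sdp.root_is_verb_on_path
    if a_id == 2:
        return sdp.contains_root
    if a_id == 3:
        return sdp.contains_verb
    raise ValueError(f"a_id must be 1, 2 or 3, got {a_id}")


def path_has_conjunction(sdp: SDPResult, *, conj_tags: frozenset[str] = CONJUNCTION_TAGS) -> bool:
    """True iff any SDP node (entity tokens included) carries a conjunction tag."""
    return any(t in conj_tags for t in sdp.upos_on_path)


def sard_predict(
    parse: DependencyParse,
    e1: EntitySpan,
    e2: EntitySpan,
    cfg: SardConfig = SardConfig(),
    *,
    conj_tags: frozenset[str] = CONJUNCTION_TAGS,
    verb_tags: frozenset[str] = VERB_TAGS,
) -> int:
    """SARD prediction (+1 related / -1 unrelated) for an entity pair.

    If the chosen assumption fails and the entity heads are not directly
    linked, predict -1; otherwise heuristic 1 predicts +1 and heuristic 2
    predicts +1 only when the SDP carries no conjunction tag.
    """
    h1 = entity_head(parse, e1)
    h2 = entity_head(parse, e2)
    sdp = shortest_dependency_path(parse, h1, h2, conj_tags=conj_tags, verb_tags=verb_tags)
    a = check_assumption(cfg.a_id, sdp)
    if not a and not sdp.direct_link:
        return -1
    if cfg.h_id == 1:
        return +1
    return -1 if path_has_conjunction(sdp, conj_tags=conj_tags) else +1


def read_conllu(path: str | Path) -> dict[str, DependencyParse]:
    """Read single-root dependency trees from a CoNLL-U file.

    Sentences are keyed by their ``# sent_id`` comment (falling back to a
    running index).  Only the ID, UPOS and HEAD columns are consumed; the
    1-based HEAD with 0 = root is converted to 0-based with -1 = root.
    Multi-word-token and empty-node lines (non-integer IDs) are skipped.
    """
    path = Path(path)
    parses: dict[str, DependencyParse] = {}
    sent_id: Optional[str] = None
    rows: list[tuple[int, str, int, str]] = []
    count = 0

    def flush() -> None:
        nonlocal sent_id, rows, count
        if rows:
            rows.sort()
            head = tuple(h - 1 if h > 0 else -1 for _, _, h, _ in rows)
            upos = tuple(u for _, u, _, _ in rows)
            dep = tuple(d for _, _, _, d in rows)
            key = sent_id if sent_id is not None else f"sent{count}"
            parses[key] = DependencyParse(head=head, deplabel=dep, upos=upos)
            count += 1
        sent_id, rows = None, []

    with path.open("r", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                flush()
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("sent_id"):
                    sent_id = body.split("=", 1)[1].strip() if "=" in body else None
                continue
            cols = line.split("\t")
            if len(cols) < 8:
                raise ValueError(f"{path}: short CoNLL-U row: {line!r}")
            if not cols[0].isdigit():
                continue  # multi-word token ranges / empty nodes
            rows.append((int(cols[0]), cols[3], int(cols[6]), cols[7]))
    flush()
    return parses
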