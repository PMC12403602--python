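"""Dependency trees, SDP extraction, and the SARD detector.

The truth-table test realizes every combination of the five structural
flags as a constructed parse and checks sard_predict against an oracle
that re-derives the path by breadth-first search and evaluates the
detector's decision rule literally.
"""

from collections import deque
from itertools import product

import pytest

from minsupre import (
    DependencyParse,
    EntitySpan,
    SardConfig,
    check_assumption,
    entity_head,
    path_has_conjunction,
    read_conllu,
    sard_predict,
    shortest_dependency_path,
)
from minsupre.synthetic import build_parse_fixture, random_tree


# --------------------------------------------------------------- oracles


def bfs_path(head, i, j):
    """Independent path finder over the undirected edge set."""
    adj = {k: set() for k in range(len(head))}
    for child, h in enumerate(head):
        if h != -1:
            adj[child].add(h)
            adj[h].add(child)
    prev = {i: None}
    q = deque([i])
    while q:
        u = q.popleft()
        if u == j:
            break
        for v in adj[u]:
            if v not in prev:
                prev[v] = u
                q.append(v)
    path, u = [], j
    while u is not None:
        path.append(u)
        u = prev[u]
    return path[::-1]


def sard_oracle(parse, e1_idx, e2_idx, a_id, h_id):
    """Literal evaluation of the detector's decision rule from scratch."""
    path = bfs_path(parse.head, e1_idx, e2_idx)
    upos = [parse.upos[k] for k in path]
    root = parse.head.index(-1)
    root_on = root in path
    if a_id == 1:
        a = root_on and parse.upos[root] == "VERB"
    elif a_id == 2:
        a = root_on
    else:
        a = "VERB" in upos
    direct = len(path) == 2
    if not a and not direct:
        return -1
    if h_id == 1:
        return +1
    return -1 if any(t in ("CCONJ", "SCONJ") for t in upos) else +1


# ----------------------------------------------------------------- types


class TestDependencyParse:
    def test_rejects_multiple_roots(self):
        with pytest.raises(ValueError, match="root"):
            DependencyParse(head=(-1, -1))

    def test_rejects_cycle(self):
        with pytest.raises(ValueError):
            DependencyParse(head=(1, 0, -1))

    def test_rejects_self_head(self):
        with pytest.raises(ValueError):
            DependencyParse(head=(0, -1))


class TestEntityHead:
    def test_single_token_span(self):
        p = DependencyParse(head=(1, -1, 1))
        assert entity_head(p, EntitySpan(2, 3, "x")) == 2

    def test_multitoken_span_head_outside(self):
        # head[0]=1 (inside), head[1]=4 (outside) -> token 1 is the span head
        p = DependencyParse(head=(1, 4, 4, 4, -1))
        assert entity_head(p, EntitySpan(0, 2, "a b")) == 1

    def test_span_covering_root(self):
        p = DependencyParse(head=(-1, 0, 0))
        assert entity_head(p, EntitySpan(0, 2, "a b")) == 0


class TestSDP:
    def test_degenerate_same_token(self):
        p = DependencyParse(head=(1, -1, 1))
        sdp = shortest_dependency_path(p, 0, 0)
        assert sdp.nodes == (0,)
        assert not sdp.direct_link

    def test_chain_contains_root(self):
        p = DependencyParse(head=(1, 2, -1))
        sdp = shortest_dependency_path(p, 0, 2)
        assert sdp.nodes == (0, 1, 2)
        assert sdp.contains_root

    def test_symmetry(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 12))
            p = random_tree(n, rng)
            i, j = rng.integers(0, n, size=2)
            fwd = shortest_dependency_path(p, int(i), int(j)).nodes
            rev = shortest_dependency_path(p, int(j), int(i)).nodes
            assert fwd == rev[::-1]

    def test_matches_bfs_on_random_trees(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 13))
            p = random_tree(n, rng)
            i, j = int(rng.integers(0, n)), int(rng.integers(0, n))
            sdp = shortest_dependency_path(p, i, j)
            assert list(sdp.nodes) == bfs_path(p.head, i, j)


class TestPredicates:
    def test_root_verb_satisfies_all_assumptions(self):
        rec = build_parse_fixture(True, True, False, False, False)
        sdp = shortest_dependency_path(rec.parse, 0, 4)
        assert all(check_assumption(a, sdp) for a in (1, 2, 3))

    def test_nonroot_verb_only_satisfies_assumption_3(self):
        rec = build_parse_fixture(False, False, True, False, False)
        sdp = shortest_dependency_path(rec.parse, 0, 4)
        assert not check_assumption(1, sdp)
        assert not check_assumption(2, sdp)
        assert check_assumption(3, sdp)

    def test_bare_path_fails_all(self):
        rec = build_parse_fixture(False, False, False, False, False)
        sdp = shortest_dependency_path(rec.parse, 0, 4)
        assert not any(check_assumption(a, sdp) for a in (1, 2, 3))

    def test_conjunction_scan(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 10))
            p = random_tree(n, rng)
            sdp = shortest_dependency_path(p, 0, n - 1)
            expected = any(t in ("CCONJ", "SCONJ") for t in sdp.upos_on_path)
            assert path_has_conjunction(sdp) == expected

    def test_invalid_assumption_id(self):
        rec = build_parse_fixture(True, True, False, False, False)
        sdp = shortest_dependency_path(rec.parse, 0, 4)
        with pytest.raises(ValueError):
            check_assumption(4, sdp)


ALL_FLAGS = list(product([False, True], repeat=5))
INFEASIBLE = (True, True, True, True, True)


class TestSard:
    def test_simple_active_sentence(self):
        # "ProteinA activates ProteinB": root verb on the path -> +1 everywhere
        p = DependencyParse(head=(1, -1, 1), upos=("NOUN", "VERB", "NOUN"))
        e1, e2 = EntitySpan(0, 1, "ProteinA"), EntitySpan(2, 3, "ProteinB")
        for a, h in product((1, 2, 3), (1, 2)):
            assert sard_predict(p, e1, e2, SardConfig(a, h)) == +1

    def test_gate_fails_without_verb_or_link(self):
        p = DependencyParse(head=(1, -1, 1), upos=("NOUN", "NOUN", "NOUN"))
        # path 0-1-2, no verb, no root?? root IS on path; use assumption 3
        assert sard_predict(p, EntitySpan(0, 1, "w0"), EntitySpan(2, 3, "w2"),
                            SardConfig(3, 1)) == -1

    def test_direct_link_escape(self):
        rec = build_parse_fixture(False, False, False, True, False)
        assert sard_predict(rec.parse, rec.instance.e1, rec.instance.e2,
                            SardConfig(3, 1)) == +1

    def test_infeasible_flag_combination_raises(self):
        with pytest.raises(ValueError, match="infeasible"):
            build_parse_fixture(*INFEASIBLE)

    @pytest.mark.parametrize("a_id,h_id", list(product((1, 2, 3), (1, 2))))
    def test_truth_table_matches_literal_oracle(self, a_id, h_id):
        """All 32 structural configurations against the from-scratch oracle."""
        for flags in ALL_FLAGS:
            realized = (True, True, False, True, True) if flags == INFEASIBLE else flags
            rec = build_parse_fixture(*realized)
            e1h = rec.instance.e1.start
            e2h = rec.instance.e2.start
            got = sard_predict(rec.parse, rec.instance.e1, rec.instance.e2,
                               SardConfig(a_id, h_id))
            assert got == sard_oracle(rec.parse, e1h, e2h, a_id, h_id), (flags, a_id, h_id)

    def test_heuristic_2_positives_subset_of_heuristic_1(self):
        for a_id in (1, 2, 3):
            for flags in ALL_FLAGS:
                if flags == INFEASIBLE:
                    continue
                rec = build_parse_fixture(*flags)
                p1 = sard_predict(rec.parse, rec.instance.e1, rec.instance.e2, SardConfig(a_id, 1))
                p2 = sard_predict(rec.parse, rec.instance.e1, rec.instance.e2, SardConfig(a_id, 2))
                if p2 == +1:
                    assert p1 == +1

    def test_assumption_1_positives_subset_of_assumption_2(self):
        for h_id in (1, 2):
            for flags in ALL_FLAGS:
                if flags == INFEASIBLE:
                    continue
                rec = build_parse_fixture(*flags)
                p1 = sard_predict(rec.parse, rec.instance.e1, rec.instance.e2, SardConfig(1, h_id))
                p2 = sard_predict(rec.parse, rec.instance.e1, rec.instance.e2, SardConfig(2, h_id))
                if p1 == +1:
                    assert p2 == +1


class TestConllu:
    CONLLU = """\
# sent_id = s1
1\tProteinA\tproteina\tNOUN\t_\t_\t2\tnsubj\t_\t_
2\tactivates\tactivate\tVERB\t_\t_\t0\troot\t_\t_
3\tProteinB\tproteinb\tNOUN\t_\t_\t2\tobj\t_\t_

# sent_id = s2
1\ta\ta\tDET\t_\t_\t2\tdet\t_\t_
2\tthing\tthing\tNOUN\t_\t_\t0\troot\t_\t_
"""

    def test_reads_sentences_and_converts_heads(self, tmp_path):
        p = tmp_path / "x.conllu"
        p.write_text(self.CONLLU)
        parses = read_conllu(p)
        assert set(parses) == {"s1", "s2"}
        assert parses["s1"].head == (1, -1, 1)
        assert parses["s1"].upos == ("NOUN", "VERB", "NOUN")
        assert parses["s2"].head == (1, -1)

    def test_sard_on_conllu_parse(self, tmp_path):
        p = tmp_path / "x.conllu"
        p.write_text(self.CONLLU)
        parse = read_conllu(p)["s1"]
        pred = sard_predict(parse, EntitySpan(0, 1, "ProteinA"),
                            EntitySpan(2, 3, "ProteinB"), SardConfig(1, 1))
        assert pred == +1
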