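"""GO DAG parsing, true-path propagation and node scores vs brute force."""

import io

import networkx as nx
import pytest

from dualsage.go import (
    FormatError,
    GOGraph,
    filter_and_compare,
    node_score,
    parse_obo,
    propagate_annotations,
)
from dualsage.tags import InputError

CHAIN_OBO = """\
format-version: 1.2

[Term]
id: GO:0000001
name: alpha
namespace: biological_process

[Term]
id: GO:0000002
name: beta
namespace: biological_process
is_a: GO:0000001 ! alpha

[Term]
id: GO:0000003
name: gamma
namespace: biological_process
alt_id: GO:0000333
is_a: GO:0000002 ! beta

[Term]
id: GO:0000009
name: dead
namespace: biological_process
is_obsolete: true
"""

DIAMOND_OBO = """\
format-version: 1.2

[Term]
id: GO:0000001
name: a
namespace: biological_process

[Term]
id: GO:0000002
name: b
namespace: biological_process
is_a: GO:0000001

[Term]
id: GO:0000003
name: c
namespace: biological_process
part_of: GO:0000001

[Term]
id: GO:0000004
name: d
namespace: biological_process
is_a: GO:0000002
is_a: GO:0000003
"""


def chain():
    return parse_obo(io.StringIO(CHAIN_OBO))


# ---- independent oracles on plain adjacency dicts ------------------------


def oracle_ancestors(parents, term):
    seen = {term}
    stack = [term]
    while stack:
        for p in parents.get(stack.pop(), ()):
            if p not in seen:
                seen.add(p)
                stack.append(p)
    return seen


def oracle_propagate(parents, annots):
    out = {}
    for seq, terms in annots.items():
        for t in terms:
            for anc in oracle_ancestors(parents, t):
                out.setdefault(anc, set()).add(seq)
    return out


def oracle_distances(parents, term):
    dist = {term: 0}
    frontier = [term]
    while frontier:
        nxt = []
        for u in frontier:
            for p in parents.get(u, ()):
                if p not in dist:
                    dist[p] = dist[u] + 1
                    nxt.append(p)
        frontier = nxt
    return dist


def oracle_scores(parents, annots, w):
    scores = {}
    for seq, terms in annots.items():
        for t in terms:
            for anc, d in oracle_distances(parents, t).items():
                scores[anc] = scores.get(anc, 0.0) + w**d
    return scores


def random_dag(rng, n_terms, n_seqs):
    """Random DAG (edges only toward lower indices) plus random annotations."""
    parents = {f"T{i}": [] for i in range(n_terms)}
    g = nx.DiGraph()
    g.add_nodes_from(
        (f"T{i}", {"name": f"t{i}", "namespace": "biological_process"})
        for i in range(n_terms)
    )
    for i in range(1, n_terms):
        k = 1 + int(rng.integers(0, min(3, i)))
        for j in rng.choice(i, size=k, replace=False):
            parents[f"T{i}"].append(f"T{j}")
            g.add_edge(f"T{i}", f"T{j}", relation="is_a")
    annots = {}
    for s in range(n_seqs):
        terms = rng.choice(n_terms, size=1 + int(rng.integers(0, 3)), replace=False)
        annots[f"seq{s}"] = {f"T{t}" for t in terms}
    return GOGraph(g), parents, annots


# ---- parsing --------------------------------------------------------------


class TestParseObo:
    def test_chain_structure(self):
        go = chain()
        assert go.graph.number_of_edges() == 2
        assert go.roots() == ["GO:0000001"]

    def test_obsolete_term_excluded(self):
        go = chain()
        assert "GO:0000009" not in go.graph

    def test_alt_id_resolves_to_primary(self):
        go = chain()
        assert go.resolve("GO:0000333") == "GO:0000003"

    def test_part_of_edges_traversed_by_default(self):
        go = parse_obo(io.StringIO(DIAMOND_OBO))
        assert go.ancestors("GO:0000004") == {
            "GO:0000001", "GO:0000002", "GO:0000003", "GO:0000004"
        }

    def test_cycle_rejected(self):
        cyclic = CHAIN_OBO.replace(
            "id: GO:0000001\nname: alpha\nnamespace: biological_process",
            "id: GO:0000001\nname: alpha\nnamespace: biological_process\n"
            "is_a: GO:0000003",
        )
        with pytest.raises(FormatError, match="GO:00000"):
            parse_obo(io.StringIO(cyclic))


# ---- propagation ----------------------------------------------------------


class TestPropagate:
    def test_chain_leaf_reaches_all_ancestors(self):
        prop = propagate_annotations(chain(), {"s": {"GO:0000003"}})
        assert prop == {
            "GO:0000001": {"s"}, "GO:0000002": {"s"}, "GO:0000003": {"s"}
        }

    def test_diamond_counts_shared_root_once(self):
        go = parse_obo(io.StringIO(DIAMOND_OBO))
        prop = propagate_annotations(go, {"s": {"GO:0000004"}})
        assert prop["GO:0000001"] == {"s"}

    def test_unknown_term_skipped_with_warning(self, caplog):
        prop = propagate_annotations(chain(), {"s": {"GO:9999999"}})
        assert prop == {}

    def test_obsolete_annotation_dropped(self):
        prop = propagate_annotations(chain(), {"s": {"GO:0000009"}})
        assert prop == {}

    def test_alt_id_annotation_resolves(self):
        prop = propagate_annotations(chain(), {"s": {"GO:0000333"}})
        assert prop["GO:0000003"] == {"s"}

    def test_matches_closure_oracle_on_random_dags(self, rng):
        for _ in range(25):
            go, parents, annots = random_dag(
                rng, 5 + int(rng.integers(0, 45)), 10
            )
            got = propagate_annotations(go, annots)
            assert got == oracle_propagate(parents, annots)


# ---- node scores ----------------------------------------------------------


class TestNodeScore:
    def test_chain_weight_one(self):
        scores = node_score(chain(), {"s": {"GO:0000003"}}, weight=1.0)
        assert dict(zip(scores["term"], scores["score"])) == {
            "GO:0000001": 1.0, "GO:0000002": 1.0, "GO:0000003": 1.0
        }

    def test_chain_weight_half_discounts_by_distance(self):
        scores = node_score(chain(), {"s": {"GO:0000003"}}, weight=0.5)
        got = dict(zip(scores["term"], scores["score"]))
        assert got == {
            "GO:0000003": 1.0, "GO:0000002": 0.5, "GO:0000001": 0.25
        }

    def test_invalid_weight(self):
        with pytest.raises(InputError):
            node_score(chain(), {}, weight=0.0)

    @pytest.mark.parametrize("weight", [1.0, 0.5])
    def test_matches_brute_force_oracle_on_random_dags(self, rng, weight):
        for _ in range(15):
            go, parents, annots = random_dag(rng, 5 + int(rng.integers(0, 45)), 8)
            got = dict(zip(*(node_score(go, annots, weight)[c]
                             for c in ("term", "score"))))
            expected = oracle_scores(parents, annots, weight)
            assert set(got) == set(expected)
            for t in got:
                assert got[t] == pytest.approx(expected[t])

    def test_root_conserves_annotation_instances(self, rng):
        go, parents, annots = random_dag(rng, 30, 12)
        scores = node_score(go, annots, weight=1.0)
        total = sum(len(v) for v in annots.values())
        root_score = scores.loc[scores["term"] == "T0", "score"].iloc[0]
        assert root_score == total

    def test_parent_score_at_least_child_when_unweighted(self, rng):
        go, parents, annots = random_dag(rng, 40, 15)
        scores = dict(zip(*(node_score(go, annots, 1.0)[c]
                            for c in ("term", "score"))))
        for child, ps in parents.items():
            for p in ps:
                assert scores.get(p, 0) >= scores.get(child, 0)


# ---- comparison -----------------------------------------------------------


class TestFilterAndCompare:
    def _tables(self, rng):
        go, _, annots = random_dag(rng, 25, 30)
        host = node_score(go, annots, 1.0)
        sym = node_score(go, {k: v for k, v in list(annots.items())[:5]}, 1.0)
        return host, sym

    def test_all_below_cutoff_empty(self, rng):
        host, sym = self._tables(rng)
        out = filter_and_compare(host, sym, cutoff=10**6)
        assert len(out) == 0

    def test_cutoff_inclusive(self):
        go = chain()
        host = node_score(go, {f"s{i}": {"GO:0000003"} for i in range(20)}, 1.0)
        sym = node_score(go, {"t": {"GO:0000002"}}, 1.0)
        out = filter_and_compare(host, sym, cutoff=20)
        assert "GO:0000003" in set(out["term"])  # score exactly 20 retained

    def test_missing_species_scores_zero(self):
        go = chain()
        host = node_score(go, {"s": {"GO:0000003"}}, 1.0)
        sym = node_score(go, {}, 1.0)
        out = filter_and_compare(host, sym, cutoff=1)
        assert (out["score_symbiont"] == 0).all()

    def test_level_filter(self):
        go = chain()
        host = node_score(go, {f"s{i}": {"GO:0000003"} for i in range(25)}, 1.0)
        sym = node_score(go, {}, 1.0)
        out = filter_and_compare(host, sym, cutoff=20, level=2)
        assert set(out["term"]) == {"GO:0000003"}
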