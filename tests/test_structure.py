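"""Structure learning: scores, MI, hill climbing, SCCs, and LSHCT stages."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest

from erasbn.core import BayesianNetwork, Cpt, DagStructure, sample
from erasbn.simulate import random_bn
from erasbn.structure import (
    DirectedGraphDraft,
    LshctConfig,
    MiMatrix,
    ScoreCache,
    UndefinedMiError,
    hill_climb,
    learn_sub_bn,
    local_score,
    lshct,
    merge_sub_bns,
    mi_matrix,
    mutual_information,
    network_score,
    orient_component,
    strongly_connected_components,
    top_k_neighbors,
)

from conftest import binary_child, binary_root, dataset


def chain_network(p_flip: float = 0.1) -> BayesianNetwork:
    """A -> B -> C with strong (1 - p_flip) state copying."""
    keep = {"0": p_flip, "1": 1 - p_flip}
    return BayesianNetwork(
        DagStructure(["A", "B", "C"], [("A", "B"), ("B", "C")]),
        {"A": binary_root("A", 0.5),
         "B": binary_child("B", "A", keep),
         "C": binary_child("C", "B", keep)},
    )


def independent_data(n: int, k: int, seed: int):
    rng = np.random.default_rng(seed)
    return dataset(
        {f"v{i}": [str(x) for x in rng.integers(0, 2, n)] for i in range(k)},
        {f"v{i}": ("0", "1") for i in range(k)},
    )


# ---------------------------------------------------------------------------
# scores
# ---------------------------------------------------------------------------

class TestScores:
    def test_bic_hand_example_parentless_binary(self):
        data = dataset({"b": ["0"] * 5 + ["1"] * 5}, {"b": ("0", "1")})
        expected = 10 * math.log(0.5) - math.log(10) / 2
        assert local_score("b", [], data) == pytest.approx(expected, abs=1e-9)

    def test_network_score_is_sum_of_local_scores(self):
        data = sample(random_bn(4, seed=3), 200, seed=4)
        dag = DagStructure(data.names, [(data.names[0], data.names[1]),
                                        (data.names[1], data.names[3])])
        total = sum(local_score(n, dag.parents(n), data) for n in dag.nodes)
        assert network_score(dag, data) == pytest.approx(total)

    def test_penalty_rejects_spurious_parent_for_independent_pair(self):
        data = independent_data(10_000, 2, seed=0)
        assert local_score("v1", ["v0"], data) < local_score("v1", [], data)

    def test_adding_independent_edge_decreases_network_score(self):
        data = independent_data(10_000, 3, seed=1)
        empty = DagStructure(data.names, ())
        with_edge = empty.with_edge("v0", "v2")
        assert network_score(with_edge, data) < network_score(empty, data)

    def test_child_among_parents_rejected(self):
        data = independent_data(10, 2, seed=2)
        with pytest.raises(ValueError):
            local_score("v0", ["v0"], data)

    def test_bdeu_score_prefers_true_edge(self):
        truth = chain_network(0.05)
        data = sample(truth, 4000, seed=8)
        cfg = LshctConfig(score="bdeu", equivalent_sample_size=1.0)
        cache = ScoreCache(data, cfg)
        assert cache.local("B", ("A",)) > cache.local("B", ())


# ---------------------------------------------------------------------------
# mutual information
# ---------------------------------------------------------------------------

class TestMutualInformation:
    def test_empirical_independence_gives_zero(self):
        # joint counts [[1,1],[1,1]]
        assert mutual_information(["0", "0", "1", "1"],
                                  ["0", "1", "0", "1"]) == pytest.approx(0.0)

    def test_identical_columns_give_entropy(self):
        col = ["0"] * 3 + ["1"] * 3
        assert mutual_information(col, col) == pytest.approx(math.log(2))

    def test_plugin_formula_small_table(self):
        # joint counts [[2,1],[1,2]], n=6 -> ~0.0566 nats
        x = ["0", "0", "0", "1", "1", "1"]
        y = ["0", "0", "1", "0", "1", "1"]
        assert mutual_information(x, y) == pytest.approx(0.0566, abs=2e-4)

    def test_no_pairwise_complete_records_raises(self):
        with pytest.raises(UndefinedMiError):
            mutual_information(["0", None], [None, "1"])

    def test_matrix_symmetry_and_entropy_diagonal(self):
        data = independent_data(500, 4, seed=5)
        m = mi_matrix(data)
        assert np.allclose(m.values, m.values.T)
        for i, name in enumerate(m.order):
            col = data.column(name)
            p1 = np.mean([c == "1" for c in col])
            h = -(p1 * math.log(p1) + (1 - p1) * math.log(1 - p1))
            assert m.values[i, i] == pytest.approx(h)
        # MI bounded by min marginal entropy
        d = np.diag(m.values)
        assert (m.values <= np.minimum.outer(d, d) + 1e-9).all()

    def test_missing_cells_match_manual_pairwise_filtering(self):
        x = ["0", "1", None, "1", "0", "1", None, "0"]
        y = ["1", "1", "0", None, "0", "1", "1", "0"]
        data = dataset({"x": x, "y": y}, {"x": ("0", "1"), "y": ("0", "1")})
        m = mi_matrix(data)
        keep = [(a, b) for a, b in zip(x, y) if a is not None and b is not None]
        manual = mutual_information([a for a, _ in keep], [b for _, b in keep])
        assert m.get("x", "y") == pytest.approx(manual)


class TestTopKNeighbors:
    def _matrix(self):
        vals = np.array([
            [1.0, 0.9, 0.5, 0.5, 0.1, 0.05],
            [0.9, 1.0, 0.0, 0.0, 0.0, 0.0],
            [0.5, 0.0, 1.0, 0.0, 0.0, 0.0],
            [0.5, 0.0, 0.0, 1.0, 0.0, 0.0],
            [0.1, 0.0, 0.0, 0.0, 1.0, 0.0],
            [0.05, 0.0, 0.0, 0.0, 0.0, 1.0],
        ])
        return MiMatrix(order=("a", "b", "c", "d", "e", "f"), values=vals)

    def test_selects_largest_with_order_tie_break(self):
        # the 0.5 tie between c and d resolves to declaration order
        assert top_k_neighbors(self._matrix(), "a", 4) == ["b", "c", "d", "e"]

    def test_k_covers_all_and_zero(self):
        m = self._matrix()
        assert len(top_k_neighbors(m, "a", 10)) == 5
        assert top_k_neighbors(m, "a", 0) == []

    def test_unknown_node(self):
        with pytest.raises(KeyError):
            top_k_neighbors(self._matrix(), "zz", 2)


# ---------------------------------------------------------------------------
# hill climbing and sub-networks
# ---------------------------------------------------------------------------

class TestHillClimb:
    def test_independent_variables_stay_empty(self):
        data = independent_data(10_000, 4, seed=6)
        result = hill_climb(data, DagStructure(data.names, ()))
        assert result.edges == frozenset()
        # exhaustive check: no single-edge addition raises the score
        base = network_score(DagStructure(data.names, ()), data)
        for u, v in itertools.permutations(data.names, 2):
            alt = DagStructure(data.names, [(u, v)])
            assert network_score(alt, data) < base

    def test_score_never_decreases_from_initial(self):
        for seed in range(5):
            truth = random_bn(5, edge_prob=0.5, seed=seed)
            data = sample(truth, 500, seed=seed + 50)
            init = DagStructure(data.names, ())
            result = hill_climb(data, init)
            assert network_score(result, data) >= network_score(init, data)

    def test_whitelist_restricts_result_edges(self):
        truth = chain_network(0.05)
        data = sample(truth, 3000, seed=1)
        wl = frozenset({("A", "B"), ("B", "A")})
        result = hill_climb(data, DagStructure(data.names, ()), whitelist=wl)
        assert result.edges <= wl

    def test_blacklist_and_protected_edges(self):
        truth = chain_network(0.05)
        data = sample(truth, 3000, seed=2)
        result = hill_climb(data, DagStructure(data.names, ()),
                            blacklist=frozenset({("A", "B"), ("B", "A")}))
        assert ("A", "B") not in result.edges and ("B", "A") not in result.edges
        spurious = DagStructure(data.names, [("A", "C")])
        kept = hill_climb(data, spurious, protected=frozenset({("A", "C")}))
        assert ("A", "C") in kept.edges

    def test_initial_violating_constraints_rejected(self):
        data = independent_data(50, 3, seed=3)
        init = DagStructure(data.names, [("v0", "v1")])
        with pytest.raises(ValueError):
            hill_climb(data, init, whitelist=frozenset({("v1", "v2")}))


class TestSubBn:
    def test_edges_confined_to_subset(self):
        truth = random_bn(6, edge_prob=0.6, seed=9)
        data = sample(truth, 800, seed=10)
        subset = list(data.names[:4])
        result = learn_sub_bn(data, subset, LshctConfig())
        assert set(result.nodes) == set(subset)
        assert all(u in subset and v in subset for u, v in result.edges)

    def test_independent_subset_learns_empty(self):
        data = independent_data(10_000, 5, seed=7)
        result = learn_sub_bn(data, list(data.names), LshctConfig())
        assert result.edges == frozenset()

    def test_dependent_pair_yields_single_connecting_edge(self):
        truth = chain_network(0.05)
        data = sample(truth, 10_000, seed=11)
        result = learn_sub_bn(data, ["A", "B"], LshctConfig())
        assert result.edges in ({("A", "B")}, {("B", "A")},
                                frozenset({("A", "B")}), frozenset({("B", "A")}))

    def test_too_small_subset(self):
        data = independent_data(10, 3, seed=0)
        with pytest.raises(ValueError):
            learn_sub_bn(data, ["v0"], LshctConfig())


# ---------------------------------------------------------------------------
# merge + SCC + orientation
# ---------------------------------------------------------------------------

class TestMerge:
    def test_single_sub_dag_passes_through(self):
        d = DagStructure(["a", "b", "c"], [("a", "b"), ("b", "c")])
        merged = merge_sub_bns([d])
        assert set(merged.edges) == set(d.edges)

    def test_majority_vote(self):
        d1 = DagStructure(["a", "b"], [("a", "b")])
        d2 = DagStructure(["a", "b"], [("a", "b")])
        d3 = DagStructure(["a", "b"], [("b", "a")])
        merged = merge_sub_bns([d1, d2, d3])
        assert set(merged.edges) == {("a", "b")}

    def test_tie_keeps_both_directions(self):
        d1 = DagStructure(["a", "b"], [("a", "b")])
        d2 = DagStructure(["a", "b"], [("b", "a")])
        merged = merge_sub_bns([d1, d2])
        assert set(merged.edges) == {("a", "b"), ("b", "a")}


def scc_oracle(nodes, edges):
    """Transitive-closure (reachability-matrix) partition oracle."""
    idx = {n: i for i, n in enumerate(nodes)}
    k = len(nodes)
    reach = np.eye(k, dtype=bool)
    for u, v in edges:
        reach[idx[u], idx[v]] = True
    for _ in range(max(1, int(np.ceil(np.log2(max(k, 2)))))):
        reach = reach | (reach @ reach)
    both = reach & reach.T
    sig = tuple(int(np.argmax(both[i])) for i in range(k))
    return sig


def partition_signature(nodes, comps):
    idx = {n: i for i, n in enumerate(nodes)}
    label = {}
    for comp in comps:
        root = min(idx[n] for n in comp)
        for n in comp:
            label[n] = root
    return tuple(label[n] for n in nodes)


class TestScc:
    def test_acyclic_graph_gives_singletons(self):
        g = DirectedGraphDraft(["a", "b", "c"], [("a", "b"), ("b", "c")])
        assert strongly_connected_components(g) == [
            frozenset({"a"}), frozenset({"b"}), frozenset({"c"})]

    def test_three_cycle_is_one_component(self):
        g = DirectedGraphDraft(["a", "b", "c"],
                               [("a", "b"), ("b", "c"), ("c", "a")])
        assert strongly_connected_components(g) == [frozenset({"a", "b", "c"})]

    @pytest.mark.parametrize("trial", range(100))
    def test_random_digraphs_match_reachability_oracle(self, trial):
        rng = np.random.default_rng(3000 + trial)
        k = int(rng.integers(2, 9))
        nodes = [f"n{i}" for i in range(k)]
        edges = [(nodes[i], nodes[j]) for i in range(k) for j in range(k)
                 if i != j and rng.random() < 0.3]
        g = DirectedGraphDraft(nodes, edges)
        comps = strongly_connected_components(g)
        assert partition_signature(nodes, comps) == scc_oracle(nodes, edges)
        # independent cross-check against networkx
        nxg = nx.DiGraph()
        nxg.add_nodes_from(nodes)
        nxg.add_edges_from(edges)
        assert {frozenset(c) for c in nx.strongly_connected_components(nxg)} \
            == set(comps)

    def test_condensation_is_acyclic(self):
        rng = np.random.default_rng(9)
        nodes = [f"n{i}" for i in range(7)]
        edges = [(a, b) for a in nodes for b in nodes
                 if a != b and rng.random() < 0.4]
        comps = strongly_connected_components(DirectedGraphDraft(nodes, edges))
        comp_of = {n: i for i, c in enumerate(comps) for n in c}
        cond = nx.DiGraph()
        cond.add_nodes_from(range(len(comps)))
        cond.add_edges_from((comp_of[u], comp_of[v]) for u, v in edges
                            if comp_of[u] != comp_of[v])
        assert nx.is_directed_acyclic_graph(cond)


class TestOrientComponent:
    def test_empty_skeleton_gives_empty_dag(self):
        data = independent_data(100, 3, seed=1)
        result = orient_component({"v0", "v1"}, [], data)
        assert result.edges == frozenset()

    def test_dependent_pair_gets_one_direction(self):
        truth = chain_network(0.05)
        data = sample(truth, 10_000, seed=12)
        result = orient_component({"A", "B"}, [frozenset({"A", "B"})], data)
        assert len(result.edges) == 1
        assert {frozenset(e) for e in result.edges} == {frozenset({"A", "B"})}

    def test_triangle_skeleton_stays_inside_and_acyclic(self):
        truth = chain_network(0.1)
        data = sample(truth, 2000, seed=13)
        skel = [frozenset({"A", "B"}), frozenset({"B", "C"}),
                frozenset({"A", "C"})]
        result = orient_component({"A", "B", "C"}, skel, data)
        result.topological_order()  # acyclic
        assert {frozenset(e) for e in result.edges} <= set(skel)

    def test_edge_outside_component_rejected(self):
        data = independent_data(50, 3, seed=2)
        with pytest.raises(ValueError):
            orient_component({"v0"}, [frozenset({"v0", "v2"})], data)

    def test_second_pass_score_at_least_first(self):
        truth = chain_network(0.1)
        data = sample(truth, 5000, seed=14)
        cfg = LshctConfig()
        cache = ScoreCache(data, cfg)
        skel = [frozenset({"A", "B"}), frozenset({"B", "C"})]
        wl = frozenset({("A", "B"), ("B", "A"), ("B", "C"), ("C", "B")})
        pass1 = hill_climb(data, DagStructure(data.names, ()), whitelist=wl,
                           config=cfg, operators=("add", "delete"), cache=cache)
        result = orient_component({"A", "B", "C"}, skel, data, cfg, cache=cache)
        assert network_score(result, data, cfg, cache=cache) >= \
            network_score(pass1, data, cfg, cache=cache) - 1e-9


# ---------------------------------------------------------------------------
# full LSHCT
# ---------------------------------------------------------------------------

class TestLshct:
    def test_chain_skeleton_recovered(self):
        data = sample(chain_network(0.1), 10_000, seed=21)
        dag = lshct(data, LshctConfig(neighbor_count=2))
        skel = {frozenset(e) for e in dag.edges}
        assert skel == {frozenset({"A", "B"}), frozenset({"B", "C"})}

    def test_independent_variables_give_empty_graph(self):
        data = independent_data(8000, 5, seed=22)
        dag = lshct(data, LshctConfig())
        assert dag.edges == frozenset()

    def test_output_acyclic_and_deterministic(self):
        for seed in range(6):
            truth = random_bn(6, edge_prob=0.4, seed=seed, n_states=2)
            data = sample(truth, 600, seed=seed + 100)
            cfg = LshctConfig(neighbor_count=3)
            a = lshct(data, cfg)
            a.topological_order()  # raises if cyclic
            b = lshct(data, cfg)
            assert a.edges == b.edges

    def test_score_not_below_assembled_stage(self):
        truth = random_bn(7, edge_prob=0.4, seed=30)
        data = sample(truth, 1000, seed=31)
        trace: dict = {}
        lshct(data, LshctConfig(), trace=trace)
        assert trace["score_final"] >= trace["score_assembled"] - 1e-9

    def test_expert_constraints_respected(self):
        data = sample(chain_network(0.1), 5000, seed=33)
        cfg = LshctConfig(expert_blacklist=frozenset({("A", "B"), ("B", "A")}))
        dag = lshct(data, cfg)
        assert ("A", "B") not in dag.edges and ("B", "A") not in dag.edges
        cfg2 = LshctConfig(expert_whitelist=frozenset({("A", "C")}))
        dag2 = lshct(data, cfg2)
        assert ("A", "C") in dag2.edges


# ---------------------------------------------------------------------------
# property tests
# ---------------------------------------------------------------------------

from hypothesis import given, settings, strategies as st

grade_columns = st.integers(2, 4).flatmap(
    lambda k: st.tuples(
        st.lists(st.integers(0, k - 1), min_size=3, max_size=40),
        st.lists(st.integers(0, k - 1), min_size=3, max_size=40),
    )
)


@settings(derandomize=True, max_examples=80, deadline=None)
@given(grade_columns)
def test_mutual_information_nonnegative_and_entropy_bounded(cols):
    """0 <= MI(X, Y) <= min(H(X), H(Y)) for any pair of grade columns."""
    xs, ys = cols
    n = min(len(xs), len(ys))
    x = [str(v) for v in xs[:n]]
    y = [str(v) for v in ys[:n]]
    mi = mutual_information(x, y)
    assert mi >= -1e-12
    hx = mutual_information(x, x)
    hy = mutual_information(y, y)
    assert mi <= min(hx, hy) + 1e-9


@settings(derandomize=True, max_examples=50, deadline=None)
@given(st.lists(st.sampled_from([("a", "b"), ("b", "a"), ("b", "c"),
                                 ("c", "b"), ("a", "c")]),
                min_size=1, max_size=12))
def test_merge_vote_resolution_properties(edge_votes):
    """Each pair keeps the majority direction, or both on an exact tie."""
    subs = [DagStructure(["a", "b", "c"], [e]) for e in edge_votes]
    merged = merge_sub_bns(subs)
    for pair in ({"a", "b"}, {"b", "c"}, {"a", "c"}):
        u, v = sorted(pair)
        fwd = edge_votes.count((u, v))
        rev = edge_votes.count((v, u))
        has_fwd = (u, v) in merged.edges
        has_rev = (v, u) in merged.edges
        if fwd == rev == 0:
            assert not has_fwd and not has_rev
        elif fwd > rev:
            assert has_fwd and not has_rev
        elif rev > fwd:
            assert has_rev and not has_fwd
        else:
            assert has_fwd and has_rev
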