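from __future__ import annotations

import math

import networkx as nx
import numpy as np
import pytest

from sbnet.bnlearn_core import (
    StructureConfig,
    bic_score,
    contingency_counts,
    g2_test,
    hill_climb,
    learn_skeleton,
    learn_structure,
    local_bic,
)
from sbnet.dataset import CategoricalDataset
from sbnet.synthetic_data import sample_categorical

from helpers import make_dataset


def _dataset_from_counts_2x2(n00, n01, n10, n11) -> CategoricalDataset:
    x = np.repeat([0, 0, 1, 1], [n00, n01, n10, n11])
    y = np.repeat([0, 1, 0, 1], [n00, n01, n10, n11])
    return make_dataset({"x": x, "y": y})


class TestContingencyCounts:
    def test_counts_sum_to_row_count(self):
        rng = np.random.default_rng(0)
        data = make_dataset({
            "x": rng.integers(0, 2, 100), "y": rng.integers(0, 2, 100),
        })
        counts = contingency_counts(data, "x", "y")
        assert counts.sum() == 100

    def test_overlapping_roles_rejected(self):
        data = make_dataset({"x": [0, 1], "y": [0, 1]})
        with pytest.raises(ValueError):
            contingency_counts(data, "x", "x")
        with pytest.raises(ValueError):
            contingency_counts(data, "x", "y", ["y"])

    def test_marginalizing_z_recovers_pair_counts(self):
        rng = np.random.default_rng(1)
        data = make_dataset({
            "x": rng.integers(0, 3, 500),
            "y": rng.integers(0, 2, 500),
            "z": rng.integers(0, 4, 500),
        })
        with_z = contingency_counts(data, "x", "y", ["z"])
        without = contingency_counts(data, "x", "y")
        np.testing.assert_array_equal(with_z.sum(axis=2), without[:, :, 0])


class TestG2Test:
    def test_exact_independence_gives_zero(self):
        data = _dataset_from_counts_2x2(25, 25, 25, 25)
        res = g2_test(data, "x", "y")
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)
        assert res.dof == 1

    def test_association_matches_direct_evaluation(self):
        # oracle: 2 * sum O ln(O/E) with every expected count equal to 20
        expected_stat = 2 * (
            30 * math.log(30 / 20) + 10 * math.log(10 / 20)
            + 10 * math.log(10 / 20) + 30 * math.log(30 / 20)
        )
        data = _dataset_from_counts_2x2(30, 10, 10, 30)
        res = g2_test(data, "x", "y")
        assert res.statistic == pytest.approx(expected_stat, rel=1e-12)
        assert res.statistic == pytest.approx(20.93, abs=0.005)
        assert res.dof == 1

    def test_single_level_variable_is_uninformative(self):
        data = make_dataset({"x": [0, 0, 0, 0], "y": [0, 1, 0, 1]}, cards={"x": 2})
        res = g2_test(data, "x", "y")
        assert res.dof == 0
        assert res.p_value == 1.0
        assert not res.informative

    def test_conditional_test_on_common_cause(self):
        # x <- z -> y: dependent marginally, independent given z
        rng = np.random.default_rng(2)
        n = 20000
        z = rng.integers(0, 2, n)
        x = (rng.random(n) < np.where(z == 1, 0.8, 0.2)).astype(int)
        y = (rng.random(n) < np.where(z == 1, 0.7, 0.3)).astype(int)
        data = make_dataset({"x": x, "y": y, "z": z})
        assert g2_test(data, "x", "y").p_value < 0.001
        assert g2_test(data, "x", "y", ["z"]).p_value > 0.01

    def test_x_equals_y_rejected(self):
        data = make_dataset({"x": [0, 1], "y": [0, 1]})
        with pytest.raises(ValueError):
            g2_test(data, "x", "x")


class TestBicScore:
    def test_closed_form_single_binary_variable(self):
        # 50/50 split, n=100: ll = 100 ln 0.5, penalty = (ln 100)/2
        data = make_dataset({"x": np.repeat([0, 1], 50)})
        g = nx.DiGraph()
        g.add_node("x")
        total, per_node = bic_score(data, g)
        expected = 100 * math.log(0.5) - math.log(100) / 2
        assert total == pytest.approx(expected, abs=1e-6)
        assert total == pytest.approx(-71.6173, abs=1e-3)
        assert per_node["x"] == pytest.approx(total)

    def test_score_is_sum_of_decomposition(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            p = int(rng.integers(3, 6))
            cols = {f"v{i}": rng.integers(0, 3, 150) for i in range(p)}
            data = make_dataset(cols)
            g = nx.DiGraph()
            g.add_nodes_from(cols)
            names = sorted(cols)
            for i, a in enumerate(names):
                for b in names[i + 1:]:
                    if rng.random() < 0.3:
                        g.add_edge(a, b)
            total, per_node = bic_score(data, g)
            assert total == pytest.approx(sum(per_node.values()), rel=1e-12)

    def test_adding_parent_to_independent_variable_lowers_score(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            data = make_dataset({
                "x": rng.integers(0, 2, 2000), "z": rng.integers(0, 3, 2000),
            })
            if local_bic(data, "x", ["z"]) < local_bic(data, "x", []):
                hits += 1
        assert hits >= 19

    def test_likelihood_equivalence_of_reversed_arc(self):
        rng = np.random.default_rng(4)
        x = rng.integers(0, 2, 500)
        y = (x + rng.integers(0, 2, 500)) % 2
        data = make_dataset({"x": x, "y": y})
        ab, ba = nx.DiGraph(), nx.DiGraph()
        ab.add_edge("x", "y")
        ba.add_edge("y", "x")
        assert bic_score(data, ab)[0] == pytest.approx(bic_score(data, ba)[0], rel=1e-12)

    def test_cyclic_graph_rejected(self):
        data = make_dataset({"x": [0, 1], "y": [0, 1]})
        g = nx.DiGraph([("x", "y"), ("y", "x")])
        with pytest.raises(ValueError):
            bic_score(data, g)


def _faithful_pair(n=10000, seed=0, dependent=True):
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 2, n)
    if dependent:
        y = (x ^ (rng.random(n) < 0.2)).astype(int)
    else:
        y = rng.integers(0, 2, n)
    return make_dataset({"x": x, "y": y})


class TestLearnSkeleton:
    def test_dependent_pair_retained(self):
        sk = learn_skeleton(_faithful_pair(dependent=True))
        assert sk.has_edge("x", "y")

    def test_independent_pair_absent(self):
        sk = learn_skeleton(_faithful_pair(dependent=False), alpha=0.05)
        assert not sk.has_edge("x", "y")

    def test_order_invariance(self):
        rng = np.random.default_rng(5)
        n = 2000
        z = rng.integers(0, 2, n)
        a = (z ^ (rng.random(n) < 0.3)).astype(int)
        b = (z ^ (rng.random(n) < 0.3)).astype(int)
        c = rng.integers(0, 3, n)
        d = (c + (rng.random(n) < 0.2)).astype(int) % 3
        cols = {"a": a, "b": b, "c": c, "d": d, "z": z}
        edges = None
        for order in (["a", "b", "c", "d", "z"], ["z", "d", "c", "b", "a"],
                      ["c", "z", "a", "d", "b"]):
            data = make_dataset({k: cols[k] for k in order}, cards={"c": 3, "d": 3})
            sk = learn_skeleton(data)
            found = {frozenset(e) for e in sk.edges}
            if edges is None:
                edges = found
            assert found == edges

    def test_empty_dataset_rejected(self):
        data = make_dataset({"x": np.array([], dtype=int), "y": np.array([], dtype=int)})
        with pytest.raises(ValueError):
            learn_skeleton(data)


class TestHillClimb:
    def _complete_skeleton(self, names):
        g = nx.Graph()
        g.add_nodes_from(names)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                g.add_edge(a, b)
        return g

    def test_independent_variables_give_empty_graph(self):
        data = _faithful_pair(dependent=False)
        g = hill_climb(data, self._complete_skeleton(["x", "y"]))
        assert g.number_of_edges() == 0

    def test_deterministic_copy_gives_single_edge(self):
        rng = np.random.default_rng(6)
        x = rng.integers(0, 2, 10000)
        data = make_dataset({"x": x, "y": x.copy()})
        g = hill_climb(data, self._complete_skeleton(["x", "y"]))
        assert g.number_of_edges() == 1
        assert {frozenset(e) for e in g.edges} == {frozenset(("x", "y"))}

    def test_score_trace_strictly_increasing(self, test_data):
        trace: list[float] = []
        sk = learn_skeleton(test_data)
        hill_climb(test_data, sk, trace=trace)
        assert len(trace) > 0
        assert all(b > a for a, b in zip(trace, trace[1:]))

    def test_additions_limited_to_skeleton(self):
        rng = np.random.default_rng(7)
        x = rng.integers(0, 2, 5000)
        y = (x ^ (rng.random(5000) < 0.1)).astype(int)
        data = make_dataset({"x": x, "y": y})
        restrict = nx.Graph()
        restrict.add_nodes_from(["x", "y"])  # no edges allowed
        g = hill_climb(data, restrict)
        assert g.number_of_edges() == 0

    def test_result_is_acyclic(self, test_data):
        sk = learn_skeleton(test_data)
        g = hill_climb(test_data, sk)
        assert nx.is_directed_acyclic_graph(g)


class TestLearnStructure:
    def test_chain_skeleton_recovered(self, chain_model):
        data = sample_categorical(chain_model, 20000, seed=21)
        g = learn_structure(data)
        assert {frozenset(e) for e in g.edges} == {
            frozenset(("A", "B")), frozenset(("B", "C"))
        }

    def test_collider_recovered_without_spurious_edge(self):
        rng = np.random.default_rng(8)
        n = 20000
        a = rng.integers(0, 2, n)
        b = rng.integers(0, 2, n)
        c = (rng.random(n) < (0.15 + 0.45 * a + 0.3 * b)).astype(int)
        data = make_dataset({"a": a, "b": b, "c": c})
        g = learn_structure(data)
        und = {frozenset(e) for e in g.edges}
        assert frozenset(("a", "c")) in und
        assert frozenset(("b", "c")) in und
        assert frozenset(("a", "b")) not in und

    def test_single_variable_gives_empty_graph(self):
        data = make_dataset({"x": [0, 1, 0, 1]})
        g = learn_structure(data)
        assert g.number_of_edges() == 0
        assert set(g.nodes) == {"x"}

    def test_shd_non_increasing_in_n(self, test_model):
        """Average structural Hamming distance to the true skeleton shrinks
        (or stays) as the sample grows."""
        from helpers import structural_hamming_distance

        truth = test_model.skeleton_edges()
        means = []
        for n in (500, 2000, 10000):
            shd = []
            for seed in range(5):
                data = sample_categorical(test_model, n, seed=100 + seed)
                g = learn_structure(data)
                shd.append(structural_hamming_distance(
                    {frozenset(e) for e in g.edges}, truth))
            means.append(float(np.mean(shd)))
        assert means[0] >= means[1] >= means[2]

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            StructureConfig(alpha=1.5)
        with pytest.raises(ValueError):
            StructureConfig(max_sepset=-1)
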