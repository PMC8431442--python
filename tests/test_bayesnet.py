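import networkx as nx
import numpy as np
import pandas as pd
import pytest

from evmir.bayesnet import (
    DiscreteDataset,
    add_pathology_nodes,
    bdeu_family_score,
    bic_family_score,
    discretize_by_median,
    exhaustive_search,
    hill_climb,
    neighborhood,
    sample_binary_network,
    tabu_search,
)


class TestDiscretize:
    def test_even_n_median_is_midpoint(self):
        norm = pd.DataFrame([[1, 2, 3, 4]], index=["m"], columns=list("abcd"))
        ds = discretize_by_median(norm)
        assert [ds.levels["m"][c] for c in ds.column("m")] == ["low", "low", "high", "high"]

    def test_constant_row_is_all_high(self):
        norm = pd.DataFrame([[5, 5, 5]], index=["m"], columns=list("abc"))
        ds = discretize_by_median(norm)
        assert ds.column("m").tolist() == [1, 1, 1]

    def test_tied_median(self):
        norm = pd.DataFrame([[1, 2, 2, 9]], index=["m"], columns=list("abcd"))
        ds = discretize_by_median(norm)  # median 2, >= rule
        assert ds.column("m").tolist() == [0, 1, 1, 1]


class TestPathologyNodes:
    @staticmethod
    def _samples():
        return pd.DataFrame({
            "diagnosis": ["CP", "PDAC", "PDAC", "healthy"],
            "metastasis": [None, "M1", "M0", None],
        }, index=list("abcd"))

    def test_indicator_encoding(self):
        norm = pd.DataFrame([[1, 2, 3, 4]], index=["m"], columns=list("abcd"))
        ds = add_pathology_nodes(discretize_by_median(norm), self._samples())
        frame = ds.to_frame()
        # CP specimen
        assert frame.loc[0, ["cancer", "pancreatitis", "metastasis"]].tolist() == \
            ["false", "true", "false"]
        # M1 PDAC
        assert frame.loc[1, ["cancer", "pancreatitis", "metastasis"]].tolist() == \
            ["true", "false", "true"]
        # M0 PDAC
        assert frame.loc[2, ["cancer", "pancreatitis", "metastasis"]].tolist() == \
            ["true", "false", "false"]

    def test_unknown_diagnosis_rejected(self):
        samples = self._samples()
        samples.loc["a", "diagnosis"] = "IPMN"
        norm = pd.DataFrame([[1, 2, 3, 4]], index=["m"], columns=list("abcd"))
        with pytest.raises(ValueError, match="unknown diagnosis"):
            add_pathology_nodes(discretize_by_median(norm), samples)


def _dataset(columns: dict) -> DiscreteDataset:
    names = list(columns)
    data = np.column_stack([columns[v] for v in names])
    return DiscreteDataset(data, names, {v: ("low", "high") for v in names})


class TestBicFamilyScore:
    def test_hand_computed_marginal(self):
        ds = _dataset({"x": [1, 1, 1, 0]})
        expected = 3 * np.log(3 / 4) + 1 * np.log(1 / 4) - 0.5 * np.log(4)
        assert bic_family_score(ds, "x", ()) == pytest.approx(expected)

    def test_deterministic_copy_parent_raises_score(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 2, size=100)
        ds = _dataset({"a": a, "b": a.copy()})
        assert bic_family_score(ds, "b", ("a",)) > bic_family_score(ds, "b", ())

    def test_independent_parent_lowers_score_usually(self):
        wins = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            ds = _dataset({"a": rng.integers(0, 2, 300),
                           "b": rng.integers(0, 2, 300)})
            wins += bic_family_score(ds, "b", ("a",)) < bic_family_score(ds, "b", ())
        assert wins >= 38  # penalty dominates in >= 95% of null draws

    def test_child_cannot_be_its_own_parent(self):
        ds = _dataset({"a": [0, 1]})
        with pytest.raises(ValueError):
            bic_family_score(ds, "a", ("a",))

    def test_bdeu_alternative_agrees_on_dependence_direction(self):
        rng = np.random.default_rng(1)
        a = rng.integers(0, 2, size=400)
        b = np.where(rng.uniform(size=400) < 0.9, a, 1 - a)
        ds = _dataset({"a": a, "b": b})
        assert bdeu_family_score(ds, "b", ("a",)) > bdeu_family_score(ds, "b", ())


class TestExhaustiveSearch:
    def test_single_node_empty_dag(self):
        ds = _dataset({"a": [0, 1, 0, 1]})
        dag = exhaustive_search(ds)
        assert dag.edges == []

    def test_two_independent_variables_empty(self):
        rng = np.random.default_rng(3)
        ds = _dataset({"a": rng.integers(0, 2, 1000),
                       "b": rng.integers(0, 2, 1000)})
        assert exhaustive_search(ds).edges == []

    def test_two_correlated_variables_one_edge(self):
        rng = np.random.default_rng(4)
        a = rng.integers(0, 2, 1000)
        ds = _dataset({"a": a, "b": a.copy()})
        dag = exhaustive_search(ds)
        assert len(dag.edges) == 1  # either orientation scores equally; tie-break
        assert dag.edges == [("a", "b")]  # lexicographically least edge set

    def test_rejects_more_than_four_variables(self):
        ds = _dataset({v: [0, 1] for v in "abcde"})
        with pytest.raises(ValueError):
            exhaustive_search(ds)


class TestTabuSearch:
    def test_independent_variables_give_empty_dag(self):
        ds = sample_binary_network(list("abcd"), [], n_obs=500, seed=7,
                                   cpt_range=(0.4, 0.6))
        dag = tabu_search(ds)
        oracle = exhaustive_search(ds)
        assert dag.score == pytest.approx(oracle.score, abs=1e-9)
        assert dag.edges == []

    def test_chain_recovers_equivalence_class(self):
        ds = sample_binary_network(list("abc"), [("a", "b"), ("b", "c")],
                                   n_obs=500, seed=8, cpt_range=(0.05, 0.95))
        dag = tabu_search(ds)
        oracle = exhaustive_search(ds)
        assert dag.score == pytest.approx(oracle.score, abs=1e-9)
        skeleton = {frozenset(e) for e in dag.edges}
        assert skeleton == {frozenset(("a", "b")), frozenset(("b", "c"))}

    def test_deterministic_given_data(self):
        ds = sample_binary_network(list("abcd"), [("a", "b"), ("c", "d")],
                                   n_obs=300, seed=9)
        d1, d2 = tabu_search(ds, seed=1), tabu_search(ds, seed=2)
        assert d1.edges == d2.edges and d1.score == d2.score

    def test_result_is_acyclic_with_consistent_score(self):
        ds = sample_binary_network(list("abcde"),
                                   [("a", "b"), ("b", "c"), ("a", "d")],
                                   n_obs=300, seed=10)
        dag = tabu_search(ds)
        assert nx.is_directed_acyclic_graph(dag.graph)
        # decomposability: total equals freshly computed family sum
        total = sum(bic_family_score(ds, v, tuple(dag.parents(v)))
                    for v in dag.nodes)
        assert dag.score == pytest.approx(total, abs=1e-9)

    def test_tabu_never_worse_than_greedy_ablation(self):
        for seed in range(6):
            ds = sample_binary_network(
                list("abcd"), [("a", "b"), ("b", "c"), ("c", "d")],
                n_obs=400, seed=seed)
            assert tabu_search(ds).score >= hill_climb(ds).score - 1e-9

    def test_rejects_nonpositive_max_iter(self):
        ds = _dataset({"a": [0, 1], "b": [1, 0]})
        with pytest.raises(ValueError):
            tabu_search(ds, max_iter=0)


class TestNeighborhood:
    def test_chain_midpoint(self):
        ds = sample_binary_network(list("abc"), [("a", "b"), ("b", "c")],
                                   n_obs=10, seed=0)
        g = nx.DiGraph([("a", "b"), ("b", "c")])
        from evmir.bayesnet import Dag
        dag = Dag(graph=g, score=0.0)
        causes, consequences, sub = neighborhood(dag, "b")
        assert causes == {"a"} and consequences == {"c"}
        assert set(sub.nodes) == {"a", "b", "c"}

    def test_isolated_node(self):
        g = nx.DiGraph()
        g.add_nodes_from("ab")
        from evmir.bayesnet import Dag
        causes, consequences, _ = neighborhood(Dag(graph=g, score=0.0), "a")
        assert causes == set() and consequences == set()

    def test_unknown_node(self):
        g = nx.DiGraph()
        g.add_node("a")
        from evmir.bayesnet import Dag
        with pytest.raises(KeyError):
            neighborhood(Dag(graph=g, score=0.0), "zz")


def test_cancer_child_recovery_single_run():
    """A miRNA generated as a child of the cancer indicator shows up in the
    cancer node's learned neighborhood."""
    rng = np.random.default_rng(42)
    n = 200
    cancer = rng.integers(0, 2, n)
    mir_child = np.where(rng.uniform(size=n) < 0.9, cancer, 1 - cancer)
    noise = rng.integers(0, 2, size=(n, 3))
    ds = DiscreteDataset(
        np.column_stack([cancer, mir_child, noise]),
        ["cancer", "miR-child", "n1", "n2", "n3"],
        {v: ("low", "high") for v in ["cancer", "miR-child", "n1", "n2", "n3"]},
    )
    dag = tabu_search(ds)
    causes, consequences, _ = neighborhood(dag, "cancer")
    assert "miR-child" in causes | consequences
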