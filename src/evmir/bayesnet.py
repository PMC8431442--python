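"""Discrete Bayesian-network structure learning over median-discretized miRNAs.

Normalized expression is discretized per miRNA at its median (values at or
above the median are "high"), three pathology indicator nodes (cancer,
pancreatitis, metastasis) are appended, and a directed acyclic graph is
learned by score-based search: greedy single-edge moves (add / delete /
reverse) maximizing the BIC of the multinomial model, with a tabu list of
recently reversed moves so the search can cross small score plateaus.
An exhaustive enumeration over all DAGs (feasible up to 4 variables) serves
as the optimality oracle.  Cause/consequence analysis of a node is its
parent and child set in the learned DAG.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from itertools import combinations, product

import networkx as nx
import numpy as np
import pandas as pd

PATHOLOGY_NODES = ("cancer", "pancreatitis", "metastasis")

__all__ = [
    "DiscreteDataset",
    "Dag",
    "discretize_by_median",
    "add_pathology_nodes",
    "bic_family_score",
    "bdeu_family_score",
    "tabu_search",
    "hill_climb",
    "exhaustive_search",
    "sample_binary_network",
    "neighborhood",
]


@dataclass
class DiscreteDataset:
    """Integer-coded discrete observations, one row per specimen."""

    data: np.ndarray  # (n_obs, n_vars) small ints
    variables: list[str]
    levels: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.int64)
        if self.data.ndim != 2 or self.data.shape[1] != len(self.variables):
            raise ValueError("data shape does not match variable list")
        if len(set(self.variables)) != len(self.variables):
            raise ValueError("duplicate variable names")

    @property
    def n_obs(self) -> int:
        return self.data.shape[0]

    def cardinality(self, var: str) -> int:
        return len(self.levels[var])

    def column(self, var: str) -> np.ndarray:
        return self.data[:, self.variables.index(var)]

    def to_frame(self) -> pd.DataFrame:
        cols = {}
        for v in self.variables:
            lv = self.levels[v]
            cols[v] = [lv[c] for c in self.column(v)]
        return pd.DataFrame(cols)


def discretize_by_median(norm_values: pd.DataFrame,
                         specimen_index: pd.Index | None = None) -> DiscreteDataset:
    """Binarize each miRNA at its own median across specimens.

    high (code 1) iff value >= median, low (code 0) otherwise; the median of
    an even number of specimens is the midpoint of the two central order
    statistics, so a constant row is all-high.
    """
    if norm_values.shape[1] < 2:
        raise ValueError("need >= 2 specimens")
    values = norm_values.to_numpy(dtype=float)
    med = np.median(values, axis=1, keepdims=True)
    codes = (values >= med).astype(np.int64).T  # specimens x miRNAs
    variables = list(norm_values.index)
    levels = {v: ("low", "high") for v in variables}
    ds = DiscreteDataset(codes, variables, levels)
    ds.specimen_ids = list(specimen_index if specimen_index is not None else norm_values.columns)
    return ds


def add_pathology_nodes(dataset: DiscreteDataset, samples: pd.DataFrame) -> DiscreteDataset:
    """Append cancer / pancreatitis / metastasis indicator variables.

    cancer is true for PDAC specimens, pancreatitis for CP specimens, and
    metastasis only for M1 PDAC specimens.
    """
    ids = getattr(dataset, "specimen_ids", None)
    if ids is None:
        raise ValueError("dataset lacks specimen ids; build it with discretize_by_median")
    sub = samples.loc[ids]
    diag = sub["diagnosis"]
    unknown = set(diag.unique()) - {"PDAC", "CP", "healthy"}
    if unknown:
        raise ValueError(f"unknown diagnosis labels: {unknown}")
    cancer = (diag == "PDAC").to_numpy(dtype=np.int64)
    panc = (diag == "CP").to_numpy(dtype=np.int64)
    if "metastasis" in sub.columns:
        met = ((diag == "PDAC") & (sub["metastasis"] == "M1")).to_numpy(dtype=np.int64)
    else:
        met = np.zeros(len(sub), dtype=np.int64)
    data = np.column_stack([dataset.data, cancer, panc, met])
    variables = dataset.variables + list(PATHOLOGY_NODES)
    levels = dict(dataset.levels)
    for v in PATHOLOGY_NODES:
        levels[v] = ("false", "true")
    out = DiscreteDataset(data, variables, levels)
    out.specimen_ids = list(ids)
    return out


def _family_counts(child_col: np.ndarray, parent_cols: list[np.ndarray],
                   r: int, parent_cards: list[int]) -> np.ndarray:
    """Contingency counts of the child against joint parent configurations,
    shape (q, r)."""
    if parent_cols:
        q = int(np.prod(parent_cards))
        idx = np.zeros(len(child_col), dtype=np.int64)
        for col, card in zip(parent_cols, parent_cards):
            idx = idx * card + col
        flat = idx * r + child_col
        return np.bincount(flat, minlength=q * r).reshape(q, r)
    return np.bincount(child_col, minlength=r).reshape(1, r)


def bic_family_score(dataset: DiscreteDataset, child: str,
                     parents: tuple[str, ...] | list[str]) -> float:
    """BIC term for one family: multinomial log-likelihood of the child given
    each parent configuration, minus (ln n / 2) * (r - 1) * q free parameters.

    Empty parent configurations and zero cells contribute nothing
    (0 * ln 0 = 0).
    """
    if child in parents:
        raise ValueError("child cannot be its own parent")
    r = dataset.cardinality(child)
    pcols = [dataset.column(p) for p in parents]
    pcards = [dataset.cardinality(p) for p in parents]
    counts = _family_counts(dataset.column(child), pcols, r, pcards)
    n_j = counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.where(counts > 0, counts * np.log(counts / n_j), 0.0).sum()
    q = counts.shape[0]
    penalty = 0.5 * np.log(dataset.n_obs) * (r - 1) * q
    return float(ll - penalty)


def bdeu_family_score(dataset: DiscreteDataset, child: str,
                      parents: tuple[str, ...] | list[str],
                      ess: float = 1.0) -> float:
    """BDeu family score (Dirichlet-multinomial marginal likelihood with an
    equivalent sample size), the Bayesian alternative to BIC."""
    from scipy.special import gammaln

    if child in parents:
        raise ValueError("child cannot be its own parent")
    r = dataset.cardinality(child)
    pcols = [dataset.column(p) for p in parents]
    pcards = [dataset.cardinality(p) for p in parents]
    counts = _family_counts(dataset.column(child), pcols, r, pcards)
    q = counts.shape[0]
    a_jk = ess / (q * r)
    a_j = ess / q
    n_j = counts.sum(axis=1)
    score = (gammaln(a_j) - gammaln(a_j + n_j)).sum()
    score += (gammaln(a_jk + counts) - gammaln(a_jk)).sum()
    return float(score)


_SCORERS = {"bic": bic_family_score, "bdeu": bdeu_family_score}


@dataclass
class Dag:
    """A learned structure: directed edges, per-node parent sets, total score
    (the sum of family score terms)."""

    graph: nx.DiGraph
    score: float
    family_scores: dict[str, float] = field(default_factory=dict, repr=False)

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return sorted(self.graph.edges)

    def parents(self, node: str) -> set[str]:
        return set(self.graph.predecessors(node))

    def children(self, node: str) -> set[str]:
        return set(self.graph.successors(node))


class _ScoreCache:
    def __init__(self, dataset: DiscreteDataset, score: str):
        self.dataset = dataset
        self.fn = _SCORERS[score]
        self.cache: dict[tuple[str, tuple[str, ...]], float] = {}

    def __call__(self, child: str, parents) -> float:
        key = (child, tuple(sorted(parents)))
        if key not in self.cache:
            self.cache[key] = self.fn(self.dataset, child, key[1])
        return self.cache[key]


def _total_score(scorer: _ScoreCache, g: nx.DiGraph) -> float:
    return sum(scorer(v, tuple(g.predecessors(v))) for v in g.nodes)


def _candidate_moves(variables: list[str], g: nx.DiGraph):
    """All single-edge moves in lexicographic order: (op, u, v)."""
    for u, v in combinations(variables, 2):
        for a, b in ((u, v), (v, u)):
            if g.has_edge(a, b):
                yield ("delete", a, b)
                yield ("reverse", a, b)
            elif not g.has_edge(b, a):
                yield ("add", a, b)


def _move_delta(scorer: _ScoreCache, g: nx.DiGraph, move) -> float | None:
    """Score change of a move, or None when it would create a cycle."""
    op, u, v = move
    pv = set(g.predecessors(v))
    if op == "add":
        if u == v or nx.has_path(g, v, u):
            return None
        return scorer(v, pv | {u}) - scorer(v, pv)
    if op == "delete":
        return scorer(v, pv - {u}) - scorer(v, pv)
    # reverse u->v to v->u
    g.remove_edge(u, v)
    creates_cycle = nx.has_path(g, u, v)
    g.add_edge(u, v)
    if creates_cycle:
        return None
    pu = set(g.predecessors(u))
    return (scorer(v, pv - {u}) - scorer(v, pv)
            + scorer(u, pu | {v}) - scorer(u, pu))


def _apply(g: nx.DiGraph, move) -> None:
    op, u, v = move
    if op == "add":
        g.add_edge(u, v)
    elif op == "delete":
        g.remove_edge(u, v)
    else:
        g.remove_edge(u, v)
        g.add_edge(v, u)


def _result_state(state: frozenset, move) -> frozenset:
    op, u, v = move
    if op == "add":
        return state | {(u, v)}
    if op == "delete":
        return state - {(u, v)}
    return (state - {(u, v)}) | {(v, u)}


def tabu_search(dataset: DiscreteDataset, max_iter: int = 10_000,
                tabu_len: int = 10, patience: int = 10, seed: int = 0,
                score: str = "bic") -> Dag:
    """Score-based DAG search with a tabu list.

    Greedy hill climbing over single-edge additions, deletions and reversals.
    The tabu list holds the last ``tabu_len`` visited structures (edge sets),
    so undoing a recent move — in particular bouncing between score-equivalent
    DAGs — is barred; when no move improves, the least-worsening non-tabu
    move is still taken for up to ``patience`` iterations without a new
    incumbent, which lets the search slide across score plateaus and out of
    shallow local optima.  Fully deterministic: moves are enumerated in
    lexicographic order and the first best move wins; ``seed`` is accepted
    for interface symmetry with the stochastic parts of the pipeline.
    """
    if max_iter <= 0:
        raise ValueError("max_iter must be positive")
    del seed  # deterministic search; kept for a uniform call signature
    scorer = _ScoreCache(dataset, score)
    g = nx.DiGraph()
    g.add_nodes_from(dataset.variables)
    current = _total_score(scorer, g)
    state = frozenset(g.edges)
    best_edges, best_score = state, current
    tabu: deque = deque(maxlen=tabu_len)
    since_best = 0
    for _ in range(max_iter):
        best_move, best_delta = None, -np.inf
        for move in _candidate_moves(dataset.variables, g):
            if _result_state(state, move) in tabu:
                continue
            delta = _move_delta(scorer, g, move)
            if delta is not None and delta > best_delta + 1e-12:
                best_move, best_delta = move, delta
        if best_move is None:
            break
        if best_delta <= 1e-12 and since_best >= patience:
            break  # plateau/worsening and the incumbent has stopped improving
        _apply(g, best_move)
        tabu.append(state)
        state = _result_state(state, best_move)
        current += best_delta
        if current > best_score + 1e-12:
            best_score, best_edges = current, state
            since_best = 0
        else:
            since_best += 1
    final = nx.DiGraph()
    final.add_nodes_from(dataset.variables)
    final.add_edges_from(sorted(best_edges))
    fam = {v: scorer(v, tuple(final.predecessors(v))) for v in final.nodes}
    return Dag(graph=final, score=sum(fam.values()), family_scores=fam)


def hill_climb(dataset: DiscreteDataset, max_iter: int = 10_000,
               score: str = "bic") -> Dag:
    """Plain greedy hill climbing (the no-tabu ablation of tabu_search)."""
    return tabu_search(dataset, max_iter=max_iter, tabu_len=0, patience=0, score=score)


def exhaustive_search(dataset: DiscreteDataset, score: str = "bic") -> Dag:
    """Globally optimal DAG by enumeration; feasible only for <= 4 variables.

    Every unordered variable pair is assigned one of {no edge, ->, <-} and
    cyclic assignments are discarded.  Ties go to the lexicographically least
    edge set.
    """
    variables = dataset.variables
    if len(variables) > 4:
        raise ValueError("exhaustive enumeration limited to 4 variables")
    scorer = _ScoreCache(dataset, score)
    pairs = list(combinations(variables, 2))
    best = None
    for assignment in product((0, 1, 2), repeat=len(pairs)):
        g = nx.DiGraph()
        g.add_nodes_from(variables)
        for (u, v), a in zip(pairs, assignment):
            if a == 1:
                g.add_edge(u, v)
            elif a == 2:
                g.add_edge(v, u)
        if not nx.is_directed_acyclic_graph(g):
            continue
        total = _total_score(scorer, g)
        key = (-total, sorted(g.edges))
        if best is None or key < best[0]:
            best = (key, g)
    g = best[1]
    fam = {v: scorer(v, tuple(g.predecessors(v))) for v in g.nodes}
    return Dag(graph=g, score=sum(fam.values()), family_scores=fam)


def sample_binary_network(variables: list[str], edges: list[tuple[str, str]],
                          n_obs: int, seed: int,
                          cpt_range: tuple[float, float] = (0.1, 0.9),
                          levels: tuple[str, str] = ("low", "high")) -> DiscreteDataset:
    """Synthetic binary observations from a known generating DAG.

    Each node gets a conditional probability table drawn uniformly from
    ``cpt_range`` per parent configuration; sampling follows a topological
    order.  Used to validate structure learning against known ground truth.
    """
    rng = np.random.default_rng(seed)
    g = nx.DiGraph()
    g.add_nodes_from(variables)
    g.add_edges_from(edges)
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("generating structure must be acyclic")
    data = np.zeros((n_obs, len(variables)), dtype=np.int64)
    col = {v: i for i, v in enumerate(variables)}
    for v in nx.topological_sort(g):
        parents = sorted(g.predecessors(v))
        q = 2 ** len(parents)
        probs = rng.uniform(*cpt_range, size=q)
        if parents:
            idx = np.zeros(n_obs, dtype=np.int64)
            for p in parents:
                idx = idx * 2 + data[:, col[p]]
            p_high = probs[idx]
        else:
            p_high = np.full(n_obs, probs[0])
        data[:, col[v]] = (rng.uniform(size=n_obs) < p_high).astype(np.int64)
    return DiscreteDataset(data, list(variables), {v: levels for v in variables})


def neighborhood(dag: Dag, node: str) -> tuple[set[str], set[str], nx.DiGraph]:
    """Causes (parents), consequences (children) and the induced subnetwork
    over the node and its neighborhood."""
    if node not in dag.graph:
        raise KeyError(f"unknown node {node!r}")
    causes = dag.parents(node)
    consequences = dag.children(node)
    sub = dag.graph.subgraph({node} | causes | consequences).copy()
    return causes, consequences, sub
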