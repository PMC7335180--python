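"""Discrete Bayesian network learning over module-score, static and aux nodes.

The joint distribution factorizes as p(x_1..x_n) = prod_v p(x_v | x_pa(v)).
Structure is learned by score-based local search (greedy hill climbing with
random restarts, or tabu search) under a node-level edge blacklist/whitelist;
whitelisted edges are clamped and never removed.  The structure score is a
decomposable Bayesian-Dirichlet marginal likelihood with a uniform
pseudo-count ``alpha`` per CPT cell (equivalent sample size alpha * prod
levels per family), consistent with the Dirichlet-smoothed parameter
estimate theta = (count + alpha) / (N + alpha * L).

Model selection across search algorithms uses k-fold cross-validation on the
negated held-out log-likelihood; edge confidence is quantified by a
nonparametric bootstrap over patients.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import gammaln

from .schema import ConstraintSet

_EPS = 1e-10
_MAX_CELLS = 2_000_000  # guard against parent-set blow-up


class BayesNetError(ValueError):
    pass


@dataclass
class DiscreteBN:
    """DAG + Dirichlet-smoothed CPTs over discrete nodes.

    ``cpts[v]`` has shape (*levels of parents in ``parents[v]`` order,
    levels[v]); every row sums to 1.
    """

    nodes: list[str]
    levels: dict[str, int]
    parents: dict[str, tuple[str, ...]]
    cpts: dict[str, np.ndarray]
    alpha: float = 1.0

    def __post_init__(self):
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            raise BayesNetError("graph is not a DAG")
        for v in self.nodes:
            cpt = self.cpts[v]
            want = tuple(self.levels[p] for p in self.parents[v]) + (self.levels[v],)
            if cpt.shape != want:
                raise BayesNetError(f"CPT shape mismatch for {v!r}: {cpt.shape} != {want}")
            if not np.allclose(cpt.sum(axis=-1), 1.0, atol=1e-9):
                raise BayesNetError(f"CPT rows of {v!r} do not sum to 1")

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for v, ps in self.parents.items():
            g.add_edges_from((p, v) for p in ps)
        return g

    @property
    def edges(self) -> list[tuple[str, str]]:
        return sorted((p, v) for v, ps in self.parents.items() for p in ps)

    def topological_order(self) -> list[str]:
        return list(nx.lexicographical_topological_sort(self.graph()))

    def copy(self) -> "DiscreteBN":
        return DiscreteBN(list(self.nodes), dict(self.levels),
                          {v: tuple(p) for v, p in self.parents.items()},
                          {v: c.copy() for v, c in self.cpts.items()}, self.alpha)

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "nodes": self.nodes,
            "levels": self.levels,
            "parents": {v: list(p) for v, p in self.parents.items()},
            "cpts": {v: c.tolist() for v, c in self.cpts.items()},
            "alpha": self.alpha,
        }

    def save(self, path: str | Path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, raw: dict) -> "DiscreteBN":
        return cls(list(raw["nodes"]), {k: int(v) for k, v in raw["levels"].items()},
                   {v: tuple(p) for v, p in raw["parents"].items()},
                   {v: np.asarray(c, float) for v, c in raw["cpts"].items()},
                   float(raw.get("alpha", 1.0)))

    @classmethod
    def load(cls, path: str | Path) -> "DiscreteBN":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def edge_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.edges, columns=["from", "to"])


@dataclass
class EdgeConfidence:
    """Relative bootstrap frequency per directed edge."""

    frequencies: dict[tuple[str, str], float]
    n_replicates: int

    def __getitem__(self, edge: tuple[str, str]) -> float:
        return self.frequencies.get(edge, 0.0)

    def to_frame(self) -> pd.DataFrame:
        rows = [(u, v, f) for (u, v), f in sorted(self.frequencies.items())]
        return pd.DataFrame(rows, columns=["from", "to", "frequency"])


# ---------------------------------------------------------------------------
# data handling


def _codes(data: pd.DataFrame, levels: dict[str, int] | None = None
           ) -> tuple[np.ndarray, list[str], np.ndarray]:
    cols = list(data.columns)
    arr = data.to_numpy()
    codes = np.empty((len(data), len(cols)), dtype=np.int64)
    for j, c in enumerate(cols):
        col = np.asarray(arr[:, j], float)
        if np.isnan(col).any():
            raise BayesNetError(f"missing values in column {c!r}")
        rounded = np.rint(col)
        if not np.allclose(col, rounded):
            raise BayesNetError(f"non-discrete column {c!r}")
        codes[:, j] = rounded.astype(np.int64)
        if codes[:, j].min() < 0:
            raise BayesNetError(f"negative level in column {c!r}")
    if levels is None:
        lv = codes.max(axis=0) + 1
    else:
        lv = np.array([levels[c] for c in cols], dtype=np.int64)
        for j, c in enumerate(cols):
            if codes[:, j].max() >= lv[j]:
                raise BayesNetError(f"level out of range in column {c!r}")
    return codes, cols, lv


class _FamilyScorer:
    """Cached decomposable BD family scores on integer-coded data."""

    def __init__(self, codes: np.ndarray, levels: np.ndarray, alpha: float):
        self.codes = codes
        self.levels = levels
        self.alpha = alpha
        self.cache: dict[tuple[int, tuple[int, ...]], float] = {}

    def family_counts(self, v: int, parents: tuple[int, ...]) -> np.ndarray:
        L = int(self.levels[v])
        q = int(np.prod(self.levels[list(parents)])) if parents else 1
        if q * L > _MAX_CELLS:
            raise BayesNetError("parent set too large for counting")
        idx = self.codes[:, v].copy()
        mult = L
        for p in parents:
            idx += self.codes[:, p] * mult
            mult *= int(self.levels[p])
        return np.bincount(idx, minlength=q * L).reshape(q, L)

    def score(self, v: int, parents: tuple[int, ...]) -> float:
        key = (v, tuple(sorted(parents)))
        if key in self.cache:
            return self.cache[key]
        counts = self.family_counts(v, key[1])
        a = self.alpha
        L = counts.shape[1]
        nj = counts.sum(axis=1)
        s = float(
            gammaln(a + counts).sum() - counts.size * gammaln(a)
            + len(nj) * gammaln(L * a) - gammaln(L * a + nj).sum()
        )
        self.cache[key] = s
        return s


# ---------------------------------------------------------------------------
# local search


def _has_path(adj: dict[int, set[int]], src: int, dst: int) -> bool:
    # DFS over child adjacency
    stack, seen = [src], set()
    while stack:
        u = stack.pop()
        if u == dst:
            return True
        for w in adj[u]:
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return False


def _search(scorer: _FamilyScorer, n_nodes: int,
            blacklist: set[tuple[int, int]], whitelist: set[tuple[int, int]],
            start_parents: dict[int, set[int]], tabu_len: int = 0,
            max_steps: int = 10_000) -> tuple[dict[int, set[int]], float]:
    parents = {v: set(ps) for v, ps in start_parents.items()}
    children = {v: set() for v in range(n_nodes)}
    for v, ps in parents.items():
        for p in ps:
            children[p].add(v)

    def fam(v):
        return scorer.score(v, tuple(parents[v]))

    score = sum(fam(v) for v in range(n_nodes))
    tabu: list[tuple[str, int, int]] = []

    pairs = [(u, v) for u in range(n_nodes) for v in range(n_nodes) if u != v]
    for _ in range(max_steps):
        best_delta, best_move = _EPS, None
        for u, v in pairs:
            if u in parents[v]:
                if (u, v) not in whitelist:
                    # delete u -> v
                    if ("del", u, v) not in tabu:
                        old = scorer.score(v, tuple(parents[v]))
                        new = scorer.score(v, tuple(parents[v] - {u}))
                        d = new - old
                        if d > best_delta:
                            best_delta, best_move = d, ("del", u, v)
                    # reverse u -> v
                    if (v, u) not in blacklist and ("rev", u, v) not in tabu:
                        children[u].discard(v)
                        cyc = _has_path({k: c for k, c in children.items()}, u, v)
                        children[u].add(v)
                        if not cyc:
                            d = (scorer.score(v, tuple(parents[v] - {u}))
                                 - scorer.score(v, tuple(parents[v]))
                                 + scorer.score(u, tuple(parents[u] | {v}))
                                 - scorer.score(u, tuple(parents[u])))
                            if d > best_delta:
                                best_delta, best_move = d, ("rev", u, v)
            else:
                # add u -> v
                if (u, v) in blacklist or ("add", u, v) in tabu:
                    continue
                if _has_path(children, v, u):
                    continue
                try:
                    d = (scorer.score(v, tuple(parents[v] | {u}))
                         - scorer.score(v, tuple(parents[v])))
                except BayesNetError:
                    continue
                if d > best_delta:
                    best_delta, best_move = d, ("add", u, v)
        if best_move is None:
            break
        op, u, v = best_move
        assert best_delta > 0  # local search never accepts score-lowering moves
        if op == "add":
            parents[v].add(u)
            children[u].add(v)
            undo = ("del", u, v)
        elif op == "del":
            parents[v].discard(u)
            children[u].discard(v)
            undo = ("add", u, v)
        else:
            parents[v].discard(u)
            children[u].discard(v)
            parents[u].add(v)
            children[v].add(u)
            undo = ("rev", v, u)
        score += best_delta
        if tabu_len > 0:
            tabu.append(undo)
            tabu = tabu[-tabu_len:]
    return parents, score


def _constraint_indices(constraints: ConstraintSet | None, cols: list[str]
                        ) -> tuple[set[tuple[int, int]], set[tuple[int, int]]]:
    if constraints is None:
        return set(), set()
    pos = {c: i for i, c in enumerate(cols)}
    bl = {(pos[u], pos[v]) for u, v in constraints.blacklist
          if u in pos and v in pos}
    wl = {(pos[u], pos[v]) for u, v in constraints.whitelist
          if u in pos and v in pos}
    return bl, wl


def _whitelist_start(n_nodes: int, whitelist: set[tuple[int, int]]
                     ) -> dict[int, set[int]]:
    parents = {v: set() for v in range(n_nodes)}
    for u, v in whitelist:
        parents[v].add(u)
    return parents


def _random_start(n_nodes: int, blacklist, whitelist, rng,
                  edge_prob: float = 0.15) -> dict[int, set[int]]:
    parents = _whitelist_start(n_nodes, whitelist)
    children = {v: set() for v in range(n_nodes)}
    for v, ps in parents.items():
        for p in ps:
            children[p].add(v)
    pairs = [(u, v) for u in range(n_nodes) for v in range(n_nodes)
             if u != v and (u, v) not in blacklist and u not in parents[v]]
    rng.shuffle(pairs)
    for u, v in pairs:
        if rng.random() < edge_prob and not _has_path(children, v, u):
            parents[v].add(u)
            children[u].add(v)
    return parents


def learn_structure(data: pd.DataFrame, constraints: ConstraintSet | None = None,
                    algorithm: str = "hc", restarts: int = 50,
                    tabu_len: int = 10, seed: int = 0, alpha: float = 1.0,
                    levels: dict[str, int] | None = None) -> nx.DiGraph:
    """Learn a constraint-respecting DAG by score-based local search.

    ``algorithm`` is "hc" (greedy hill climbing; ``restarts`` additional
    climbs from random constraint-respecting DAGs) or "tabu" (hill climbing
    with a move-reversal tabu list of length ``tabu_len``).  Ties between
    equally scoring moves break on lexicographic (u, v) order, so results
    are deterministic given the seed.
    """
    codes, cols, lv = _codes(data, levels)
    bl, wl = _constraint_indices(constraints, cols)
    n_nodes = len(cols)
    wl_graph = nx.DiGraph()
    wl_graph.add_nodes_from(range(n_nodes))
    wl_graph.add_edges_from(wl)
    if not nx.is_directed_acyclic_graph(wl_graph):
        raise BayesNetError("whitelist is cyclic")
    if algorithm not in ("hc", "tabu"):
        raise BayesNetError(f"unknown algorithm {algorithm!r}")

    scorer = _FamilyScorer(codes, lv, alpha)
    rng = np.random.default_rng(seed)
    t_len = tabu_len if algorithm == "tabu" else 0

    best_parents, best_score = _search(
        scorer, n_nodes, bl, wl, _whitelist_start(n_nodes, wl), tabu_len=t_len)
    n_restarts = restarts if algorithm == "hc" else 0
    for _ in range(n_restarts):
        start = _random_start(n_nodes, bl, wl, rng)
        parents, score = _search(scorer, n_nodes, bl, wl, start, tabu_len=0)
        if score > best_score + _EPS:
            best_parents, best_score = parents, score

    g = nx.DiGraph()
    g.add_nodes_from(cols)
    for v, ps in best_parents.items():
        g.add_edges_from((cols[p], cols[v]) for p in ps)
    if constraints is not None:  # post-hoc contract check
        for e in g.edges:
            assert e not in constraints.blacklist
        for e in constraints.whitelist:
            if e[0] in cols and e[1] in cols:
                assert g.has_edge(*e)
    return g


def fit_parameters(dag: nx.DiGraph, data: pd.DataFrame, alpha: float = 1.0,
                   levels: dict[str, int] | None = None) -> DiscreteBN:
    """Dirichlet-smoothed CPTs: theta = (count + alpha) / (N + alpha * L).

    Unobserved parent configurations get the uniform row 1/L.
    """
    if alpha <= 0:
        raise BayesNetError("alpha must be > 0")
    codes, cols, lv = _codes(data, levels)
    pos = {c: i for i, c in enumerate(cols)}
    scorer = _FamilyScorer(codes, lv, alpha)
    nodes = list(dag.nodes)
    parents = {v: tuple(sorted(dag.predecessors(v))) for v in nodes}
    level_map = {c: int(lv[pos[c]]) for c in cols}
    cpts = {}
    for v in nodes:
        ps = tuple(pos[p] for p in parents[v])
        counts = scorer.family_counts(pos[v], ps).astype(float)
        L = counts.shape[1]
        if ps:
            # family_counts ravels parent configs with the first parent
            # fastest; reorder so cpts[v][p1, ..., pk, x] indexes naturally
            counts = counts.reshape(tuple(int(lv[p]) for p in ps[::-1]) + (L,))
            counts = np.transpose(counts, axes=(*range(len(ps) - 1, -1, -1), len(ps)))
        else:
            counts = counts.reshape(L)
        cpts[v] = (counts + alpha) / (counts.sum(axis=-1, keepdims=True) + alpha * L)
    return DiscreteBN(nodes, level_map, parents, cpts, alpha)


def log_likelihood(bn: DiscreteBN, data: pd.DataFrame
                   ) -> tuple[np.ndarray, float]:
    """Per-row and total log-likelihood of discrete data under the BN."""
    codes, cols, lv = _codes(data, bn.levels)
    pos = {c: i for i, c in enumerate(cols)}
    total = np.zeros(len(data))
    for v in bn.nodes:
        if v not in pos:
            raise BayesNetError(f"node {v!r} missing from data")
        idx = tuple(codes[:, pos[p]] for p in bn.parents[v]) + (codes[:, pos[v]],)
        total += np.log(bn.cpts[v][idx])
    return total, float(total.sum())


@dataclass
class CVResult:
    """Fold-wise negated mean held-out log-likelihoods per algorithm."""

    scores: dict[str, np.ndarray]

    @property
    def ranking(self) -> list[str]:
        return sorted(self.scores, key=lambda a: float(np.mean(self.scores[a])))

    @property
    def best(self) -> str:
        return self.ranking[0]


def cv_select(data: pd.DataFrame, constraints: ConstraintSet | None,
              algorithms=("hc", "tabu"), k: int = 10, seed: int = 0,
              alpha: float = 1.0, **search_kwargs) -> CVResult:
    """Rank structure-learning algorithms by k-fold held-out negated
    log-likelihood (lower = better generalization)."""
    if k < 2:
        raise BayesNetError("need k >= 2 folds")
    if len(data) < k:
        raise BayesNetError("fewer rows than folds")
    _, _, lv = _codes(data)
    levels = {c: int(l) for c, l in zip(data.columns, lv)}
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(data))
    folds = np.array_split(idx, k)
    out: dict[str, np.ndarray] = {}
    for alg_i, alg in enumerate(algorithms):
        name = alg if alg not in out else f"{alg}#{alg_i}"
        scores = []
        for f in folds:
            train = data.iloc[np.setdiff1d(idx, f, assume_unique=False)]
            test = data.iloc[f]
            dag = learn_structure(train, constraints, algorithm=alg, seed=seed,
                                  alpha=alpha, levels=levels, **search_kwargs)
            bn = fit_parameters(dag, train, alpha=alpha, levels=levels)
            per_row, _ = log_likelihood(bn, test)
            scores.append(-float(per_row.mean()))
        out[name] = np.asarray(scores)
    return CVResult(out)


def bootstrap_edges(data: pd.DataFrame, constraints: ConstraintSet | None,
                    algorithm: str = "hc", B: int = 1000, seed: int = 0,
                    alpha: float = 1.0, **search_kwargs) -> EdgeConfidence:
    """Nonparametric bootstrap edge frequencies over B patient resamples."""
    if B < 1:
        raise BayesNetError("need B >= 1 bootstrap replicates")
    _, _, lv = _codes(data)
    levels = {c: int(l) for c, l in zip(data.columns, lv)}
    rng = np.random.default_rng(seed)
    counts: dict[tuple[str, str], int] = {}
    n = len(data)
    search_kwargs.setdefault("restarts", 0)
    for b in range(B):
        sample = data.iloc[rng.integers(0, n, size=n)]
        dag = learn_structure(sample, constraints, algorithm=algorithm,
                              seed=int(rng.integers(2**31 - 1)), alpha=alpha,
                              levels=levels, **search_kwargs)
        for e in dag.edges:
            counts[e] = counts.get(e, 0) + 1
    return EdgeConfidence({e: c / B for e, c in counts.items()}, B)
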