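import itertools

import numpy as np
import pandas as pd
import pytest

from vcforge.bayesnet import (BayesNetError, DiscreteBN, _FamilyScorer,
                              bootstrap_edges, cv_select, fit_parameters,
                              learn_structure, log_likelihood)
from vcforge.schema import ConstraintSet
from vcforge.simulate import ancestral_sample

from conftest import chain_bn, enumerate_joint


def copy_data(n=500, seed=0):
    """X uniform binary, Y = X deterministically, Z independent binary."""
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 2, n)
    z = rng.integers(0, 2, n)
    return pd.DataFrame({"X": x, "Y": x.copy(), "Z": z})


def all_dags_3(names=("X", "Y", "Z")):
    """All 25 DAGs over three nodes (each pair: none / u->v / v->u)."""
    pairs = list(itertools.combinations(range(3), 2))
    for states in itertools.product((0, 1, 2), repeat=3):
        parents = {i: set() for i in range(3)}
        for (i, j), s in zip(pairs, states):
            if s == 1:
                parents[j].add(i)
            elif s == 2:
                parents[i].add(j)
        # acyclicity: only the 3-cycle patterns are cyclic; detect generically
        order, seen = [], set()
        rem = dict(parents)
        ok = True
        while rem:
            roots = [v for v, ps in rem.items() if not (ps - seen)]
            if not roots:
                ok = False
                break
            seen.update(roots)
            for r in roots:
                rem.pop(r)
        if ok:
            yield {names[v]: tuple(names[p] for p in sorted(ps))
                   for v, ps in parents.items()}


class TestLearnStructure:
    def test_copy_relation_recovered_against_exhaustive_oracle(self):
        data = copy_data()
        dag = learn_structure(data, None, algorithm="hc", restarts=2, seed=0)
        skeleton = {frozenset(e) for e in dag.edges}
        assert frozenset({"X", "Y"}) in skeleton
        assert not any("Z" in e for e in skeleton)

        # oracle: exhaustive enumeration of all 25 three-node DAGs
        codes = data.to_numpy()
        scorer = _FamilyScorer(codes, codes.max(axis=0) + 1, alpha=1.0)
        pos = {c: i for i, c in enumerate(data.columns)}
        best_score, best_parents = -np.inf, None
        for parents in all_dags_3():
            s = sum(scorer.score(pos[v], tuple(pos[p] for p in ps))
                    for v, ps in parents.items())
            if s > best_score:
                best_score, best_parents = s, parents
        oracle_skel = {frozenset((p, v)) for v, ps in best_parents.items()
                       for p in ps}
        assert skeleton == oracle_skel

    def test_total_blacklist_gives_empty_graph(self):
        data = copy_data(n=100)
        nodes = tuple(data.columns)
        bl = frozenset((u, v) for u in nodes for v in nodes if u != v)
        cs = ConstraintSet(nodes, bl, frozenset())
        dag = learn_structure(data, cs, restarts=0)
        assert len(dag.edges) == 0

    def test_whitelisted_edge_always_present(self):
        data = copy_data(n=100)
        cs = ConstraintSet(("X", "Y", "Z"), frozenset(),
                           frozenset({("Z", "Y")}))
        dag = learn_structure(data, cs, restarts=2, seed=0)
        assert dag.has_edge("Z", "Y")

    def test_row_order_invariance(self):
        data = copy_data(n=200, seed=3)
        a = learn_structure(data, None, restarts=0, seed=0)
        b = learn_structure(data.sample(frac=1, random_state=1), None,
                            restarts=0, seed=0)
        assert set(a.edges) == set(b.edges)

    def test_cyclic_whitelist_rejected(self):
        data = copy_data(n=50)
        with pytest.raises(Exception):
            cs = ConstraintSet(("X", "Y", "Z"), frozenset(),
                               frozenset({("X", "Y"), ("Y", "X")}))
            learn_structure(data, cs)

    def test_non_discrete_column_rejected(self):
        df = pd.DataFrame({"X": [0.5, 1.2], "Y": [0, 1]})
        with pytest.raises(BayesNetError, match="non-discrete"):
            learn_structure(df)

    def test_tabu_matches_or_beats_hc_on_simple_data(self):
        data = copy_data(n=300, seed=5)
        hc = learn_structure(data, None, algorithm="hc", restarts=0)
        tb = learn_structure(data, None, algorithm="tabu", tabu_len=5)
        assert {frozenset(e) for e in hc.edges} == {frozenset(e) for e in tb.edges}


class TestFitParameters:
    def test_dirichlet_closed_form(self):
        df = pd.DataFrame({"X": [0, 0]})
        import networkx as nx

        g = nx.DiGraph()
        g.add_node("X")
        bn = fit_parameters(g, df, alpha=1.0, levels={"X": 2})
        assert np.allclose(bn.cpts["X"], [0.75, 0.25])

    def test_unobserved_parent_configuration_uniform(self):
        df = pd.DataFrame({"A": [0, 0, 0], "B": [0, 1, 1]})
        import networkx as nx

        g = nx.DiGraph([("A", "B")])
        bn = fit_parameters(g, df, alpha=1.0, levels={"A": 2, "B": 2})
        assert np.allclose(bn.cpts["B"][1], [0.5, 0.5])  # A=1 never observed

    def test_alpha_to_zero_recovers_mle(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"X": rng.integers(0, 3, 300)})
        import networkx as nx

        g = nx.DiGraph()
        g.add_node("X")
        bn = fit_parameters(g, df, alpha=1e-9)
        freq = df["X"].value_counts(normalize=True).sort_index().to_numpy()
        assert np.allclose(bn.cpts["X"], freq, atol=1e-6)

    def test_cpt_parent_axis_ordering(self):
        # B's CPT must be indexed cpts[B][a, b]
        df = pd.DataFrame({"A": [0] * 50 + [1] * 50,
                           "B": [0] * 50 + [1] * 50})
        import networkx as nx

        g = nx.DiGraph([("A", "B")])
        bn = fit_parameters(g, df, alpha=0.01)
        assert bn.cpts["B"][0, 0] > 0.95
        assert bn.cpts["B"][1, 1] > 0.95


class TestLogLikelihood:
    def test_single_uniform_binary_node(self):
        bn = DiscreteBN(["X"], {"X": 2}, {"X": ()}, {"X": np.array([0.5, 0.5])})
        per_row, total = log_likelihood(bn, pd.DataFrame({"X": [1]}))
        assert np.isclose(total, np.log(0.5))

    def test_independent_nodes_factorize(self):
        bn = DiscreteBN(["A", "B"], {"A": 2, "B": 2}, {"A": (), "B": ()},
                        {"A": np.array([0.3, 0.7]), "B": np.array([0.9, 0.1])})
        df = pd.DataFrame({"A": [0, 1], "B": [1, 0]})
        _, total = log_likelihood(bn, df)
        expected = np.log(0.3) + np.log(0.1) + np.log(0.7) + np.log(0.9)
        assert np.isclose(total, expected)

    def test_matches_bruteforce_joint_on_chain(self):
        bn = chain_bn()
        joint = enumerate_joint(bn)
        df = pd.DataFrame({"A": [0, 1, 1], "B": [1, 0, 1], "C": [0, 0, 1]})
        per_row, _ = log_likelihood(bn, df)
        for i, row in df.iterrows():
            assert np.isclose(per_row[i], np.log(joint[tuple(row)]))

    def test_unseen_level_rejected(self):
        bn = chain_bn()
        with pytest.raises(BayesNetError):
            log_likelihood(bn, pd.DataFrame({"A": [2], "B": [0], "C": [0]}))


class TestCvSelect:
    def test_true_structure_beats_forced_empty_graph(self):
        gt = chain_bn()
        data = ancestral_sample(gt, 1000, seed=0)
        nodes = tuple(data.columns)
        bl_all = frozenset((u, v) for u in nodes for v in nodes if u != v)
        empty_cs = ConstraintSet(nodes, bl_all, frozenset())
        free = cv_select(data, None, algorithms=("hc",), k=5, seed=0,
                         restarts=0)
        forced = cv_select(data, empty_cs, algorithms=("hc",), k=5, seed=0,
                           restarts=0)
        assert free.scores["hc"].mean() < forced.scores["hc"].mean()

    def test_identical_algorithms_identical_scores(self):
        data = copy_data(n=120)
        res = cv_select(data, None, algorithms=("hc", "hc"), k=4, seed=2,
                        restarts=0)
        keys = list(res.scores)
        assert np.array_equal(res.scores[keys[0]], res.scores[keys[1]])

    def test_reproducible_folds(self):
        data = copy_data(n=120)
        a = cv_select(data, None, algorithms=("hc",), k=4, seed=3, restarts=0)
        b = cv_select(data, None, algorithms=("hc",), k=4, seed=3, restarts=0)
        assert np.array_equal(a.scores["hc"], b.scores["hc"])

    def test_too_few_folds_rejected(self):
        with pytest.raises(BayesNetError):
            cv_select(copy_data(50), None, k=1)


class TestBootstrapEdges:
    def test_deterministic_copy_edge_high_frequency(self):
        data = copy_data(n=500, seed=1)
        conf = bootstrap_edges(data, None, B=100, seed=0)
        skel_freq = conf[("X", "Y")] + conf[("Y", "X")]
        assert skel_freq >= 0.9

    def test_blacklisted_edge_frequency_zero(self):
        data = copy_data(n=200)
        nodes = tuple(data.columns)
        bl = frozenset({("X", "Y"), ("Y", "X")})
        cs = ConstraintSet(nodes, bl, frozenset())
        conf = bootstrap_edges(data, cs, B=30, seed=0)
        assert conf[("X", "Y")] == 0.0 and conf[("Y", "X")] == 0.0

    def test_deterministic_under_seed(self):
        data = copy_data(n=150)
        a = bootstrap_edges(data, None, B=20, seed=4)
        b = bootstrap_edges(data, None, B=20, seed=4)
        assert a.frequencies == b.frequencies

    def test_frequencies_in_unit_interval(self):
        data = copy_data(n=150)
        conf = bootstrap_edges(data, None, B=20, seed=0)
        assert all(0.0 <= f <= 1.0 for f in conf.frequencies.values())


class TestDiscreteBN:
    def test_serialization_roundtrip(self, tmp_path):
        bn = chain_bn()
        bn.save(tmp_path / "bn.json")
        back = DiscreteBN.load(tmp_path / "bn.json")
        assert back.nodes == bn.nodes
        assert back.parents == bn.parents
        for v in bn.nodes:
            assert np.allclose(back.cpts[v], bn.cpts[v])

    def test_invalid_cpt_rows_rejected(self):
        with pytest.raises(BayesNetError, match="sum to 1"):
            DiscreteBN(["X"], {"X": 2}, {"X": ()}, {"X": np.array([0.5, 0.4])})

    def test_cycle_rejected(self):
        with pytest.raises(BayesNetError, match="DAG"):
            DiscreteBN(["A", "B"], {"A": 2, "B": 2},
                       {"A": ("B",), "B": ("A",)},
                       {"A": np.full((2, 2), 0.5), "B": np.full((2, 2), 0.5)})
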