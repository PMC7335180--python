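import numpy as np
import pandas as pd
import pytest
from scipy.stats import chisquare

from vcforge.bayesnet import DiscreteBN
from vcforge.simulate import (InterventionSpec, SimulationError,
                              ancestral_sample, conservative_filter,
                              generate_vc, logic_sample, mutilate,
                              simulate_intervention)

from conftest import chain_bn, enumerate_joint


class TestAncestralSampling:
    def test_single_node_marginal_within_binomial_error(self):
        bn = DiscreteBN(["X"], {"X": 2}, {"X": ()}, {"X": np.array([0.3, 0.7])})
        s = ancestral_sample(bn, 10_000, seed=0)
        freq = (s["X"] == 1).mean()
        sd = np.sqrt(0.7 * 0.3 / 10_000)
        assert abs(freq - 0.7) < 3 * sd

    def test_deterministic_cpts_unique_configuration(self):
        bn = chain_bn(((0.0, 1.0), ((1.0, 0.0), (0.0, 1.0)),
                       ((1.0, 0.0), (0.0, 1.0))))
        s = ancestral_sample(bn, 50, seed=1)
        assert (s["A"] == 1).all() and (s["B"] == 1).all() and (s["C"] == 1).all()

    def test_two_node_chain_joint_matches_product_form(self):
        bn = chain_bn()
        joint = enumerate_joint(bn)
        s = ancestral_sample(bn, 10_000, seed=2)
        cells = [(a, b, c) for a in (0, 1) for b in (0, 1) for c in (0, 1)]
        observed = np.array([((s["A"] == a) & (s["B"] == b) & (s["C"] == c)).sum()
                             for a, b, c in cells])
        expected = np.array([joint[cell] for cell in cells]) * len(s)
        stat, p = chisquare(observed, expected)
        assert p > 0.01

    def test_seed_determinism(self):
        bn = chain_bn()
        a = ancestral_sample(bn, 200, seed=9)
        b = ancestral_sample(bn, 200, seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestConservativeFilter:
    def test_copies_of_real_rows_accepted_with_high_confidence(self):
        rng = np.random.default_rng(0)
        real = pd.DataFrame(rng.integers(0, 3, size=(150, 4)),
                            columns=list("abcd"))
        virtual = real.sample(100, random_state=1).reset_index(drop=True)
        vc = conservative_filter(real, virtual, weight=100, seed=0, n_trees=200)
        assert vc.accepted.all()
        assert vc.confidence.mean() > 0.9  # ~ weighted class prior

    def test_disjoint_level_pattern_rejected(self):
        real = pd.DataFrame({"a": [0] * 100, "b": [1] * 100})
        virtual = pd.DataFrame({"a": [2] * 50, "b": [0] * 50})
        vc = conservative_filter(real, virtual, weight=100, seed=0, n_trees=200)
        assert not vc.accepted.any()

    def test_weight_one_separable_classes_all_rejected(self):
        real = pd.DataFrame({"a": [0] * 80, "b": [0] * 80})
        virtual = pd.DataFrame({"a": [1] * 80, "b": [1] * 80})
        vc = conservative_filter(real, virtual, weight=1, seed=0, n_trees=200)
        assert (vc.confidence < 0.5).all()
        assert not vc.accepted.any()

    def test_column_mismatch_rejected(self):
        real = pd.DataFrame({"a": [0, 1]})
        virtual = pd.DataFrame({"b": [0, 1]})
        with pytest.raises(SimulationError, match="columns"):
            conservative_filter(real, virtual)

    def test_accepted_confidences_dominate_overall(self):
        rng = np.random.default_rng(1)
        real = pd.DataFrame(rng.integers(0, 2, size=(120, 5)))
        real.columns = [f"n{i}" for i in range(5)]
        virtual = pd.DataFrame(rng.integers(0, 2, size=(120, 5)))
        virtual.columns = real.columns
        vc = conservative_filter(real, virtual, weight=100, seed=0, n_trees=200)
        if vc.accepted.any() and not vc.accepted.all():
            assert vc.confidence[vc.accepted].min() >= vc.threshold
            assert (vc.confidence[vc.accepted].mean()
                    >= vc.confidence.mean())


class TestGenerateVc:
    def test_threshold_zero_one_round_no_rejection(self):
        bn = chain_bn()
        real = ancestral_sample(bn, 100, seed=0)
        vc = generate_vc(bn, real, n_target=50, threshold=0.0, seed=0)
        assert len(vc.table) == 50
        assert len(vc.acceptance_log) == 1

    def test_fixed_seed_identical_cohort(self):
        bn = chain_bn()
        real = ancestral_sample(bn, 150, seed=0)
        a = generate_vc(bn, real, 60, seed=5, n_trees=100)
        b = generate_vc(bn, real, 60, seed=5, n_trees=100)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_zero_acceptance_raises_with_rate(self):
        # the BN deterministically emits a pattern absent from real data
        bn = chain_bn(((0.0, 1.0), ((1.0, 0.0), (0.0, 1.0)),
                       ((1.0, 0.0), (0.0, 1.0))))
        real = pd.DataFrame({"A": [0] * 100, "B": [0] * 100, "C": [0] * 100})
        with pytest.raises(SimulationError, match="acceptance rate"):
            generate_vc(bn, real, 10, max_rounds=2, seed=0, n_trees=100)


class TestIntervention:
    def test_mutilated_target_has_no_parents(self):
        bn = chain_bn()
        mut = mutilate(bn, InterventionSpec({"B": 1}))
        assert mut.parents["B"] == ()
        assert np.allclose(mut.cpts["B"], [0.0, 1.0])

    def test_root_intervention_leaves_graph_unchanged(self):
        bn = chain_bn()
        mut = mutilate(bn, InterventionSpec({"A": 0}))
        assert mut.parents == bn.parents

    def test_invalid_level_rejected(self):
        bn = chain_bn()
        with pytest.raises(SimulationError, match="level"):
            mutilate(bn, InterventionSpec({"B": 5}))

    def test_do_on_chain_matches_enumeration_oracle(self):
        bn = chain_bn()
        s = simulate_intervention(bn, InterventionSpec({"B": 1}, n=20_000, seed=0))
        # downstream: P(C | do(B=1)) = P(C | B=1); upstream: P(A) = prior
        assert abs((s["C"] == 1).mean() - bn.cpts["C"][1, 1]) < 0.015
        assert abs((s["A"] == 1).mean() - bn.cpts["A"][1]) < 0.015

    def test_collider_do_differs_from_conditioning(self):
        # A -> C <- B; do(C) must leave A at its prior, conditioning must not
        cpt_c = np.array([[[0.9, 0.1], [0.5, 0.5]],
                          [[0.5, 0.5], [0.1, 0.9]]])
        bn = DiscreteBN(["A", "B", "C"], {"A": 2, "B": 2, "C": 2},
                        {"A": (), "B": (), "C": ("A", "B")},
                        {"A": np.array([0.7, 0.3]), "B": np.array([0.4, 0.6]),
                         "C": cpt_c})
        joint = enumerate_joint(bn)
        p_a1_given_c1 = (sum(p for (a, b, c), p in joint.items()
                             if a == 1 and c == 1)
                         / sum(p for (a, b, c), p in joint.items() if c == 1))

        do = simulate_intervention(bn, InterventionSpec({"C": 1}, n=20_000, seed=0))
        assert abs((do["A"] == 1).mean() - 0.3) < 0.015

        cond = logic_sample(bn, {"C": 1}, 10_000, seed=0)
        assert abs((cond["A"] == 1).mean() - p_a1_given_c1) < 0.02
        assert abs(p_a1_given_c1 - 0.3) > 0.05  # the two notions must differ

    def test_per_patient_target_values(self):
        bn = chain_bn()
        values = np.array([0, 1] * 50)
        s = simulate_intervention(bn, InterventionSpec({"B": values}, seed=0))
        assert len(s) == 100
        assert np.array_equal(s["B"].to_numpy(), values)

    def test_zero_samples_empty_table(self):
        bn = chain_bn()
        s = simulate_intervention(bn, InterventionSpec({"B": 0}, n=0))
        assert len(s) == 0

    def test_impossible_evidence_rejected(self):
        bn = chain_bn(((1.0, 0.0), ((1.0, 0.0), (0.0, 1.0)),
                       ((1.0, 0.0), (0.0, 1.0))))
        with pytest.raises(SimulationError, match="support"):
            logic_sample(bn, {"A": 1}, 10, seed=0, max_batches=3)
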