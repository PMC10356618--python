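"""Mk/ER machinery: transition probabilities, pruning likelihood, marginal
ancestral probabilities, rate fitting, recruitment-node assignment."""
from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import phylorecruit as pr
from phylorecruit import simulate as sim
from phylorecruit.deog import DEOGMatrix
from phylorecruit.mk import Q_MIN

from _oracles import enum_loglik_and_marginals, expm_transition


class TestTransitionProb:
    def test_t_zero_is_identity(self):
        assert np.allclose(pr.er_transition_prob(1.3, 0.0), np.eye(2))

    def test_saturation_at_half(self):
        P = pr.er_transition_prob(5.0, 1e6)
        assert np.allclose(P, 0.25 + np.full((2, 2), 0.25))

    def test_closed_form_value(self):
        P = pr.er_transition_prob(0.5, 1.0)
        assert P[0, 0] == pytest.approx((1 + math.exp(-1)) / 2, abs=1e-12)
        assert np.allclose(P, expm_transition(0.5, 1.0), atol=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            pr.er_transition_prob(1.0, -0.1)

    @given(q=st.floats(0.01, 10), t1=st.floats(0, 5), t2=st.floats(0, 5))
    @settings(max_examples=100, deadline=None)
    def test_rows_sum_and_chapman_kolmogorov(self, q, t1, t2):
        P1, P2 = pr.er_transition_prob(q, t1), pr.er_transition_prob(q, t2)
        assert np.allclose(P1.sum(axis=1), 1.0, atol=1e-12)
        assert np.allclose(P1 @ P2, pr.er_transition_prob(q, t1 + t2), atol=1e-10)


class TestLogLik:
    def test_single_tip(self, single_tip_tree):
        assert pr.mk_loglik(single_tip_tree, {"A": 1}, 0.7) == pytest.approx(
            math.log(0.5)
        )

    def test_cherry_no_change_limit(self):
        tree = pr.parse_newick("(A:1,B:1);")
        ll = pr.mk_loglik(tree, {"A": 1, "B": 1}, 1e-8)
        assert ll == pytest.approx(math.log(0.5), abs=1e-6)

    def test_missing_tip_contributes_ones(self, cherry3):
        # marginalising B is the same as declaring it missing
        ll_missing = pr.mk_loglik(cherry3, {"A": 1, "B": None, "C": 0}, 0.4)
        lik_sum = sum(
            math.exp(pr.mk_loglik(cherry3, {"A": 1, "B": b, "C": 0}, 0.4))
            for b in (0, 1)
        )
        assert ll_missing == pytest.approx(math.log(lik_sum), abs=1e-10)

    def test_absent_tip_rejected(self, cherry3):
        with pytest.raises(KeyError, match="C"):
            pr.mk_loglik(cherry3, {"A": 1, "B": 0}, 0.4)

    @pytest.mark.parametrize("case_seed", range(10))
    def test_matches_enumeration_oracle(self, case_seed):
        rng = np.random.default_rng(1000 + case_seed)
        tree = sim.simulate_tree(5, seed=case_seed)
        states = {t: int(rng.integers(0, 2)) for t in tree.tip_names}
        q = 0.7
        ll = pr.mk_loglik(tree, states, q)
        ll_oracle, _ = enum_loglik_and_marginals(tree, states, q)
        assert ll == pytest.approx(ll_oracle, abs=1e-10)


class TestMarginals:
    def test_symmetric_cherry_root_half(self):
        tree = pr.parse_newick("(A:1,B:1);")
        probs = pr.marginal_ancestral_probs(tree, {"A": 1, "B": 0}, 0.5)
        assert probs[tree.root.label] == pytest.approx(0.5, abs=1e-12)

    def test_concordant_cherry_small_rate(self):
        tree = pr.parse_newick("(A:1,B:1);")
        probs = pr.marginal_ancestral_probs(tree, {"A": 1, "B": 1}, 1e-6)
        assert probs[tree.root.label] == pytest.approx(1.0, abs=1e-4)

    def test_matches_enumeration_oracle(self, quartet):
        states = {"A": 1, "B": 0, "C": 1, "D": 0}
        probs = pr.marginal_ancestral_probs(quartet, states, 0.5)
        _, oracle = enum_loglik_and_marginals(quartet, states, 0.5)
        for lab, expect in oracle.items():
            assert probs[lab] == pytest.approx(expect, abs=1e-10)

    def test_flat_and_stationary_priors_identical(self, quartet):
        states = {"A": 1, "B": 1, "C": 0, "D": 1}
        flat = pr.marginal_ancestral_probs(quartet, states, 0.8, root_prior="flat")
        stat = pr.marginal_ancestral_probs(
            quartet, states, 0.8, root_prior="stationary"
        )
        assert flat == stat

    def test_probabilities_in_unit_interval_and_complementary(self, quartet):
        states = {"A": 1, "B": 0, "C": 0, "D": 0}
        p1 = pr.marginal_ancestral_probs(quartet, states, 1.3)
        flipped = {t: 1 - s for t, s in states.items()}
        p0 = pr.marginal_ancestral_probs(quartet, flipped, 1.3)
        for lab in p1:
            assert 0.0 <= p1[lab] <= 1.0
            # ER symmetry: flipping all tip states flips the marginals
            assert p1[lab] == pytest.approx(1 - p0[lab], abs=1e-10)


class TestFitRate:
    def test_constant_character_hits_lower_bound(self, quartet):
        fit = pr.fit_er_rate(quartet, {"A": 1, "B": 1, "C": 1, "D": 1})
        assert fit.at_bound
        assert fit.q == pytest.approx(Q_MIN, rel=1e-3)

    def test_single_observed_tip_is_flat(self, cherry3):
        fit = pr.fit_er_rate(cherry3, {"A": 1, "B": None, "C": None})
        assert fit.at_bound  # likelihood flat in q

    def test_all_missing_rejected(self, cherry3):
        with pytest.raises(ValueError):
            pr.fit_er_rate(cherry3, {"A": None, "B": None, "C": None})

    def test_pooled_rate_recovery_small(self):
        # moderate-size sanity check; the full-size recovery lives in
        # the acceptance suite
        tree = sim.simulate_tree(32, seed=3)
        chars = sim.simulate_er_characters(tree, q=0.5, n_chars=400, seed=4)
        fit = pr.fit_er_rate(tree, chars)
        assert fit.q == pytest.approx(0.5, rel=0.25)
        assert not fit.at_bound


class TestAssignment:
    def test_all_passing_gives_root(self, quartet):
        probs = {lab: 0.9 for lab in quartet.internal_labels}
        tips = {"A": 1, "B": 1, "C": 1, "D": 1}
        assert pr.assign_recruitment_node(quartet, probs, tips) == quartet.root.label

    def test_subclade_only(self, quartet):
        probs = {"A|B": 0.7, quartet.root.label: 0.5, "C|D": 0.1}
        tips = {"A": 1, "B": 1, "C": 0, "D": 0}
        assert pr.assign_recruitment_node(quartet, probs, tips) == "A|B"

    def test_no_passing_single_tip_species_specific(self, quartet):
        probs = {lab: 0.2 for lab in quartet.internal_labels}
        tips = {"A": 1, "B": 0, "C": 0, "D": 0}
        assert pr.assign_recruitment_node(quartet, probs, tips) == "A"

    def test_no_passing_multiple_tips_unassigned(self, quartet):
        probs = {lab: 0.2 for lab in quartet.internal_labels}
        tips = {"A": 1, "B": 0, "C": 1, "D": 0}
        assert pr.assign_recruitment_node(quartet, probs, tips) == "unassigned"

    def test_tie_broken_by_clade_size(self):
        tree = pr.parse_newick("(((A:1,B:1):1,C:1):1,(D:1,E:1):1);")
        # two depth-1 nodes; A|B|C has more descendant tips than D|E
        probs = {"A|B|C": 0.7, "D|E": 0.7}
        tips = {t: 1 for t in tree.tip_names}
        assert pr.assign_recruitment_node(tree, probs, tips) == "A|B|C"

    def test_threshold_bounds(self, quartet):
        with pytest.raises(ValueError):
            pr.assign_recruitment_node(quartet, {}, {}, threshold=0.4)


class TestReconstructAll:
    def test_all_zero_matrix_counts_zero(self, quartet):
        m = DEOGMatrix(
            direction="up",
            hog_ids=["H1", "H2"],
            species=list(quartet.tip_names),
            cells=np.zeros((2, 4), dtype=np.uint8),
        )
        assignment, counts = pr.reconstruct_all(m, quartet)
        assert len(assignment) == 0
        assert all(v == 0 for v in counts.values())

    def test_all_ones_rows_all_assigned_root(self, quartet):
        n = 1000
        m = DEOGMatrix(
            direction="up",
            hog_ids=[f"H{i}" for i in range(n)],
            species=list(quartet.tip_names),
            cells=np.ones((n, 4), dtype=np.uint8),
        )
        assignment, counts = pr.reconstruct_all(m, quartet)
        assert counts[quartet.root.label] == n

    def test_invariant_to_hog_relabelling_and_tip_order(self, quartet):
        rng = np.random.default_rng(0)
        cells = rng.integers(0, 2, size=(20, 4)).astype(np.uint8)
        species = list(quartet.tip_names)
        m1 = DEOGMatrix("up", [f"H{i}" for i in range(20)], species, cells)
        perm = [2, 0, 3, 1]
        m2 = DEOGMatrix(
            "up",
            [f"X{i}" for i in range(20)],
            [species[j] for j in perm],
            cells[:, perm],
        )
        _, c1 = pr.reconstruct_all(m1, quartet)
        _, c2 = pr.reconstruct_all(m2, quartet)
        assert c1 == c2

    def test_species_mismatch_rejected(self, quartet):
        m = DEOGMatrix("up", ["H1"], ["A", "B", "C", "Z"],
                       np.ones((1, 4), dtype=np.uint8))
        with pytest.raises(ValueError, match="tree tips"):
            pr.reconstruct_all(m, quartet)

    def test_absent_as_missing_mode(self, quartet):
        cells = np.array([[1, 1, 0, 0]], dtype=np.uint8)
        m = DEOGMatrix("up", ["H1"], list(quartet.tip_names), cells)
        presence = {"H1": frozenset(["A", "B"])}  # C, D have no genes
        a_zero, _ = pr.reconstruct_all(m, quartet, rate_mode="per_hog")
        a_miss, _ = pr.reconstruct_all(
            m, quartet, absent_as_missing=True, presence=presence,
            rate_mode="per_hog",
        )
        # with C and D missing the evidence for deeper regulation is weaker
        # or equal, never stronger
        assert a_miss.node_of["H1"] in {"A|B", quartet.root.label}
        assert a_zero.node_of["H1"] == "A|B"
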