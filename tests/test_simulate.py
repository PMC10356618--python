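"""Synthetic-data generators: determinism, validity, planted-truth wiring."""
from __future__ import annotations

import numpy as np
import pytest

import phylorecruit as pr
from phylorecruit import simulate as sim


class TestSimulateTree:
    def test_structure_and_determinism(self):
        t1 = sim.simulate_tree(9, seed=7)
        t2 = sim.simulate_tree(9, seed=7)
        assert len(t1.tip_names) == 9
        assert len(t1.internal_labels) == 8
        assert t1.to_newick() == t2.to_newick()

    def test_different_seed_differs(self):
        assert sim.simulate_tree(9, seed=7).to_newick() != sim.simulate_tree(
            9, seed=8
        ).to_newick()

    def test_too_few_tips_rejected(self):
        with pytest.raises(ValueError):
            sim.simulate_tree(2, seed=0)


class TestSimulateOrthogroups:
    def test_no_loss_root_gain_present_everywhere(self):
        tree = sim.simulate_tree(5, seed=1)
        og, _ = sim.simulate_orthogroups(
            tree, n_hogs=50, gain_node_weights={tree.root.label: 1.0},
            loss_prob_per_branch=0.0, seed=2,
        )
        for hog in og.hog_ids:
            assert og.presence(hog) == set(tree.tip_names)

    def test_total_loss_leaves_tip_gains_only(self):
        tree = sim.simulate_tree(5, seed=1)
        og, truth = sim.simulate_orthogroups(
            tree, n_hogs=100, loss_prob_per_branch=1.0, seed=3
        )
        for hog in og.hog_ids:
            present = og.presence(hog)
            origin_is_tip = truth.origin[hog] in tree.tip_names
            if origin_is_tip:
                assert present == {truth.origin[hog]}
            else:
                assert present == set()

    def test_passes_reader_validation(self, tmp_path):
        tree = sim.simulate_tree(5, seed=1)
        og, _ = sim.simulate_orthogroups(tree, n_hogs=80, seed=4)
        og.write(tmp_path / "og.tsv")
        again = pr.read_orthogroups(tmp_path / "og.tsv")
        assert again.hog_ids == og.hog_ids

    def test_zero_weights_rejected(self):
        tree = sim.simulate_tree(4, seed=1)
        with pytest.raises(ValueError, match="zero"):
            sim.simulate_orthogroups(
                tree, n_hogs=5, gain_node_weights={tree.root.label: 0.0}, seed=0
            )


class TestSimulateRegulation:
    def test_no_recruitment_no_fp_gives_empty_deogs(self):
        tree = sim.simulate_tree(5, seed=1)
        og, _ = sim.simulate_orthogroups(tree, n_hogs=60, seed=2)
        stats, truth = sim.simulate_regulation(
            tree, og, recruit_fraction=0.0, fp_deg_rate=0.0, seed=3
        )
        assert truth.recruitment == {}
        degs = {
            sp: pr.select_degs(stats[sp], 0.05, 1.0, "up") for sp in tree.tip_names
        }
        matrix = pr.code_deogs(og, degs, list(tree.tip_names))
        assert not matrix.cells.any()

    def test_tiny_rate_root_recruitment_fully_recovered(self):
        tree = sim.simulate_tree(5, seed=1)
        og, _ = sim.simulate_orthogroups(
            tree, n_hogs=40, gain_node_weights={tree.root.label: 1.0},
            loss_prob_per_branch=0.0, seed=2,
        )
        stats, truth = sim.simulate_regulation(
            tree, og, recruit_fraction=0.5, q_true=1e-6, fp_deg_rate=0.0, seed=3
        )
        degs = {
            sp: pr.select_degs(stats[sp], 0.05, 0.0, "up") for sp in tree.tip_names
        }
        matrix = pr.code_deogs(og, degs, list(tree.tip_names))
        assignment, _ = pr.reconstruct_all(matrix, tree)
        for hog in truth.recruitment:
            assert assignment.node_of[hog] == tree.root.label

    def test_deterministic(self):
        tree = sim.simulate_tree(5, seed=1)
        og, _ = sim.simulate_orthogroups(tree, n_hogs=30, seed=2)
        s1, t1 = sim.simulate_regulation(tree, og, seed=9)
        s2, t2 = sim.simulate_regulation(tree, og, seed=9)
        assert t1.recruitment == t2.recruitment
        for sp in tree.tip_names:
            assert s1[sp].frame.equals(s2[sp].frame)

    def test_stats_pass_reader_validation(self, tmp_path):
        tree = sim.simulate_tree(4, seed=1)
        og, _ = sim.simulate_orthogroups(tree, n_hogs=30, seed=2)
        stats, _ = sim.simulate_regulation(tree, og, seed=3)
        sp = tree.tip_names[0]
        stats[sp].frame.to_csv(tmp_path / "s.tsv", sep="\t", index=False)
        again = pr.read_deg_stats(tmp_path / "s.tsv", sp)
        assert len(again) == len(stats[sp])

    def test_truth_recruitment_compatible_with_origin(self, small_dataset):
        tree, truth = small_dataset["tree"], small_dataset["truth"]
        for hog, node in truth.recruitment.items():
            assert tree.is_ancestor_or_equal(truth.origin[hog], node)


class TestSimulateProteomes:
    def test_planted_family_construction(self):
        tree = sim.simulate_tree(4, seed=1)
        og, _ = sim.simulate_orthogroups(tree, n_hogs=40, seed=2)
        sp = tree.tip_names[0]
        proteins, release, og_ext = sim.simulate_proteomes(
            og, {"species": sp, "ncr_like": 20, "release_background": 0}, seed=5
        )
        planted = [g for g in release.gene_ids]
        assert len(planted) == 20
        ss = pr.classify_species_specific(og_ext)
        for g in planted:
            seq = proteins.records[g]
            assert 40 <= len(seq) <= 120
            assert seq.count("C") / len(seq) >= 0.10
            assert proteins.signal_peptide[g]
            assert og_ext.gene_to_hog[g] in ss[sp]

    def test_no_planting_release_from_background(self):
        tree = sim.simulate_tree(4, seed=1)
        og, _ = sim.simulate_orthogroups(tree, n_hogs=40, seed=2)
        sp = tree.tip_names[0]
        proteins, release, og_ext = sim.simulate_proteomes(
            og, {"species": sp, "release_background": 30}, seed=5
        )
        assert og_ext is og  # no new HOGs
        n_bg = len(og.species_genes(sp))
        assert len(release.gene_ids) == min(30, n_bg // 2)
        assert release.gene_ids <= set(og.species_genes(sp))

    def test_byte_identical_fasta_under_seed(self, tmp_path):
        tree = sim.simulate_tree(4, seed=1)
        og, _ = sim.simulate_orthogroups(tree, n_hogs=20, seed=2)
        sp = tree.tip_names[0]
        for i in (1, 2):
            ps, _, _ = sim.simulate_proteomes(og, {"species": sp, "ncr_like": 5}, seed=8)
            ps.write_fasta(tmp_path / f"p{i}.fasta")
        assert (tmp_path / "p1.fasta").read_bytes() == (tmp_path / "p2.fasta").read_bytes()

    def test_unknown_species_rejected(self):
        tree = sim.simulate_tree(4, seed=1)
        og, _ = sim.simulate_orthogroups(tree, n_hogs=10, seed=2)
        with pytest.raises(ValueError, match="unknown target species"):
            sim.simulate_proteomes(og, {"species": "nope"}, seed=1)
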