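"""Stratified permutation null: conservation, determinism, p-value
arithmetic.  The uniformity calibration lives in the acceptance suite."""
from __future__ import annotations

import numpy as np
import pytest

import phylorecruit as pr
from phylorecruit import simulate as sim
from phylorecruit.null_model import NullDistribution


@pytest.fixture(scope="module")
def dataset():
    tree = sim.simulate_tree(6, seed=21)
    og, _ = sim.simulate_orthogroups(tree, n_hogs=200, seed=22)
    origin = pr.build_origin_map(og, tree)
    rng = np.random.default_rng(23)
    observed = {}
    for sp in tree.tip_names:
        genes = og.species_genes(sp)
        take = rng.choice(len(genes), size=min(25, len(genes)), replace=False)
        observed[sp] = pr.DEGSet(
            species=sp, direction="up",
            gene_ids=frozenset(genes[i] for i in take),
        )
    return tree, og, origin, observed


def strata_counts(og, origin, degs):
    out = {}
    for sp, ds in degs.items():
        for g in ds.gene_ids:
            key = (sp, origin[og.gene_to_hog[g]])
            out[key] = out.get(key, 0) + 1
    return out


class TestStratifiedResample:
    def test_exact_conservation_per_species_and_stratum(self, dataset):
        tree, og, origin, observed = dataset
        redraw = pr.stratified_resample(og, origin, observed, rng_seed=1)
        for sp in observed:
            assert len(redraw[sp]) == len(observed[sp])
        assert strata_counts(og, origin, redraw) == strata_counts(
            og, origin, observed
        )

    def test_same_seed_identical(self, dataset):
        tree, og, origin, observed = dataset
        a = pr.stratified_resample(og, origin, observed, rng_seed=42)
        b = pr.stratified_resample(og, origin, observed, rng_seed=42)
        assert {s: d.gene_ids for s, d in a.items()} == {
            s: d.gene_ids for s, d in b.items()
        }

    def test_degenerate_full_stratum_draw(self, quartet):
        og = pr.OrthogroupTable(
            ["H1"], ["A", "B", "C", "D"], {("H1", "A"): ("a1", "a2")}
        )
        origin = pr.build_origin_map(og, quartet)
        observed = {
            "A": pr.DEGSet(species="A", direction="up", gene_ids=frozenset(["a1", "a2"]))
        }
        redraw = pr.stratified_resample(og, origin, observed, rng_seed=0)
        assert redraw["A"].gene_ids == {"a1", "a2"}


class TestNullNodeCounts:
    def test_single_replicate_shape(self, dataset):
        tree, og, origin, observed = dataset
        null = pr.null_node_counts(og, tree, origin, observed, n_reps=1, rng_seed=5)
        assert null.counts.shape[1] == 1

    def test_no_degs_all_zero(self, dataset):
        tree, og, origin, _ = dataset
        empty = {
            sp: pr.DEGSet(species=sp, direction="up", gene_ids=frozenset())
            for sp in tree.tip_names
        }
        null = pr.null_node_counts(og, tree, origin, empty, n_reps=3, rng_seed=5)
        assert not null.counts.any()

    def test_same_seed_identical_counts(self, dataset):
        tree, og, origin, observed = dataset
        a = pr.null_node_counts(og, tree, origin, observed, n_reps=10, rng_seed=9)
        b = pr.null_node_counts(og, tree, origin, observed, n_reps=10, rng_seed=9)
        assert (a.counts == b.counts).all()

    def test_replicate_totals_equal_nonzero_deogs(self, dataset):
        # per replicate, the summed node counts equal the number of
        # orthogroups containing >=1 resampled DEG (nothing counted twice)
        tree, og, origin, observed = dataset
        null = pr.null_node_counts(og, tree, origin, observed, n_reps=5, rng_seed=7)
        # replicate 0 shares the RNG stream with a fresh draw at the same seed
        redraw = pr.stratified_resample(og, origin, observed, rng_seed=7)
        matrix = pr.code_deogs(og, redraw, list(tree.tip_names))
        assert null.counts[:, 0].sum() == len(matrix.nonzero_hogs())

    def test_mk_mode_runs_and_conserves_totals(self, dataset):
        tree, og, origin, observed = dataset
        null = pr.null_node_counts(
            og, tree, origin, observed, n_reps=2, rng_seed=3,
            assignment_method="mk",
        )
        redraw = pr.stratified_resample(og, origin, observed, rng_seed=3)
        matrix = pr.code_deogs(og, redraw, list(tree.tip_names))
        assert null.counts[:, 0].sum() == len(matrix.nonzero_hogs())

    def test_parsimony_matches_direct_recount(self, dataset):
        tree, og, origin, observed = dataset
        null = pr.null_node_counts(og, tree, origin, observed, n_reps=1, rng_seed=77)
        redraw = pr.stratified_resample(og, origin, observed, rng_seed=77)
        matrix = pr.code_deogs(og, redraw, list(tree.tip_names))
        expect = dict.fromkeys(null.nodes, 0)
        for hog in matrix.nonzero_hogs():
            row = matrix.row(hog)
            node = pr.assign_origin_node(tree, row)
            expect[node] += 1
        got = dict(zip(null.nodes, null.counts[:, 0]))
        assert {k: int(v) for k, v in got.items()} == expect


class TestCompareToNull:
    def make_null(self, counts_row, nodes=("root",)):
        arr = np.array([counts_row])
        return NullDistribution(
            nodes=list(nodes), counts=arr, n_reps=arr.shape[1], seed=0
        )

    def test_pct_change_definition(self):
        null = self.make_null([10] * 4)
        out = pr.compare_to_null({"root": 30}, null)
        assert out.loc["root", "pct_change"] == pytest.approx(200.0)

    def test_all_replicates_equal_observation(self):
        null = self.make_null([5] * 10)
        out = pr.compare_to_null({"root": 5}, null)
        assert out.loc["root", "p_upper"] == pytest.approx(1.0)
        assert out.loc["root", "p_lower"] == pytest.approx(1.0)

    def test_observation_above_all_replicates(self):
        null = self.make_null(list(range(1000)))
        out = pr.compare_to_null({"root": 10_000}, null)
        assert out.loc["root", "p_upper"] == pytest.approx(1 / 1001)

    def test_zero_mean_gives_inf_sentinel(self):
        null = self.make_null([0, 0, 0])
        out = pr.compare_to_null({"root": 2}, null)
        assert np.isinf(out.loc["root", "pct_change"])

    def test_unknown_node_rejected(self):
        null = self.make_null([1, 2])
        with pytest.raises(ValueError, match="absent"):
            pr.compare_to_null({"nope": 1}, null)
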