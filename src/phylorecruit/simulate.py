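"""Synthetic datasets with planted ground truth.

Every generator is a pure function of its parameters and seed, and its
output satisfies the package readers' validation.  The generators emulate
the statistical structure the analysis assumes: a small rooted analysis
tree; orthogroups gained at a node and lost along branches (giving
lineage-specific presence/absence); differential-expression calls whose
binary orthogroup character evolves under the same equal-rates Markov
model the estimator fits, planted at a known recruitment node; and
proteomes carrying planted short cysteine-rich or proline-rich secreted
families restricted to species-specific orthogroups.  Planted truth is
returned as an explicit table so recovery tests never peek at generator
internals.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .parsimony import build_origin_map
from .tables import (
    DEStatsTable,
    OrthogroupTable,
    ProteinSet,
    TraitGeneSet,
)
from .trees import SpeciesTree, TreeNode, write_newick

log = logging.getLogger(__name__)

__all__ = [
    "TruthTable",
    "simulate_tree",
    "simulate_er_characters",
    "simulate_orthogroups",
    "simulate_regulation",
    "simulate_proteomes",
    "write_fixture",
]

_AA20 = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass
class TruthTable:
    """Planted ground truth, keyed by HOG id."""

    origin: dict[str, str] = field(default_factory=dict)
    recruitment: dict[str, str] = field(default_factory=dict)  # hog -> node label
    planted_family: dict[str, str] = field(default_factory=dict)  # hog -> family

    def merged(self, other: "TruthTable") -> "TruthTable":
        return TruthTable(
            origin={**self.origin, **other.origin},
            recruitment={**self.recruitment, **other.recruitment},
            planted_family={**self.planted_family, **other.planted_family},
        )

    def to_frame(self) -> pd.DataFrame:
        hogs = sorted(
            set(self.origin) | set(self.recruitment) | set(self.planted_family)
        )
        return pd.DataFrame(
            {
                "hog_id": hogs,
                "origin_node": [self.origin.get(h, "") for h in hogs],
                "true_recruitment_node": [
                    self.recruitment.get(h, "") for h in hogs
                ],
                "planted_family": [
                    self.planted_family.get(h, "none") for h in hogs
                ],
            }
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, lineterminator="\n")


def simulate_tree(n_tips: int, seed: int, tip_prefix: str = "S") -> SpeciesTree:
    """Random rooted bifurcating tree by uniform coalescent-style joins.

    Tips are named ``S1..Sn``; every branch length is an independent
    Exponential(1) draw.  Deterministic under the seed.
    """
    if n_tips < 3:
        raise ValueError(f"need at least 3 tips, got {n_tips}")
    rng = np.random.default_rng(seed)
    lineages = [TreeNode(label=f"{tip_prefix}{i + 1}") for i in range(n_tips)]
    while len(lineages) > 1:
        i, j = rng.choice(len(lineages), size=2, replace=False)
        i, j = int(min(i, j)), int(max(i, j))
        right = lineages.pop(j)
        left = lineages.pop(i)
        parent = TreeNode(label=None)
        for child in (left, right):
            child.branch_length = float(rng.exponential(1.0))
            parent.add_child(child)
        lineages.append(parent)
    root = lineages[0]
    root.branch_length = 0.0
    return SpeciesTree(root)


def _evolve_binary(
    tree: SpeciesTree, start_label: str, q: float, rng: np.random.Generator
) -> dict[str, int]:
    """Evolve a 0/1 state from ``start_label`` (state 1) down to the tips
    under ER(q); tips outside the start clade are 0."""
    state: dict[str, int] = {start_label: 1}
    start = tree.nodes_by_label[start_label]
    stack = list(start.children)
    while stack:
        node = stack.pop()
        p_switch = 0.5 * (1.0 - math.exp(-2.0 * q * node.branch_length))
        parent_state = state[node.parent.label]
        flip = rng.random() < p_switch
        state[node.label] = parent_state ^ int(flip)
        stack.extend(node.children)
    return {
        t: state.get(t, 0) for t in tree.tip_names
    }


def simulate_er_characters(
    tree: SpeciesTree, q: float, n_chars: int, seed: int
) -> list[dict[str, int]]:
    """Independent binary characters under ER(q) with a uniform root state."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_chars):
        root_state = int(rng.random() < 0.5)
        tips = _evolve_binary(tree, tree.root.label, q, rng)
        if root_state == 0:  # ER is symmetric: relabel states
            tips = {t: 1 - s for t, s in tips.items()}
        out.append(tips)
    return out


def simulate_orthogroups(
    tree: SpeciesTree,
    n_hogs: int = 5000,
    gain_node_weights: dict[str, float] | None = None,
    loss_prob_per_branch: float = 0.05,
    genes_per_species_mean: float = 2.0,
    seed: int = 0,
) -> tuple[OrthogroupTable, TruthTable]:
    """Gain/loss orthogroup simulator.

    Each HOG gains at a node drawn by ``gain_node_weights`` (default: 0.4
    on the root, 0.3 split over other internal nodes, 0.3 over tips —
    a mix of ancient families and lineage-specific ones), survives each
    descendant branch with probability ``1 - loss_prob_per_branch``, and
    present tips receive ``Poisson(genes_per_species_mean)`` (min 1)
    genes.  The truth table records the gain node of every HOG.
    """
    if not (0.0 <= loss_prob_per_branch <= 1.0):
        raise ValueError("loss_prob_per_branch must lie in [0, 1]")
    if gain_node_weights is None:
        internal = [l for l in tree.internal_labels if l != tree.root.label]
        gain_node_weights = {tree.root.label: 0.4}
        for l in internal:
            gain_node_weights[l] = 0.3 / len(internal) if internal else 0.0
        for t in tree.tip_names:
            gain_node_weights[t] = 0.3 / len(tree.tip_names)
    labels = sorted(gain_node_weights)
    weights = np.array([gain_node_weights[l] for l in labels], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("all gain-node weights are zero")
    weights = weights / weights.sum()
    for lab in labels:
        if lab not in tree.nodes_by_label:
            raise ValueError(f"gain node {lab!r} not in tree")

    rng = np.random.default_rng(seed)
    width = len(str(n_hogs))
    genes: dict[tuple[str, str], tuple[str, ...]] = {}
    hog_ids = []
    truth = TruthTable()
    counters = {sp: 0 for sp in tree.tip_names}
    for k in range(n_hogs):
        hog = f"HOG{k + 1:0{width}d}"
        hog_ids.append(hog)
        gain = labels[int(rng.choice(len(labels), p=weights))]
        truth.origin[hog] = gain
        # presence survives each branch below the gain node independently
        present: list[str] = []
        gain_node = tree.nodes_by_label[gain]
        if gain_node.is_tip:
            present = [gain]
        else:
            alive = {gain}
            stack = list(gain_node.children)
            while stack:
                node = stack.pop()
                if node.parent.label in alive and rng.random() >= loss_prob_per_branch:
                    alive.add(node.label)
                    if node.is_tip:
                        present.append(node.label)
                    else:
                        stack.extend(node.children)
        for sp in sorted(present):
            n_genes = max(1, int(rng.poisson(genes_per_species_mean)))
            ids = []
            for _ in range(n_genes):
                counters[sp] += 1
                ids.append(f"{sp}_g{counters[sp]:05d}")
            genes[(hog, sp)] = tuple(ids)
    og = OrthogroupTable(hog_ids, list(tree.tip_names), genes)
    return og, truth


def simulate_regulation(
    tree: SpeciesTree,
    og: OrthogroupTable,
    recruit_fraction: float = 0.1,
    recruit_node_weights: dict[str, float] | None = None,
    q_true: float = 0.3,
    fp_deg_rate: float = 0.01,
    seed: int = 0,
    contrast: str = "sym",
) -> tuple[dict[str, DEStatsTable], TruthTable]:
    """Plant trait regulation on a fraction of orthogroups.

    For each recruited HOG, a recruitment node is drawn by weight among
    nodes compatible with the HOG's origin (the regulation cannot predate
    the family), the binary "regulated" state evolves from that node under
    ER(``q_true``), and each state-1 tip with genes in the HOG emits one
    significant DE row (logFC ~ Normal(3, 1) clipped positive, FDR ~
    Uniform(0, 0.05)).  All other genes emit null rows (logFC ~
    Normal(0, 0.5), FDR ~ Uniform(0.05, 1)); false-positive significant
    rows are sprinkled at ``fp_deg_rate`` per null gene.
    """
    if not (0.0 <= recruit_fraction <= 1.0):
        raise ValueError("recruit_fraction must lie in [0, 1]")
    if recruit_node_weights is None:
        recruit_node_weights = {tree.root.label: 1.0}
    for lab in recruit_node_weights:
        if lab not in tree.nodes_by_label:
            raise ValueError(f"recruitment node {lab!r} not in tree")
    rng = np.random.default_rng(seed)
    origin = build_origin_map(og, tree)

    labels = sorted(recruit_node_weights)
    weights = np.array([recruit_node_weights[l] for l in labels], dtype=float)
    weights = weights / weights.sum()
    # HOGs eligible for node v: v lies within the clade where the family exists
    eligible = {
        v: [
            h
            for h in og.hog_ids
            if h in origin and tree.is_ancestor_or_equal(origin[h], v)
        ]
        for v in labels
    }
    n_recruit = int(round(recruit_fraction * og.n_hogs))
    truth = TruthTable()
    deg_genes: dict[str, set[str]] = {sp: set() for sp in tree.tip_names}
    taken: set[str] = set()
    n_skipped = 0
    for _ in range(n_recruit):
        v = labels[int(rng.choice(len(labels), p=weights))]
        pool = [h for h in eligible[v] if h not in taken]
        if not pool:
            n_skipped += 1
            continue
        hog = pool[int(rng.choice(len(pool)))]
        taken.add(hog)
        truth.recruitment[hog] = v
        tips = _evolve_binary(tree, v, q_true, rng)
        for sp in tree.tip_names:
            if tips[sp] == 1:
                hog_genes = og.genes(hog, sp)
                if hog_genes:
                    deg_genes[sp].add(hog_genes[0])
    if n_skipped:
        log.warning("%d recruitments skipped: eligible HOG pool exhausted", n_skipped)

    stats: dict[str, DEStatsTable] = {}
    for sp in tree.tip_names:
        rows = []
        for gene in og.species_genes(sp):
            is_deg = gene in deg_genes[sp]
            if not is_deg and rng.random() < fp_deg_rate:
                is_deg = True
            if is_deg:
                logfc = max(float(rng.normal(3.0, 1.0)), 0.01)
                fdr = float(rng.uniform(0.0, 0.05))
            else:
                logfc = float(rng.normal(0.0, 0.5))
                fdr = float(rng.uniform(0.05, 1.0))
            rows.append(
                {"gene_id": gene, "contrast": contrast, "logFC": logfc, "FDR": fdr}
            )
        frame = pd.DataFrame(rows, columns=["gene_id", "contrast", "logFC", "FDR"])
        stats[sp] = DEStatsTable(species=sp, frame=frame)
    return stats, truth


def _random_sequence(
    rng: np.random.Generator, length: int, rich_residue: str | None = None,
    rich_prop: float = 0.0,
) -> str:
    n_rich = int(round(rich_prop * length)) if rich_residue else 0
    others = [a for a in _AA20 if a != rich_residue]
    body = rng.choice(len(others), size=length - n_rich)
    seq = [others[i] for i in body] + [rich_residue] * n_rich
    perm = rng.permutation(length)
    return "".join(np.array(seq, dtype=object)[perm].tolist())


def simulate_proteomes(
    og: OrthogroupTable,
    planted_spec: dict,
    seed: int,
) -> tuple[ProteinSet, TraitGeneSet, OrthogroupTable]:
    """Proteome of one species with optional planted secreted families.

    ``planted_spec`` keys: ``species`` (target, required), ``ncr_like``
    and ``prp_like`` (counts of planted short Cys-rich / Pro-rich
    signal-peptide families, default 0), ``release_background`` (number
    of ordinary background proteins additionally tagged into the release
    module, default 150), ``background_signalp_rate`` (default 0.08).

    Background proteins cover every gene of the target species in the
    orthogroup table, with LogNormal lengths (mean ~350 aa) and uniform
    residue usage.  Each planted protein lives in its own new
    species-specific HOG, is 40–120 aa with the rich residue at
    proportion >= 0.10, carries a signal peptide and is release-tagged.
    Returns the protein set, the release module and the orthogroup table
    extended with the planted HOGs.
    """
    species = planted_spec.get("species")
    if species is None or species not in og.species:
        raise ValueError(f"unknown target species {species!r}")
    n_ncr = int(planted_spec.get("ncr_like", 0))
    n_prp = int(planted_spec.get("prp_like", 0))
    n_bg_release = int(planted_spec.get("release_background", 150))
    sp_rate = float(planted_spec.get("background_signalp_rate", 0.08))

    rng = np.random.default_rng(seed)
    records: dict[str, str] = {}
    flags: dict[str, bool] = {}
    backgrounds = og.species_genes(species)
    for gene in backgrounds:
        length = int(np.clip(rng.lognormal(math.log(320.0), 0.45), 50, 3000))
        records[gene] = _random_sequence(rng, length)
        flags[gene] = bool(rng.random() < sp_rate)

    release: set[str] = set()
    new_rows: dict[str, dict[str, tuple[str, ...]]] = {}
    planted_families: dict[str, str] = {}
    k = 0
    for family, count, residue in (
        ("ncr_like", n_ncr, "C"),
        ("prp_like", n_prp, "P"),
    ):
        for _ in range(count):
            k += 1
            gene = f"{species}_sp{k:04d}"
            length = int(rng.integers(40, 121))
            rich_prop = float(rng.uniform(0.10, 0.25))
            records[gene] = _random_sequence(rng, length, residue, rich_prop)
            flags[gene] = True
            release.add(gene)
            hog = f"HOGsp{k:04d}"
            new_rows[hog] = {species: (gene,)}
            planted_families[hog] = family

    if backgrounds and n_bg_release:
        # cap so the non-release background stays non-empty
        take = min(n_bg_release, len(backgrounds) // 2)
        picks = rng.choice(len(backgrounds), size=take, replace=False)
        release.update(backgrounds[i] for i in sorted(picks.tolist()))

    og_ext = og.extended(new_rows) if new_rows else og
    proteins = ProteinSet(records=records, signal_peptide=flags)
    release_set = TraitGeneSet(
        name="release", species=species, gene_ids=frozenset(release)
    )
    if planted_families:
        proteins.planted_hogs = planted_families  # type: ignore[attr-defined]
    return proteins, release_set, og_ext


def write_fixture(
    outdir,
    seed: int = 11,
    n_tips: int = 9,
    n_hogs: int = 5000,
    recruit_fraction: float = 0.1,
    q_true: float = 0.3,
    fp_deg_rate: float = 0.01,
    ncr_like: int = 100,
    prp_like: int = 0,
    n_null_reps: int = 100,
    protein_species: str | None = None,
) -> Path:
    """Write a complete fixture directory for the pipeline.

    Contents: ``tree.nwk``, ``orthogroups.tsv``, ``deg_stats/<sp>.tsv``,
    ``proteins.fasta``, ``signalp.tsv``, ``release_genes.txt``,
    ``truth.tsv`` and a ready-to-run ``config.yaml``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tree = simulate_tree(n_tips, seed=seed)
    og, truth_og = simulate_orthogroups(tree, n_hogs=n_hogs, seed=seed + 1)
    stats, truth_reg = simulate_regulation(
        tree,
        og,
        recruit_fraction=recruit_fraction,
        q_true=q_true,
        fp_deg_rate=fp_deg_rate,
        seed=seed + 2,
    )
    if protein_species is None:
        protein_species = tree.tip_names[0]
    proteins, release, og_ext = simulate_proteomes(
        og,
        {"species": protein_species, "ncr_like": ncr_like, "prp_like": prp_like},
        seed=seed + 3,
    )
    truth = truth_og.merged(truth_reg)
    truth.planted_family.update(getattr(proteins, "planted_hogs", {}))

    write_newick(tree, outdir / "tree.nwk")
    og_ext.write(outdir / "orthogroups.tsv")
    (outdir / "deg_stats").mkdir(exist_ok=True)
    for sp, table in stats.items():
        table.frame.to_csv(
            outdir / "deg_stats" / f"{sp}.tsv", sep="\t", index=False,
            lineterminator="\n",
        )
    proteins.write_fasta(outdir / "proteins.fasta")
    proteins.write_signal_flags(outdir / "signalp.tsv")
    (outdir / "release_genes.txt").write_text(
        "\n".join(sorted(release.gene_ids)) + "\n"
    )
    truth.write(outdir / "truth.tsv")

    config = {
        "seed": seed,
        "tree": "tree.nwk",
        "orthogroups": "orthogroups.tsv",
        "deg_stats": {sp: f"deg_stats/{sp}.tsv" for sp in tree.tip_names},
        "direction": "up",
        "fdr_max": 0.05,
        "logfc_min": 1.0,
        "recruit_threshold": 0.6,
        "n_null_reps": n_null_reps,
        "proteins": "proteins.fasta",
        "signal_peptides": "signalp.tsv",
        "trait_sets": [
            {
                "name": "release",
                "species": protein_species,
                "path": "release_genes.txt",
            }
        ],
    }
    (outdir / "config.yaml").write_text(yaml.safe_dump(config, sort_keys=True))
    return outdir
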