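"""Stratified gene-resampling permutation null for per-node DEOG counts.

The observed count of DEOGs assigned to each tree node depends on nuisance
structure — how many DEGs each species has, and how old the orthogroups
containing them are.  The null preserves both: for every species and every
origin stratum (the phylostratum of the orthogroup holding the gene), the
observed number of DEGs is redrawn uniformly without replacement from that
species' genes residing in orthogroups of the same origin.  Each replicate
is then re-coded into DEOGs and every non-empty DEOG is assigned a node by
parsimony on the DEG-presence pattern (the MRCA of species with a
resampled DEG); an optional mode runs the full Mk pipeline instead.
Empirical p-values use the add-one convention.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .deog import code_deogs
from .mk import reconstruct_all
from .parsimony import assign_origin_node
from .tables import DEGSet, OrthogroupTable
from .trees import SpeciesTree

log = logging.getLogger(__name__)

__all__ = [
    "NullDistribution",
    "stratified_resample",
    "null_node_counts",
    "compare_to_null",
]


@dataclass
class NullDistribution:
    """Per-node DEOG counts over permutation replicates."""

    nodes: list[str]
    counts: np.ndarray  # shape (n_nodes, n_reps)
    n_reps: int
    seed: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.nodes), self.n_reps):
            raise ValueError("counts shape does not match nodes x n_reps")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=pd.Index(self.nodes, name="node"),
            columns=[f"rep{r}" for r in range(self.n_reps)],
        )


class _Strata:
    """Per-(species, origin-node) gene pools and required draw sizes."""

    def __init__(
        self,
        og: OrthogroupTable,
        origin: dict[str, str],
        observed_degs: dict[str, DEGSet],
    ):
        self.hog_index = {h: i for i, h in enumerate(og.hog_ids)}
        need: dict[tuple[str, str], int] = {}
        dropped = 0
        for sp, degset in observed_degs.items():
            for gene in degset.gene_ids:
                hog = og.gene_to_hog.get(gene)
                if hog is None or hog not in origin:
                    dropped += 1
                    continue
                key = (sp, origin[hog])
                need[key] = need.get(key, 0) + 1
        if dropped:
            log.warning(
                "%d observed DEGs not resolvable to an orthogroup with an "
                "origin node (excluded from the null strata)",
                dropped,
            )
        self.need = need

        species_wanted = {sp for sp, _v in need}
        pool_genes: dict[tuple[str, str], list[str]] = {}
        pool_hogs: dict[tuple[str, str], list[int]] = {}
        for sp in sorted(species_wanted):
            for hog in og.hog_ids:
                v = origin.get(hog)
                if v is None:
                    continue
                genes = og.genes(hog, sp)
                if not genes:
                    continue
                key = (sp, v)
                pool_genes.setdefault(key, []).extend(genes)
                pool_hogs.setdefault(key, []).extend(
                    [self.hog_index[hog]] * len(genes)
                )
        self.pool_genes = {k: np.array(v, dtype=object) for k, v in pool_genes.items()}
        self.pool_hogs = {k: np.array(v, dtype=np.int64) for k, v in pool_hogs.items()}

        for key, n in sorted(self.need.items()):
            avail = len(self.pool_genes.get(key, ()))
            if n > avail:
                raise ValueError(
                    f"stratum (species={key[0]!r}, origin={key[1]!r}) requires "
                    f"{n} genes but only {avail} are available"
                )
        self.order = sorted(self.need)

    def draw_indices(self, rng: np.random.Generator) -> dict[tuple[str, str], np.ndarray]:
        out = {}
        for key in self.order:
            n = self.need[key]
            pool_size = len(self.pool_genes[key])
            out[key] = rng.choice(pool_size, size=n, replace=False)
        return out


def _as_rng(rng_seed) -> np.random.Generator:
    if isinstance(rng_seed, np.random.Generator):
        return rng_seed
    return np.random.default_rng(rng_seed)


def stratified_resample(
    og: OrthogroupTable,
    origin: dict[str, str],
    observed_degs: dict[str, DEGSet],
    rng_seed,
) -> dict[str, DEGSet]:
    """One stratified redraw of the DEG sets.

    Per-species totals and per-(species, origin) totals are exactly
    preserved; draws are uniform without replacement within each stratum.
    """
    strata = _Strata(og, origin, observed_degs)
    rng = _as_rng(rng_seed)
    idx = strata.draw_indices(rng)
    per_species: dict[str, set[str]] = {sp: set() for sp in observed_degs}
    for key in strata.order:
        sp = key[0]
        per_species[sp].update(strata.pool_genes[key][idx[key]].tolist())
    return {
        sp: DEGSet(
            species=sp,
            direction=observed_degs[sp].direction,
            gene_ids=frozenset(genes),
        )
        for sp, genes in per_species.items()
    }


def null_node_counts(
    og: OrthogroupTable,
    tree: SpeciesTree,
    origin: dict[str, str],
    observed_degs: dict[str, DEGSet],
    n_reps: int,
    rng_seed: int,
    assignment_method: str = "parsimony",
    recruit_threshold: float = 0.6,
) -> NullDistribution:
    """Null distribution of per-node DEOG counts over ``n_reps`` replicates.

    Default node assignment is parsimony on the resampled DEG-presence
    pattern (MRCA of species with a DEG in the orthogroup); the ``"mk"``
    mode runs the full Mk reconstruction per replicate for sensitivity
    analysis.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if assignment_method not in ("parsimony", "mk"):
        raise ValueError(f"unknown assignment_method {assignment_method!r}")
    tips = set(tree.tip_names)
    unknown = set(observed_degs) - tips
    if unknown:
        raise ValueError(f"DEG species not on the tree: {sorted(unknown)}")

    strata = _Strata(og, origin, observed_degs)
    rng = _as_rng(rng_seed)
    nodes = tree.labels + ["unassigned"]
    node_index = {lab: i for i, lab in enumerate(nodes)}
    counts = np.zeros((len(nodes), n_reps), dtype=np.int64)

    tip_order = list(tree.tip_names)
    bit_of = {sp: np.uint64(1) << np.uint64(j) for j, sp in enumerate(tip_order)}
    n_hogs = og.n_hogs

    if assignment_method == "parsimony":
        mask_to_node: dict[int, int] = {}

        def node_for_mask(mask: int) -> int:
            cached = mask_to_node.get(mask)
            if cached is not None:
                return cached
            present = [
                sp for j, sp in enumerate(tip_order) if mask & (1 << j)
            ]
            if len(present) == 1:
                label = present[0]
            else:
                label = tree.mrca(present).label
            mask_to_node[mask] = node_index[label]
            return node_index[label]

        for r in range(n_reps):
            idx = strata.draw_indices(rng)
            mask = np.zeros(n_hogs, dtype=np.uint64)
            for key in strata.order:
                hogs = strata.pool_hogs[key][idx[key]]
                np.bitwise_or.at(mask, hogs, bit_of[key[0]])
            nz = mask[mask != np.uint64(0)]
            vals, reps = np.unique(nz, return_counts=True)
            for v, c in zip(vals.tolist(), reps.tolist()):
                counts[node_for_mask(int(v)), r] += c
    else:  # full Mk pipeline per replicate
        for r in range(n_reps):
            idx = strata.draw_indices(rng)
            per_species: dict[str, set[str]] = {sp: set() for sp in observed_degs}
            for key in strata.order:
                per_species[key[0]].update(
                    strata.pool_genes[key][idx[key]].tolist()
                )
            degs = {
                sp: DEGSet(
                    species=sp,
                    direction=observed_degs[sp].direction,
                    gene_ids=frozenset(g),
                )
                for sp, g in per_species.items()
            }
            matrix = code_deogs(og, degs, tip_order)
            _assign, table = reconstruct_all(matrix, tree, recruit_threshold)
            for lab, c in table.items():
                counts[node_index[lab], r] += c

    return NullDistribution(
        nodes=nodes,
        counts=counts,
        n_reps=n_reps,
        seed=int(rng_seed) if not isinstance(rng_seed, np.random.Generator) else -1,
    )


def compare_to_null(
    observed_counts: dict[str, int], null: NullDistribution
) -> pd.DataFrame:
    """Observed counts versus the null: mean, percent change, empirical p.

    ``pct_change = 100 * (obs - mean_null) / mean_null`` (+inf sentinel
    when the null mean is zero but the observation is not);
    ``p_upper = (1 + #{replicates >= obs}) / (n_reps + 1)`` and
    ``p_lower`` analogously — both reported, no automatic two-siding.
    """
    unknown = set(observed_counts) - set(null.nodes)
    if unknown:
        raise ValueError(f"observed nodes absent from the null: {sorted(unknown)}")
    rows = []
    for i, node in enumerate(null.nodes):
        obs = int(observed_counts.get(node, 0))
        reps = null.counts[i]
        mean = float(reps.mean())
        sd = float(reps.std(ddof=1)) if null.n_reps > 1 else 0.0
        if mean > 0:
            pct = 100.0 * (obs - mean) / mean
        elif obs > 0:
            pct = float("inf")
        else:
            pct = 0.0
        p_upper = (1 + int((reps >= obs).sum())) / (null.n_reps + 1)
        p_lower = (1 + int((reps <= obs).sum())) / (null.n_reps + 1)
        rows.append(
            {
                "node": node,
                "observed": obs,
                "mean_null": mean,
                "sd_null": sd,
                "pct_change": pct,
                "p_upper": p_upper,
                "p_lower": p_lower,
            }
        )
    return pd.DataFrame(rows).set_index("node")
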