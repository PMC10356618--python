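"""Cross-referencing DEGs with orthogroups: binary DEOG matrices.

A differentially expressed orthogroup (DEOG) is a HOG that contains at
least one DEG in a given species; per direction this yields a binary
HOG x species matrix — the discrete character analysed on the species
tree.  The module also classifies species-specific HOGs (judged on the
full orthogroup table, which may span more genomes than the analysis
tree) and applies the presence/absence candidate filter used to shortlist
ancestral orthogroups.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import DEGSet, OrthogroupTable

log = logging.getLogger(__name__)

__all__ = [
    "DEOGMatrix",
    "code_deogs",
    "classify_species_specific",
    "candidate_filter",
]


@dataclass
class DEOGMatrix:
    """Binary HOG x species matrix; cell = 1 iff the HOG holds a DEG there.

    All-zero rows are retained: they are needed as denominators downstream.
    ``unmapped`` counts DEGs that were found in no orthogroup, per species.
    """

    direction: str
    hog_ids: list[str]
    species: list[str]
    cells: np.ndarray  # uint8, shape (n_hogs, n_species)
    unmapped: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=np.uint8)
        if self.cells.shape != (len(self.hog_ids), len(self.species)):
            raise ValueError("cells shape does not match hog_ids x species")
        if not np.isin(self.cells, (0, 1)).all():
            raise ValueError("cells must be binary")

    def row(self, hog: str) -> dict[str, int]:
        i = self.hog_ids.index(hog)
        return {s: int(v) for s, v in zip(self.species, self.cells[i])}

    def nonzero_hogs(self) -> list[str]:
        mask = self.cells.any(axis=1)
        return [h for h, m in zip(self.hog_ids, mask) if m]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.cells, index=pd.Index(self.hog_ids, name="HOG"), columns=self.species
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", lineterminator="\n")


def code_deogs(
    og: OrthogroupTable,
    degs: dict[str, DEGSet],
    analysis_species: list[str],
) -> DEOGMatrix:
    """Code each HOG 1 for every species in which it contains a DEG."""
    directions = {d.direction for d in degs.values()}
    if len(directions) > 1:
        raise ValueError(f"mixed directions in DEG sets: {sorted(directions)}")
    direction = directions.pop() if directions else "up"
    for sp in degs:
        if sp not in analysis_species:
            raise ValueError(f"DEG set species {sp!r} not in analysis species")
        if sp not in og.species:
            raise ValueError(f"species {sp!r} absent from orthogroup table")
    hog_index = {h: i for i, h in enumerate(og.hog_ids)}
    cells = np.zeros((og.n_hogs, len(analysis_species)), dtype=np.uint8)
    unmapped: dict[str, int] = {}
    for j, sp in enumerate(analysis_species):
        degset = degs.get(sp)
        if degset is None:
            continue
        miss = 0
        for gene in degset.gene_ids:
            hog = og.gene_to_hog.get(gene)
            if hog is None:
                miss += 1
                continue
            cells[hog_index[hog], j] = 1
        if miss:
            unmapped[sp] = miss
            log.warning("%d DEGs of %s found in no orthogroup (ignored)", miss, sp)
    return DEOGMatrix(
        direction=direction,
        hog_ids=list(og.hog_ids),
        species=list(analysis_species),
        cells=cells,
        unmapped=unmapped,
    )


def classify_species_specific(
    og: OrthogroupTable, analysis_species: list[str] | None = None
) -> dict[str, set[str]]:
    """HOGs whose genes all belong to a single species.

    Specificity is judged against the FULL species set of the orthogroup
    table, not the analysis subset: a HOG restricted to one species among
    all sequenced genomes is species-specific.  Only species listed in
    ``analysis_species`` (default: all) receive assignments.
    """
    wanted = set(analysis_species) if analysis_species is not None else set(og.species)
    out: dict[str, set[str]] = {sp: set() for sp in wanted}
    n_empty = 0
    for hog in og.hog_ids:
        present = og.presence(hog)
        if not present:
            n_empty += 1
            continue
        if len(present) == 1:
            (sp,) = present
            if sp in wanted:
                out[sp].add(hog)
    if n_empty:
        log.warning("%d HOG rows contain no genes at all (malformed)", n_empty)
    return out


def candidate_filter(
    og: OrthogroupTable,
    ancestral_hogs: set[str],
    rns_species: list[str],
    non_rns_species: list[str],
) -> set[str]:
    """Ancestral HOGs present in every trait-forming species and absent
    from at least one non-forming species (presence/absence shortlist)."""
    overlap = set(rns_species) & set(non_rns_species)
    if overlap:
        raise ValueError(f"species lists overlap: {sorted(overlap)}")
    for sp in list(rns_species) + list(non_rns_species):
        if sp not in og.species:
            raise ValueError(f"species {sp!r} not in orthogroup table")
    kept = set()
    for hog in ancestral_hogs:
        present = og.presence(hog)
        if all(s in present for s in rns_species) and any(
            t not in present for t in non_rns_species
        ):
            kept.add(hog)
    return kept
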