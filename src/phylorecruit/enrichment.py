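"""Node-by-node enrichment of trait modules and Venn cross-referencing.

For each tree node the trait module's DEOG count is compared with the
whole-response background via Fisher's exact test; the two-sided p-value
follows the minimum-likelihood convention (sum of hypergeometric point
probabilities no larger than the observed table's).  The reported odds
ratio is the sample odds ratio ad/bc, with the Haldane–Anscombe +0.5
correction applied to all cells when any cell is zero.  Trait and
background overlap by construction (the trait is a subset of the whole
response); the test is run on the overlapping sets as-is, which is
anti-conservative — documented, not corrected.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import pandas as pd
from scipy.stats import fisher_exact as _scipy_fisher

from .mk import RecruitmentAssignment
from .tables import DEGSet, TraitGeneSet
from .trees import SpeciesTree

log = logging.getLogger(__name__)

__all__ = [
    "EnrichmentRow",
    "fisher_exact_2x2",
    "trait_module_filter",
    "node_enrichment",
    "cross_reference_sets",
    "stars_for_p",
]


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher's exact test on the table [[a, b], [c, d]].

    Returns ``(odds_ratio, p)``.  The odds ratio is the sample estimate
    ad/bc; when any cell is zero the Haldane–Anscombe correction adds 0.5
    to every cell (logged).  p is the minimum-likelihood two-sided tail.
    """
    cells = (a, b, c, d)
    if any(x < 0 for x in cells):
        raise ValueError(f"negative cell in 2x2 table: {cells}")
    if any(int(x) != x for x in cells):
        raise ValueError(f"2x2 cells must be integer counts: {cells}")
    cells = tuple(int(x) for x in cells)
    a, b, c, d = cells
    if sum(cells) == 0:
        raise ValueError("empty 2x2 table")
    if min(cells) == 0:
        aa, bb, cc, dd = (x + 0.5 for x in cells)
        log.debug("zero cell in %s: Haldane-Anscombe correction applied", cells)
    else:
        aa, bb, cc, dd = cells
    odds_ratio = (aa * dd) / (bb * cc)
    _or, p = _scipy_fisher([[a, b], [c, d]], alternative="two-sided")
    return float(odds_ratio), float(p)


def stars_for_p(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def trait_module_filter(
    trait_set: TraitGeneSet, whole_response: DEGSet
) -> TraitGeneSet:
    """Restrict a trait gene set to genes also in the whole response.

    A gene belongs to a trait module only if it is regulated both in the
    trait contrast and in the whole symbiotic response of the species.
    """
    if trait_set.species != whole_response.species:
        raise ValueError(
            f"species mismatch: trait {trait_set.species!r} vs "
            f"response {whole_response.species!r}"
        )
    inter = trait_set.gene_ids & whole_response.gene_ids
    if not inter:
        log.warning(
            "trait %r shares no gene with the whole response", trait_set.name
        )
    return TraitGeneSet(
        name=trait_set.name, species=trait_set.species, gene_ids=frozenset(inter)
    )


@dataclass
class EnrichmentRow:
    """One node's 2x2 trait-vs-background test."""

    node: str
    trait_at_node: int
    trait_total: int
    background_at_node: int
    background_total: int
    odds_ratio: float
    p_value: float
    stars: str


def node_enrichment(
    trait_assignments: RecruitmentAssignment,
    background_assignments: RecruitmentAssignment,
    nodes: list[str],
    tree: SpeciesTree | None = None,
) -> list[EnrichmentRow]:
    """Fisher test per node: trait DEOGs at the node vs elsewhere, against
    the background (whole-response) DEOGs at the node vs elsewhere."""
    if tree is not None:
        known = set(tree.labels) | {"unassigned"}
        bad = [n for n in nodes if n not in known]
        if bad:
            raise ValueError(f"nodes absent from tree: {bad}")
    if not trait_assignments.node_of:
        raise ValueError("empty trait assignment set")
    trait_total = len(trait_assignments.node_of)
    bg_total = len(background_assignments.node_of)
    trait_counts: dict[str, int] = {}
    for node in trait_assignments.node_of.values():
        trait_counts[node] = trait_counts.get(node, 0) + 1
    bg_counts: dict[str, int] = {}
    for node in background_assignments.node_of.values():
        bg_counts[node] = bg_counts.get(node, 0) + 1

    rows = []
    for node in nodes:
        t_at = trait_counts.get(node, 0)
        b_at = bg_counts.get(node, 0)
        odds, p = fisher_exact_2x2(
            t_at, trait_total - t_at, b_at, bg_total - b_at
        )
        rows.append(
            EnrichmentRow(
                node=node,
                trait_at_node=t_at,
                trait_total=trait_total,
                background_at_node=b_at,
                background_total=bg_total,
                odds_ratio=odds,
                p_value=p,
                stars=stars_for_p(p),
            )
        )
    return rows


def enrichment_frame(rows: list[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "node": r.node,
                "trait_at_node": r.trait_at_node,
                "trait_total": r.trait_total,
                "background_at_node": r.background_at_node,
                "background_total": r.background_total,
                "odds_ratio": r.odds_ratio,
                "p_value": r.p_value,
                "stars": r.stars,
            }
            for r in rows
        ]
    )


def cross_reference_sets(
    named_sets: dict[str, set[str]]
) -> dict[str, int]:
    """Venn-region counts for 2–4 named sets of orthogroup IDs.

    Every one of the 2^k - 1 membership regions is reported (zeros
    included) under a signature joining member names with ``&`` in the
    input order; region counts sum to the size of the union.
    """
    names = list(named_sets)
    if not (2 <= len(names) <= 4):
        raise ValueError(f"need 2-4 sets, got {len(names)}")
    regions: dict[str, int] = {}
    for k in range(1, len(names) + 1):
        for combo in itertools.combinations(names, k):
            inside = set.intersection(*(set(named_sets[n]) for n in combo))
            outside = set().union(
                *(set(named_sets[n]) for n in names if n not in combo)
            ) if len(combo) < len(names) else set()
            regions["&".join(combo)] = len(inside - outside)
    return regions
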