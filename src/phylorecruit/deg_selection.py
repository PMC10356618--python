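"""Differentially expressed gene (DEG) selection.

A gene counts as differentially expressed in a direction when its FDR is
strictly below the cutoff and its log2 fold-change clears a per-species
threshold.  Because sampling and sequencing depth differ between species,
the fold-change threshold can instead be chosen from a fixed grid so that
species end up with comparable DEG counts.  DEG lists from multiple
contrasts (time points / conditions) are unioned to form the whole
trait response of a species.
"""
from __future__ import annotations

import logging

import numpy as np

from .tables import DEGSet, DEStatsTable

log = logging.getLogger(__name__)

__all__ = ["select_degs", "choose_logfc_threshold", "union_contrasts", "LOGFC_GRID"]

#: candidate log2 fold-change thresholds for the comparable-counts rule
LOGFC_GRID = tuple(round(0.1 * i, 1) for i in range(51))  # 0.0 .. 5.0


def select_degs(
    stats: DEStatsTable, fdr_max: float, logfc_min: float, direction: str
) -> DEGSet:
    """Genes with FDR < ``fdr_max`` and logFC beyond ``logfc_min``.

    ``direction`` "up" keeps rows with logFC >= logfc_min, "down" keeps
    rows with logFC <= -logfc_min (``logfc_min`` itself is nonnegative).
    A gene qualifies if any of its contrasts qualifies.
    """
    if logfc_min < 0:
        raise ValueError("logfc_min must be >= 0")
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be up/down, got {direction!r}")
    frame = stats.frame
    sig = frame["FDR"] < fdr_max
    if direction == "up":
        keep = sig & (frame["logFC"] >= logfc_min) & (frame["logFC"] > 0)
    else:
        keep = sig & (frame["logFC"] <= -logfc_min) & (frame["logFC"] < 0)
    genes = frozenset(frame.loc[keep, "gene_id"])
    return DEGSet(species=stats.species, direction=direction, gene_ids=genes)


def choose_logfc_threshold(
    stats: DEStatsTable, target_count: int, fdr_max: float, direction: str
) -> float:
    """Smallest grid threshold whose DEG count is <= ``target_count``.

    The grid runs 0.0..5.0 in steps of 0.1 (log2 units).  If even 5.0
    leaves more DEGs than the target, 5.0 is returned with a warning.
    Larger targets yield smaller-or-equal thresholds (monotone).
    """
    if target_count < 1:
        raise ValueError("target_count must be >= 1")
    frame = stats.frame
    sig = frame[frame["FDR"] < fdr_max]
    if direction == "up":
        vals = sig.loc[sig["logFC"] > 0].groupby("gene_id")["logFC"].max()
    else:
        neg = sig.loc[sig["logFC"] < 0]
        vals = (-neg["logFC"]).groupby(neg["gene_id"]).max()
    if len(vals) == 0:
        log.warning("no significant rows; threshold defaults to 0.0")
        return 0.0
    arr = np.sort(vals.to_numpy())
    for thr in LOGFC_GRID:
        count = len(arr) - int(np.searchsorted(arr, thr, side="left"))
        if count <= target_count:
            return thr
    log.warning(
        "DEG count %d above target %d even at the grid maximum 5.0",
        count,
        target_count,
    )
    return LOGFC_GRID[-1]


def union_contrasts(sets: list[DEGSet]) -> DEGSet:
    """Union of DEG sets over contrasts; all must share species and direction."""
    if not sets:
        raise ValueError("union_contrasts needs at least one DEG set")
    species = {s.species for s in sets}
    directions = {s.direction for s in sets}
    if len(species) > 1 or len(directions) > 1:
        raise ValueError(
            f"mixed species {sorted(species)} or directions {sorted(directions)}"
        )
    genes: frozenset[str] = frozenset().union(*(s.gene_ids for s in sets))
    return DEGSet(species=sets[0].species, direction=sets[0].direction, gene_ids=genes)
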