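"""Maximum-parsimony reconstruction for binary presence/absence.

Used to place each orthogroup at the node where the gene family first
appears (its phylostratum): the Fitch dynamic program gives the minimum
number of state changes, and the origin node is taken as the MRCA of all
presence tips — the unique deepest node every single-gain parsimony
reconstruction passes through.
"""
from __future__ import annotations

from .tables import OrthogroupTable
from .trees import SpeciesTree

__all__ = ["fitch_score", "assign_origin_node", "build_origin_map"]


def fitch_score(tree: SpeciesTree, tip_states: dict) -> tuple[int, frozenset[int]]:
    """Classic Fitch bottom-up pass.

    Returns the minimum number of state changes and the root state set
    (the states attainable at the root under some minimal reconstruction).
    Every tip must carry a 0/1 state.
    """
    sets: dict[str, frozenset[int]] = {}
    score = 0
    for node in tree.postorder:
        if node.is_tip:
            if node.label not in tip_states:
                raise KeyError(f"tip {node.label!r} has no state")
            v = tip_states[node.label]
            if v not in (0, 1):
                raise ValueError(f"state must be 0/1, got {v!r}")
            sets[node.label] = frozenset([int(v)])
        else:
            acc: frozenset[int] | None = None
            for child in node.children:
                s = sets[child.label]
                if acc is None:
                    acc = s
                    continue
                inter = acc & s
                if inter:
                    acc = inter
                else:
                    acc = acc | s
                    score += 1
            sets[node.label] = acc if acc is not None else frozenset()
    return score, sets[tree.root.label]


def assign_origin_node(tree: SpeciesTree, presence: dict) -> str:
    """Origin node of a gene family: the MRCA of all presence-1 tips.

    A family present in a single tip originates at that tip; an all-absent
    family has no origin (error).
    """
    ones = [t for t in tree.tip_names if presence.get(t) == 1]
    if not ones:
        raise ValueError("family absent from every tip: no origin node")
    if len(ones) == 1:
        return ones[0]
    return tree.mrca(ones).label


def build_origin_map(og: OrthogroupTable, tree: SpeciesTree) -> dict[str, str]:
    """Origin node for every HOG with >=1 gene among the tree's tips.

    HOGs with no gene in any analysis species are skipped (they carry no
    information on the analysis tree).
    """
    tips = set(tree.tip_names)
    missing = tips - set(og.species)
    if missing:
        raise ValueError(f"tree tips absent from orthogroup table: {sorted(missing)}")
    origin: dict[str, str] = {}
    for hog in og.hog_ids:
        present = og.presence(hog) & tips
        if not present:
            continue
        presence = {t: (1 if t in present else 0) for t in tree.tip_names}
        origin[hog] = assign_origin_node(tree, presence)
    return origin
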