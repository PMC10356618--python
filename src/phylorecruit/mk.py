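"""Two-state equal-rates Markov (Mk/ER) ancestral-state machinery.

The binary character is "this orthogroup is differentially regulated in
this species" (a DEOG).  Under the ER model a single rate ``q`` governs
0->1 and 1->0 transitions; the transition probabilities on a branch of
length ``t`` are closed-form:

    P(stay)   = (1 + exp(-2 q t)) / 2
    P(switch) = (1 - exp(-2 q t)) / 2

The module provides the pruning (Felsenstein) log-likelihood, bounded ML
estimation of ``q``, exact marginal ancestral probabilities via an
inside-outside (up/down) pass — not joint reconstruction — and the
recruitment-node rule: among internal nodes whose marginal probability of
state 1 exceeds the threshold, keep the most ancient (closest to the
root).  For two-state ER the stationary distribution is uniform, so the
flat and stationary root priors coincide.
"""
from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .trees import SpeciesTree

log = logging.getLogger(__name__)

__all__ = [
    "Q_MIN",
    "Q_MAX",
    "MkFit",
    "RecruitmentAssignment",
    "er_transition_prob",
    "mk_loglik",
    "fit_er_rate",
    "marginal_ancestral_probs",
    "assign_recruitment_node",
    "reconstruct_all",
]

Q_MIN = 1e-8
Q_MAX = 1e2
MISSING = 2  # internal encoding of an unobserved tip state

_PRIORS = ("flat", "stationary")  # identical for 2-state ER


def er_transition_prob(q: float, t: float) -> np.ndarray:
    """2x2 transition-probability matrix of the ER chain over time ``t``."""
    if q <= 0:
        raise ValueError(f"rate q must be positive, got {q}")
    if t < 0:
        raise ValueError(f"negative branch length t={t}")
    e = math.exp(-2.0 * q * t)
    stay = 0.5 * (1.0 + e)
    switch = 0.5 * (1.0 - e)
    return np.array([[stay, switch], [switch, stay]])


# ---------------------------------------------------------------------------
# flattened tree arrays (cached per SpeciesTree instance)


class _TreeArrays:
    def __init__(self, tree: SpeciesTree):
        nodes = tree.postorder  # children precede parents; root last
        self.labels = [n.label for n in nodes]
        index = {id(n): i for i, n in enumerate(nodes)}
        self.children = [[index[id(c)] for c in n.children] for n in nodes]
        self.blen = np.array([n.branch_length for n in nodes], dtype=float)
        self.is_tip = np.array([n.is_tip for n in nodes])
        self.tip_names = list(tree.tip_names)
        tip_col = {name: j for j, name in enumerate(self.tip_names)}
        self.tip_col = np.array(
            [tip_col[n.label] if n.is_tip else -1 for n in nodes], dtype=int
        )
        self.root = len(nodes) - 1
        self.internal = [i for i in range(len(nodes)) if not self.is_tip[i]]


def _arrays(tree: SpeciesTree) -> _TreeArrays:
    cache = getattr(tree, "_mk_arrays", None)
    if cache is None:
        cache = _TreeArrays(tree)
        tree._mk_arrays = cache  # type: ignore[attr-defined]
    return cache


def _encode_patterns(tree: SpeciesTree, tip_states_list) -> np.ndarray:
    """Encode tip-state mappings as a (m, n_tips) array of {0, 1, 2=missing}."""
    rows = []
    for tip_states in tip_states_list:
        row = []
        for name in tree.tip_names:
            if name not in tip_states:
                raise KeyError(f"tip {name!r} absent from tip-state mapping")
            v = tip_states[name]
            if v is None or v == "missing" or (isinstance(v, float) and math.isnan(v)):
                row.append(MISSING)
            elif v in (0, 1):
                row.append(int(v))
            else:
                raise ValueError(f"tip state must be 0/1/missing, got {v!r}")
        rows.append(row)
    return np.array(rows, dtype=np.uint8)


def _edge_probs(arr: _TreeArrays, q: float) -> tuple[np.ndarray, np.ndarray]:
    e = np.exp(-2.0 * q * arr.blen)
    return 0.5 * (1.0 + e), 0.5 * (1.0 - e)


def _up_pass(arr: _TreeArrays, patterns: np.ndarray, q: float):
    """Pruning pass.  Returns (partials, messages, logscale).

    ``partials[i]`` is the (m, 2) conditional likelihood of the data below
    node i given its state (rescaled rowwise; the dropped factors are
    accumulated in ``logscale``); ``messages[i]`` is the message node i
    sends to its parent.
    """
    stay, switch = _edge_probs(arr, q)
    m = patterns.shape[0]
    partials: list[np.ndarray] = [None] * len(arr.labels)  # type: ignore[list-item]
    messages: list[np.ndarray] = [None] * len(arr.labels)  # type: ignore[list-item]
    logscale = np.zeros(m)
    for i in range(len(arr.labels)):
        if arr.is_tip[i]:
            st = patterns[:, arr.tip_col[i]]
            L = np.empty((m, 2))
            L[:, 0] = st != 1  # observed 0 or missing
            L[:, 1] = st != 0  # observed 1 or missing
        else:
            L = np.ones((m, 2))
            for c in arr.children[i]:
                L = L * messages[c]
            scale = L.max(axis=1)
            pos = scale > 0
            L = np.where(pos[:, None], L / np.where(pos, scale, 1.0)[:, None], 0.0)
            with np.errstate(divide="ignore"):
                logscale = logscale + np.log(np.where(pos, scale, 0.0))
        partials[i] = L
        if i != arr.root:
            msg = np.empty_like(L)
            msg[:, 0] = stay[i] * L[:, 0] + switch[i] * L[:, 1]
            msg[:, 1] = switch[i] * L[:, 0] + stay[i] * L[:, 1]
            messages[i] = msg
    return partials, messages, logscale


def _loglik_from_up(partials, logscale, root: int) -> np.ndarray:
    lik = 0.5 * partials[root][:, 0] + 0.5 * partials[root][:, 1]
    with np.errstate(divide="ignore"):
        return np.log(lik) + logscale


def _check_prior(root_prior: str) -> None:
    if root_prior not in _PRIORS:
        raise ValueError(f"root_prior must be one of {_PRIORS}, got {root_prior!r}")


def mk_loglik(
    tree: SpeciesTree,
    tip_states: dict,
    q: float,
    root_prior: str = "flat",
) -> float:
    """Log-likelihood of one binary character under ER(``q``).

    Missing tips contribute the vector (1, 1).  The root prior is uniform
    (flat == stationary for two-state ER).
    """
    _check_prior(root_prior)
    if q <= 0:
        raise ValueError(f"rate q must be positive, got {q}")
    arr = _arrays(tree)
    patterns = _encode_patterns(tree, [tip_states])
    partials, _msgs, logscale = _up_pass(arr, patterns, q)
    return float(_loglik_from_up(partials, logscale, arr.root)[0])


def _loglik_many(tree: SpeciesTree, patterns: np.ndarray, q: float) -> np.ndarray:
    arr = _arrays(tree)
    partials, _msgs, logscale = _up_pass(arr, patterns, q)
    return _loglik_from_up(partials, logscale, arr.root)


@dataclass
class MkFit:
    """Result of the bounded ML search for the single ER rate."""

    q: float
    log_likelihood: float
    converged: bool
    at_bound: bool


def fit_er_rate(
    tree: SpeciesTree,
    tip_states,
    root_prior: str = "flat",
) -> MkFit:
    """Maximum-likelihood ER rate for one character or a pooled set.

    ``tip_states`` is a single tip->state mapping or a sequence of them;
    with several characters the pooled (summed) log-likelihood is
    maximised.  The search is a bounded scalar maximisation over log q in
    [1e-8, 100]; ``at_bound`` flags estimates pinned at either bound
    (which also covers degenerate, likelihood-flat data).
    """
    _check_prior(root_prior)
    if isinstance(tip_states, dict):
        tip_states = [tip_states]
    if not tip_states:
        raise ValueError("no characters supplied")
    patterns = _encode_patterns(tree, tip_states)
    if (patterns == MISSING).all():
        raise ValueError("no observed tip in any character")

    lo, hi = math.log(Q_MIN), math.log(Q_MAX)

    def nll(x: float) -> float:
        return -float(_loglik_many(tree, patterns, math.exp(x)).sum())

    res = minimize_scalar(
        nll, bounds=(lo, hi), method="bounded", options={"xatol": 1e-10}
    )
    q_hat = float(math.exp(res.x))
    ll = -float(res.fun)
    flat = abs(nll(lo) - nll(hi)) < 1e-12
    at_bound = flat or q_hat <= Q_MIN * (1 + 1e-4) or q_hat >= Q_MAX * (1 - 1e-4)
    # the bounded method can stall short of a boundary optimum; snap if better
    for xb, qb in ((lo, Q_MIN), (hi, Q_MAX)):
        llb = -nll(xb)
        if llb > ll + 1e-12:
            q_hat, ll, at_bound = qb, llb, True
    return MkFit(q=q_hat, log_likelihood=ll, converged=bool(res.success), at_bound=at_bound)


def _marginals_from_passes(arr: _TreeArrays, partials, messages, q: float):
    """Down (outside) pass; returns per-node (m, 2) posterior marginals."""
    stay, switch = _edge_probs(arr, q)
    m = partials[arr.root].shape[0]
    outside: list[np.ndarray] = [None] * len(arr.labels)  # type: ignore[list-item]
    outside[arr.root] = np.full((m, 2), 0.5)
    for i in reversed(range(len(arr.labels))):  # parents before children
        if arr.is_tip[i]:
            continue
        cs = arr.children[i]
        k = len(cs)
        # prefix/suffix products of child messages (excluding each child)
        prefix = [np.ones((m, 2))]
        for c in cs:
            prefix.append(prefix[-1] * messages[c])
        suffix: list = [None] * (k + 1)
        suffix[k] = np.ones((m, 2))
        for j in range(k - 1, -1, -1):
            suffix[j] = suffix[j + 1] * messages[cs[j]]
        for j, c in enumerate(cs):
            base = outside[i] * prefix[j] * suffix[j + 1]
            out = np.empty((m, 2))
            out[:, 0] = stay[c] * base[:, 0] + switch[c] * base[:, 1]
            out[:, 1] = switch[c] * base[:, 0] + stay[c] * base[:, 1]
            norm = out.sum(axis=1, keepdims=True)
            norm[norm == 0] = 1.0
            outside[c] = out / norm
    post = []
    for i in range(len(arr.labels)):
        joint = partials[i] * outside[i]
        norm = joint.sum(axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        post.append(joint / norm)
    return post


def marginal_ancestral_probs(
    tree: SpeciesTree,
    tip_states: dict,
    q: float,
    root_prior: str = "flat",
) -> dict[str, float]:
    """Exact marginal P(state = 1 | all tips) at every internal node."""
    _check_prior(root_prior)
    if q <= 0:
        raise ValueError(f"rate q must be positive, got {q}")
    arr = _arrays(tree)
    patterns = _encode_patterns(tree, [tip_states])
    partials, messages, _ls = _up_pass(arr, patterns, q)
    post = _marginals_from_passes(arr, partials, messages, q)
    return {
        arr.labels[i]: float(post[i][0, 1])
        for i in range(len(arr.labels))
        if not arr.is_tip[i]
    }


def assign_recruitment_node(
    tree: SpeciesTree,
    probs: dict[str, float],
    tip_states: dict,
    threshold: float = 0.6,
) -> str:
    """Most ancient internal node whose marginal P(1) exceeds the threshold.

    "Most ancient" is measured in edges from the root; ties are broken by
    larger descendant-tip count, then lexicographic label.  When no
    internal node passes, a single observed state-1 tip is returned
    (species-specific recruitment); otherwise ``"unassigned"``.
    """
    if not (0.5 < threshold < 1.0):
        raise ValueError(f"threshold must lie in (0.5, 1), got {threshold}")
    internal = set(tree.internal_labels)
    passing = [lab for lab, p in probs.items() if lab in internal and p > threshold]
    if passing:
        return min(
            passing,
            key=lambda lab: (
                tree.depth[lab],
                -tree.n_descendant_tips(lab),
                lab,
            ),
        )
    ones = [t for t in tree.tip_names if tip_states.get(t) == 1]
    if len(ones) == 1:
        return ones[0]
    return "unassigned"


@dataclass
class RecruitmentAssignment:
    """Per-HOG recruitment node plus the fit diagnostics behind it."""

    threshold: float
    node_of: dict[str, str] = field(default_factory=dict)
    q_hat: dict[str, float] = field(default_factory=dict)
    max_prob: dict[str, float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.node_of)

    def to_records(self, direction: str = "") -> list[dict]:
        return [
            {
                "hog_id": hog,
                "direction": direction,
                "q_hat": self.q_hat.get(hog, float("nan")),
                "assigned_node": node,
                "max_prob": self.max_prob.get(hog, float("nan")),
            }
            for hog, node in sorted(self.node_of.items())
        ]


def reconstruct_all(
    deogs,
    tree: SpeciesTree,
    threshold: float = 0.6,
    absent_as_missing: bool = False,
    presence: dict[str, frozenset] | None = None,
    pooled_q: float | None = None,
    rate_mode: str = "pooled",
) -> tuple[RecruitmentAssignment, dict[str, int]]:
    """Fit, reconstruct and assign a recruitment node for every DEOG row.

    Species with no DEG in a HOG are coded state 0 by default; with
    ``absent_as_missing`` (and a HOG -> present-species ``presence`` map)
    species lacking any gene in the HOG are coded missing instead.
    All-zero rows are skipped ("not a DEOG").

    ``rate_mode="pooled"`` (default) maximises one shared ER rate over the
    pooled likelihood of all non-empty characters before reconstructing —
    a single binary character carries almost no information about its own
    rate, and per-character ML degenerates on homoplastic patterns.
    ``rate_mode="per_hog"`` fits each character separately instead;
    ``pooled_q`` pins the shared rate explicitly.  Identical tip patterns
    share one reconstruction (the likelihood depends on the pattern only).

    Returns the assignment and a per-node count table covering every tree
    node plus ``"unassigned"``.
    """
    if rate_mode not in ("pooled", "per_hog"):
        raise ValueError(f"rate_mode must be pooled/per_hog, got {rate_mode!r}")
    if set(deogs.species) != set(tree.tip_names):
        raise ValueError(
            "DEOG matrix species do not match tree tips: "
            f"{sorted(deogs.species)} vs {sorted(tree.tip_names)}"
        )
    if absent_as_missing and presence is None:
        raise ValueError("absent_as_missing requires a presence map")
    col_of = {sp: j for j, sp in enumerate(deogs.species)}
    order = [col_of[name] for name in tree.tip_names]

    # collect the per-HOG tip patterns first (needed for the pooled fit)
    hog_patterns: list[tuple[str, tuple[int, ...]]] = []
    for i, hog in enumerate(deogs.hog_ids):
        row = deogs.cells[i]
        states = [int(row[j]) for j in order]
        if absent_as_missing:
            present = presence.get(hog, frozenset())  # type: ignore[union-attr]
            states = [
                s if name in present else MISSING
                for s, name in zip(states, tree.tip_names)
            ]
        if not any(s == 1 for s in states):
            continue  # not a DEOG
        hog_patterns.append((hog, tuple(states)))

    if pooled_q is None and rate_mode == "pooled" and hog_patterns:
        pooled_chars = [
            {
                name: (None if s == MISSING else s)
                for name, s in zip(tree.tip_names, states)
            }
            for _hog, states in hog_patterns
        ]
        pooled_q = fit_er_rate(tree, pooled_chars).q

    assignment = RecruitmentAssignment(threshold=threshold)
    counts: Counter[str] = Counter()
    cache: dict[tuple[int, ...], tuple[float, str, float]] = {}

    for hog, key in hog_patterns:
        if key not in cache:
            states = key
            tip_states = {
                name: (None if s == MISSING else s)
                for name, s in zip(tree.tip_names, states)
            }
            if pooled_q is not None:
                q = pooled_q
            else:
                q = fit_er_rate(tree, tip_states).q
            probs = marginal_ancestral_probs(tree, tip_states, q)
            node = assign_recruitment_node(tree, probs, tip_states, threshold)
            cache[key] = (q, node, max(probs.values()) if probs else float("nan"))
        q, node, max_prob = cache[key]
        assignment.node_of[hog] = node
        assignment.q_hat[hog] = q
        assignment.max_prob[hog] = max_prob
        counts[node] += 1

    table = {label: counts.get(label, 0) for label in tree.labels}
    table["unassigned"] = counts.get("unassigned", 0)
    return assignment, table
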