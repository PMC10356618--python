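"""Independent brute-force oracles used to validate the implementation.

These deliberately avoid the package's own code paths: transition matrices
come from scipy's matrix exponential, likelihoods and marginals from full
enumeration over ancestral state assignments, parsimony scores from
enumeration of all internal labelings, and Fisher p-values from direct
hypergeometric enumeration.
"""
from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.linalg import expm
from scipy.stats import hypergeom


def expm_transition(q: float, t: float) -> np.ndarray:
    Q = np.array([[-q, q], [q, -q]], dtype=float)
    return expm(Q * t)


def enum_loglik_and_marginals(tree, tip_states: dict, q: float):
    """Sum over all ancestral (and missing-tip) state assignments.

    Returns (log-likelihood, {internal label: P(state 1 | tips)}).
    """
    P = {
        n.label: expm_transition(q, n.branch_length)
        for n in tree.postorder
        if n.parent is not None
    }
    internal = [n for n in tree.postorder if not n.is_tip]
    tips = [n for n in tree.postorder if n.is_tip]
    observed = {
        t.label: tip_states[t.label]
        for t in tips
        if tip_states.get(t.label) in (0, 1)
    }
    free = [t for t in tips if t.label not in observed]
    total = 0.0
    marg = {n.label: 0.0 for n in internal}
    for assign in itertools.product((0, 1), repeat=len(internal) + len(free)):
        state = dict(observed)
        for node, s in zip(internal + free, assign):
            state[node.label] = s
        p = 0.5  # uniform root prior
        for n in tree.postorder:
            if n.parent is not None:
                p *= P[n.label][state[n.parent.label], state[n.label]]
        total += p
        for n in internal:
            if state[n.label] == 1:
                marg[n.label] += p
    return math.log(total), {k: v / total for k, v in marg.items()}


def enum_min_changes(tree, tip_states: dict) -> int:
    """Minimum number of state changes over all internal assignments."""
    internal = [n for n in tree.postorder if not n.is_tip]
    best = None
    for assign in itertools.product((0, 1), repeat=len(internal)):
        state = {n.label: s for n, s in zip(internal, assign)}
        for t in tree.postorder:
            if t.is_tip:
                state[t.label] = tip_states[t.label]
        changes = sum(
            1
            for n in tree.postorder
            if n.parent is not None and state[n.label] != state[n.parent.label]
        )
        best = changes if best is None else min(best, changes)
    return best


def enum_fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Minimum-likelihood two-sided Fisher p by hypergeometric enumeration."""
    N = a + b + c + d
    K = a + b  # row-1 total
    n = a + c  # col-1 total
    lo, hi = max(0, K + n - N), min(K, n)
    xs = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(xs, N, K, n)
    p_obs = hypergeom.pmf(a, N, K, n)
    return float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())


def welch_closed_form(x, y):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    nx, ny = len(x), len(y)
    sx, sy = x.var(ddof=1) / nx, y.var(ddof=1) / ny
    t = (x.mean() - y.mean()) / math.sqrt(sx + sy)
    df = (sx + sy) ** 2 / (sx**2 / (nx - 1) + sy**2 / (ny - 1))
    from scipy.stats import t as tdist

    p = 2 * tdist.sf(abs(t), df)
    return t, df, p
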