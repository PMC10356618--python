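"""Secreted-protein signature analysis for a trait gene module.

Compares proteins of a trait module (e.g. "symbiosome release") against
the rest of the whole-response proteome of the same species: length and
residue-composition Welch t-tests, signal-peptide enrichment, and the
enrichment of small cysteine-rich / proline-rich proteins in
species-specific orthogroups (the pattern of nodule cysteine-rich-like
peptide families).  Signal peptides are input flags from an external
predictor.  The "small" / "Cys-rich" / "Pro-rich" cutoffs carry no
canonical values and are configuration parameters reported alongside the
results.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import AnalysisConfig
from .enrichment import fisher_exact_2x2
from .tables import AA_ALPHABET, OrthogroupTable, ProteinSet

log = logging.getLogger(__name__)

__all__ = [
    "compute_protein_features",
    "welch_t_test",
    "release_signature_tests",
]

_AA_ORDER = sorted(AA_ALPHABET)


def compute_protein_features(
    proteins: ProteinSet,
    og: OrthogroupTable,
    release_set: set[str],
    species_specific: dict[str, set[str]],
) -> pd.DataFrame:
    """Per-protein feature table.

    Columns: ``length``, one ``prop_<residue>`` per letter of the 20+X
    alphabet (summing to 1 per protein), ``signal_peptide``,
    ``species_specific_hog`` (the protein's HOG contains genes of a
    single species in the full orthogroup table) and ``in_release_set``.
    """
    missing = [g for g in release_set if g not in proteins.records]
    if missing:
        raise ValueError(
            f"release genes without a sequence: {sorted(missing)[:10]}"
        )
    ss_hogs = set().union(*species_specific.values()) if species_specific else set()
    rows = []
    for gene, seq in proteins.records.items():
        n = len(seq)
        counts = {aa: 0 for aa in _AA_ORDER}
        for ch in seq:
            counts[ch] += 1
        hog = og.gene_to_hog.get(gene)
        row = {
            "gene_id": gene,
            "length": n,
            "signal_peptide": bool(proteins.signal_peptide.get(gene, False)),
            "species_specific_hog": hog in ss_hogs,
            "in_release_set": gene in release_set,
        }
        for aa in _AA_ORDER:
            row[f"prop_{aa}"] = counts[aa] / n
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene_id")


def welch_t_test(x, y) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test with Satterthwaite df.

    Returns ``(t, df, p_two_sided)``.  Requires at least two values per
    group and a nonzero pooled variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("welch_t_test needs >= 2 values per group")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx + vy == 0:
        # both groups constant: no test unless the means already agree,
        # in which case t = 0, p = 1 by continuity
        if x.mean() == y.mean():
            return 0.0, float(len(x) + len(y) - 2), 1.0
        raise ValueError("degenerate (zero) variance in both groups")
    res = sps.ttest_ind(x, y, equal_var=False)
    sx, sy = vx / len(x), vy / len(y)
    df = (sx + sy) ** 2 / (sx**2 / (len(x) - 1) + sy**2 / (len(y) - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def release_signature_tests(
    features: pd.DataFrame, config: AnalysisConfig
) -> dict:
    """Signature statistics of the release module vs the rest of the table.

    The background is the feature table minus the release rows (the whole
    response without the release-tagged genes).  Reports:

    * signal-peptide enrichment (Fisher odds ratio, two-sided p);
    * Welch t-tests on length, Cys proportion and Pro proportion, each
      with the ratio of group means;
    * enrichment of species-specific orthogroups among proteins that are
      small (length <= ``small_protein_max_len``) and Cys-rich
      (``prop_C >= cys_rich_min_prop``) or Pro-rich
      (``prop_P >= pro_rich_min_prop``), over the whole table.
    """
    rel = features[features["in_release_set"]]
    bg = features[~features["in_release_set"]]
    if len(rel) == 0 or len(bg) == 0:
        raise ValueError("both release and background groups must be non-empty")

    report: dict = {
        "n_release": int(len(rel)),
        "n_background": int(len(bg)),
        "small_protein_max_len": config.small_protein_max_len,
        "cys_rich_min_prop": config.cys_rich_min_prop,
        "pro_rich_min_prop": config.pro_rich_min_prop,
    }

    a = int(rel["signal_peptide"].sum())
    b = int(len(rel) - a)
    c = int(bg["signal_peptide"].sum())
    d = int(len(bg) - c)
    odds, p = fisher_exact_2x2(a, b, c, d)
    report["signalp_odds_ratio"] = odds
    report["signalp_p"] = p

    for key, col in (("length", "length"), ("cys_prop", "prop_C"), ("pro_prop", "prop_P")):
        xs, ys = rel[col].to_numpy(float), bg[col].to_numpy(float)
        try:
            t, df, pt = welch_t_test(xs, ys)
        except ValueError:
            t = df = pt = float("nan")
        mr, mb = float(xs.mean()), float(ys.mean())
        report[f"mean_release_{key}"] = mr
        report[f"mean_background_{key}"] = mb
        report[f"ratio_mean_{key}"] = mr / mb if mb else float("inf")
        report[f"t_{key}"] = t
        report[f"df_{key}"] = df
        report[f"p_{key}"] = pt

    small = features["length"] <= config.small_protein_max_len
    ss = features["species_specific_hog"]
    for key, rich in (
        ("small_cys", features["prop_C"] >= config.cys_rich_min_prop),
        ("small_pro", features["prop_P"] >= config.pro_rich_min_prop),
    ):
        target = small & rich
        a = int((target & ss).sum())
        b = int((target & ~ss).sum())
        c = int((~target & ss).sum())
        d = int((~target & ~ss).sum())
        try:
            odds, p = fisher_exact_2x2(a, b, c, d)
        except ValueError:
            odds, p = float("nan"), float("nan")
        report[f"ss_{key}_a"] = a
        report[f"ss_{key}_b"] = b
        report[f"ss_{key}_odds_ratio"] = odds
        report[f"ss_{key}_p"] = p
    return report
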