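"""End-to-end analysis pipeline.

Stages run in a fixed order — DEG selection, DEOG coding, Mk ancestral
reconstruction and recruitment assignment, parsimony origins, the
stratified permutation null, trait enrichment, protein signatures — all
driven by one YAML configuration and one global seed.  Per-stage child
seeds are derived by hashing the stage name with the global seed, so
adding a stage never perturbs earlier random streams.  Intermediates are
plain TSVs with a provenance header comment (tool version + seed), and a
rerun with the same config and seed is byte-identical.
"""
from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .config import AnalysisConfig
from .deg_selection import select_degs, union_contrasts
from .deog import classify_species_specific, code_deogs
from .enrichment import enrichment_frame, node_enrichment, trait_module_filter
from .mk import RecruitmentAssignment, reconstruct_all
from .null_model import compare_to_null, null_node_counts
from .parsimony import build_origin_map
from .protein_features import compute_protein_features, release_signature_tests
from .tables import (
    DEGSet,
    read_deg_stats,
    read_fasta_proteins,
    read_gene_list,
    read_orthogroups,
)
from .trees import read_newick_tree

import yaml

log = logging.getLogger(__name__)

__all__ = ["PipelineReport", "run_pipeline", "stage_seed"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage child seed (stable across platforms)."""
    digest = hashlib.blake2s(
        f"{stage}:{global_seed}".encode(), digest_size=4
    ).digest()
    return int.from_bytes(digest, "big") % (2**31)


@dataclass
class PipelineReport:
    """All result tables of one pipeline run, keyed by output-file stem."""

    seed: int
    outdir: Path
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)


def _write(frame: pd.DataFrame, path: Path, seed: int, index: bool = False) -> None:
    header = f"# phylorecruit {__version__} seed={seed}\n"
    body = frame.to_csv(sep="\t", index=index, lineterminator="\n", float_format="%.10g")
    path.write_text(header + body)


def _load_config(config_path) -> tuple[dict, Path]:
    config_path = Path(config_path)
    if not config_path.exists():
        raise FileNotFoundError(f"missing input: config ({config_path})")
    raw = yaml.safe_load(config_path.read_text()) or {}
    return raw, config_path.parent


def run_pipeline(config_path, outdir, seed: int | None = None) -> PipelineReport:
    """Run the full analysis described by a YAML config.

    Input paths in the config are resolved relative to the config file.
    All inputs are checked before any computation; a failing stage aborts
    with a stage-named error.
    """
    raw, base = _load_config(config_path)
    seed = int(raw.get("seed", 0)) if seed is None else int(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    cfg = AnalysisConfig(
        fdr_max=float(raw.get("fdr_max", 0.05)),
        logfc_min=raw.get("logfc_min", 1.0),
        recruit_threshold=float(raw.get("recruit_threshold", 0.6)),
        n_null_reps=int(raw.get("n_null_reps", 1000)),
        rng_seed=seed,
        direction=str(raw.get("direction", "up")),
        small_protein_max_len=int(raw.get("small_protein_max_len", 150)),
        cys_rich_min_prop=float(raw.get("cys_rich_min_prop", 0.06)),
        pro_rich_min_prop=float(raw.get("pro_rich_min_prop", 0.10)),
    )

    # ---- input validation before any computation -----------------------
    for key in ("tree", "orthogroups", "deg_stats"):
        if key not in raw:
            raise FileNotFoundError(f"missing input: {key}")
    paths = {"tree": base / raw["tree"], "orthogroups": base / raw["orthogroups"]}
    deg_paths = {sp: base / p for sp, p in raw["deg_stats"].items()}
    for key, p in {**paths, **deg_paths}.items():
        if not Path(p).exists():
            raise FileNotFoundError(f"missing input: {key} ({p})")
    optional = {}
    for key in ("proteins", "signal_peptides"):
        if key in raw:
            p = base / raw[key]
            if not p.exists():
                raise FileNotFoundError(f"missing input: {key} ({p})")
            optional[key] = p
    trait_specs = raw.get("trait_sets", [])
    for spec in trait_specs:
        p = base / spec["path"]
        if not p.exists():
            raise FileNotFoundError(f"missing input: trait {spec['name']} ({p})")

    report = PipelineReport(seed=seed, outdir=outdir)

    def _stage(name):
        log.info("stage: %s", name)

    # ---- inputs ---------------------------------------------------------
    _stage("read inputs")
    tree = read_newick_tree(paths["tree"])
    og = read_orthogroups(paths["orthogroups"])
    missing_tips = set(tree.tip_names) - set(og.species)
    if missing_tips:
        raise ValueError(
            f"inconsistent species sets: tree tips {sorted(missing_tips)} "
            f"absent from {paths['orthogroups']}"
        )
    unknown_deg = set(deg_paths) - set(tree.tip_names)
    if unknown_deg:
        raise ValueError(
            f"inconsistent species sets: DEG stats for {sorted(unknown_deg)} "
            "but no matching tree tip"
        )
    stats = {sp: read_deg_stats(p, sp) for sp, p in sorted(deg_paths.items())}

    directions = ["up", "down"] if cfg.direction == "both" else [cfg.direction]
    origin = build_origin_map(og.restrict(tree.tip_names), tree)
    origin_frame = pd.DataFrame(
        sorted(origin.items()), columns=["hog_id", "origin_node"]
    )
    report.tables["origin_map"] = origin_frame
    _write(origin_frame, outdir / "origin_map.tsv", seed)

    whole_response: dict[str, dict[str, DEGSet]] = {}
    assignments: dict[str, RecruitmentAssignment] = {}

    for direction in directions:
        # ---- DEG selection ----------------------------------------------
        _stage(f"deg_selection[{direction}]")
        degs: dict[str, DEGSet] = {}
        for sp, table in stats.items():
            per_contrast = [
                select_degs(
                    type(table)(species=sp, frame=grp),
                    cfg.fdr_max,
                    cfg.logfc_for(sp),
                    direction,
                )
                for _, grp in table.frame.groupby("contrast", sort=True)
            ]
            degs[sp] = union_contrasts(per_contrast) if per_contrast else DEGSet(
                species=sp, direction=direction, gene_ids=frozenset()
            )
        whole_response[direction] = degs
        deg_frame = pd.DataFrame(
            [
                {"species": sp, "gene_id": g}
                for sp in sorted(degs)
                for g in sorted(degs[sp].gene_ids)
            ],
            columns=["species", "gene_id"],
        )
        report.tables[f"degs_{direction}"] = deg_frame
        _write(deg_frame, outdir / f"degs_{direction}.tsv", seed)

        # ---- DEOG coding ------------------------------------------------
        _stage(f"deog_coding[{direction}]")
        matrix = code_deogs(og, degs, list(tree.tip_names))
        report.tables[f"deog_matrix_{direction}"] = matrix.to_frame()
        _write(matrix.to_frame(), outdir / f"deog_matrix_{direction}.tsv", seed, index=True)

        # ---- Mk reconstruction ------------------------------------------
        _stage(f"mk_asr[{direction}]")
        assignment, node_counts = reconstruct_all(
            matrix, tree, cfg.recruit_threshold
        )
        assignments[direction] = assignment
        assign_frame = pd.DataFrame(
            assignment.to_records(direction),
            columns=["hog_id", "direction", "q_hat", "assigned_node", "max_prob"],
        )
        report.tables[f"assignments_{direction}"] = assign_frame
        _write(assign_frame, outdir / f"assignments_{direction}.tsv", seed)
        counts_frame = pd.DataFrame(
            sorted(node_counts.items()), columns=["node", "count"]
        )
        report.tables[f"node_counts_{direction}"] = counts_frame
        _write(counts_frame, outdir / f"node_counts_{direction}.tsv", seed)

        # ---- permutation null -------------------------------------------
        _stage(f"null_model[{direction}]")
        null = null_node_counts(
            og.restrict(tree.tip_names),
            tree,
            origin,
            degs,
            n_reps=cfg.n_null_reps,
            rng_seed=stage_seed(seed, f"null_{direction}"),
        )
        comparison = compare_to_null(node_counts, null).reset_index()
        report.tables[f"null_comparison_{direction}"] = comparison
        _write(comparison, outdir / f"null_comparison_{direction}.tsv", seed)

        # ---- trait enrichment -------------------------------------------
        for spec in trait_specs:
            name, sp = spec["name"], spec["species"]
            _stage(f"enrichment[{name},{direction}]")
            trait = read_gene_list(base / spec["path"], name, sp)
            if sp not in degs:
                raise ValueError(f"trait {name!r}: no DEG stats for {sp!r}")
            module = trait_module_filter(trait, degs[sp])
            trait_hogs = {
                og.gene_to_hog[g] for g in module.gene_ids if g in og.gene_to_hog
            }
            trait_assign = RecruitmentAssignment(
                threshold=cfg.recruit_threshold,
                node_of={
                    h: assignment.node_of[h]
                    for h in trait_hogs
                    if h in assignment.node_of
                },
            )
            if not trait_assign.node_of:
                log.warning(
                    "trait %r has no DEOG with a recruitment node (%s); skipped",
                    name,
                    direction,
                )
                continue
            rows = node_enrichment(
                trait_assign,
                assignment,
                nodes=tree.labels + ["unassigned"],
                tree=tree,
            )
            frame = enrichment_frame(rows)
            report.tables[f"enrichment_{name}_{direction}"] = frame
            _write(frame, outdir / f"enrichment_{name}_{direction}.tsv", seed)

    # ---- protein signatures --------------------------------------------
    if "proteins" in optional and trait_specs:
        _stage("protein_features")
        spec = trait_specs[0]
        sp = spec["species"]
        proteins = read_fasta_proteins(
            optional["proteins"], optional.get("signal_peptides")
        )
        release = read_gene_list(base / spec["path"], spec["name"], sp)
        # the supplied FASTA defines the analysis universe (the species'
        # whole-response proteome); background = universe minus release
        universe = set(proteins.records)
        ss = classify_species_specific(og)
        features = compute_protein_features(
            proteins, og, set(release.gene_ids) & universe, ss
        )
        report.tables["protein_features"] = features.reset_index()
        _write(features.reset_index(), outdir / "protein_features.tsv", seed)
        prot_report = release_signature_tests(features, cfg)
        prot_frame = pd.DataFrame(
            sorted(prot_report.items()), columns=["statistic", "value"]
        )
        report.tables["protein_report"] = prot_frame
        _write(prot_frame, outdir / "protein_report.tsv", seed)

    return report
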