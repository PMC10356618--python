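"""Tabular data model: orthogroups, DE statistics, proteins, trait gene sets.

All tables are tab-separated UTF-8; gene identifiers are opaque strings and
are never parsed for species prefixes.  Readers validate the invariants the
downstream analyses rely on (unique gene-to-orthogroup membership, FDR in
[0, 1], a clean amino-acid alphabet) and fail loudly with the offending
identifiers or row numbers.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

__all__ = [
    "OrthogroupTable",
    "read_orthogroups",
    "DEStatsTable",
    "read_deg_stats",
    "write_deg_stats",
    "DEGSet",
    "ProteinSet",
    "read_fasta_proteins",
    "read_signal_peptide_flags",
    "TraitGeneSet",
    "read_gene_list",
]

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")


# ---------------------------------------------------------------------------
# orthogroups


class OrthogroupTable:
    """Hierarchical orthogroup (HOG) table: HOG x species -> gene IDs.

    The species set of the table may be a superset of the analysis tree's
    tips (the orthogroup inference typically spans more genomes than the
    expression analysis).  Every gene ID must occur in exactly one HOG.
    """

    def __init__(
        self,
        hog_ids: list[str],
        species: list[str],
        genes: dict[tuple[str, str], tuple[str, ...]],
    ):
        self.hog_ids = list(hog_ids)
        self.species = list(species)
        self._genes = genes
        self._validate()

    def _validate(self) -> None:
        seen: dict[str, str] = {}
        dupes: set[str] = set()
        for (hog, _sp), ids in self._genes.items():
            for g in ids:
                if g in seen and seen[g] != hog:
                    dupes.add(g)
                seen[g] = hog
        if dupes:
            raise ValueError(
                f"gene IDs present in more than one HOG: {sorted(dupes)[:10]}"
                + ("..." if len(dupes) > 10 else "")
            )
        self._gene_to_hog = seen

    # -- queries ----------------------------------------------------------

    @property
    def gene_to_hog(self) -> dict[str, str]:
        """Mapping gene ID -> HOG ID (each gene belongs to exactly one HOG)."""
        return self._gene_to_hog

    def genes(self, hog: str, species: str) -> tuple[str, ...]:
        return self._genes.get((hog, species), ())

    def presence(self, hog: str) -> frozenset[str]:
        """Species (over the full table) with at least one gene in the HOG."""
        return frozenset(s for s in self.species if self._genes.get((hog, s)))

    def species_genes(self, species: str) -> list[str]:
        """All genes of one species, in HOG order (deterministic)."""
        out: list[str] = []
        for hog in self.hog_ids:
            out.extend(self._genes.get((hog, species), ()))
        return out

    def species_gene_count(self, species: str) -> int:
        return sum(len(self._genes.get((h, species), ())) for h in self.hog_ids)

    @property
    def n_hogs(self) -> int:
        return len(self.hog_ids)

    def restrict(self, species: list[str]) -> "OrthogroupTable":
        missing = set(species) - set(self.species)
        if missing:
            raise ValueError(f"species not in orthogroup table: {sorted(missing)}")
        genes = {
            (h, s): v for (h, s), v in self._genes.items() if s in set(species)
        }
        return OrthogroupTable(self.hog_ids, list(species), genes)

    def extended(
        self, new_rows: dict[str, dict[str, tuple[str, ...]]]
    ) -> "OrthogroupTable":
        """Return a copy with extra HOG rows appended (used by simulators)."""
        genes = dict(self._genes)
        hog_ids = list(self.hog_ids)
        for hog, per_sp in new_rows.items():
            if hog in set(self.hog_ids):
                raise ValueError(f"HOG id already present: {hog}")
            hog_ids.append(hog)
            for sp, ids in per_sp.items():
                if sp not in self.species:
                    raise ValueError(f"unknown species {sp!r}")
                genes[(hog, sp)] = tuple(ids)
        return OrthogroupTable(hog_ids, self.species, genes)

    # -- serialisation ----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        data = {"HOG": self.hog_ids}
        for sp in self.species:
            data[sp] = [
                ", ".join(self._genes.get((h, sp), ())) for h in self.hog_ids
            ]
        return pd.DataFrame(data)

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_orthogroups(path, species: list[str] | None = None) -> OrthogroupTable:
    """Read an N0-style hierarchical orthogroup TSV.

    First column holds HOG identifiers; every further column is a species
    whose cells contain comma-separated gene IDs (possibly empty).  When
    ``species`` is given the table is restricted to those columns; a
    requested species missing from the header is an error.
    """
    frame = pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False, comment="#"
    )
    if frame.shape[1] < 2:
        raise ValueError(f"orthogroup table needs >=2 columns: {path}")
    hog_col = frame.columns[0]
    available = list(frame.columns[1:])
    if species is None:
        species = available
    else:
        missing = set(species) - set(available)
        if missing:
            raise ValueError(
                f"requested species missing from orthogroup header: {sorted(missing)}"
            )
    hog_ids = frame[hog_col].tolist()
    if len(set(hog_ids)) != len(hog_ids):
        raise ValueError("duplicate HOG identifiers")
    genes: dict[tuple[str, str], tuple[str, ...]] = {}
    for sp in species:
        col = frame[sp].tolist()
        for hog, cell in zip(hog_ids, col):
            ids = tuple(g.strip() for g in cell.split(",") if g.strip())
            if ids:
                genes[(hog, sp)] = ids
    return OrthogroupTable(hog_ids, list(species), genes)


# ---------------------------------------------------------------------------
# differential-expression statistics


@dataclass
class DEStatsTable:
    """Per-species differential-expression statistics.

    ``frame`` columns: gene_id, contrast, logFC (log2 units), FDR in [0, 1];
    one row per (gene, contrast) pair.
    """

    species: str
    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["gene_id", "contrast", "logFC", "FDR"]
        missing = [c for c in required if c not in self.frame.columns]
        if missing:
            raise ValueError(f"DE stats missing columns: {missing}")
        fdr = self.frame["FDR"]
        bad = self.frame[(fdr < 0) | (fdr > 1) | fdr.isna()]
        if len(bad):
            raise ValueError(
                f"FDR outside [0, 1] at rows {list(bad.index[:5])} "
                f"(species {self.species})"
            )
        dup = self.frame.duplicated(subset=["gene_id", "contrast"])
        if dup.any():
            pairs = self.frame.loc[dup, ["gene_id", "contrast"]].head(5)
            raise ValueError(
                f"duplicate (gene, contrast) pairs: {pairs.values.tolist()}"
            )

    def __len__(self) -> int:
        return len(self.frame)


def read_deg_stats(path, species: str) -> DEStatsTable:
    """Read a TSV of per-gene DE statistics for one species."""
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, comment="#")
    required = ["gene_id", "contrast", "logFC", "FDR"]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    frame = raw[required].copy()
    for col in ("logFC", "FDR"):
        vals = pd.to_numeric(frame[col], errors="coerce")
        bad = vals.isna() & (frame[col].astype(str).str.strip() != "")
        if len(frame) and bad.any():
            rows = [int(i) + 2 for i in frame.index[bad][:5]]  # 1-based + header
            raise ValueError(f"{path}: non-numeric {col} at file rows {rows}")
        if len(frame) and (frame[col].astype(str).str.strip() == "").any():
            rows = [
                int(i) + 2
                for i in frame.index[frame[col].astype(str).str.strip() == ""][:5]
            ]
            raise ValueError(f"{path}: empty {col} at file rows {rows}")
        frame[col] = vals
    return DEStatsTable(species=species, frame=frame.reset_index(drop=True))


def write_deg_stats(table: DEStatsTable, path) -> None:
    table.frame.to_csv(path, sep="\t", index=False, lineterminator="\n")


@dataclass(frozen=True)
class DEGSet:
    """A per-species set of differentially expressed genes, one direction."""

    species: str
    direction: str  # "up" | "down"
    gene_ids: frozenset[str]

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ValueError(f"direction must be up/down, got {self.direction!r}")

    def __len__(self) -> int:
        return len(self.gene_ids)


# ---------------------------------------------------------------------------
# proteins


@dataclass
class ProteinSet:
    """Amino-acid sequences plus externally predicted signal-peptide flags.

    Sequences are stored after stripping one trailing stop symbol ``*``;
    the alphabet is restricted to the 20 standard residues plus X.  Signal
    peptides are input flags — running a predictor is out of scope.
    """

    records: dict[str, str] = field(default_factory=dict)
    signal_peptide: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cleaned = {}
        for gene, seq in self.records.items():
            s = seq.rstrip("*").upper()
            if not s:
                raise ValueError(f"empty sequence for {gene!r}")
            bad = set(s) - AA_ALPHABET
            if bad:
                raise ValueError(
                    f"invalid residues {sorted(bad)} in sequence of {gene!r}"
                )
            cleaned[gene] = s
        self.records = cleaned

    def __len__(self) -> int:
        return len(self.records)

    def write_fasta(self, path) -> None:
        recs = [
            SeqRecord(Seq(seq), id=gene, description="")
            for gene, seq in self.records.items()
        ]
        with open(path, "w") as fh:
            SeqIO.write(recs, fh, "fasta")

    def write_signal_flags(self, path) -> None:
        frame = pd.DataFrame(
            {
                "gene_id": list(self.records),
                "signal_peptide": [
                    int(self.signal_peptide.get(g, False)) for g in self.records
                ],
            }
        )
        frame.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_fasta_proteins(fasta_path, signalp_path=None) -> ProteinSet:
    records = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        records[rec.id] = str(rec.seq)
    flags = read_signal_peptide_flags(signalp_path) if signalp_path else {}
    return ProteinSet(records=records, signal_peptide=flags)


def read_signal_peptide_flags(path) -> dict[str, bool]:
    """TSV with columns gene_id, signal_peptide (0/1 or true/false)."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, comment="#")
    if not {"gene_id", "signal_peptide"} <= set(frame.columns):
        raise ValueError(f"{path}: need columns gene_id, signal_peptide")
    truthy = {"1", "true", "yes"}
    falsy = {"0", "false", "no"}
    flags = {}
    for _, row in frame.iterrows():
        val = str(row["signal_peptide"]).strip().lower()
        if val in truthy:
            flags[row["gene_id"]] = True
        elif val in falsy:
            flags[row["gene_id"]] = False
        else:
            raise ValueError(f"{path}: unparseable flag {val!r}")
    return flags


# ---------------------------------------------------------------------------
# trait gene sets


@dataclass(frozen=True)
class TraitGeneSet:
    """A named, single-species gene module (e.g. a symbiotic-stage response)."""

    name: str
    species: str
    gene_ids: frozenset[str]

    def __len__(self) -> int:
        return len(self.gene_ids)


def read_gene_list(path, name: str, species: str) -> TraitGeneSet:
    """Plain text, one gene ID per line; blank lines and # comments skipped."""
    ids = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            ids.add(line)
    return TraitGeneSet(name=name, species=species, gene_ids=frozenset(ids))
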