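"""Analysis configuration.

The thresholds that govern the whole pipeline live here: the FDR and
log2-fold-change cutoffs that define a differentially expressed gene, the
marginal-probability cutoff above which an internal node counts as
"recruited", the number of permutation replicates for the null, and the
protein-feature cutoffs ("small", cysteine-rich, proline-rich) used by the
secreted-protein signature analysis.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = ["AnalysisConfig"]


@dataclass
class AnalysisConfig:
    """Tunable analysis parameters with validated defaults.

    ``logfc_min`` may be a single float applied to every species or a
    mapping species -> threshold (sequencing-depth heterogeneity between
    species motivates per-species thresholds chosen for comparable DEG
    counts).
    """

    fdr_max: float = 0.05
    logfc_min: float | dict[str, float] = 1.0
    recruit_threshold: float = 0.6
    n_null_reps: int = 1000
    rng_seed: int = 0
    direction: str = "up"  # "up" | "down"
    small_protein_max_len: int = 150
    cys_rich_min_prop: float = 0.06
    pro_rich_min_prop: float = 0.10

    def __post_init__(self) -> None:
        if not (0.5 < self.recruit_threshold < 1.0):
            raise ValueError(
                f"recruit_threshold must lie in (0.5, 1), got {self.recruit_threshold}"
            )
        if self.n_null_reps < 1:
            raise ValueError("n_null_reps must be >= 1")
        if not (0 < self.fdr_max <= 1):
            raise ValueError("fdr_max must lie in (0, 1]")
        if self.direction not in ("up", "down"):
            raise ValueError(f"direction must be up/down, got {self.direction!r}")

    def logfc_for(self, species: str) -> float:
        if isinstance(self.logfc_min, dict):
            if species not in self.logfc_min:
                raise KeyError(f"no logfc_min for species {species!r}")
            return float(self.logfc_min[species])
        return float(self.logfc_min)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in data.items() if k in known})

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))
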