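"""Analysis thresholds, collected so every cutoff appears exactly once.

Defaults follow the depot-atlas study design this package implements:
expression filter (>= 20% of a tissue's samples above 0.1 TPM and median
TPM > 0.5), tissue-specificity calls at a median fold change above 5 with
per-contrast FDR below 0.01, depot differential expression at |log2FC| > 3
and FDR < 0.01, over-representation at FDR < 0.05, sample selection at
RIN >= 6.0 and at least 30 donors per tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

#: canonical tissue labels for the two adipose depots
SUBCUTANEOUS = "Adipose - Subcutaneous"
OMENTAL = "Adipose - Visceral (Omentum)"

#: tissue labels excluded up front: mammary (high fat content) and
#: cultured / transformed non-tissue samples
DEFAULT_EXCLUDED_TISSUES = (
    "Breast - Mammary Tissue",
    "Cells - Cultured fibroblasts",
    "Cells - Transformed fibroblasts",
    "Cells - EBV-transformed lymphocytes",
)


@dataclass
class AnalysisConfig:
    """Thresholds governing every pipeline stage.

    All inequalities on fold changes and the expression-filter median are
    strict ("more than"); the RIN cutoff and the filter fraction are
    inclusive.  ``deg_lfc_comparator`` may be set to ``"ge"`` to make the
    DEG fold-change cutoff inclusive.
    """

    fold_threshold: float = 5.0          # median fold, depot vs each other tissue
    specificity_fdr: float = 0.01        # per-contrast BH cutoff
    filter_fraction: float = 0.20        # fraction of samples above the TPM floor
    filter_tpm_floor: float = 0.1
    filter_median_floor: float = 0.5     # strict: median must exceed this
    min_rin: float = 6.0                 # inclusive
    min_donors: int = 30                 # tissues below this are dropped whole
    deg_lfc_threshold: float = 3.0       # |log2FC| cutoff for depot DEGs
    deg_lfc_comparator: str = "gt"       # "gt" (strict) or "ge"
    deg_fdr: float = 0.01
    ora_fdr: float = 0.05
    pseudocount: float = 1.0             # epsilon for log2 transforms and fold means
    subcutaneous_label: str = SUBCUTANEOUS
    omental_label: str = OMENTAL
    excluded_tissues: tuple[str, ...] = DEFAULT_EXCLUDED_TISSUES

    def __post_init__(self) -> None:
        for name in (
            "fold_threshold", "specificity_fdr", "filter_fraction", "filter_tpm_floor",
            "filter_median_floor", "min_rin", "deg_lfc_threshold", "deg_fdr",
            "ora_fdr", "pseudocount",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 < self.filter_fraction < 1:
            raise ValueError("filter_fraction must lie in (0, 1)")
        if self.deg_lfc_comparator not in ("gt", "ge"):
            raise ValueError("deg_lfc_comparator must be 'gt' or 'ge'")

    @property
    def depot_labels(self) -> tuple[str, str]:
        return (self.subcutaneous_label, self.omental_label)

    def lfc_passes(self, log2fc: float) -> bool:
        """Apply the configured |log2FC| comparator."""
        mag = abs(log2fc)
        if self.deg_lfc_comparator == "gt":
            return mag > self.deg_lfc_threshold
        return mag >= self.deg_lfc_threshold

    def to_dict(self) -> dict:
        d = asdict(self)
        d["excluded_tissues"] = list(self.excluded_tissues)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh) or {}
        if "excluded_tissues" in raw:
            raw["excluded_tissues"] = tuple(raw["excluded_tissues"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        with path.open("w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
        return path
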