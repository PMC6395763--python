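"""Depot differential expression: subcutaneous vs omental adipose tissue.

Read counts are depth-normalized with median-of-ratios size factors, tested
per gene with a Welch t-test on log2-transformed normalized counts, and
thresholded at |log2FC| > 3 with BH FDR < 0.01 (both configurable).  Fold
change is oriented subcutaneous over omental.  DEGs are broken down by
Ensembl biotype into five groups: protein-coding, lincRNA, pseudogene,
antisense, and other.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from ._stats import bh_adjust, welch_rows
from .config import AnalysisConfig
from .io_formats import CountMatrix

__all__ = [
    "estimate_size_factors",
    "depot_de_test",
    "classify_degs",
    "biotype_group",
    "biotype_breakdown",
    "BIOTYPE_GROUPS",
]

logger = logging.getLogger(__name__)

BIOTYPE_GROUPS = ("protein_coding", "lincRNA", "pseudogene", "antisense", "other")
DIRECTIONS = ("up_subcutaneous", "up_omental")


def estimate_size_factors(counts: CountMatrix) -> pd.Series:
    """Median-of-ratios sequencing-depth factors.

    The reference expression of a gene is the geometric mean of its counts
    across samples; only genes with strictly positive counts in every sample
    enter.  A sample's size factor is the median of its count/reference
    ratios over those genes.
    """
    mat = counts.values.to_numpy(dtype=float)
    all_positive = (mat > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError("no gene has positive counts in every sample")
    pos = mat[all_positive]
    log_ref = np.log(pos).mean(axis=1)
    ratios = np.log(pos) - log_ref[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    return pd.Series(factors, index=counts.values.columns, name="size_factor")


def depot_de_test(counts: CountMatrix, config: AnalysisConfig) -> pd.DataFrame:
    """Per-gene log2 fold change (subcutaneous/omental) and Welch p-value.

    Counts are divided by their size factor; the fold change is
    log2((mean_sub + eps) / (mean_om + eps)) on normalized counts; the test
    compares log2(normalized + eps) between depots.
    """
    labels = set(counts.tissue_of.values())
    allowed = {config.subcutaneous_label, config.omental_label}
    if not labels:
        raise ValueError("count matrix has no tissue labels")
    if labels - allowed:
        raise ValueError(f"unexpected depot labels: {sorted(labels - allowed)}")
    sub = counts.samples_of_tissue(config.subcutaneous_label)
    om = counts.samples_of_tissue(config.omental_label)
    if len(sub) < 2 or len(om) < 2:
        raise ValueError("each depot needs at least 2 samples")
    sf = estimate_size_factors(counts)
    norm = counts.values.to_numpy(dtype=float) / sf.to_numpy()[None, :]
    idx = {s: i for i, s in enumerate(counts.values.columns)}
    a = norm[:, [idx[s] for s in sub]]
    b = norm[:, [idx[s] for s in om]]
    eps = config.pseudocount
    log2fc = np.log2((a.mean(axis=1) + eps) / (b.mean(axis=1) + eps))
    p = welch_rows(np.log2(a + eps), np.log2(b + eps))
    return pd.DataFrame(
        {"gene_id": counts.gene_ids, "log2fc": log2fc, "p": p}
    )


def classify_degs(records: pd.DataFrame, config: AnalysisConfig) -> pd.DataFrame:
    """BH-adjust across all genes and keep records passing both DEG criteria.

    Emitted records satisfy |log2fc| beyond the configured threshold
    (strict by default) and q below ``deg_fdr``; direction follows the sign
    of the fold change.
    """
    if "p" not in records.columns:
        raise ValueError("records must carry a 'p' column")
    out = records.copy()
    out["q"] = bh_adjust(out["p"].to_numpy())
    lfc_ok = out["log2fc"].map(config.lfc_passes)
    degs = out[lfc_ok & (out["q"] < config.deg_fdr)].copy()
    degs["direction"] = np.where(degs["log2fc"] > 0, "up_subcutaneous", "up_omental")
    return degs.sort_values("gene_id", kind="mergesort").reset_index(drop=True)


def biotype_group(biotype: str) -> str:
    """Collapse an Ensembl biotype into one of the five summary groups."""
    if biotype == "protein_coding":
        return "protein_coding"
    if biotype == "lincRNA":
        return "lincRNA"
    if "pseudogene" in biotype:
        return "pseudogene"
    if biotype == "antisense":
        return "antisense"
    return "other"


def biotype_breakdown(degs: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Direction x biotype-group count table (2 rows x 5 columns).

    DEG genes absent from the annotation fall into "other" with a warning.
    """
    biotypes = annotation.set_index("gene_id")["biotype"]
    table = pd.DataFrame(0, index=list(DIRECTIONS), columns=list(BIOTYPE_GROUPS))
    missing = 0
    for _, row in degs.iterrows():
        bt = biotypes.get(row["gene_id"])
        if bt is None:
            missing += 1
            group = "other"
        else:
            group = biotype_group(str(bt))
        table.loc[row["direction"], group] += 1
    if missing:
        logger.warning("%d DEG genes missing from annotation; grouped as 'other'", missing)
    table.index.name = "direction"
    return table
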