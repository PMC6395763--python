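"""Depot-resolved expression map of the HOX developmental gene clusters.

Humans carry 39 HOX transcription-factor genes in four chromosomal clusters
(A-D) with paralog numbers 1-13.  The map reports, for each gene, the
log2(median TPM + 1) expression in subcutaneous and omental adipose tissue
together with a differential-expression flag from the depot comparison at
FDR < 0.01 — deliberately without any fold-change threshold, so subtle but
consistent depot shifts in these low-expressed regulators are visible.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .io_formats import ExpressionMatrix

__all__ = ["HOX_CLUSTERS", "hox_annotation", "build_hox_map", "export_heatmap"]

#: paralog numbers present in each human HOX cluster (39 genes total)
HOX_CLUSTERS: dict[str, tuple[int, ...]] = {
    "A": (1, 2, 3, 4, 5, 6, 7, 9, 10, 11, 13),
    "B": (1, 2, 3, 4, 5, 6, 7, 8, 9, 13),
    "C": (4, 5, 6, 8, 9, 10, 11, 12, 13),
    "D": (1, 3, 4, 8, 9, 10, 11, 12, 13),
}


def hox_annotation() -> dict[str, tuple[str, int]]:
    """Symbol -> (cluster, paralog) for the 39 human HOX genes."""
    return {
        f"HOX{cluster}{paralog}": (cluster, paralog)
        for cluster, paralogs in HOX_CLUSTERS.items()
        for paralog in paralogs
    }


def build_hox_map(
    matrix: ExpressionMatrix,
    annotation: dict[str, tuple[str, int]],
    de_records: pd.DataFrame,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Build the cluster-ordered depot expression map.

    ``matrix`` must carry the two depot tissue labels; ``annotation`` maps
    gene keys (ids or symbols present in the matrix index) to (cluster,
    paralog); ``de_records`` is a frame with gene_id and q columns from the
    depot test adjusted across all genes (no fold-change threshold).  Genes
    absent from the matrix are emitted with missing-value markers.
    """
    config = config or AnalysisConfig()
    for gene, (cluster, paralog) in annotation.items():
        if cluster not in HOX_CLUSTERS:
            raise ValueError(f"{gene}: cluster {cluster!r} outside A-D")
        if not 1 <= int(paralog) <= 13:
            raise ValueError(f"{gene}: paralog {paralog} outside 1-13")
    sub = matrix.samples_of_tissue(config.subcutaneous_label)
    om = matrix.samples_of_tissue(config.omental_label)
    qmap = de_records.set_index("gene_id")["q"] if len(de_records) else pd.Series(dtype=float)
    rows = []
    for gene in sorted(annotation, key=lambda g: (annotation[g][0], annotation[g][1])):
        cluster, paralog = annotation[gene]
        if gene in matrix.values.index:
            log2_sub = float(np.log2(matrix.values.loc[gene, sub].median() + 1.0)) if sub else np.nan
            log2_om = float(np.log2(matrix.values.loc[gene, om].median() + 1.0)) if om else np.nan
            q = float(qmap.get(gene, np.nan))
        else:
            log2_sub = log2_om = q = np.nan
        rows.append(
            {
                "cluster": cluster,
                "paralog": int(paralog),
                "symbol": gene,
                "log2_sub": log2_sub,
                "log2_om": log2_om,
                "q": q,
                "de_flag": bool(q < config.specificity_fdr) if np.isfinite(q) else False,
            }
        )
    return pd.DataFrame(
        rows, columns=["cluster", "paralog", "symbol", "log2_sub", "log2_om", "q", "de_flag"]
    )


def export_heatmap(hox_map: pd.DataFrame, path) -> None:
    """Render the map as a minimal two-column heatmap (values only)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = hox_map[["log2_sub", "log2_om"]].to_numpy(dtype=float)
    fig, ax = plt.subplots(figsize=(3, max(2, 0.22 * len(hox_map))))
    im = ax.imshow(data, aspect="auto", cmap="Blues")
    ax.set_xticks([0, 1], ["subcutaneous", "omental"])
    ax.set_yticks(range(len(hox_map)), hox_map["symbol"])
    for i, flagged in enumerate(hox_map["de_flag"]):
        if flagged:
            ax.text(1.55, i, "*", va="center")
    fig.colorbar(im, ax=ax, label="log2(median TPM + 1)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
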