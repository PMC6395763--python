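"""Classify genes as adipose-specific or adipose-enhanced per depot.

The classification works on a multi-tissue TPM atlas.  After quality-based
sample selection and an expression filter, per-tissue medians are computed
for every gene.  A gene is called *specific* to a depot when its depot
median exceeds the median of every other (non-adipose) tissue by more than
the fold threshold (default 5) with a per-contrast BH-adjusted p-value below
0.01; *enhanced* calls tolerate one or two exception tissues provided their
medians remain below the depot median.  The relative median value — depot
median over the arithmetic mean of all non-depot tissue medians — is
reported alongside each call as a single-number specificity score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stats import bh_adjust, welch_rows
from .config import AnalysisConfig
from .io_formats import ExpressionMatrix

__all__ = [
    "MedianProfile",
    "SpecificityCall",
    "bh_adjust",
    "select_samples",
    "filter_expressed",
    "tissue_medians",
    "relative_median_value",
    "pairwise_folds",
    "pairwise_fold_table",
    "pairwise_tests",
    "classify_genes",
    "calls_to_frame",
]

logger = logging.getLogger(__name__)

#: short depot names used in outputs
DEPOT_SHORT = {"subcutaneous": "subcutaneous", "omental": "omental"}


@dataclass
class MedianProfile:
    """Per-gene, per-tissue sample medians with the depot tissues singled out."""

    medians: pd.DataFrame                 # genes x tissues
    depot_tissues: tuple[str, str]        # (subcutaneous label, omental label)

    @property
    def non_depot_tissues(self) -> list[str]:
        return [t for t in self.medians.columns if t not in self.depot_tissues]

    def depot_label(self, depot: str) -> str:
        """Resolve 'subcutaneous' / 'omental' (or a full label) to a column."""
        if depot == "subcutaneous":
            return self.depot_tissues[0]
        if depot == "omental":
            return self.depot_tissues[1]
        if depot in self.medians.columns:
            return depot
        raise KeyError(f"unknown depot {depot!r}")


@dataclass
class SpecificityCall:
    """One specificity/enhancement call for a gene in one depot."""

    gene_id: str
    depot: str                            # "subcutaneous" or "omental"
    category: str                         # specific_all | enhanced_except1 | enhanced_except2
    relative_median: float
    exception_tissues: list[str] = field(default_factory=list)
    min_fold: float = float("nan")        # smallest passing fold over non-exception tissues
    max_q: float = float("nan")           # largest q over non-exception tissues

    def __post_init__(self) -> None:
        expected = {"specific_all": 0, "enhanced_except1": 1, "enhanced_except2": 2}
        if self.category not in expected:
            raise ValueError(f"unknown category {self.category!r}")
        if len(self.exception_tissues) != expected[self.category]:
            raise ValueError("exception list length inconsistent with category")


# ---------------------------------------------------------------------------
# sample selection and expression filter
# ---------------------------------------------------------------------------

def select_samples(
    matrix: ExpressionMatrix, samples: pd.DataFrame, config: AnalysisConfig
) -> ExpressionMatrix:
    """Apply quality and coverage rules to the atlas.

    Keeps samples with RIN >= ``min_rin`` (inclusive), drops the configured
    excluded tissue labels, then drops whole tissues represented by fewer
    than ``min_donors`` distinct donors.
    """
    known = set(samples["sample_id"])
    missing = [s for s in matrix.sample_ids if s not in known]
    if missing:
        raise KeyError(f"matrix samples absent from sample table: {missing[:5]}")
    sub = samples[samples["sample_id"].isin(matrix.sample_ids)]
    sub = sub[sub["rin"] >= config.min_rin]
    sub = sub[~sub["tissue"].isin(set(config.excluded_tissues))]
    donors = sub.groupby("tissue")["donor_id"].nunique()
    keep_tissues = set(donors[donors >= config.min_donors].index)
    dropped = set(donors.index) - keep_tissues
    if dropped:
        logger.info("dropping tissues below %d donors: %s", config.min_donors, sorted(dropped))
    sub = sub[sub["tissue"].isin(keep_tissues)]
    out = matrix.subset_samples(list(sub["sample_id"]))
    return out.with_tissues(sub)


def filter_expressed(matrix: ExpressionMatrix, config: AnalysisConfig) -> set[str]:
    """Genes passing the expression filter in at least one tissue.

    A gene passes in a tissue when at least ``filter_fraction`` of that
    tissue's samples exceed ``filter_tpm_floor`` TPM *and* the tissue median
    is strictly above ``filter_median_floor``.
    """
    if not matrix.tissue_of:
        raise ValueError("matrix has no tissue labels; join a sample table first")
    keep = pd.Series(False, index=matrix.values.index)
    for tissue in matrix.tissues:
        cols = matrix.samples_of_tissue(tissue)
        if not cols:
            raise ValueError(f"tissue {tissue!r} has zero samples")
        block = matrix.values[cols]
        frac = (block > config.filter_tpm_floor).mean(axis=1)
        med = block.median(axis=1)
        keep |= (frac >= config.filter_fraction) & (med > config.filter_median_floor)
    return set(keep.index[keep])


# ---------------------------------------------------------------------------
# medians, folds, relative medians
# ---------------------------------------------------------------------------

def tissue_medians(matrix: ExpressionMatrix, config: AnalysisConfig) -> MedianProfile:
    """Per-gene, per-tissue sample medians (even n: mean of central pair)."""
    if not matrix.tissue_of:
        raise ValueError("matrix has no tissue labels")
    cols = {}
    for tissue in matrix.tissues:
        samp = matrix.samples_of_tissue(tissue)
        if not samp:
            raise ValueError(f"tissue {tissue!r} has zero samples")
        cols[tissue] = matrix.values[samp].median(axis=1)
    medians = pd.DataFrame(cols)
    return MedianProfile(medians, (config.subcutaneous_label, config.omental_label))


def relative_median_value(profile: MedianProfile, gene: str, depot: str) -> float:
    """Depot median over the mean of all non-depot tissue medians.

    Both adipose depots are excluded from the denominator.  Returns +inf when
    the denominator is 0 and the numerator positive, 0 when both are 0.
    """
    if gene not in profile.medians.index:
        raise KeyError(f"unknown gene {gene!r}")
    col = profile.depot_label(depot)
    num = float(profile.medians.at[gene, col])
    denom = float(profile.medians.loc[gene, profile.non_depot_tissues].mean())
    if denom == 0:
        return float("inf") if num > 0 else 0.0
    return num / denom


def _fold_array(depot_medians: np.ndarray, other: np.ndarray) -> np.ndarray:
    """Element-wise depot/other fold with 0-median conventions.

    fold = +inf when the other tissue's median is 0 and the depot's positive;
    fold = 0 when the depot median is 0.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = depot_medians / other
    fold = np.where(depot_medians == 0, 0.0, fold)
    fold = np.where((other == 0) & (depot_medians > 0), np.inf, fold)
    return fold


def pairwise_folds(profile: MedianProfile, gene: str, depot: str) -> dict[str, float]:
    """Fold of the depot median over each non-depot tissue's median."""
    if gene not in profile.medians.index:
        raise KeyError(f"unknown gene {gene!r}")
    col = profile.depot_label(depot)
    num = float(profile.medians.at[gene, col])
    others = profile.medians.loc[gene, profile.non_depot_tissues].to_numpy(dtype=float)
    folds = _fold_array(np.full_like(others, num), others)
    return dict(zip(profile.non_depot_tissues, folds.tolist()))


def pairwise_fold_table(profile: MedianProfile, depot: str) -> pd.DataFrame:
    """Genes x non-depot-tissues table of median folds for one depot."""
    col = profile.depot_label(depot)
    num = profile.medians[col].to_numpy(dtype=float)[:, None]
    others = profile.medians[profile.non_depot_tissues].to_numpy(dtype=float)
    folds = _fold_array(np.broadcast_to(num, others.shape).copy(), others)
    return pd.DataFrame(folds, index=profile.medians.index, columns=profile.non_depot_tissues)


# ---------------------------------------------------------------------------
# pairwise tests
# ---------------------------------------------------------------------------

def pairwise_tests(
    matrix: ExpressionMatrix, depot: str, config: AnalysisConfig
) -> pd.DataFrame:
    """BH-adjusted q-values for the depot-vs-each-other-tissue contrasts.

    For every gene and non-depot tissue j, a Welch two-sample t-test compares
    depot samples against tissue-j samples on log2(TPM + pseudocount);
    p-values are BH-adjusted across genes within each contrast.
    """
    depot_col = {"subcutaneous": config.subcutaneous_label, "omental": config.omental_label}.get(depot, depot)
    depot_samples = matrix.samples_of_tissue(depot_col)
    if len(depot_samples) < 2:
        raise ValueError(f"depot {depot_col!r} has fewer than 2 samples")
    logged = np.log2(matrix.values.to_numpy(dtype=float) + config.pseudocount)
    col_index = {s: i for i, s in enumerate(matrix.values.columns)}
    a = logged[:, [col_index[s] for s in depot_samples]]
    qcols = {}
    non_depot = [t for t in matrix.tissues if t not in (config.subcutaneous_label, config.omental_label)]
    for tissue in non_depot:
        samp = matrix.samples_of_tissue(tissue)
        if len(samp) < 2:
            raise ValueError(f"tissue {tissue!r} has fewer than 2 samples")
        b = logged[:, [col_index[s] for s in samp]]
        qcols[tissue] = bh_adjust(welch_rows(a, b))
    return pd.DataFrame(qcols, index=matrix.values.index)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_genes(
    profile: MedianProfile,
    folds: pd.DataFrame,
    qvalues: pd.DataFrame,
    depot: str,
    config: AnalysisConfig,
) -> list[SpecificityCall]:
    """Call specific/enhanced genes for one depot.

    A non-depot tissue *passes* for a gene when fold > ``fold_threshold``
    (strict) and q < ``specificity_fdr``.  With zero failing tissues the gene
    is ``specific_all``; with one or two failing tissues whose medians all
    lie strictly below the depot median it is ``enhanced_except1``/``2``;
    otherwise no call is made.
    """
    tissues = list(folds.columns)
    if list(qvalues.columns) != tissues:
        qvalues = qvalues[tissues]
    depot_col = profile.depot_label(depot)
    calls: list[SpecificityCall] = []
    f = folds.to_numpy(dtype=float)
    q = qvalues.to_numpy(dtype=float)
    passing = (f > config.fold_threshold) & (q < config.specificity_fdr)
    n_fail = (~passing).sum(axis=1)
    candidates = np.flatnonzero(n_fail <= 2)
    for i in candidates:
        gene = folds.index[i]
        fail_idx = np.flatnonzero(~passing[i])
        exceptions = [tissues[j] for j in fail_idx]
        depot_median = float(profile.medians.at[gene, depot_col])
        if exceptions:
            exc_medians = profile.medians.loc[gene, exceptions]
            if not (exc_medians < depot_median).all():
                continue  # an exception tissue out-expresses the depot: excluded
        category = {0: "specific_all", 1: "enhanced_except1", 2: "enhanced_except2"}[len(exceptions)]
        ok_idx = np.flatnonzero(passing[i])
        calls.append(
            SpecificityCall(
                gene_id=gene,
                depot=depot,
                category=category,
                relative_median=relative_median_value(profile, gene, depot),
                exception_tissues=sorted(exceptions),
                min_fold=float(f[i, ok_idx].min()) if ok_idx.size else float("nan"),
                max_q=float(q[i, ok_idx].max()) if ok_idx.size else float("nan"),
            )
        )
    calls.sort(key=lambda c: c.gene_id)
    return calls


def calls_to_frame(calls: list[SpecificityCall], annotation: pd.DataFrame | None = None) -> pd.DataFrame:
    """Tabulate calls for TSV export (exception tissues semicolon-joined)."""
    rows = [
        {
            "gene_id": c.gene_id,
            "depot": c.depot,
            "category": c.category,
            "relative_median": c.relative_median,
            "exception_tissues": ";".join(c.exception_tissues),
            "min_fold": c.min_fold,
            "max_q": c.max_q,
        }
        for c in calls
    ]
    df = pd.DataFrame(
        rows,
        columns=["gene_id", "depot", "category", "relative_median",
                 "exception_tissues", "min_fold", "max_q"],
    )
    if annotation is not None and len(df):
        sym = annotation.set_index("gene_id")["symbol"]
        df.insert(1, "symbol", df["gene_id"].map(sym).fillna(""))
    return df
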