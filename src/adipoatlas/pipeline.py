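"""End-to-end orchestration of the analysis stages.

Each ``run_*`` function chains the stage operations on validated inputs,
writes deterministic TSV outputs, and contributes row counts to a run
manifest (config snapshot, input digests, seed, per-stage counts) so any
two runs on identical inputs are byte-identical and auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import __version__
from ._stats import bh_adjust
from .config import AnalysisConfig
from .io_formats import CountMatrix, ExpressionMatrix, TraitCategoryMap, write_tables
from . import depot_deg as dd
from . import gwas_integration as gw
from . import hox_map as hm
from . import specificity as sp

logger = logging.getLogger(__name__)


def _digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class RunManifest:
    """Accumulates provenance for one pipeline run."""

    def __init__(self, config: AnalysisConfig, seed: int | None = None):
        self.data = {
            "tool_version": __version__,
            "seed": seed,
            "config": config.to_dict(),
            "inputs": {},
            "stages": {},
        }

    def add_input(self, name: str, path: str | Path) -> None:
        self.data["inputs"][name] = {"path": str(path), "sha256": _digest(path)}

    def add_stage(self, name: str, rows_in: int, rows_out: int, elapsed: float) -> None:
        self.data["stages"][name] = {
            "rows_in": rows_in,
            "rows_out": rows_out,
            "elapsed_s": round(elapsed, 3),
        }
        logger.info("stage %s: %d -> %d rows (%.2fs)", name, rows_in, rows_out, elapsed)

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        with path.open("w") as fh:
            json.dump(self.data, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return path


def run_specificity(
    config: AnalysisConfig,
    matrix: ExpressionMatrix,
    samples: pd.DataFrame,
    annotation: pd.DataFrame | None = None,
    out_dir: str | Path | None = None,
    manifest: RunManifest | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Sample selection -> filter -> medians -> folds/tests -> calls.

    Returns the call table and a summary with per-depot category counts and
    the subcutaneous/omental/both Venn partition.
    """
    t0 = time.monotonic()
    selected = sp.select_samples(matrix, samples, config)
    expressed = sp.filter_expressed(selected, config)
    working = selected.subset_genes(expressed)
    profile = sp.tissue_medians(working, config)
    calls = []
    for depot in ("subcutaneous", "omental"):
        folds = sp.pairwise_fold_table(profile, depot)
        qvals = sp.pairwise_tests(working, depot, config)
        calls.extend(sp.classify_genes(profile, folds, qvals, depot, config))
    table = sp.calls_to_frame(calls, annotation)
    by_depot = {
        d: set(table.loc[table["depot"] == d, "gene_id"]) for d in ("subcutaneous", "omental")
    }
    both = by_depot["subcutaneous"] & by_depot["omental"]
    summary = {
        "n_samples_selected": len(selected.sample_ids),
        "n_genes_expressed": len(expressed),
        "n_calls": len(table),
        "per_category": table.groupby(["depot", "category"]).size().to_dict() if len(table) else {},
        "venn": {
            "subcutaneous_only": len(by_depot["subcutaneous"] - both),
            "omental_only": len(by_depot["omental"] - both),
            "both": len(both),
        },
    }
    if manifest is not None:
        manifest.add_stage("specificity", len(matrix.gene_ids), len(table), time.monotonic() - t0)
    if out_dir is not None:
        write_tables({"specificity_calls": table}, out_dir)
    return table, summary


def run_depot_deg(
    config: AnalysisConfig,
    counts: CountMatrix,
    annotation: pd.DataFrame | None = None,
    out_dir: str | Path | None = None,
    manifest: RunManifest | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Size factors -> per-gene test -> DEG thresholding -> biotype table."""
    t0 = time.monotonic()
    records = dd.depot_de_test(counts, config)
    degs = dd.classify_degs(records, config)
    breakdown = None
    if annotation is not None:
        degs = degs.merge(annotation[["gene_id", "symbol", "biotype"]], on="gene_id", how="left")
        degs["biotype_group"] = degs["biotype"].fillna("").map(dd.biotype_group)
        breakdown = dd.biotype_breakdown(degs, annotation)
    if manifest is not None:
        manifest.add_stage("depot_deg", len(records), len(degs), time.monotonic() - t0)
    if out_dir is not None:
        tables = {"depot_degs": degs}
        if breakdown is not None:
            tables["deg_biotype_breakdown"] = breakdown.reset_index()
        write_tables(tables, out_dir)
    return degs, breakdown


def run_integration(
    config: AnalysisConfig,
    gene_lists: dict[str, list[str]],
    catalog,
    categories: TraitCategoryMap,
    gene_sets: dict[str, set[str]] | None = None,
    universe: list[str] | None = None,
    out_dir: str | Path | None = None,
    manifest: RunManifest | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame | None, dict]:
    """Catalog extraction -> gene matching -> counts -> optional enrichment.

    ``gene_lists`` maps a source label (e.g. ``adipose_specific_enhanced``,
    ``depot_deg``) to its query symbols.
    """
    t0 = time.monotonic()
    catalog_sets = gw.extract_catalog_genes(catalog, categories)
    all_results = []
    summary: dict = {}
    for source, genes in gene_lists.items():
        results = gw.match_genes(genes, catalog_sets, source_list=source)
        per_cat, histogram = gw.category_counts(results)
        summary[source] = {
            "n_matched": len(results),
            "per_category": per_cat,
            "category_cardinality": histogram,
        }
        all_results.extend(results)
    assoc = gw.associations_to_frame(all_results)
    enrichment = None
    if gene_sets and universe:
        query = sorted({g for genes in gene_lists.values() for g in genes})
        query = [g for g in query if g.casefold() in {u.casefold() for u in universe}]
        enrichment = gw.overrepresentation_test(query, gene_sets, universe, config)
    if manifest is not None:
        manifest.add_stage(
            "integration", sum(len(g) for g in gene_lists.values()), len(assoc), time.monotonic() - t0
        )
    if out_dir is not None:
        tables = {"gwas_associations": assoc}
        if enrichment is not None:
            tables["enrichment"] = enrichment
        write_tables(tables, out_dir)
    return assoc, enrichment, summary


def run_hox_map(
    config: AnalysisConfig,
    matrix: ExpressionMatrix,
    counts: CountMatrix,
    annotation: dict[str, tuple[str, int]] | None = None,
    out_dir: str | Path | None = None,
    manifest: RunManifest | None = None,
) -> pd.DataFrame:
    """Depot test on counts (BH over all genes, no fold cutoff) + TPM map."""
    t0 = time.monotonic()
    annotation = annotation or hm.hox_annotation()
    records = dd.depot_de_test(counts, config)
    records = records.assign(q=bh_adjust(records["p"].to_numpy()))
    hox = hm.build_hox_map(matrix, annotation, records, config)
    if manifest is not None:
        manifest.add_stage("hox_map", len(annotation), len(hox), time.monotonic() - t0)
    if out_dir is not None:
        write_tables({"hox_map": hox}, out_dir)
    return hox
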