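"""Packaged worked-example data.

``load_adipose_gwas_examples`` returns a curated table of 14 human
adipose-specific/enhanced genes together with the obesity-related GWAS
trait categories (obesity, type 2 diabetes, blood lipids, inflammation)
each gene is associated with, and the depot(s) in which it is specifically
expressed.  It serves as a small real-data worked example for the
category-counting operations.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .gwas_integration import AssociationResult

__all__ = ["load_adipose_gwas_examples", "examples_as_results"]


def load_adipose_gwas_examples() -> pd.DataFrame:
    """The 14-gene adipose/GWAS association example table.

    Columns: gene symbol, cytogenetic region, expression group
    (specific_all / enhanced_except1 / enhanced_except2), depot
    (subcutaneous / omental / both), and semicolon-joined trait categories.
    """
    ref = resources.files("adipoatlas").joinpath("data/adipose_gwas_associations.tsv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def examples_as_results(df: pd.DataFrame | None = None) -> list[AssociationResult]:
    """Convert the example table into association results for counting."""
    if df is None:
        df = load_adipose_gwas_examples()
    return [
        AssociationResult(
            symbol=row["gene"],
            categories=set(str(row["categories"]).split(";")),
            source_list="adipose_specific_enhanced",
            depot_or_direction=row["depot"],
        )
        for _, row in df.iterrows()
    ]
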