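"""Readers and writers for the external formats the pipeline touches.

Formats supported:

* GCT v1.2 (``#1.2`` header, then ``n_rows n_cols``, then a ``Name`` /
  ``Description`` column pair) and a plain TSV dialect for expression
  matrices in TPM units.
* Tab-separated sample-attribute tables (sample id, donor id, tissue, RIN).
* Flat gene-annotation TSVs (Ensembl-style id, symbol, biotype, coordinates).
* The public GWAS Catalog "All associations" TSV dialect.
* YAML trait-category configuration (category name -> list of trait strings).
* GMT gene-set files for over-representation input.

Every reader validates its output against the type invariants and raises a
named error on violation; no partially constructed object escapes.  Gene id
version suffixes (``ENSG....N``) are stripped at ingest so all downstream
joins are on versionless ids.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: significant digits used when serialising real values
FLOAT_FORMAT = "%.6g"


# ---------------------------------------------------------------------------
# errors
# ---------------------------------------------------------------------------

class FormatError(ValueError):
    """Base class for malformed input files."""


class DimensionMismatchError(FormatError):
    """A GCT header declared a shape that does not match the body."""


class NegativeValueError(FormatError):
    """An expression or count matrix contained a negative or non-finite value."""


class DuplicateGeneError(FormatError):
    """A matrix contained the same (versionless) gene id twice."""


class DuplicateSampleError(FormatError):
    """A sample-attribute table contained the same sample id twice."""


class MissingColumnError(FormatError):
    """A mandatory column is absent from a tabular input."""


class DuplicateCategoryError(FormatError):
    """A trait-category configuration declared the same category twice."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

_VERSION_SUFFIX = re.compile(r"\.\d+$")


def strip_gene_version(gene_id: str) -> str:
    """Drop a trailing ``.N`` version suffix from an Ensembl-style gene id."""
    return _VERSION_SUFFIX.sub("", gene_id)


@dataclass
class ExpressionMatrix:
    """A genes x samples table of non-negative TPM values.

    ``values`` is indexed by versionless gene id with one column per sample.
    ``tissue_of`` maps sample ids to tissue labels; it may be empty until the
    matrix is joined with a sample-attribute table.
    """

    values: pd.DataFrame
    tissue_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = self.values.to_numpy()
        if arr.size and (not np.isfinite(arr).all() or (arr < 0).any()):
            raise NegativeValueError("expression values must be finite and >= 0")
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise DuplicateGeneError(f"duplicate gene ids: {list(dupes)[:5]}")
        unknown = set(self.tissue_of) - set(self.values.columns)
        if unknown:
            raise FormatError(f"tissue labels for unknown samples: {sorted(unknown)[:5]}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def tissues(self) -> list[str]:
        """Sorted list of distinct tissue labels."""
        return sorted(set(self.tissue_of.values()))

    def samples_of_tissue(self, tissue: str) -> list[str]:
        return [s for s in self.values.columns if self.tissue_of.get(s) == tissue]

    def with_tissues(self, samples: pd.DataFrame) -> "ExpressionMatrix":
        """Attach tissue labels from a sample-attribute table."""
        missing = [s for s in self.values.columns if s not in set(samples["sample_id"])]
        if missing:
            raise KeyError(f"samples absent from sample table: {missing[:5]}")
        lookup = dict(zip(samples["sample_id"], samples["tissue"]))
        return ExpressionMatrix(
            self.values, {s: lookup[s] for s in self.values.columns}
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        keep = [s for s in self.values.columns if s in set(sample_ids)]
        return ExpressionMatrix(
            self.values[keep], {s: self.tissue_of[s] for s in keep if s in self.tissue_of}
        )

    def subset_genes(self, gene_ids: Iterable[str]) -> "ExpressionMatrix":
        keep = [g for g in self.values.index if g in set(gene_ids)]
        return ExpressionMatrix(self.values.loc[keep], dict(self.tissue_of))


@dataclass
class CountMatrix:
    """A genes x samples table of non-negative integer read counts."""

    values: pd.DataFrame
    tissue_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = self.values.to_numpy()
        if arr.size:
            if not np.isfinite(arr).all() or (arr < 0).any():
                raise NegativeValueError("counts must be finite and >= 0")
            if not np.array_equal(arr, np.round(arr)):
                raise FormatError("counts must be integers")
        if self.values.index.duplicated().any():
            raise DuplicateGeneError("duplicate gene ids in count matrix")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_of_tissue(self, tissue: str) -> list[str]:
        return [s for s in self.values.columns if self.tissue_of.get(s) == tissue]


@dataclass
class GWASCatalogRecord:
    """One association row from a GWAS Catalog dump."""

    trait: str
    reported_genes: list[str]
    mapped_genes: list[str]
    snp_id: str = ""
    chromosome: str = ""
    position: int = 0


def _normalize_trait(trait: str) -> str:
    """Case-fold and collapse internal whitespace for exact trait matching."""
    return " ".join(trait.split()).casefold()


@dataclass
class TraitCategoryMap:
    """Named groupings of GWAS trait strings.

    ``categories`` keeps the original trait strings; matching is done on a
    normalized (case-folded, whitespace-collapsed) form.
    """

    categories: dict[str, list[str]]

    def __post_init__(self) -> None:
        for name, traits in self.categories.items():
            normed = [_normalize_trait(t) for t in traits]
            if len(set(normed)) != len(normed):
                raise FormatError(f"duplicate trait within category {name!r}")
        self._lookup: dict[str, set[str]] = {}
        for name, traits in self.categories.items():
            for t in traits:
                self._lookup.setdefault(_normalize_trait(t), set()).add(name)

    @property
    def names(self) -> list[str]:
        return list(self.categories)

    def categories_of(self, trait: str) -> set[str]:
        """Categories whose trait list contains ``trait`` (normalized exact match)."""
        return set(self._lookup.get(_normalize_trait(trait), ()))


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def read_expression_matrix(path: str | Path, dialect: str = "gct") -> ExpressionMatrix:
    """Read a TPM matrix from a GCT v1.2 file or a plain TSV.

    Gene id version suffixes are stripped; ``tissue_of`` is left empty until
    the matrix is joined with a sample table via :meth:`ExpressionMatrix.with_tissues`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "gct":
        with path.open() as fh:
            version = fh.readline().strip()
            if version != "#1.2":
                raise FormatError(f"unsupported GCT version line: {version!r}")
            dims = fh.readline().split()
            if len(dims) < 2:
                raise DimensionMismatchError("GCT dimension line must hold two integers")
            n_rows, n_cols = int(dims[0]), int(dims[1])
            body = pd.read_csv(fh, sep="\t")
        if "Name" not in body.columns or "Description" not in body.columns:
            raise MissingColumnError("GCT body must start with Name and Description")
        data = body.drop(columns=["Description"]).set_index("Name")
        if data.shape != (n_rows, n_cols):
            raise DimensionMismatchError(
                f"header declares {(n_rows, n_cols)} but body is {data.shape}"
            )
    elif dialect == "tsv":
        data = pd.read_csv(path, sep="\t", index_col=0)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    data.index = [strip_gene_version(str(g)) for g in data.index]
    data.index.name = "gene_id"
    return ExpressionMatrix(data.astype(float))


def write_expression_matrix(
    matrix: ExpressionMatrix, path: str | Path, dialect: str = "gct"
) -> Path:
    """Serialise a matrix as GCT v1.2 or plain TSV with 6 significant digits."""
    path = Path(path)
    df = matrix.values
    if dialect == "gct":
        with path.open("w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{df.shape[0]}\t{df.shape[1]}\n")
            out = df.copy()
            out.insert(0, "Description", ["na"] * len(out))
            out.index.name = "Name"
            out.to_csv(fh, sep="\t", float_format=FLOAT_FORMAT)
    elif dialect == "tsv":
        df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return path


def write_count_matrix(counts: CountMatrix, path: str | Path) -> Path:
    path = Path(path)
    counts.values.astype(int).to_csv(path, sep="\t")
    return path


def read_count_matrix(path: str | Path) -> CountMatrix:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = [strip_gene_version(str(g)) for g in df.index]
    df.index.name = "gene_id"
    return CountMatrix(df)


# ---------------------------------------------------------------------------
# sample attributes / gene annotation
# ---------------------------------------------------------------------------

_SAMPLE_COLUMNS = {
    "sample_id": "sample_id",
    "donor_id": "donor_id",
    "tissue": "tissue",
    "rin": "rin",
}


def read_sample_attributes(
    path: str | Path, columns: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Read a sample-attribute TSV into a frame with canonical column names.

    ``columns`` maps canonical names (sample_id, donor_id, tissue, rin) to the
    header names used in the file.  Rows whose RIN does not parse as a number
    are dropped with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    colmap = dict(_SAMPLE_COLUMNS)
    if columns:
        colmap.update(columns)
    raw = pd.read_csv(path, sep="\t", dtype=str)
    missing = [src for src in colmap.values() if src not in raw.columns]
    if missing:
        raise MissingColumnError(f"sample table lacks columns: {missing}")
    df = pd.DataFrame(
        {canon: raw[src] for canon, src in colmap.items()}
    )
    rin = pd.to_numeric(df["rin"], errors="coerce")
    bad = rin.isna()
    if bad.any():
        logger.warning("dropping %d sample rows with unparsable RIN", int(bad.sum()))
        df = df[~bad]
        rin = rin[~bad]
    df = df.assign(rin=rin.astype(float)).reset_index(drop=True)
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise DuplicateSampleError(f"duplicate sample ids: {dupes[:5]}")
    return df


def write_sample_attributes(samples: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    samples.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
    return path


_ANNOTATION_COLUMNS = ["gene_id", "symbol", "biotype", "chromosome", "start", "end", "strand"]


def read_gene_annotation(path: str | Path) -> pd.DataFrame:
    """Read a flat gene-annotation TSV (id, symbol, biotype, coordinates)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    missing = [c for c in _ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise MissingColumnError(f"annotation lacks columns: {missing}")
    df["gene_id"] = df["gene_id"].map(strip_gene_version)
    if df["gene_id"].duplicated().any():
        raise DuplicateGeneError("duplicate gene ids in annotation")
    if (df["start"] > df["end"]).any():
        raise FormatError("annotation rows with start > end")
    if df["biotype"].isna().any() or (df["biotype"].astype(str).str.len() == 0).any():
        raise FormatError("annotation rows with empty biotype")
    return df


def write_gene_annotation(annotation: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    annotation.to_csv(path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# GWAS catalog
# ---------------------------------------------------------------------------

#: tokens in gene columns that denote "no gene" in the public catalog dialect
_NULL_GENE_TOKENS = {"nr", "intergenic", ""}


def _split_gene_field(value: object, intergenic: bool) -> list[str]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return []
    text = str(value)
    parts = text.split(",")
    if intergenic:
        # "GENE1 - GENE2" marks an intergenic hit; keep both flanking genes
        parts = [p for chunk in parts for p in chunk.split(" - ")]
    genes = []
    for token in parts:
        token = token.strip()
        if token.casefold() in _NULL_GENE_TOKENS:
            continue
        genes.append(token)
    return genes


def read_gwas_catalog(path: str | Path) -> list[GWASCatalogRecord]:
    """Parse a GWAS Catalog "All associations" TSV into records.

    Reported genes are split on commas; mapped genes additionally on the
    ``" - "`` intergenic separator, keeping both flanking genes.  The tokens
    ``NR``, ``intergenic`` and empty strings are dropped.  A missing trait
    column is fatal; missing gene columns yield empty lists.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "DISEASE/TRAIT" not in df.columns:
        raise MissingColumnError("GWAS catalog file lacks DISEASE/TRAIT column")
    records = []
    for _, row in df.iterrows():
        trait = str(row["DISEASE/TRAIT"]).strip()
        if not trait:
            continue
        records.append(
            GWASCatalogRecord(
                trait=trait,
                reported_genes=_split_gene_field(
                    row.get("REPORTED GENE(S)", ""), intergenic=False
                ),
                mapped_genes=_split_gene_field(row.get("MAPPED_GENE", ""), intergenic=True),
                snp_id=str(row.get("SNPS", "")),
                chromosome=str(row.get("CHR_ID", "")),
                position=int(row["CHR_POS"]) if str(row.get("CHR_POS", "")).isdigit() else 0,
            )
        )
    return records


def write_gwas_catalog(
    records: Iterable[GWASCatalogRecord], path: str | Path, intergenic_every: int = 0
) -> Path:
    """Serialise records in the catalog dialect.

    With ``intergenic_every = k > 0``, every k-th record with two or more
    mapped genes writes its first pair in the intergenic ``"A - B"`` form;
    reading the file back recovers both flanking genes.
    """
    path = Path(path)
    rows = []
    for i, r in enumerate(records):
        mapped = list(r.mapped_genes)
        if intergenic_every and (i + 1) % intergenic_every == 0 and len(mapped) >= 2:
            mapped = [f"{mapped[0]} - {mapped[1]}"] + mapped[2:]
        rows.append(
            {
                "DISEASE/TRAIT": r.trait,
                "REPORTED GENE(S)": ", ".join(r.reported_genes) or "NR",
                "MAPPED_GENE": ", ".join(mapped),
                "SNPS": r.snp_id,
                "CHR_ID": r.chromosome,
                "CHR_POS": r.position,
            }
        )
    pd.DataFrame(
        rows,
        columns=["DISEASE/TRAIT", "REPORTED GENE(S)", "MAPPED_GENE", "SNPS", "CHR_ID", "CHR_POS"],
    ).to_csv(path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# trait categories / gene sets
# ---------------------------------------------------------------------------

def read_trait_categories(path: str | Path) -> TraitCategoryMap:
    """Read a YAML mapping of category name -> list of trait strings."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with path.open() as fh:
        # yaml silently keeps the last duplicate key, so detect duplicates by hand
        text = fh.read()
    raw = yaml.safe_load(text) or {}
    keys = [
        line.split(":", 1)[0].strip()
        for line in text.splitlines()
        if line and not line[0].isspace() and ":" in line and not line.lstrip().startswith("#")
    ]
    if len(keys) != len(set(keys)):
        raise DuplicateCategoryError("category declared twice in trait config")
    if not raw:
        logger.warning("trait-category config %s is empty", path)
        return TraitCategoryMap({})
    categories = {}
    for name, traits in raw.items():
        if not traits:
            logger.warning("category %r has an empty trait list", name)
            traits = []
        categories[str(name)] = [str(t) for t in traits]
    return TraitCategoryMap(categories)


def write_trait_categories(categories: TraitCategoryMap, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        yaml.safe_dump(categories.categories, fh, sort_keys=True)
    return path


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT gene-set file (set name, description, then gene symbols)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sets: dict[str, set[str]] = {}
    with path.open() as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            sets[fields[0]] = {g for g in fields[2:] if g}
    return sets


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

def write_tables(results: Mapping[str, pd.DataFrame], out_dir: str | Path) -> dict[str, Path]:
    """Write each result frame as a deterministic, sorted TSV.

    Rows are sorted by all columns (gene id first where present) so repeated
    runs on identical inputs produce byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in results.items():
        out = df.copy()
        if len(out):
            sort_cols = [c for c in out.columns if out[c].map(lambda v: not isinstance(v, (list, set))).all()]
            if sort_cols:
                out = out.sort_values(sort_cols, kind="mergesort").reset_index(drop=True)
        target = out_dir / f"{name}.tsv"
        out.to_csv(target, sep="\t", index=False, float_format=FLOAT_FORMAT)
        paths[name] = target
    return paths
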