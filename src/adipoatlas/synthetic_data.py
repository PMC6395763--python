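"""Synthetic GTEx-like inputs with planted ground truth.

The generators emulate the statistical shape of the real study inputs — a
46-tissue TPM atlas containing two adipose depots, read-count matrices for
the depot comparison, and a GWAS-catalog association file — at a scale a
laptop handles, with every planted effect recorded in a truth table so the
pipeline's calls can be scored against it.

Atlas TPM values are drawn from a gamma distribution per gene x tissue mean
(the atlas stages consume TPM directly); the depot comparison gets genuine
negative-binomial counts with log-normal per-sample depth factors so
size-factor estimation is exercised.  Donor-level correlation across
tissues, batch effects, and GTEx covariance structure are deliberately not
modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import OMENTAL, SUBCUTANEOUS
from .io_formats import CountMatrix, ExpressionMatrix, GWASCatalogRecord, TraitCategoryMap

__all__ = [
    "GTEX_TISSUES",
    "SimConfig",
    "generate_atlas",
    "generate_depot_counts",
    "generate_gwas_catalog",
]

#: the 44 non-adipose tissue labels of the atlas (GTEx naming)
NON_ADIPOSE_TISSUES: tuple[str, ...] = (
    "Adrenal Gland",
    "Artery - Aorta",
    "Artery - Coronary",
    "Artery - Tibial",
    "Brain - Amygdala",
    "Brain - Anterior cingulate cortex (BA24)",
    "Brain - Caudate (basal ganglia)",
    "Brain - Cerebellar Hemisphere",
    "Brain - Cerebellum",
    "Brain - Cortex",
    "Brain - Frontal Cortex (BA9)",
    "Brain - Hippocampus",
    "Brain - Hypothalamus",
    "Brain - Nucleus accumbens (basal ganglia)",
    "Brain - Putamen (basal ganglia)",
    "Brain - Spinal cord (cervical c-1)",
    "Brain - Substantia nigra",
    "Colon - Sigmoid",
    "Colon - Transverse",
    "Esophagus - Gastroesophageal Junction",
    "Esophagus - Mucosa",
    "Esophagus - Muscularis",
    "Heart - Atrial Appendage",
    "Heart - Left Ventricle",
    "Kidney - Cortex",
    "Liver",
    "Lung",
    "Minor Salivary Gland",
    "Muscle - Skeletal",
    "Nerve - Tibial",
    "Ovary",
    "Pancreas",
    "Pituitary",
    "Prostate",
    "Skin - Not Sun Exposed (Suprapubic)",
    "Skin - Sun Exposed (Lower leg)",
    "Small Intestine - Terminal Ileum",
    "Spleen",
    "Stomach",
    "Testis",
    "Thyroid",
    "Uterus",
    "Vagina",
    "Whole Blood",
)

#: full 46-tissue atlas: the two adipose depots plus the 44 others
GTEX_TISSUES: tuple[str, ...] = (SUBCUTANEOUS, OMENTAL) + NON_ADIPOSE_TISSUES

_BIOTYPE_MIX = (
    ("protein_coding", 0.55),
    ("lincRNA", 0.15),
    ("antisense", 0.10),
    ("processed_pseudogene", 0.07),
    ("transcribed_unprocessed_pseudogene", 0.05),
    ("snRNA", 0.08),
)

ATLAS_ROLES = ("specific_sub", "specific_om", "specific_both", "enhanced_except1", "enhanced_except2")


@dataclass
class SimConfig:
    """Study-condition parameters for the generators.

    Defaults mirror the scale the pipeline is designed for: a 46-tissue
    atlas with 50 samples per tissue (real per-tissue sample sizes ranged
    from 35 to 560), 20-fold planted depot-specific effects, exception
    tissues planted at a 3-fold depot/exception ratio (below the 5-fold
    call threshold but clearly above parity), and a planted depot |log2FC|
    of 4 for count-level DEGs.
    """

    seed: int                                   # mandatory; every draw flows from it
    n_tissues: int = 46
    samples_per_tissue: int = 50
    n_genes: int = 2000
    n_specific_sub: int = 10
    n_specific_om: int = 10
    n_specific_both: int = 10
    n_enhanced_except1: int = 10
    n_enhanced_except2: int = 10
    baseline_log2_mean: float = 3.0             # baseline TPM ~ 2**N(3, 1)
    baseline_log2_sd: float = 1.0
    dispersion: float = 0.1                     # gamma CV^2 of TPM noise
    specific_fold: float = 20.0                 # depot mean over baseline
    enhanced_exception_fold: float = 3.0        # depot mean over exception-tissue mean
    rin_sub6_fraction: float = 0.05             # samples planted below the RIN cutoff
    # depot count simulation
    n_deg_up_sub: int = 15
    n_deg_up_om: int = 15
    deg_log2fc: float = 4.0
    count_log_mean: float = math.log(500.0)     # baseline counts ~ logN
    count_log_sd: float = 0.8
    nb_dispersion: float = 0.05
    depth_log_sd: float = 0.3                   # per-sample depth factor spread
    # gwas catalog simulation
    gwas_n_records: int = 150
    gwas_overlap_fraction: float = 0.7          # chance a drawn gene is a planted one
    gwas_n_decoy_traits: int = 10

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not 3 <= self.n_tissues <= len(GTEX_TISSUES):
            raise ValueError(f"n_tissues must be in [3, {len(GTEX_TISSUES)}]")
        planted = (
            self.n_specific_sub + self.n_specific_om + self.n_specific_both
            + self.n_enhanced_except1 + self.n_enhanced_except2
        )
        if planted > self.n_genes:
            raise ValueError("planted role counts exceed n_genes")
        if self.n_deg_up_sub + self.n_deg_up_om > self.n_genes:
            raise ValueError("planted DEG counts exceed n_genes")
        for name in ("specific_fold", "enhanced_exception_fold"):
            if getattr(self, name) <= 1:
                raise ValueError(f"{name} must exceed 1")
        if self.deg_log2fc <= 0:
            raise ValueError("deg_log2fc must be positive")

    @property
    def tissues(self) -> list[str]:
        return list(GTEX_TISSUES[: self.n_tissues])


def _gene_ids(n: int, prefix: str = "ENSGS") -> list[str]:
    return [f"{prefix}{i:011d}" for i in range(1, n + 1)]


def _annotation(rng: np.random.Generator, gene_ids: list[str]) -> pd.DataFrame:
    biotypes, weights = zip(*_BIOTYPE_MIX)
    chosen = rng.choice(len(biotypes), size=len(gene_ids), p=np.array(weights) / sum(weights))
    chroms = rng.integers(1, 23, size=len(gene_ids))
    starts = rng.integers(10_000, 10_000_000, size=len(gene_ids))
    lengths = rng.integers(500, 100_000, size=len(gene_ids))
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "symbol": [f"GN{i:05d}" for i in range(1, len(gene_ids) + 1)],
            "biotype": [biotypes[i] for i in chosen],
            "chromosome": [str(c) for c in chroms],
            "start": starts,
            "end": starts + lengths,
            "strand": rng.choice(["+", "-"], size=len(gene_ids)),
        }
    )


def generate_atlas(
    config: SimConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate the multi-tissue TPM atlas with planted specificity roles.

    Returns (expression matrix with tissue labels attached, sample table,
    gene annotation, truth table).  Specific roles multiply the depot
    mean(s) by ``specific_fold``; enhanced roles additionally raise one or
    two randomly chosen non-depot exception tissues to
    ``specific_fold / enhanced_exception_fold`` times baseline, keeping the
    depot/exception ratio below the call threshold while the exception stays
    below the depot.  Bit-reproducible for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    tissues = config.tissues
    non_depot = [t for t in tissues if t not in (SUBCUTANEOUS, OMENTAL)]
    gene_ids = _gene_ids(config.n_genes)
    annotation = _annotation(rng, gene_ids)

    # role assignment over a random permutation of genes
    roles = np.array(["null"] * config.n_genes, dtype=object)
    perm = rng.permutation(config.n_genes)
    counts = [
        ("specific_sub", config.n_specific_sub),
        ("specific_om", config.n_specific_om),
        ("specific_both", config.n_specific_both),
        ("enhanced_except1", config.n_enhanced_except1),
        ("enhanced_except2", config.n_enhanced_except2),
    ]
    cursor = 0
    for role, n in counts:
        roles[perm[cursor:cursor + n]] = role
        cursor += n

    baseline = 2.0 ** rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, config.n_genes)
    means = np.tile(baseline[:, None], (1, len(tissues)))
    t_index = {t: j for j, t in enumerate(tissues)}
    exception_lists: list[list[str]] = [[] for _ in range(config.n_genes)]
    for i in range(config.n_genes):
        role = roles[i]
        if role == "null":
            continue
        if role in ("specific_sub", "specific_both", "enhanced_except1", "enhanced_except2"):
            means[i, t_index[SUBCUTANEOUS]] = baseline[i] * config.specific_fold
        if role in ("specific_om", "specific_both", "enhanced_except1", "enhanced_except2"):
            means[i, t_index[OMENTAL]] = baseline[i] * config.specific_fold
        if role in ("enhanced_except1", "enhanced_except2"):
            n_exc = 1 if role == "enhanced_except1" else 2
            chosen = rng.choice(len(non_depot), size=n_exc, replace=False)
            for j in chosen:
                means[i, t_index[non_depot[j]]] = (
                    baseline[i] * config.specific_fold / config.enhanced_exception_fold
                )
            exception_lists[i] = sorted(non_depot[j] for j in chosen)

    # gamma noise: shape k = 1/dispersion gives CV^2 = dispersion
    shape = 1.0 / config.dispersion
    n_samp = config.samples_per_tissue
    blocks, sample_ids, tissue_of = [], [], {}
    for j, tissue in enumerate(tissues):
        blocks.append(rng.gamma(shape, means[:, j, None] / shape, size=(config.n_genes, n_samp)))
        for k in range(n_samp):
            sid = f"SAMP-{j:02d}-{k:03d}"
            sample_ids.append(sid)
            tissue_of[sid] = tissue
    values = pd.DataFrame(np.concatenate(blocks, axis=1), index=gene_ids, columns=sample_ids)
    values.index.name = "gene_id"

    n_total = len(sample_ids)
    low = rng.random(n_total) < config.rin_sub6_fraction
    rin = np.where(low, rng.uniform(4.0, 5.9, n_total), rng.uniform(6.0, 10.0, n_total))
    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "donor_id": [f"DONOR-{i:05d}" for i in range(n_total)],
            "tissue": [tissue_of[s] for s in sample_ids],
            "rin": np.round(rin, 1),
        }
    )

    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "symbol": annotation["symbol"],
            "role": roles,
            "effect_size": np.where(roles == "null", 1.0, config.specific_fold),
            "exception_tissues": [";".join(e) for e in exception_lists],
        }
    )
    matrix = ExpressionMatrix(values, tissue_of)
    return matrix, samples, annotation, truth


def generate_depot_counts(config: SimConfig) -> tuple[CountMatrix, pd.DataFrame]:
    """Simulate NB read counts for the two depots with planted log2FCs.

    ``deg_up_sub``/``deg_up_om`` genes get the planted |log2FC| split
    symmetrically across the two depot means; per-sample depth factors are
    log-normal so size-factor estimation has real work to do.
    """
    rng = np.random.default_rng(config.seed + 1 if config.seed < 2**31 - 1 else config.seed - 1)
    gene_ids = _gene_ids(config.n_genes, prefix="ENSGC")
    roles = np.array(["null"] * config.n_genes, dtype=object)
    perm = rng.permutation(config.n_genes)
    roles[perm[: config.n_deg_up_sub]] = "deg_up_sub"
    roles[perm[config.n_deg_up_sub: config.n_deg_up_sub + config.n_deg_up_om]] = "deg_up_om"

    baseline = np.exp(rng.normal(config.count_log_mean, config.count_log_sd, config.n_genes))
    half = 2.0 ** (config.deg_log2fc / 2.0)
    mu_sub = baseline * np.where(roles == "deg_up_sub", half, np.where(roles == "deg_up_om", 1 / half, 1.0))
    mu_om = baseline * np.where(roles == "deg_up_om", half, np.where(roles == "deg_up_sub", 1 / half, 1.0))

    n_samp = config.samples_per_tissue
    depth = np.exp(rng.normal(0.0, config.depth_log_sd, 2 * n_samp))
    inv_disp = 1.0 / config.nb_dispersion
    cols, sample_ids, tissue_of = [], [], {}
    for k in range(2 * n_samp):
        depot_mu = mu_sub if k < n_samp else mu_om
        mu = depot_mu * depth[k]
        p = inv_disp / (inv_disp + mu)
        cols.append(rng.negative_binomial(inv_disp, p))
        label = SUBCUTANEOUS if k < n_samp else OMENTAL
        sid = f"CSAMP-{'S' if k < n_samp else 'O'}-{k % n_samp:03d}"
        sample_ids.append(sid)
        tissue_of[sid] = label
    values = pd.DataFrame(np.column_stack(cols), index=gene_ids, columns=sample_ids)
    values.index.name = "gene_id"

    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "role": roles,
            "log2fc": np.where(
                roles == "deg_up_sub", config.deg_log2fc,
                np.where(roles == "deg_up_om", -config.deg_log2fc, 0.0),
            ),
        }
    )
    return CountMatrix(values, tissue_of), truth


def generate_gwas_catalog(
    config: SimConfig, truth: pd.DataFrame, categories: TraitCategoryMap
) -> tuple[list[GWASCatalogRecord], dict[str, set[str]]]:
    """Simulate a miniature GWAS-catalog file plus its ground-truth sets.

    Traits are drawn from the category map and from decoy traits belonging
    to no category; gene symbols come from the planted (non-null) genes with
    probability ``gwas_overlap_fraction``, otherwise from a decoy pool.
    Returns the records together with the per-category gene sets a perfect
    extraction should recover.  (Serialising with
    ``write_gwas_catalog(..., intergenic_every=10)`` additionally exercises
    the intergenic ``"A - B"`` mapped-gene form; it round-trips to the same
    gene sets.)
    """
    if not categories.names:
        raise ValueError("categories must be non-empty")
    rng = np.random.default_rng(config.seed + 2 if config.seed < 2**31 - 2 else config.seed - 2)
    planted = truth.loc[truth["role"] != "null", "symbol"].tolist() if "symbol" in truth else []
    all_traits = [t for traits in categories.categories.values() for t in traits]
    decoy_traits = [f"Unrelated trait {i}" for i in range(1, config.gwas_n_decoy_traits + 1)]
    expected: dict[str, set[str]] = {name: set() for name in categories.names}
    records = []
    for r in range(config.gwas_n_records):
        if all_traits and rng.random() < 0.6:
            trait = all_traits[rng.integers(len(all_traits))]
        else:
            trait = decoy_traits[rng.integers(len(decoy_traits))]
        n_genes = int(rng.integers(1, 4))
        genes = []
        for _ in range(n_genes):
            if planted and rng.random() < config.gwas_overlap_fraction:
                genes.append(planted[rng.integers(len(planted))])
            else:
                genes.append(f"DECOY{rng.integers(1, 200):03d}")
        genes = list(dict.fromkeys(genes))
        reported = genes[:1]
        mapped = genes
        records.append(
            GWASCatalogRecord(
                trait=trait,
                reported_genes=reported,
                mapped_genes=mapped,
                snp_id=f"rs{int(rng.integers(10**6, 10**7))}",
                chromosome=str(int(rng.integers(1, 23))),
                position=int(rng.integers(10**4, 10**8)),
            )
        )
        for cat in categories.categories_of(trait):
            expected[cat].update(genes)
    return records, expected
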