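# Methods

This note documents the models, conventions and design choices behind
`adipoatlas`, in the spirit of the methods documentation of packages like
statsmodels or scanpy: what is computed, under which assumptions, and what
the synthetic validation does and does not demonstrate.

## Sample selection

The atlas is first restricted to samples with RNA integrity number (RIN)
≥ 6.0 (inclusive — RIN is a quality score in [1, 10] and 6.0 is the
conventional usability bar). Tissue labels on a configurable exclusion
list are dropped (defaults: mammary tissue, which is confounded by its fat
content, and cultured/transformed cell lines, which are not tissues).
Finally, whole tissues represented by fewer than 30 distinct donors are
removed, so every per-tissue median rests on a reasonable sample. All
three rules live in `AnalysisConfig` (`min_rin`, `excluded_tissues`,
`min_donors`).

## Expression filter

A gene enters the analysis when, in **at least one tissue**, both hold:

* ≥ 20% of that tissue's samples exceed 0.1 TPM, and
* the tissue median is strictly above 0.5 TPM.

The any-tissue reading is the permissive one: it cannot drop a gene that is
genuinely expressed in adipose tissue just because it is silent elsewhere.
Note that with these defaults the fraction condition is implied by the
median condition (a median above 0.5 forces ≥ 50% of samples above 0.1);
it becomes binding only when the floors are reconfigured.

## Specificity model

Per-tissue medians use the standard even-*n* convention (mean of the two
central order statistics). For a depot *A* and gene *g*:

* **Pairwise fold** against each non-adipose tissue *j*:
  `fold(j) = median_A / median_j`, with `+inf` when `median_j = 0 <
  median_A` (absence elsewhere is maximal specificity) and `0` when
  `median_A = 0`.
* **Pairwise test**: Welch two-sample *t* on `log2(TPM + 1)` between the
  depot's samples and tissue *j*'s samples, one p-value per gene, BH
  adjustment across genes **within each contrast** (the criterion is an
  FDR per depot-vs-*j* comparison, not a global one). Zero-variance
  degenerate groups get p = 1 when the means are equal and p = 0 otherwise,
  which makes constant fixtures deterministic.
* **Call**: a tissue *passes* when `fold > 5` (strict) and `q < 0.01`.
  Zero failing tissues → `specific_all`; one or two failing tissues whose
  medians all stay strictly below the depot median → `enhanced_except1/2`;
  anything else, including an exception tissue that out-expresses the
  depot, yields no call.
* **Relative median value** `r = median_A / mean(non-depot medians)` is the
  reported specificity score. Both adipose depots are excluded from the
  denominator, consistent with the pairwise criterion ranging only over
  non-adipose tissues. `r` is scale-invariant; conventions `inf` (0
  denominator, positive numerator) and `0` (both zero) handle silent genes.

A Welch *t* was chosen over a moderated/empirical-Bayes linear-model fit:
with ≥ 30 samples per group (guaranteed by the donor rule) per-gene
variance moderation changes little, the test is robust to the unequal
group variances typical across tissues, and its behaviour is easy to
validate against planted truth. This is a documented divergence from
moderated-ANOVA machinery; the package's claims are about the
classification criteria, not about reproducing any specific fitter's
p-values bit-for-bit.

## Depot differential expression

Counts are normalized with median-of-ratios size factors: the reference is
the geometric mean of each gene's counts across samples (genes with any
zero count are excluded from the reference), and a sample's factor is the
median of its count/reference ratios. Size factors are defined up to a
common constant; all statements about them are relative.

The per-gene statistic is `log2fc = log2((mean_sub + 1) / (mean_om + 1))`
on normalized counts (pseudocount ε = 1, configurable, so depot-exclusive
genes stay finite), with a Welch *t* on `log2(normalized + 1)` and BH
across all genes. DEGs satisfy `|log2fc| > 3` (strict; an inclusive `>=`
comparator is available via `deg_lfc_comparator="ge"`) and `q < 0.01`.
The Welch-on-log-counts test replaces a negative-binomial Wald fit for the
same reasons as above — at n = 50 per depot and |log2FC| > 3 the criteria,
not the likelihood, do the work — and planted-truth recovery validates the
combination. Dispersion-trend fitting and fold-change shrinkage are out of
scope.

Biotype grouping collapses Ensembl biotypes to five classes:
`protein_coding`, `lincRNA`, any biotype containing the substring
"pseudogene", `antisense`, and `other`.

## GWAS integration

Trait matching is **exact** on case-folded, whitespace-collapsed trait
strings against the configured category lists — substring or fuzzy
matching would silently inflate categories. A matching catalog record
contributes the union of its author-reported and positionally-mapped gene
symbols; symbols are compared case-insensitively, with no synonym
expansion (symbol aliasing would drag in an external dependency and make
results snapshot-dependent). Intergenic mapped-gene entries
(`"GENE1 - GENE2"`) keep both flanking genes; the `NR` / `intergenic` /
empty tokens denote "no gene".

Counting reports distinct genes per category (a gene may count in several
categories) plus a histogram of how many categories each gene hits. The
packaged 14-gene worked example (`adipoatlas.datasets`) exercises exactly
this logic: 4 obesity, 7 blood-lipids, 2 type-2-diabetes and 4
inflammation genes, 13 of the 14 in exactly one category, with a 2/5/7
subcutaneous/omental/both depot split.

Over-representation uses the hypergeometric upper tail `P(X ≥ k)` with the
gene set intersected with the universe first, BH across sets, FDR < 0.05.
Pathway content (GMT) is an input, never bundled, to stay database-version
independent.

## HOX depot map

The 39 human HOX genes sit in four clusters (A: 11 genes, B: 10, C: 9,
D: 9) with paralog numbers 1–13. The map orders entries cluster-major,
paralog-ascending, and reports `log2(median TPM + 1)` per depot plus a
differential flag at q < 0.01 from the depot count test adjusted across
**all** genes — deliberately with *no* fold-change threshold, since the
point of the map is consistent depot bias in low-expressed developmental
regulators, not large effects. Genes absent from the matrix are emitted
with missing-value markers so the map shape is always determined by the
annotation. The annotation is user-replaceable, so synthetic pseudo-genes
can exercise the machinery.

## Synthetic data generator

The generator emulates the *statistical shape* of the study inputs at desk
scale, with defaults chosen once as the reference study conditions:

| parameter | default | rationale |
|---|---|---|
| tissues | 46 (2 depots + 44) | the atlas tissue panel, GTEx labels |
| samples/tissue | 50 | inside the real 35–560 per-tissue range |
| genes | 2,000 | enough nulls to measure a 1% false-call rate |
| planted roles | 10 per role | specific sub/om/both, enhanced ±1/±2 |
| TPM noise | gamma, CV² = 0.1 | heavier than Poisson, right skew |
| specific fold | 20 | comfortably above the 5-fold call bar |
| exception fold | 3 | depot/exception ratio below 5 but above 1, mirroring enhanced genes whose exception tissue sits at ~26% of the depot median |
| depot counts | NB, dispersion 0.05, baseline ~ logN(ln 500, 0.8) | typical bulk count overdispersion; baseline high enough that the ε = 1 pseudocount does not bias planted log2FC = 4 recovery |
| depth factors | logN(0, 0.3) | exercises size-factor estimation |
| RIN | 5% of samples below 6.0 | exercises sample selection |

TPM values are drawn directly from a gamma distribution per gene × tissue
mean (the specificity stages consume TPM, so simulating read counts and
lengths would add machinery without adding test power); genuine
negative-binomial counts are generated only for the depot comparison,
which is the stage that consumes counts. Enhanced roles are planted in
both depots with their exception tissues raised to
`specific_fold / exception_fold` × baseline.

**What passing tests show** — that the classification criteria, threshold
conventions, normalization and bookkeeping are implemented correctly and
recover planted effects of the stated sizes at the stated sample sizes.
**What they do not show** — performance on real GTEx data, where
donor-level correlation across tissues, batch structure, heavy-tailed
expression and annotation noise exist and are deliberately not modelled,
and where the published headline gene counts depend on the full ~10,000
sample matrix and a specific GWAS-catalog snapshot.

## Numerical conventions

* BH step-up is `q(i) = min_{k ≥ rank(i)} p(k)·m/k`, capped at 1,
  order-preserving; validated against both a literal O(m²) oracle and
  statsmodels.
* Real numbers serialize with 6 significant digits — beyond TPM precision,
  stable for diffs; all output tables are fully sorted so identical inputs
  give byte-identical files.
* Gene id version suffixes (`ENSG….N`) are stripped at ingest; every join
  is on versionless ids, since atlas and annotation releases disagree on
  versions.
* The acceptance/demo problem sizes (2,000-gene atlas, 1,000-gene count
  matrices, 20 null replicates) are the package's reference validation
  scale: large enough to measure a 1% false-positive bound with useful
  precision, small enough to run in seconds.

## Known limitations

* Symbol-based GWAS matching misses renamed genes and aliases by design.
* The expression filter's any-tissue rule is the permissive reading of an
  ambiguous criterion; a stricter adipose-only variant is a one-line
  config change away (`filter` operates per tissue already).
* The Welch tests assume approximate normality of log-expression within a
  tissue; for tiny groups (< 5 samples) the q-values are only indicative,
  though the donor rule prevents such groups in practice.
* No LD-aware locus assignment: a GWAS hit is linked to a gene purely via
  the catalog's reported/mapped columns.
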