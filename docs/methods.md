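# Methods

## Data model

The unit of observation is a (cell barcode, SNV locus) pair with two read
counts: `N_VAR` (reads carrying the alternate allele) and `N_REF` (reads
carrying the reference allele). The expressed variant allele fraction is
`VAF_RNA = N_VAR / (N_VAR + N_REF)`, defined only when the denominator is
at least 1. Every entry of the cells × SNVs matrix is in exactly one of
four allelic states, a pure function of the two counts:

| state | condition | VAF |
|---|---|---|
| `no_coverage` | N_VAR = N_REF = 0 | undefined |
| `ref_only` | N_VAR = 0, N_REF ≥ 1 | 0 |
| `var_only` | N_VAR ≥ 1, N_REF = 0 | 1 |
| `biallelic` | both ≥ 1 | (0, 1) |

The distinction between `ref_only` (locus expressed, variant absent —
negative signal) and `no_coverage` (locus not expressed — no signal) is
preserved end to end: unobserved entries are structural zeros plus an
explicit boolean layer, never a sentinel count; undefined VAFs serialize
as empty fields, never as 0 or the text "NaN"; and plots draw no-signal
cells in a reserved grey outside every color gradient.

Positions are 1-based throughout. Multiallelic sites are distinct loci
(same chrom:pos, different alt) because VAF is allele-specific. Duplicate
(SNV, barcode) input rows are an error by default (`dedup_policy="sum"`
opts into aggregation), since duplicates normally indicate an upstream
fault. Input rows with both counts zero are dropped on load and tallied.

## Filters

Two SNV-level filters, applied in a fixed order:

1. **depth** — entries with `N_VAR + N_REF < min_depth` become unobserved
   (counts zeroed);
2. **cell support** — SNVs observed in fewer than `min_cells_per_snv`
   cells are dropped as columns.

Depth runs first so that an entry failing the depth requirement does not
count toward an SNV's cell support. Thresholds use strict "fewer than"
semantics (support exactly at the threshold is kept). Filtering is
monotone and idempotent, and never removes cells — cell-level QC belongs
to the expression pipeline. Defaults are permissive (0/0); typical
working values are `min_cells_per_snv=20`, `min_depth=3`. The depth
filter is per-entry, not per-SNV-mean: a per-entry rule is the only one
that keeps the observed layer a pure function of the retained counts.

## Per-cell metrics

Over a selected SNV set, each cell reports:

* `n_snvs` — loci with `N_VAR ≥ 1`. "Expressed SNV" means the variant
  allele was seen; ref-only loci are covered but count as negative
  signal, not as an expressed SNV.
* `total_nvar`, `total_nref` — summed counts.
* `total_vaf` — pooled fraction Σ N_VAR / Σ (N_VAR + N_REF) over covered
  selected loci; a read-weighted mean, hence always within the range of
  the per-locus VAFs.
* `mean_vaf`, `median_vaf` — unweighted mean/median of per-locus VAFs
  over **covered** loci, explicitly including VAF = 0 loci. Excluding
  negative signal would bias these toward 1 and erase the core
  distinction.

All three ratios are undefined (NaN) exactly when the cell covers no
selected locus. Medians of even counts are the mean of the two central
values. Group summaries (per cluster, cell type, sample) report n, mean,
median and IQR per metric over the cells where the metric is defined,
plus histogram counts: VAF metrics use 50 fixed bins on [0, 1] with the
final bin right-closed (the numpy convention); count metrics use
integer-aligned edges from 0 to the next bin-width multiple above the
observed maximum.

The per-cell-across-SNVs and per-SNV-across-cells readings of "mean/
median VAF" are both available: the former in `CellMetrics`, the latter
in `SNVProfile`.

## Origin classification

The underlying patterns are qualitative; this package makes them
operational with explicit thresholds, all recorded in `OriginThresholds`
and all settable from the CLI. Rules run in fixed order **hom → het →
somatic → rna**, most to least constrained, first match wins; SNVs
covered in fewer than `min_cells_covered` (default 10) cells stay
`unclassified` regardless of pattern. With fractions taken over covered
cells and "carrier" meaning state ∈ {var_only, biallelic}:

| label | rule (defaults) |
|---|---|
| `germline_hom` | var-only fraction ≥ 0.95 **and** mean VAF ≥ 0.95 |
| `germline_het` | biallelic fraction ≥ 0.2 **and** median VAF ∈ [0.35, 0.65] |
| `somatic_like` | carrier fraction ∈ [0.05, 0.5] **and** median VAF among carriers ≥ 0.2 |
| `rna_origin_like` | median VAF < 0.2 **and** median N_VAR among carriers ≤ 2 |

The defaults encode: homozygous ≈ monoallelic variant expression in
essentially all expressing cells; heterozygous ≈ substantial biallelic
expression centered near 0.5; somatic ≈ a minority-but-nonnegligible cell
subset with transcription-consistent carrier VAF; RNA-origin ≈ sporadic
one-or-two-read variant signal on a reference background.

**Random monoallelic expression** is an orthogonal boolean flag, not a
fifth label, because it co-occurs with germline heterozygosity (an
X-inactivated het locus is both). A locus is flagged when biallelic cells
are ≤ 10% of covered cells and the var-only : ref-only cell ratio lies in
[1/3, 3] (both tallies ≥ 1) — per-cell exclusive expression of one
allele, split roughly evenly between alleles. Below the coverage gate the
flag is undefined (None), not False. X-inactivation and transcriptional
bursting produce the same signature at this level, so the flag names
neither mechanism.

Known overlap: a low-rate RNA-origin locus whose carrier fraction drifts
above 5% and whose carrier VAF is not far below the somatic floor can
match the somatic rule first; on the default synthetic world this costs
part of the rna class (macro recall stays above the 0.9 target). The rule
order is deliberate and documented rather than hidden.

## Embedding and clustering pipeline

A fixed, self-contained, seeded workflow over raw counts (scanpy
backend): library-size normalization to 10,000 counts per cell → log1p →
top 2,000 variable genes (dispersion-based) → per-gene standardization →
PCA to 30 components → 15-nearest-neighbor graph → Leiden communities at
resolution 1.0 → UMAP (and/or t-SNE, PCA) in 2 and 3 dimensions. Every
stochastic step takes the same seed, and equal seeds give bit-identical
coordinates. Requesting more PCs than cells is an error; below ~50 cells
a warning is emitted.

**Transposed SNV matrix.** For SNV clustering, cells act as features.
Each SNV's feature vector is the concatenation of its per-cell VAFs
(unobserved entries encoded as 0) with its per-cell observed indicator,
so the clustering can still tell "no signal" from "negative signal" (a
ref-only cell contributes VAF 0 with indicator 1; an uncovered cell,
VAF 0 with indicator 0). PCA → kNN → Leiden → 2-D UMAP follow. The SNV
graph has tens of nodes, not thousands, and modularity at resolution 1.0
over-partitions graphs that small, so `cluster_snvs` defaults to
resolution 0.3 (planted hom/het separation is stable across 0.1–0.5);
the cell pipeline keeps 1.0. Both are caller-settable.

**Integration.** Multiple samples are embedded jointly by intersecting
genes, concatenating counts under `sampleid_`-prefixed barcodes, and
standardizing each gene within each sample before the joint PCA. This
per-sample standardization is a deliberately simple, fully specified
substitute for anchor/CCA-style batch correction: it removes per-sample
location/scale differences per gene but not nonlinear batch structure,
and it is what the integration tests establish — no more.

## Synthetic data generator

The generator states a world and keeps it fixed. Defaults: 300 cells,
500 genes, 3 expression groups, SNV locus coverage λ = 5 reads/cell,
50 SNVs per class, seed-deterministic throughout.

* **Cells** draw a log-normal size factor (σ = 0.35, mean 1) shared
  between the expression and SNV layers — the only coupling between the
  two, since no gene↔SNV mapping is assumed.
* **Expression** is gamma-Poisson (negative binomial, dispersion
  θ = 10) around log-normal baseline gene means; each group elevates its
  own disjoint block of 60 marker genes 4-fold, emulating distinct cell
  types of moderate, realistic separation.
* **SNV depth** per cell is Poisson(λ · size factor); depth-0 entries
  are omitted from the table, creating genuine no-signal loci. Given
  depth D, the variant count is: het — Binomial(D, 0.5); hom — D;
  somatic — Binomial(D, 0.5) within a planted subclone of cell fraction
  f = 0.2, zero elsewhere (a somatic mutation is one allele of two, so
  carriers are heterozygous); rna — Binomial(D, e = 0.02) in all cells;
  bursting — a fair per-cell coin picks one allele, all reads from it.

What a green recovery test establishes: the classifier and the
transposed-matrix clustering recover these idealized patterns at
realistic coverage. What it does not: robustness to allele-preferential
expression, allele-specific dropout, ambient RNA, doublets, CNV-driven
VAF shifts, or alignment artifacts — none of which are modeled.

## Numerical and serialization choices

* Undefined ratios are NaN in memory, empty fields on disk; metric TSVs
  round-trip exactly (counts as integers, ratios via `%.17g`).
* Table equality is order-insensitive (a table is a set of records).
* Barcode harmonization ("auto") strips a trailing `-<digits>` suffix
  only when the raw intersection is empty, and warns when the overlap
  covers less than half of either side.
* The interactive HTML documents embed their full data as a JSON block
  (`<script type="application/json" id="cellsnv-data">`) with one point
  per cell in the active view; the inline renderer is display-only, so
  all guarantees are checked against the JSON, and static PNG snapshots
  are re-rendered from the same block. The reserved no-signal grey
  `#bdbdbd` cannot be produced by either gradient (both have unequal RGB
  channels away from their white endpoints).
* Count-metric color scales are linear on [0, observed max] with an
  optional log10(1+x) toggle; VAF scales are fixed to [0, 1] with the
  bichromatic gradient's white midpoint at 0.5.

## Limitations

* Origin calls are heuristic pattern matches, not genotype likelihoods;
  they carry no posterior probabilities and no multiple-testing control.
* The somatic/rna boundary depends on carrier fraction and carrier VAF
  thresholds; loci near the boundary are ambiguous by construction.
* No phasing, no haplotype grouping, no annotation database lookups, no
  BAM/VCF parsing: the package starts from per-cell count tables.
* t-SNE coordinates are 2-D only; 3-D interactive views rely on UMAP or
  PCA.
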