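# Methods

## Scope and model

The package implements the computational core of an early-embryo
chromatin study at desk scale: spike-normalized chromatin-mark signal,
cross-stage ambivalent-state calling, single-cell multiome
preprocessing and statistics, background-matched peak-to-gene linkage,
and the RNAPII pausing index — together with a synthetic-data layer
that plants each effect so the estimators can be tested for recovery.
All genomic arithmetic is 0-based half-open; signal tracks are
fixed-bin (default 10 bp) mean densities per chromosome.

## Normalization model

A library's lambda spike-in read count is proportional to sequencing
depth because every library receives the same spike-in mass.  The
depth factor is `K / n_lambda` with K = 10⁶ chosen as an arbitrary
common scale (a library with 10⁶ lambda reads has factor 1).  The
starting-material factor uses the paired total-H3 control: after spike
normalization an H3 library's genome read count is proportional to the
nuclei in its pool, so

    correction(sample) = [sf(H3_ref) · reads(H3_ref)] / [sf(H3_sample) · reads(H3_sample)],

with the first wild-type H3 sample as the default reference.  Both
factors are applied at the track level; peak quantification integrates
the normalized density over ±1 kb around the peak **midpoint** (the
flank convention is ambiguous between edges and center; midpoint keeps
the window length constant across peak widths).  Scale equivariance
(scaling track, genome reads and lambda reads together is a no-op) and
the two confounder-removal identities are tested exactly.

## Ambivalent states

Peak sets from all stages are merged into connected components of the
overlap graph.  Book-ended half-open intervals (`[a,b)`, `[b,c)`)
share no base and are **not** merged.  Per stage, a unified peak is
`ambivalent` if it shares ≥ 1 bp with both an me3 and an ac peak;
any-overlap rather than reciprocal-fraction overlap is used since only
"overlap" is specified by the classification rule.  An optional
exclusion list (e.g. H3K9me3 intervals, for antibody cross-reaction)
can be subtracted from a mark's peak set before classification.
Transition tables count peaks per (state, state) pair between stages;
marginals reproduce the per-stage counts by construction.  Peak-to-
gene assignment uses strict distance-to-TSS < 10 kb, 0 if the TSS lies
inside the peak.

## Multiome statistics

RNA: log1p of counts-per-10k.  ATAC: log TF-IDF,
`ln(1 + tf · idf · 10⁴)` with `tf = c_ij / colsum_j` and
`idf = n_cells / n_cells_detecting_i`.  QC keeps cells with ≥ 300
counts, ≥ 200 detected genes and ≤ 20% mitochondrial counts (the
discard rules are strict inequalities, so boundary cells are kept).

HVG selection standardizes each gene with its own mean but a **trend**
sd — the median gene variance of its mean-expression rank bin — clips
standardized values at √n_cells and ranks genes by the variance of the
clipped values.  Standardizing by each gene's own sd would make every
variance exactly 1; the robust binned-median trend is what lets
genuinely overdispersed genes stand out while a handful of variable
genes cannot drag the trend up.

Signature scores follow the binned-control scheme: genes are binned by
mean expression (25 bins, clamped to n_genes/4 for small universes so
every signature bin retains non-signature controls), `n_ctrl` = 50
controls are drawn per occupied bin with a seeded generator, and the
score is the signature mean minus the pooled-control mean per cell.

Differential expression is a per-gene two-sided Mann–Whitney test
between cell groups with BH adjustment; genes detected in < 1% of
cells of *either* compared group are excluded (the exclusion rule
names "any condition"; per-compared-group is the reading adopted).
log2FC compares mean `expm1` back-transformed expression with a 10⁻⁹
pseudocount.  The rank-sum statistic enumerates the exact permutation
distribution when the smaller group has ≤ 10 observations (ties
handled by permuting midranks; an enumeration-size cap avoids
combinatorial blow-up against huge complements) and otherwise uses the
tie- and continuity-corrected normal approximation.  BH is the step-up
procedure with running-minimum monotonicity.  Both are cross-checked
against scipy and statsmodels in the tests.

The gene identity score defines each gene's primary germ layer as the
argmax of mean wild-type expression over layers (ties break by layer
name) and reports, within any queried genotype, the fraction of the
gene's expressing (count > 0) cells found in that layer.  The score is
invariant to cell order and expression scale; genes with zero
expressing cells are reported missing.

## Peak-to-gene linkage

For each gene and each peak whose interval lies within the window
(default ±20 kb) of its TSS, Pearson r is computed across cells
between log TF-IDF accessibility and log-normalized expression.  The
null for a candidate peak is the set of correlations between the same
gene and the candidate's `n_background` = 200 nearest neighbours in
standardized (GC content, mean accessibility, log width) space,
excluding the candidate; z = (r − mean)/sd of that null and p is the
one-sided upper tail — positive regulation is the alternative, and
negative links are retained in the table but never chosen as
enhancers.  k-NN matching (rather than bin sampling) is this
package's choice of background mechanism; it is deterministic, so the
calibration rests on the matched covariates, which is verified
empirically: with expression independent of accessibility the
fraction of candidates passing p < 0.05 is ≈ 5%.

Promoter assignment: most accessible peak (mean over the designated
cells, typically WT) overlapping TSS ± 500 bp; ties break to the
smaller peak id.  Enhancer assignment: among links with p < 0.05 and
r > 0 within ±20 kb, excluding peaks overlapping the promoter window,
the maximal-r peak — a function of the link table only.  Genes missing
either element are excluded from the correlation contrasts, so the
promoter and enhancer distributions cover the same genes.

## Pausing index

PI = mean density over TSS ± 300 bp divided by mean density over
300–5000 bp downstream, strand-aware (on the minus strand the body
runs in decreasing coordinates).  Mean density rather than summed
signal is used so the unequal window lengths (600 vs 4700 bp) compare
as enrichment, and PI is invariant to global track rescaling.  Genes
shorter than the body window are truncated at the gene end and flagged
`short_gene`; zero-body genes are reported missing rather than
infinite, keeping rank tests well-defined.  Condition comparisons
report per gene set the two-sided Mann–Whitney p and median(KD)/
median(WT).

## Synthetic data: what it emulates, and what it does not

The genome is a single chromosome with one gene per 50 kb slot
(alternating strand, 8 kb body), which guarantees every peak of a gene
lies inside its own ±20 kb linkage window and outside every
neighbour's.  Per gene: a promoter peak (TSS ± 200 bp) open in every
cell with probability 0.8 independent of expression; an enhancer peak
6 kb upstream open with probability 0.8 in the gene's own germ layer
and 0.05 elsewhere; and noise peaks with cell-type-independent
accessibility.  ATAC counts are Bernoulli-gated shifted-Poisson
(mean 1.5) so open peaks carry ≥ 1 fragment.  RNA counts are
negative-binomial (gamma–Poisson) with dispersion 0.3 — typical
droplet overdispersion — and mean 1 × (1 + effect) in cells whose
enhancer copy is open, default effect 2.0.  5% of genes are labelled
mitochondrial (flat mean 2, no peaks) so the QC filter is
exercisable.  A knockdown mode lets each marker activate in
`n_leak_layers` extra layers with per-cell probability `leak_rate`,
emulating de-confined expression.

Mark libraries assign each of 2·n_genes peaks exactly one of
{me3, ac, none} per cell type; a `mark_discordance_rate` fraction is
split between the two marks across cell types.  Raw tracks are
*expected* (noise-free) coverage scaled by depth × nuclei per sample;
lambda reads scale with depth only and H3 controls cover all peaks for
all cell types.  Noise-free tracks make the normalization identities
exact, which is what the invariance checks assert; Poisson sampling
would only blur a property that holds in expectation.  S5P tracks
plant per-bin mean 20 over the body and ratio × 20 over the promoter
window, Poisson-sampled by default with a noise-off switch for
machine-precision oracle checks.

Not emulated: read-level artifacts (no FASTQ/alignment), doublets,
batch effects, genome-wide transcriptome size, chromatin co-variation
beyond the planted enhancers, and real peak-width/GC distributions.
Passing tests therefore demonstrate correctness of the estimators
under the assumed generative structure, not robustness to the full
noise spectrum of real libraries.

## Problem sizes and defaults

The shipped analyses run at desk scale: 100–500 genes, 300–1200
cells, 200–2500 peaks, 10 bp bins — sizes at which the brute-force
per-bp oracles in the test suite are feasible and the whole suite
plus the acceptance script complete in seconds.  The demo pipeline
keeps every analysis threshold at its standard default but rescales
the two cell-QC minima (30 counts, 10 genes) because the simulated
transcriptome has ~10² genes rather than genome-wide coverage; runs
on real data should restore 300/200 via the config file.

## Known limitations

- The linkage null is normal-approximate; with very few background
  peaks the z-scores are noisy and `sd = 0` nulls are flagged rather
  than tested.
- `transitions` requires identical peak universes; peaks absent at a
  stage are a single `unassigned` state rather than a separate
  "absent" category.
- The H3 correction anchors to a declared reference sample; absolute
  signal units are therefore relative to that reference.
- Exact rank-sum enumeration is capped (smaller group ≤ 10 and ≤ 5·10⁵
  combinations); beyond that the tie-corrected normal approximation is
  used.
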