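# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices and the known limitations of `crossleaf`.

## The partitioning model

Pseudobulk samples are formed by summing raw counts over cells within each
(cell type × time × batch) group (groups below `min_cells` cells are
dropped). Size factors are DESeq-style median-of-ratios over genes with a
finite geometric mean, falling back to total-count ratios for zero-heavy
matrices.

Per gene the partitioning test fits a negative-binomial GLM with log link
and offset log(size factor):

- full model: `count ~ 1 + cell_type + time_h`
- reduced model: `count ~ 1 + time_h`

and compares them by a likelihood-ratio test against χ²(1). The reported
log2 fold change is the cell-type coefficient divided by log 2, oriented so
positive values favour the first cell type of the pair. The "ANCOVA"
framing — cell-type membership tested while controlling for time — is
realized **without** a cell-type×time interaction: an interaction would
change the question from "is the gene partitioned" to "does its light
response differ", which the light-response module addresses separately. A
dark-only variant restricts to 0 h samples and tests `~ cell_type` against
the intercept-only model across replicate batches.

Dispersion (variance μ + αμ²) is estimated per gene by method of moments
from full-model Poisson fitted means, α̂ = Σ[(y−μ̂)² − μ̂]/Σμ̂², floored at
1e−8, then shrunk halfway toward the across-gene mean (a deliberately
simplified stand-in for empirical-Bayes trend shrinkage; weight 0.5). The
GLM itself is fitted by IRLS with a fixed dispersion; the fits are verified
against statsmodels' NB GLM in the test suite (coefficients and
log-likelihood to 1e−5), and the LRT is checked to agree with the Wald test
at large n. Non-converged genes are flagged with p set to 1. Calibration:
on null simulations (500 genes × 20 seeds) the pooled rejection rate at
nominal 0.05 falls in [0.03, 0.07] and the p-values pass a KS uniformity
test.

Markers are one-vs-rest Wilcoxon rank-sum tests on log-normalized
expression (counts scaled to the median per-cell total, log1p), BH
adjusted, with filters on pct-in-cluster and "expression specificity",
interpreted as the in-cluster/out-of-cluster ratio of mean normalized
expression (the source protocol does not define it; ∞ is reported when the
gene is silent outside the cluster).

## Cross-species comparison

Gene sets are compared through orthogroups; one-to-many relationships are
kept ("orthogroup" mode) or collapsed deterministically to the
lexicographically smallest partner ("one-to-one" mode — a fixed tie-break
rather than an arbitrary retention). Overlap significance is the one-sided
hypergeometric (= one-sided Fisher) test with the total number of
orthogroups in the map as the universe. Classification of orthologue pairs
significant in both species uses fold-change signs oriented to
mesophyll-positive; orthogroups whose member pairs disagree form a separate
"complex" bucket. Marker-conservation percentages are floored to integers
for display (31/229 → 13), with the raw fraction always reported; the
any-orthogroup-member rule is used because higher-order orthology is
retained. Cell-type similarity uses −log10 of the overlap p, and each
species-B cell type is matched to the argmax species-A cell type.

## Motif scanning and enrichment

PWMs are position probability matrices with a per-cell pseudocount
(default ε = 0.01) applied before column normalization. Scores are log2
odds against the background (uniform by default). For exact p-value
thresholds the log-odds are rounded onto an integer grid of 1,000 steps
spanning the score range, and the null distribution of the window score is
computed by dynamic programming over positions with background base
probabilities — exact up to the discretization, and verified in tests
against exhaustive 4^w enumeration for w ≤ 8. The threshold is the smallest
score whose upper tail does not exceed the per-position p (0.005 for
DOF-site counting, matching the quantification protocol; 1e−4 for
enrichment hit calling, the FIMO-default order, because presence/absence
hits at 0.005 would saturate few-hundred-bp peaks). Both strands are
scanned (reverse-complemented matrix on the forward sequence); windows
containing N are skipped; overlapping hits all count.

DOF-site counting assigns each peak overlapping [TSS−1,500, TSS+1,500) to
the TSS closest to its midpoint (ties → lexicographically smaller gene) and
sums hits per gene. The cross-species excess test is a one-sided sign test
over orthologue pairs with ties dropped — the pairing unit and tie handling
are design choices, as the source protocol names only a binomial p.

Enrichment follows the permutation-rank protocol: per permutation a
background set matched on GC deciles × length quartiles is sampled without
replacement from non-foreground peaks (2× the foreground size per stratum;
under-filled strata relax to the nearest stratum with a warning), per-motif
hypergeometric enrichment of peaks-with-hit is computed, motifs are ranked
within the permutation (average ranks on ties), and ranks are averaged over
B = 100 permutations. A motif's significance across permutations is
summarized by the median BH-adjusted p; the top-25 cross-species overlap
restricts to motifs with median adjusted p < 0.05 and tests the overlap
against the full library as universe. Accessibility matching is
approximated by GC + length strata, since raw fragment counts are not part
of this module's contract.

## Chromatin

Peak→gene assignment first trims peaks with extreme total accessibility at
the 2.5th/97.5th percentiles (the "around 5% outliers" removal is otherwise
undefined; the trim quantiles are configurable), then keeps for each gene
the candidate within ±2,000 bp of the gene body with the highest total
accessibility (ties → closest to the TSS → smallest peak id; the selection
rule is a documented choice, as only "one peak per gene" is specified).
Accessibility profiles are min-max normalized to [0,1]; constant vectors
map to zeros and are flagged. Group comparisons are Welch unequal-variance
t-tests with the one-sided direction declared by the caller. Differential
peaks use one-vs-rest rank-sum tests on per-cell fragment counts with a
fraction-accessible threshold. Peak–gene links are Pearson correlations
across matched pseudobulk samples against a seeded permutation null
(≥1,000 label permutations, two-sided, +1 correction), BH adjusted within
gene — a permutation null is exact at this scale and needs no genome-wide
GC-matched background.

## Light response

Within one cell type, pseudobulk profiles are log-normalized and
gene-centred; PC1/PC2 sample scores come from the SVD, with each PC's sign
fixed so the largest-|loading| gene loads positively (determinism). Genes
are regressed on each PC score and on time (slope t-tests), and an NB LRT
contrasts 0 h vs 12 h; each source is BH-adjusted separately and a gene is
light-responsive if significant in any source (a union, by construction).
The regression-on-PC-scores reading was chosen over using PCs as design
covariates — the protocol text is ambiguous — because it is calibrated and
directly interpretable as "follows the dominant temporal trend".
Trend clustering z-scales per-gene profiles, applies complete-linkage
hierarchical clustering on Euclidean distance (linkage and metric fixed by
choice; unstated in the source), cuts at the smallest cluster count giving
≥ target_k clusters of ≥ min_size = 10 genes, merges smaller clusters into
the nearest large centroid, and smooths each cluster mean by lowess.

## The synthetic-data generator

The generator emulates a paired two-species de-etiolation atlas at desk
scale; its defaults are the study conditions of the test suite:

- 300 genes per species; 6 cell types (mesophyll, bundle sheath, guard,
  epidermis, phloem, xylem); time points 0/6/12 h; 50 cells per cell type
  and time; 2 batches.
- NB counts, mean/dispersion parameterization with shared dispersion
  α = 0.1 and baseline mean 1 count/cell; per-cell log-normal(0, 0.2)
  size factors force downstream normalization.
- 20% of orthogroups consistently and 15% differentially partitioned at
  |log2FC| = 2, applied ±fc/2 symmetrically to mesophyll and bundle sheath;
  differential genes favour mesophyll in species A and bundle sheath in
  species B. One-to-many orthology rows at a 10% rate (classes are planted
  on one-to-one orthogroups).
- 10 markers per cell type at +3 log2, half conserved cross-species; 20% of
  genes light-responsive at ±0.15 log2/h, slope signs shared between
  orthologues.
- One toy chromosome per species; one TSS per gene every 4 kb; a proximal
  peak (±500 bp jitter around the TSS) per gene plus a distal peak
  (>1,500 bp from the TSS) for every fifth gene; 300-bp peaks; i.i.d.
  sequence at GC 0.45.
- Planted motif: the 8-bp DOF-like consensus `CAAAGCTC` (AAAG core with
  fixed flanks — long enough that chance occurrences in 300-bp peaks are
  rare, so planted-recovery and rank tests are sharp), inserted as the
  exact consensus (deterministic scanner recovery) at Poisson rate 2.0 per
  foreground peak (promoter peaks of genes differentially partitioned
  toward the species-B bundle sheath) and 0.2 elsewhere.
- Per-cell peak fragment counts are Poisson with rate
  0.1 + 0.4·log2(1 + mean expression of the assigned gene in the cell's
  group), so accessibility correlates positively with expression by
  construction.

Identical configs (same seed) produce byte-identical serialized outputs.
What the generator does **not** emulate: ambient RNA, doublets, UMI
saturation, empty droplets, gene-length or mappability biases,
gene-specific dispersions, correlated gene programs, realistic promoter
architecture or motif syntax. Passing tests therefore demonstrate
correctness and calibration of the statistical machinery under the stated
generative model, not performance on real atlases.

## Numerical choices and degenerate inputs

- IRLS: linear predictor clipped to ±30, convergence on relative
  log-likelihood change < 1e−12, 100 iterations max; singular weighted
  normal equations or non-finite likelihoods flag the gene (p = 1).
- BH adjustment via statsmodels `multipletests`.
- All-zero genes are excluded from partition tests and reported; clusters
  with <3 cells are skipped in marker detection; peaks accessible in zero
  cells are skipped in differential accessibility.
- Welch test with zero variance in both groups and equal means returns
  one-sided p = 0.5; empty marker sets give overlap p = 1.
- Coordinates are 0-based half-open everywhere (BED convention); strands
  are stored explicitly; unicode minus in strand columns is accepted.
- Seeds: the expression, per-species and landscape streams derive from the
  config seed via `SeedSequence` spawns, so species A and B are independent
  but jointly reproducible.

## Problem sizes

Defaults throughout target desk-scale validation: simulations of 100–500
genes, ≤ 900 cells per species, 10-motif scanning libraries, 100
enrichment permutations and 1,000 linkage permutations. These sizes give
every calibration and recovery test adequate resolution while keeping the
full suite and the acceptance script to a few minutes on one CPU.

## Known limitations

- The dispersion shrinkage is a fixed 50/50 blend, not empirical Bayes;
  very low sample counts per group will under- or over-shrink.
- The enrichment statistic is presence/absence per peak, not hit counts;
  motifs with many weak sites in long peaks are treated the same as single
  strong sites.
- The permutation null for peak–gene links floors at 1/(B+1); very small
  p-values are censored accordingly.
- One-to-one orthologue collapse by lexicographic order is deterministic
  but biologically arbitrary; orthogroup mode is preferred for inference.
- Atlas-scale headline counts from real data (hundreds of
  partitioned orthologues, genome-wide peak sets) are out of desk-scale
  reach; the pipeline validates the machinery on synthetic truth instead.
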