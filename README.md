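# crossleaf

Cross-species single-nucleus comparison of gene-expression **partitioning**
between mesophyll (M) and bundle-sheath (BS) leaf cells, and of the
*cis*-regulatory code behind it.

In C3 grasses (e.g. rice) photosynthesis runs in the mesophyll; C4 grasses
(e.g. sorghum) have repurposed the bundle sheath. Comparing single-nucleus
expression and chromatin-accessibility atlases of a C3 and a C4 species asks,
per orthologue: is the gene preferentially expressed in the same cell type in
both species (*consistently partitioned*), or has it swapped cell types
(*differentially partitioned*) — and did swapped genes acquire cell-identity
cis-elements, in particular DOF-family binding sites (core consensus `AAAG`),
in their accessible promoter regions?

`crossleaf` implements this analysis as a tested, reusable pipeline, together
with a two-species synthetic-data generator with known ground truth, so that
every statistical stage can be validated end-to-end.

## What it computes

- **Partitioning test** — per gene, a negative-binomial GLM likelihood-ratio
  test on pseudobulk counts: full model `count ~ cell_type + time` against
  reduced `count ~ time` (log link, log size-factor offset, χ²(1)),
  Benjamini–Hochberg adjusted. A dark-only (0 h) variant drops the time
  covariate.
- **Cross-species classification** — orthologue pairs significant in both
  species are classified by fold-change sign: same sign ⇒ consistent,
  opposite ⇒ differential (`sign(log2FC_A) · sign(log2FC_B)`); orthogroups
  with disagreeing members are reported as complex. Overlaps between
  orthogroup sets use the one-sided Fisher/hypergeometric test with the full
  orthogroup universe as background.
- **Marker conservation and cell-type similarity** — one-vs-rest Wilcoxon
  markers per cell type; a species-A marker is conserved when any orthogroup
  member is a same-cell-type marker in species B (e.g. 184/426 → 43%,
  31/229 → 13%); cell types are matched across species by −log10 overlap p.
- **Motif machinery** — JASPAR PFM parsing; log2-odds PWM scanning with
  *exact* p-value thresholds from a dynamic-programming null (DOF-site
  counting uses p ≤ 0.005 in peaks within ±1,500 bp of the TSS); a paired
  one-sided sign test for cross-species excess of sites; GC- and
  length-matched background enrichment with 100-permutation rank averaging;
  top-25 cross-species motif-set overlap.
- **Chromatin** — one peak per gene within ±2,000 bp of the gene body
  (extreme-total outliers trimmed, ≈5%), 0–1 min-max accessibility
  renormalization, one-sided Welch t-tests, one-vs-rest differential peaks,
  and permutation-based peak–gene expression linkage.
- **Light response** — per-cell-type pseudobulk differential expression as a
  union of PC1/PC2-score regressions, linear-in-time regression and an NB
  pairwise 0 h vs 12 h contrast, followed by hierarchical trend clustering
  (clusters of ≥10 genes).

## Worked example

```python
from crossleaf.simulate import SimConfig, simulate_expression
from crossleaf.partition import pseudobulk, partition_test
from crossleaf.orthology import classify_partitioning

cfg = SimConfig(seed=1, n_genes_per_species=300, cells_per_type_per_time=100)
adata_a, adata_b, orthology, truth = simulate_expression(cfg)

records = {}
for name, adata in [("rice-like", adata_a), ("sorghum-like", adata_b)]:
    pb = pseudobulk(adata, min_cells=3)
    recs, _ = partition_test(pb, "mesophyll", "bundle_sheath", alpha=0.05)
    records[name] = recs
    n_sig = sum(r.padj < 0.05 for r in recs)
    print(f"{name}: {n_sig} of {len(recs)} genes partitioned (adjusted p < 0.05)")

classes, report = classify_partitioning(
    records["rice-like"], records["sorghum-like"], orthology, alpha=0.05)
n_cons = sum(r.klass == "consistent" for r in classes)
n_diff = sum(r.klass == "differential" for r in classes)
print(f"consistent: {n_cons}, differential: {n_diff}, "
      f"complex orthogroups: {report['n_complex']}")
```

prints

```
rice-like: 144 of 300 genes partitioned (adjusted p < 0.05)
sorghum-like: 140 of 300 genes partitioned (adjusted p < 0.05)
consistent: 67, differential: 47, complex orthogroups: 0
```

The simulation planted 20% consistently and 15% differentially partitioned
orthogroups at |log2FC| = 2 on 300 genes; the test recovers them (the
remaining significant genes at this sample size are the planted ones — null
genes reject at ≈5%), and the sign rule classifies the doubly significant
pairs into the two categories.

There is also a CLI:

```bash
crossleaf simulate --seed 1 --outdir sim/           # write MTX/BED/FASTA/TSV + truth.json
crossleaf partition --counts sim/species_a.mtx --pair mesophyll,bundle_sheath --out part.tsv
crossleaf run --seed 1 --outdir run/                # all stages + report.json
```

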