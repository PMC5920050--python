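# lncmm

Analysis toolkit for long non-coding RNA (lncRNA) expression compendia in
multiple myeloma (MM)-style bulk RNA-seq cohorts.

MM is a plasma-cell malignancy stratified into molecular subgroups by
recurrent lesions — hyperdiploidy (HD), the IGH translocations t(11;14),
t(4;14) and MAF-family translocations, copy-number lesions (del(13),
del(17), 1q gain) and somatic mutations (NRAS/KRAS/BRAF, DIS3, ...).
Given a gene annotation (GTF), a fragment-count matrix (featureCounts
style), a per-sample molecular-annotation table and a list of anchor
"MM genes", `lncmm` runs the complete downstream analysis:

1. **Annotation** — select lncRNA genes by GENCODE biotype (lincRNA,
   antisense, bidirectional_promoter_lncRNA, sense_intronic,
   sense_overlapping, 3prime_overlapping_ncRNA), flag genes whose spans
   overlap another gene (ambiguous quantification), resolve anchor symbols.
2. **Expression** — detectability filter (total count > 0), FPKM from
   counts and gene lengths, descriptive summaries.
3. **Differential expression** — a negative-binomial one-vs-rest model per
   molecular subgroup: median-of-ratios size factors `s_j`, per-gene
   dispersion `α` in `Var = μ + αμ²` (method of moments with a fitted
   `a₀ + a₁/μ` trend, conservative max), and a Wald test on
   `log2FC = log2((q̄₊ + ε)/(q̄₋ + ε))` with delta-method standard errors;
   Benjamini–Hochberg FDR (default 0.01) defines the up/down signatures.
4. **Unsupervised analysis** — top-500 genes by coefficient of variation,
   hierarchical clustering of samples under the 1 − Pearson distance
   (centroid or average linkage), per-branch Fisher exact tests and a
   stratified (Cochran–Mantel–Haenszel) chi-squared association test with
   permutation-calibrated p-values.
5. **Cis-pair discovery** — lncRNAs within 4 Mb (edge to edge) of an anchor
   gene, Pearson correlation of log2(FPKM+1) profiles, the |r| > 0.4 and
   p < 0.01 filter, and annotation with the DE signatures.
6. **Cross-platform validation** — per-gene agreement with an independent
   normalized (array-style) matrix and re-clustering on it.
7. **Simulation** — a fully synthetic cohort generator (NB counts, planted
   subgroup fold changes, latent-factor cis-correlations, controlled
   genomic geometry, exact published cohort frequencies) with truth tables,
   so every stage is testable offline.

The differential-expression core follows the statsmodels idiom: a model
object (`NBDifferential`) whose `fit()` returns a results object with the
estimates, standard errors, p/q-values and a `summary()` table.

## Worked example

```python
from lncmm import (SimulationConfig, simulate, filter_expressed,
                   contrasts_from_cohort, NBDifferential)

ds = simulate(SimulationConfig(seed=7))          # synthetic 30-patient cohort
lnc_ids = [r.gene_id for r in ds.annotation if r.is_lncRNA]
lnc = filter_expressed(ds.counts.subset_genes(lnc_ids))
hd = [c for c in contrasts_from_cohort(ds.cohort) if c.name == "HD"][0]
res = NBDifferential(lnc, hd).fit(fdr=0.01)
print(res.summary(top=5))
```

prints

```
NB one-vs-rest differential expression
======================================================
Contrast:        HD (8 vs 20 samples)
Genes tested:    1478
FDR threshold:   0.01
Significant:     15 up, 10 down

Top 5 genes by Wald statistic magnitude:
gene                  baseMean   log2FC    stat    pvalue      padj  dir
SIML000233              136.17     2.31    5.00  5.72e-07  5.69e-04  UP
SIML000248              119.80    -2.30   -4.91  9.28e-07  5.69e-04  DW
SIML000225              132.94     2.21    4.79  1.66e-06  5.69e-04  UP
SIML000224              164.57     2.21    4.79  1.68e-06  5.69e-04  UP
SIML000232              168.49     2.18    4.72  2.35e-06  5.69e-04  UP
```

The cohort carries 30 planted HD-specific lncRNAs at ±4-fold; 25 are called
at FDR < 0.01 here, all with the planted sign: `baseMean` is the mean
normalized count, `stat` the Wald statistic (positive = up in HD), `padj`
the BH-adjusted p-value.

The same cohort can be driven end to end from the shell:

```sh
lncmm simulate --seed 7 --out data/
lncmm config-template > cfg.yaml   # edit paths, then:
lncmm run --config cfg.yaml
```

which writes per-contrast DE tables, the signature union, the dendrogram
(Newick), the association report, the cis-pair table and a content-hash
manifest under the output directory.

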