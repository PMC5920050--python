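# Methods

This note documents the models, numerical choices and limitations of
`lncmm`. All empirical statements below are reproduced by the test suite or
by `scripts/acceptance.py`.

## Annotation model

Genes are the unit of analysis (one record per `gene` feature of a
GENCODE-dialect GTF; transcript/isoform structure is out of scope).
Coordinates are 1-based inclusive as read; Ensembl version suffixes are
stripped from gene ids so RNA-seq and array annotations join on stable
identifiers; chromosome names are compared with any leading `chr` removed
but emitted as read. Both `gene_type` (GENCODE) and `gene_biotype`
(Ensembl) attribute keys are accepted.

"Ambiguous" quantification is defined at gene level: a gene is flagged when
its span intersects any other gene's span on the same chromosome,
strand-agnostically, and both members of an overlapping pair are flagged.
This is a conservative, testable stand-in for probe/transcript-level
ambiguity rules; the pipeline by default excludes flagged lncRNAs.

## Expression

"Detectable" means a positive total fragment count over all samples; no
abundance threshold beyond that is applied, because scarcely expressed
lncRNAs can still be biologically meaningful in cis. FPKM is computed from
counts and gene lengths, `FPKM = counts · 10⁹ / (length · library size)`;
this equals isoform-aware FPKM only for single-isoform genes, which is
accepted as the contract here. Correlation and clustering operate on
`log2(FPKM + 1)` by default (counts are dominated by library size, raw
FPKM by expression magnitude).

## Negative-binomial differential expression

One-vs-rest contrasts per molecular feature; samples with unknown (NA)
status are excluded from both sides (no imputation), and features with
fewer than 3 positive samples are not tested (the cohort design leaves
groups of 1–2 samples for some mutations, too small for a group
comparison). A pooled "MAPK" contrast unites NRAS/KRAS/BRAF-mutated
samples.

* **Normalization** — median-of-ratios size factors over genes positive in
  every sample, rescaled to geometric mean 1. The median is taken on the
  linear ratio scale (with an even reference-gene count this differs from
  the log-scale median by the averaging of the two central values).
* **Dispersion** — per-gene method-of-moments `α̂ = max(0, (s² − μ̄)/μ̄²)` on
  normalized counts, estimated within each side of the contrast and pooled
  with degree-of-freedom weights (so real group differences do not inflate
  it); a trend `α(μ) = a₀ + a₁/μ` is least-squares fitted to the positive
  raw estimates; the working value is the conservative
  `max(α̂, trend(μ̄))`.
* **Wald test** — `log2FC = log2((q̄₊ + ε)/(q̄₋ + ε))` with ε = 0.5
  normalized pseudo-counts (configurable). The variance of each group mean
  propagates `Var(K/s) = q/s + αq²` through the log by the delta method,
  with the variance evaluated at `q̄ + ε`: a group observed at zero still
  carries sampling variance. Without this, genes seen only in one group
  get a zero plug-in variance on the other side and the far p-tail
  inflates roughly tenfold, breaking FDR control. The p-value is two-sided
  normal; genes all-zero in the used samples get p = 1.
* **FDR** — Benjamini–Hochberg step-up with the monotonicity pass; the
  signature of a contrast is the set of genes with q below the threshold
  (default 0.01), split by fold-change sign.

Calibration, measured by the acceptance suite: null type-I error
0.05 ± 0.02 at the 5% level on no-effect NB cohorts with detectable
expression (means log-normal(ln 50, 1.0)); realized FDR within nominal +
0.02 at 0.01 and 0.05 on 2,000-gene signal-plus-null cohorts. Known
limitation: for genes with near-zero counts the ε-offset variance makes
the test deliberately conservative — p-values for such genes are honest
but not uniform under the null.

## Unsupervised analysis

Feature selection ranks genes by the coefficient of variation (sd/mean) of
FPKM, ties broken lexicographically, top 500 by default. The selected
genes' `log2(FPKM+1)` values are z-scored per gene before clustering.

Samples are clustered agglomeratively under `d = 1 − r` (Pearson across
the selected genes). Centroid linkage — the protocol's stated choice — is
applied through the Lance–Williams update on squared distances; on a
correlation distance this is geometrically ill-posed and can produce
inversions, so average linkage (UPGMA) is also provided and is the default
in the pipeline and tests. Merging is exactly deterministic: equal
distances merge the pair with the lowest creation-order indices, and no
randomness is used. `cut(k)` undoes the last k−1 merges.

Association of a k-cut with a molecular feature uses (a) per-cluster 2×2
two-sided Fisher exact tests (in/out of cluster × feature ±, NA excluded)
and (b) a stratified chi-squared across features, one stratum per feature
built from the cluster with the largest standardized positive enrichment.
The stratified statistic uses the Cochran variance `r₁r₂c₁c₂/n³`, so a
single stratum reduces exactly to the ordinary 1-df Pearson chi-squared.
Because each feature's stratum is *selected* to maximize enrichment, the
chi-squared reference distribution is anti-conservative (permuted labels
rejected at ~10× nominal in our checks); the reported p is therefore
calibrated by permuting each feature's labels and re-running the selection
(20,000 permutations from a fixed internal stream, p floor 1/(B+1) ≈
5·10⁻⁵). The standalone `mantel_haenszel` function, used when the strata
are given a priori, keeps the classical chi-squared reference and is
calibrated as such.

## Cis-pair discovery

Candidates are (anchor gene, lncRNA) pairs on the same chromosome whose
spans lie within 4 Mb edge to edge (overlap = distance 0; strand ignored),
found with an interval index and verified against a brute-force scan in
tests. Pearson r over samples on `log2(FPKM+1)`; p two-sided from
`t = r√(n−2)/√(1−r²)` with n−2 df (|r| = 1 ⇒ p = 0). The filter keeps
|r| > 0.4 and p < 0.01, both strict, without multiple-testing correction
(an optional BH mode is deliberately off by default to match the published
selection procedure); surviving pairs are annotated with the signature
membership of their lncRNA. The packaged reference table of 43 published
pairs ships as `lncmm/data/reference_cispairs.tsv`; one row's p prints as
0.00 in the source and is stored as 0.0 with a flag note, and one row
(p = 0.023) exceeds the stated p < 0.01 criterion, so tests treat the
table as a self-consistency fixture rather than a filter oracle.

## Cross-platform validation

The array matrix is consumed as already normalized (RMA and probe
annotation are upstream concerns). Gene pairing is by shared identifier;
per-gene Pearson r is computed across shared samples between
`log2(FPKM+1)` and the array values; clustering + association re-run on
the signature-restricted array matrix, with normal-control samples carried
as extra columns flagged `control`.

## Synthetic cohort generator

The generator emits the statistical structure the analysis assumes, and is
a pure function of its integer seed (three independent sub-streams for
annotation, cohort, counts/array).

* **Cohort** — 30 samples; the published feature frequencies are
  reproduced *exactly* (e.g. HD 8 positive / 20 negative / 2 NA). The four
  primary subgroups (HD 8, t(11;14) 8, t(4;14) 7, MAF-trx 4) occupy
  disjoint sample blocks; secondary lesions/mutations are assigned at
  random subject to their exact counts.
* **Genome** — every anchor gene sits in its own locus block, separated
  from all other blocks by more than the 4 Mb window, so the true
  candidate-pair set is exactly the planted (20, ρ = 0.8) plus null
  (200, ρ = 0) pairs; pair gaps are drawn in [50 kb, 3.9 Mb] or set
  explicitly and are recoverable from the emitted coordinates.
* **Counts** — `NB(mean = s_j · μ_g · 2^(Δ + L), α(μ_g) = a₀ + a₁/μ_g)`
  with a₀ = 0.05, a₁ = 1 and log-normal size factors (σ = 0.3). Baseline
  lncRNA means are log-normal(0.7, 1.8), matching the published scarcity
  profile (median total count ≈ 57 across 30 samples, ~90% of means < 30).
  Planted subgroup effects Δ = ±2 (4-fold) on 30 lncRNAs per subgroup with
  means log-normal(ln 100, 0.5).
* **Cis-correlation** — pair members share a per-sample Gaussian factor on
  the log2 scale; the shared/independent variance split adds the NB
  measurement variance `(1/μ + α)/ln²2` analytically so the *realized*
  Pearson r on `log2(FPKM+1)` hits the requested ρ (mean sample r 0.80 at
  ρ = 0.8 over replicates). Pair members are highly expressed
  (log-normal(ln 500, 0.5)) to keep the measurement term small.
* **Array** — per-gene affine transform of `log2(FPKM+1)` (slope
  U(0.5, 1.5), intercept U(−2, 2)) plus N(0, 0.5) noise on a randomly
  detectable 67% gene subset, with 4 control samples generated from the
  no-lesion expression state.

What the generator does **not** emulate: co-occurring lesions within a
patient, correlated gene–gene background structure beyond the planted
pairs, isoform structure, GC/length biases, batch effects, and real
lncRNA–target biology. Passing tests therefore demonstrate the pipeline's
statistical behaviour under its own model assumptions, not performance on
GEO-scale real cohorts; the published cohort-level tallies (9,540
detectable lncRNAs, 391-gene signature union, etc.) require the deposited
data and annotation and are out of desk-scale scope.

## Benchmark conditions (fixed in `lncmm.benchmarks`)

* *DE recovery* — default cohort with constant dispersion α = 0.05
  (a₀ = 0.05, a₁ = 0) and the planted 4-fold changes: ≥ 80% of planted
  lncRNAs recovered at FDR 0.01 with ≤ 5 false positives per run
  (measured ≈ 100% and ≈ 1).
* *Cis-pair screen* — default cohort: ≥ 16/20 planted and ≤ 6/200 null
  pairs pass the filter (measured 20/20 and ≈ 1.6).
* *Clustering* — strong-effect condition: 16-fold changes on 50 scarce
  lncRNAs per subgroup (means log-normal(ln 10, 0.8)), mirroring the very
  large test statistics at low base means that real subgroup markers show.
  Under the default 4-fold/30-gene condition the informative genes do not
  reach the top-500 CV list (scarce noise genes dominate count-scale CV),
  so subgroup recovery is only expected at strong effect sizes. Adjusted
  Rand index is computed over the 27 samples that belong to one of the
  four subgroups; measured ≈ 1.0.
* *Problem sizes* — 2,000 genes × 30 samples per simulated cohort; 10–20
  seeds per benchmark. These sizes keep the whole suite and the
  reproduction script in the minutes range while leaving the measured
  rates stable.
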