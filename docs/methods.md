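# Methods

## Data model and coordinates

Genotypes are unphased allele-pair strings (`"AG"` ≡ `"GA"`, `"00"`
missing) with per-SNP annotation (chromosome, 1-based position, allele
pair, risk allele). Additive dosage is the count of risk-allele copies
in the call, so `β_SNP` is a per-risk-allele effect and a positive sign
means expression increases with the risk allele. Expression is a probes
× samples matrix of log2 intensities with per-probe gene, chromosome and
start coordinates. Missing genotypes are handled pairwise-complete:
samples missing a SNP are dropped only from that SNP's tests, the way
array eQTL pipelines maximize n.

## Sex inference

*From genotypes.* For each sample, over its non-missing X-chromosome
SNPs, `F = 1 − O_het/E_het` with `E_het = Σ 2p_i(1−p_i)`; allele
frequencies come from female samples when known, otherwise from all
samples (unbiased either way because hemizygous male calls are written
as homozygotes and contribute a single allele counted twice). Thresholds
are the genotype-QC conventions `F > 0.8` male, `F < 0.2` female,
ambiguous between; both are configurable. At least 20 informative X
SNPs are required per sample; with ~1,000 X SNPs (the generator default,
small relative to a real array's X content) the female F distribution
has SD ≈ 0.04, so misclassification is vanishingly rare.
Pseudoautosomal SNPs must be excluded from the X list upstream — they
are heterozygous in males and bias F downward.

*From expression.* Y non-recombining-region genes are expressed only in
males, so Y probes that vary across a mixed-sex cohort vary because of
sex. Probes with cross-sample coefficient of variation above the 25th
percentile of Y-probe CVs are retained; samples are clustered by 1-D
2-means on their mean retained-Y expression with deterministic
initialization at the two extremes (order-independent, no RNG), and the
higher-centroid cluster is called male.

*Reconciliation.* A final sex is assigned only when both calls agree;
anything else is reported and excluded by the pipeline default. On
generator output the two calls agree with truth on 100% of samples
across seeds, which validates the machinery — it does not bound error
rates on real arrays, where intensity artifacts, XXY/X0 karyotypes and
sample swaps produce genuinely ambiguous samples.

## Detection cutoff and normalization

Because Y genes are silent in females, a Y probe's female mean estimates
pure array background. Candidate Y probes are ranked by male-to-female
mean ratio; within the top fraction (default 0.5, tie-inclusive: ratios
at or above the lower-interpolated median survive, so a two-candidate
set keeps both) the probe with the *highest* female mean is chosen and
its female mean is the cutoff — a deliberately conservative background
estimate. Probes with ≥ 20% of samples strictly below the cutoff are
excluded; the boundary is inclusive (exactly 20% drops the probe).
Filtering applies after sex reconciliation, on the retained samples.
Surviving probes are z-scored per probe across all retained samples,
both sexes pooled, using the population SD (divisor n; the choice only
rescales coefficients, never t or p, but must be fixed for
reproducibility). Effects are therefore in expression-SD units.

## Additive cis scan

Windows are closed intervals: a probe belongs to a seed SNP's window
when it is on the same chromosome and `|probe_start − snp_pos| ≤ 1 Mb`
(probe start is the single-point reduction of gene position; the window
size is configurable). Each pair is fitted by OLS of z-scored expression
on `(1, dosage, sex)` and the dosage coefficient tested two-sided.
Pairs are testable only if dosage is polymorphic and every genotype
class present has ≥ 3 samples (`min_genotype_count`, configurable) —
this is also how sparse-allele regions are kept out of the analysis.
BH FDR is computed once over all pairs of the scan (one family, as a
single restricted-pair eQTL run would produce); a per-window family is
available but not the default. Trans associations are out of scope.

## SNP×sex interaction test

The full model `(1, dosage, sex, dosage·sex)` is fitted by OLS;
`beta_int` is the interaction coefficient, with two-sided t-tests on all
four terms. A cross-over interaction (slopes of opposite sign per sex)
appears as `|beta_int|` near the slope difference, and per-sex
stratified fits (`stratified_fit`) expose the directions.

The permutation null shuffles the genotype vector of each SNP across
samples — expression and sex stay linked, so the sex–expression
relationship is preserved while both the SNP main effect and the
interaction are destroyed. This follows the analysis convention the
model targets; it is conservative for pairs with strong main effects
(the permuted |t*| distribution is computed under "no SNP effect at
all"). One shuffle per SNP per permutation is shared across that SNP's
probes, preserving cross-probe correlation; independent-per-pair
shuffles can be had by building separate nulls. The default is 10,000
permutations; the implementation batches the per-permutation 4×4 normal
equations, so nulls for hundreds of pairs cost seconds.

Permutation p-values use the add-one estimator
`(1 + #{|t*| ≥ |t_obs|})/(1 + n_perm)`, bounded below by
`1/(n_perm+1)`. The permutation FDR at threshold c is
`π₀ · median_b #{|t*_b| ≥ c} / max(1, #{|t_obs| ≥ c})`, clipped to
[0, 1] and made monotone non-increasing in c (q-value-style reverse
cumulative minimum over thresholds). π₀ is the Storey–Tibshirani
quantile estimate at λ = 0.5 on the per-pair permutation p-values,
floored at 1/m. With very small families the median permuted tail count
at a stringent threshold is often exactly 0, giving FDR estimates of 0;
this is inherent to median-count FDRs and is why the pipeline's
significance flag requires *both* perm_p and perm_fdr below α (default
0.05).

LD between SNPs is the composite r²: the squared Pearson correlation of
additive dosages on pairwise-complete samples. It is symmetric,
invariant to allele-label flips (dosage → 2 − dosage), and requires no
phase information; haplotype-based D′/r² is out of scope.

## Synthetic cohorts

The generator encodes the study conditions the analysis assumes:
287 samples (125 males, 162 females), unit residual SD on the log2
scale, HWE autosomal genotypes at stated MAFs with the risk allele as
the minor allele, X SNPs HWE in females and hemizygous-as-homozygous in
males, and Y marker probes at background (5.0) in females and background
+ 6 noise SDs in males (the > 4σ separation guarantees exact Y-based
bipartition). Expression follows
`baseline + noise_sd·(β_SNP·d + β_sex·s + β_int·d·s) + N(0, noise_sd²)`
with `baseline = 8.0` (a mid-range log2 intensity, comfortably above the
Y-derived cutoff) and effects in expression-SD units. Everything is
driven by one integer seed; identical configs give bit-identical
matrices and files.

What the generator deliberately omits: LD structure between autosomal
SNPs (beyond explicit perfect-proxy copies), probe-specific variances,
batch and array effects, non-Gaussian noise, age or ancestry structure,
and genuinely ambiguous sexes. Passing tests therefore demonstrate the
estimators and the permutation machinery are correct under the model's
own assumptions — not robustness to real-array artifacts.

Note on scales: planted effects enter before z-scoring, so pipeline
estimates are attenuated by the factor total-SD/noise-SD of the probe
(≈ 8% for a lone β_int = 0.66 at MAF 0.3–0.45). Parameter-recovery
checks therefore fit the model on the generator's raw scale, where OLS
is unbiased for the planted value; the worked example shows the
attenuated pipeline-scale estimate.

## Validation experiment sizes

The test suite and `scripts/acceptance.py` use: 1,000 random instances
(n 30–300) for OLS oracle equivalence against statsmodels; 200
replicates at n = 287 for recovery of β_int = 0.66 (mean within 0.05,
95% CI coverage in [0.92, 0.97]); 1,000 all-null pairs for type-I error
([0.03, 0.07] at α = 0.05); 50 seeds × 500 pairs × 1,000 permutations
for permutation-FDR calibration (null discovery proportion ≤ 0.075);
50 seeded cohorts for sex-inference concordance; and 100 seeds for
perfect-proxy confirmation. Calibration cohorts draw MAFs in
[0.2, 0.5] so every genotype class clears the min-count rule at
n = 287 and all planned pairs are actually testable. Proxy confirmation
is scored as concordance — a seed fails only if the causal SNP's
interaction is permutation-significant and its r² = 1 proxy's is not —
mirroring how proxy SNPs are used to corroborate already-significant
hits; the proxy experiment plants β_int = 0.66 at MAF 0.45 so the
causal interaction is detectable in most seeds.

## Known limitations

- The F-statistic thresholds and the Y-probe CV quantile are
  conventions, not fitted quantities; unusual karyotypes will surface as
  "unresolved" rather than being classified.
- The genotype-only permutation null is conservative in the presence of
  strong SNP main effects; a residual-permutation scheme would be
  exchangeability-exact but is not what this analysis specifies.
- Median-count permutation FDRs are coarse for families of fewer than
  ~20 pairs; rely on perm_p there.
- Windowing uses probe start positions; probes far from their gene's
  TSS can enter or leave windows relative to a TSS-based definition.
- No support for binary array formats (IDAT, PLINK bed, VCF); inputs
  must be converted to the documented TSVs upstream.
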