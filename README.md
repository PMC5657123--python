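# sexqtl

Sex-aware cis-eQTL mapping for genotyped expression cohorts.

Many disease-associated SNPs are expression quantitative trait loci
(eQTLs) whose effects depend on biological context. For autoimmune
diseases with strong female bias (e.g. systemic lupus erythematosus and
primary Sjögren's syndrome), a natural question is whether risk SNPs
regulate nearby genes *differently in males and females*. `sexqtl`
implements that analysis end to end for cohorts with array genotypes and
log2 expression data:

1. **Dual sex inference** — per-sample X-chromosome inbreeding
   coefficient `F = 1 − O_het/E_het` (F > 0.8 male, F < 0.2 female) and,
   independently, 2-means clustering of samples on high-variance
   Y-chromosome probe expression; samples where the two calls disagree
   are excluded.
2. **Detection filtering** — the expression cutoff is the female mean of
   the Y-gene probe with the highest female signal among the top
   male-to-female ratio probes (Y genes are silent in females, so this
   estimates array background); probes with ≥ 20% of samples below the
   cutoff are dropped, and the rest are z-scored per probe.
3. **Additive cis scan** — for each seed SNP, every probe within a closed
   ±1 Mb window is tested with OLS

   `expression ~ β₀ + β_SNP·dosage + β_sex·sex`

   where dosage counts risk-allele copies (0/1/2) and sex is 0 (male) /
   1 (female); Benjamini–Hochberg FDR is pooled over the scan.
4. **SNP×sex interaction scan** —

   `expression ~ β₀ + β_SNP·dosage + β_sex·sex + β_int·dosage·sex`

   where `β_int` measures how the per-allele effect differs in females.
   Significance uses a genotype-permutation null (each SNP's genotype
   vector shuffled, default 10,000 times, shared across that SNP's
   probes) with add-one permutation p-values and a SAMseq-style
   permutation FDR (median permuted tail counts, Storey–Tibshirani π₀ at
   λ = 0.5).
5. **Proxy confirmation** — composite-LD r² between dosage vectors, so
   significant interactions can be re-tested with proxy SNPs in high LD.

A seeded synthetic-cohort generator (`sexqtl.synthdata`) reproduces the
statistical structure the analysis assumes — HWE genotypes, male X
hemizygosity, male-restricted Y-probe expression, and the linear
interaction model — so the whole pipeline is testable without any
access-controlled cohort.

## Worked example

Simulate a 287-sample cohort (125 males, 162 females) with two seed SNPs
and a planted SNP×sex interaction of 0.66 SD on the SLC39A8 probe, then
run the full pipeline:

```python
import sexqtl
from sexqtl import pipeline

paths = pipeline.make_fixture(sexqtl.default_config(seed=42), "fx")
cfg = pipeline.RunConfig(
    genotypes=str(paths["genotypes"]),
    snp_annotation=str(paths["snp_annotation"]),
    expression=str(paths["expression"]),
    probe_annotation=str(paths["probe_annotation"]),
    out_dir="fx/out", n_perm=10_000, seed=1)
out = pipeline.run_pipeline(cfg)
print(sexqtl.read_results(out / "interaction_results.tsv").head(3))
```

The run log reports perfect sex inference and the Y-anchored cutoff:

```
sex inference: 125 male, 162 female, 0 unresolved (excluded)
filtering: cutoff 5.0541 (probe ILMN_Y00003, gene DDX3Y); kept 9/15 probes
interaction scan: 7 pairs tested, 0 untestable, 10000 permutations
```

and the planted interaction pair tops the interaction table:

```
      snp        probe    gene    p_snp    p_sex    p_int  beta_int   perm_p  perm_fdr
rs4637409 ILMN_4000001 SLC39A8 0.415003 0.293896 0.000279  0.610160 0.000400  0.000000
rs7574865 ILMN_2000003  NULL2A 0.231264 0.405104 0.039538 -0.435879 0.039096  0.000000
```

`beta_int = 0.61` estimates the planted 0.66 (slightly attenuated by
z-scoring, see `docs/methods.md`); its permutation p of 4×10⁻⁴ means
only 3 of 10,000 genotype shuffles produced as extreme an interaction
|t|. The additive scan likewise recovers the planted per-allele effect
on INPP1 (`beta = 0.51, FDR = 4×10⁻⁶`).

The same pipeline runs from the shell:

```bash
sexqtl simulate --config synth.yaml --out fx/
sexqtl run --config run.yaml
sexqtl ld --genotypes fx/genotypes.tsv --snp-annotation fx/snp_annotation.tsv \
          --a rs7574865 --b rs4637409
```

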