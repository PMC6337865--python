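# ovimpute

Evaluation pipeline for **whole-genome-sequence (WGS) imputation accuracy in
multi-breed livestock populations** — and for what imputation quality does to
downstream genomic prediction.

Sequencing a reference population and imputing array-genotyped animals up to
sequence is now the standard route to WGS genotypes in breeding programs.
Before the imputed variants are trusted in association studies or genomic
prediction, three questions need quantitative answers:

1. **How accurate is the imputation?** — measured per variant as the Pearson
   correlation `r` between imputed and true genotypes across held-out
   individuals in a masking/cross-validation design, stratified by minor
   allele frequency, genomic position (1-Mb windows), and annotation class.
2. **Can poorly imputed variants be recognised without truth data?** — via
   the model-free dosage-variance quality statistic
   `R² = Var(d) / (p̂(1−p̂))` over the per-haplotype imputed dosages `d`
   (poor imputation shrinks dosages towards the allele frequency `p̂`,
   deflating the ratio), and threshold policies `thr4` (`R² > 0.4`) and
   `thr8` (`R² > 0.8`).
3. **Does imputation quality matter downstream?** — by drawing allele-
   frequency-matched variant sets from quality strata and comparing genomic
   heritability and GEBV accuracy from a BayesR fit
   (SNP effects ~ mixture of N(0, γ_k σ²_g), γ = (0, 10⁻⁴, 10⁻³, 10⁻²),
   Gibbs sampling), with accuracy = cor(GEBV, y)/√h² and its standard error
   over replicate sets.

The imputation engine is a haplotype-copying (Li–Stephens) HMM: a target
haplotype typed only at array positions is modelled as an imperfect mosaic
of reference haplotypes, with recombination switches between adjacent sites
(`P(stay) = exp(−λ·d)` in map distance) and allele-mismatch emissions (ε).
Forward–backward posteriors yield per-haplotype allele dosages in [0, 1],
per-individual dosages in [0, 2], and most-likely genotypes.

Everything runs on synthetic populations from the built-in generator
(ancestral haplotype pool → per-breed bottlenecks → recombination-mosaic
descent, with young breed-private mutations, SNP-array ascertainment,
annotation labels, low-fidelity regions, and heritable phenotypes), so the
whole pipeline is testable end-to-end on one CPU with no downloads.  See
`docs/methods.md` for the model details and the limits of what the
synthetic data can show.

## Worked example

```python
from ovimpute import (default_config, simulate_population, ascertain_nested_panels,
                      make_fold_plan, cross_validate_impute, per_variant_accuracy,
                      apply_threshold, stratified_summary)

cfg = default_config(seed=1)                    # 235 animals, 3 breeds + F1, 100k variants
panel = simulate_population(cfg)
arrays = ascertain_nested_panels(panel, cfg.array_sizes,
                                 maf_floor=cfg.array_maf_floor, seed=2)
plan = make_fold_plan(panel.individual_ids, k=5, seed=3)
mer = [i for i, b in zip(panel.individual_ids, panel.breed_labels) if b == "MER"]
imputed = cross_validate_impute(panel, arrays["HD"], plan, target_ids=mer)
acc = per_variant_accuracy(imputed, panel, plan, use_dosage=False)

scorable = acc[acc["excluded_reason"] == "none"]
print(f"scorable variants: {len(scorable)}")
for pol in ("thr0", "thr4", "thr8"):
    kept, n, _ = apply_threshold(acc, pol)
    print(f"{pol}: mean accuracy {kept['empirical_r'].mean():.3f} over {n} variants")
bands = stratified_summary(acc, "maf_bands")
print(bands[["stratum", "n", "mean_r"]].head(3).to_string(index=False))
```

prints

```
scorable variants: 27389
thr0: mean accuracy 0.986 over 27389 variants
thr4: mean accuracy 0.987 over 27367 variants
thr8: mean accuracy 0.988 over 27103 variants
  stratum    n   mean_r
0.01-0.02 3028 0.971824
0.02-0.03 2032 0.983865
0.03-0.04 1398 0.985839
```

Reading this: the 117 Merino-like animals were masked to the HD array in
five folds and imputed back to sequence against the remaining multi-breed
reference.  27,389 untyped sequence variants were scorable; filtering on the
quality statistic raises the mean empirical accuracy (thr0 → thr8), and
accuracy climbs with minor allele frequency — rare variants are the hard
ones.

## Command line

```bash
ovimpute simulate --config config.yaml --out-dir out/      # panel VCF + arrays + phenotypes
ovimpute impute   --ref-vcf ref.vcf --target-vcf t.vcf \
                  --array-tsv out/array_HD.tsv --out imp.vcf
ovimpute evaluate --truth-vcf out/panel.vcf \
                  --array-tsv out/array_HD.tsv --out-dir eval/
ovimpute all      --config config.yaml --out-dir run/      # full pipeline + manifest
```

Panels travel as phased VCF 4.2 (`GT` with `|`); imputation output carries
per-sample `GT`/`DS` and per-variant `INFO` keys `R2`, `MAF`, `TYPED`.
`ovimpute all` writes a JSON manifest with seeds, per-stage wall-clock and
SHA-256 checksums of every output; identical configs reproduce identical
checksums.

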