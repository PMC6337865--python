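# Methods

`ovimpute` evaluates how well whole-genome-sequence (WGS) genotypes can be
imputed from SNP-array genotypes in a multi-breed livestock population, and
what imputation quality does to downstream genomic prediction.  Because no
real sequenced reference population ships with the package, every stage is
driven by a synthetic-population generator whose job is to reproduce the
*statistical phenomenology* that the evaluation depends on — haplotype
sharing within and between breeds, a rare-skewed sequence allele-frequency
spectrum against a flat array spectrum, breed-private young variants,
poorly-mappable regions, and heritable phenotypes — not to be a calibrated
model of any particular species.

## The synthetic population

**Generative model.**  A pool of `A` ancestral haplotypes (default 400) is
drawn site-by-site with alternative-allele counts following a truncated
`i^-skew` spectrum (default skew 1.0, i = 1..A-1).  Each breed passes
through a founder bottleneck (a subset of the ancestral pool) and then `G`
generations of recombination-mosaic descent: every generation, a new pool of
`Ne` haplotypes is built, each haplotype a crossover mosaic of two random
parents (crossovers Poisson with rate 1e-8 /bp/generation, i.e. 1 cM/Mb).
Individuals are final meioses from their breed pool; F1 crosses take one
haplotype from each parental pool.  Drift during descent differentiates
breeds, so between-breed Fst grows with divergence generations at roughly
`G/Ne` — about 0.1 at the defaults, in the range reported for real sheep
breeds.  Breed pool sizes are ordered (Merino-like > Poll-Dorset-like >
Border-Leicester-like) to mirror the ordering of published effective
population sizes; the absolute values are desk-scale stand-ins.

**Young variants.**  A fraction of sites (default 0.4) starts monomorphic
and receives its single mutation on one haplotype at a random generation of
a random breed's descent (weighted by `G x Ne` mutation opportunity).  These
variants are rare, often breed-private, and sit on one haplotype background,
which makes them genuinely hard to impute — they produce the low tail of the
quality-score distribution and the MAF-accuracy gradient.  Without them,
desk-scale imputation is essentially perfect everywhere and no quality
stratification exists to evaluate.

**Scale.**  The default genome is 2 chromosomes x 20 Mb with 100,000
variant sites and 235 individuals (117 + 29 + 30 purebred, 59 F1),
standing in for 26 autosomes x 52.7M variants x 935 animals.  100k sites
(rather than a smaller desk genome) keeps >= 20,000 scorable sequence
variants after the MAC filter, array exclusion, and within-target
monomorphism, and keeps the WGS:HD density ratio (~17:1) closer to the
~100:1 of real data.  Arrays are 400 / 1,600 / 6,000 SNPs (LD / 50k / HD
analogues), nested, ascertained with a MAF floor of 0.05 and decile-balanced
("uniform MAF") selection.

**Annotation labels** are a label simulator, not a functional predictor:
class counts are fixed exactly from the requested proportions (defaults
63 / 30 / 6.4 / 0.3 / 0.3 % for intergenic / intronic / up-downstream /
missense / UTR) and membership is drawn with weights that multiply rare
(MAF < 0.05) variants for the functional classes, giving missense and UTR
classes their rare-skewed MAF profile.

**Phenotypes** are additive: random causal variants, normal effects, and a
residual orthogonalised against the genetic values and rescaled so the
realised Var(TBV)/Var(y) equals the target heritability exactly.

**Low-fidelity regions** emulate assembly/mapping failure: inside the
region, variant density can be multiplied (new variants with random,
LD-free haplotype assignment) and existing entries are flipped independently
at an error rate, destroying local haplotype sharing.  Both the reference
and the truth carry the corruption — the region is *really* noisy, exactly
as a mismapped segment is in real data.

## The imputation engine

A target haplotype observed at array positions is modelled as an imperfect
mosaic of the reference haplotypes (the haplotype-copying HMM).  Hidden
state: which reference haplotype is copied (H states).  Transition between
adjacent sites at map distance `d` Morgans: no switch with probability
`exp(-lambda d)`, otherwise a switch to a uniformly chosen state (including
the current one).  Defaults: `lambda` = 100 switches/Morgan with a map scale
of 1 cM/Mb, i.e. about one expected switch per Mb; emission mismatch
probability `epsilon` = 1e-3.  Untyped sites carry uniform emissions, so
their posteriors interpolate between flanking typed sites (simpler than the
typed-grid interpolation of production tools, and exactly checkable against
path enumeration).  Forward-backward runs in scaled arithmetic (normalised
at every site, so no underflow at any length); a compiled kernel reduces the
posterior to the allele dosage on the fly, and a plain NumPy implementation
of the same recursion is kept for small-instance work and cross-checking.

Per individual, the two haplotype dosages sum to the 0-2 genotype dosage;
the most-likely genotype is the dosage rounded half-to-even and clamped to
{0,1,2} — one declared rule rather than a per-genotype argmax.

**Reference filter.**  Reference panels drop variants with minor allele
count below 5 before imputation; the removal log travels in the panel
metadata.  Under cross-validation the filter is applied once to the full
panel so all folds share one variant scope (per-fold refiltering would make
the per-variant accuracy table ill-defined across folds).

**Quality statistic.**  For each variant, `rsq = PopVar(d) / (p(1-p))` over
all target haplotype dosages `d` with `p = mean(d)` (population variance,
dividing by the haplotype count; defined 0 when `p` is 0 or 1 or the
dosages are constant).  Poor imputation shrinks dosages towards `p`,
deflating the ratio.  The raw value can marginally exceed 1 and is clamped
only for binning and reporting.  Under cross-validation the statistic is
computed over the haplotype dosages pooled across folds, so each variant
carries one well-defined value.

**Stepwise imputation** chains LD -> 50k -> HD -> WGS; between stages
haplotype dosages are hardened to best-guess alleles, as chained runs of
imputation tools consume hard genotypes.  The synthetic world has no
separate array-genotyped intermediate panel, so the sequenced reference
restricted to the stage's array positions serves as the stage reference.
The final typed mask marks the HD positions, so evaluation excludes the same
sites as a direct HD -> WGS run.

## Accuracy evaluation

Individuals are split into `k = 5` balanced folds; each fold's members are
masked to the array and imputed against everyone else (so ~80 % of each
breed stays in the reference).  Per variant, the (imputed, true) genotype
pairs pooled over all held-out individuals give a Pearson correlation —
from dosages ("probability" scoring) or most-likely genotypes (hard
scoring).  Typed variants and variants monomorphic on either side are
flagged (`typed`, `monomorphic_truth`, `monomorphic_imputed`) and counted,
never silently dropped; every summary carries an accounting block that
reconciles stratum counts + exclusions with the total.

Thresholds follow the strict-inequality convention: `thr4` keeps
`rsq > 0.4`, `thr8` keeps `rsq > 0.8`, `thr0-4` keeps `rsq <= 0.4`, `thr0`
keeps everything.  Stratifiers: contiguous MAF bands (0.01-0.02 ...
0.08-0.10, 0.10-0.50; a non-contiguous reporting ladder seen in published
tables is available as a named preset), 100 half-open quality-score
bins of width 0.01 (final bin closed at 1.0, on the clamped score),
half-open 1-Mb windows, annotation class, and chromosome.  Per-chromosome
and per-window means weight variants equally.

**Paired scoring comparisons.**  When two scoring routes (dosage vs hard
calls) or two reference designs are compared, means are taken over the
variants scorable under *both*: a variant whose hard calls are constant is
excluded under hard scoring but scored (usually poorly) under dosages, so
unpaired means would compare different variant sets.

## BayesR genomic prediction

SNP effects follow a four-component normal mixture with variances
(0, 1e-4, 1e-3, 1e-2) x sigma^2_g.  Single-site Gibbs: per variant, the
class-conditional posteriors are computed from the current residual, a class
is sampled, then the effect; mixing proportions get a Dirichlet(1,1,1,1)
update; sigma^2_e and sigma^2_g get scaled-inverse-chi-square updates
(df 4).  The residual prior scale is data-scaled at half the phenotypic
variance; the genetic-variance prior scale is weakly informative at 0.1 x
Var(y) — a stronger prior asserts a-priori genetic variance of the order of
the phenotypic variance and visibly inflates heritability for null traits
at desk-scale n/m ratios.  Genotype dosages are centered by training-set
column means and not standardised, keeping effects on the allele-count
scale.  Genomic heritability is recorded per kept iteration as
Var(X beta)/Var(y) on the training individuals (computed as Var(y - e), so
no extra matrix product).  The desk schedule is 4,000 iterations / 2,000
burn-in; the published 40,000 / 20,000 with 5 chains is available as
`BayesRConfig.paper()`.

**Matched variant sets.**  For each quality stratum, eligible variants
(stratum predicate and MAF strictly above 0.01) are binned by MAF quantile
deciles and every set receives identical per-bin quotas, so the sets share
one allele-frequency distribution by construction; sets are disjoint
whenever supply allows and any forced overlap is reported.

**Accuracy and its error.**  GEBV = centered target dosages x
posterior-mean effects; accuracy = cor(GEBV, adjusted phenotype) / sqrt(h2),
where h2 is the stratum-level mean genomic heritability (the role of an
externally estimated trait heritability; it can be supplied explicitly).
Heritability and accuracy are averaged across chains within a set; the
standard error is the SD over the set-level accuracies divided by sqrt(number
of sets).  In the permutation-null design the phenotype is re-shuffled for
each replicate and the SE is taken across permutations — set-level
accuracies within one shuffle share its chance associations and would
understate the null spread — and correlations are scaled by the trait's
simulated heritability, since the within-run estimate collapses under the
null.

## Desk-scale study designs

`ovimpute.studies` pins the exact conditions used by the test suite and the
reproduction script, so they cannot drift apart:

- headline CV study: default population, HD -> WGS, 117 Merino-like targets;
- stepwise vs direct: 1 chromosome x 20 Mb, 30k variants, 90 individuals,
  12 targets, paired comparison, hard-call scoring;
- problem region: 2-Mb injected region (error rate 0.05, density x2) in a
  single-breed panel, window-level detection and thr4 recovery;
- reference composition: Poll-Dorset-like targets, a 60-individual
  multi-breed reference versus a 60-individual Merino-only reference;
- heritability recovery: 1,000-individual cohort, 2,000 fitted variants
  containing the 100 causal ones, simulated h2 = 0.3;
- stratified prediction: 250-individual cohort imputed from a 250-SNP
  LD-density array with four injected low-fidelity regions (so the poorly
  imputed stratum contains common variants), sets of 400 variants,
  3 sets x 2 chains, 1,500/750 Gibbs schedule.

## Numerical choices and degenerate inputs

- All randomness flows through `numpy.random.default_rng` seeded per
  operation; every stage is bit-reproducible under a fixed seed, and the
  pipeline manifest records SHA-256 checksums of all outputs.
- Posterior normalisation at every site bounds round-off; forward-backward
  agrees with exhaustive path enumeration to < 1e-10 on small instances.
- Dosage written to VCF with 3 decimals (DS), quality statistic with 6
  significant digits (INFO/R2); round trips are exact to those precisions.
- Accuracy-pattern tests treat stratum-mean differences below 1e-3 as ties:
  bin means are Monte-Carlo averages and differences at that scale carry no
  information about the pattern under test.
- Empty references, monomorphic variants, constant dosages, h2 at the 0/1
  boundaries, and non-nested arrays all either take a defined branch or
  raise a typed error (`PanelError`/`ConfigError`), never a silent NaN.

## What passing does and does not show

The generator reproduces the qualitative structure the evaluation needs,
so passing tests demonstrate that the *machinery* — masking design, HMM,
quality score, stratified summaries, BayesR — behaves as the designs
predict on data with that structure.  They do not certify accuracy values
for any real population: the desk-scale genome is far smaller, the
between-breed haplotype sharing model is cruder than real breed history
(sharing is driven solely by founder-set overlap, which makes single-breed
cross-imputation harsher than in real sheep), phasing is treated as exact,
and genotyping error in the arrays is not modelled.
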