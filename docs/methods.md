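# Methods

This note documents the models and procedures implemented in `famgs`, the
defaults and why they were chosen, what the synthetic cohorts emulate, and
the numerical and design decisions a maintainer should know about.

## The liability-threshold model

Disease status is modelled through a standard-normal latent liability L;
an individual is affected when L > t = Φ⁻¹(1 − K) for sex-specific
prevalence K.  Derived quantities used throughout: z = φ(t), mean case
liability i = z/K, mean control liability i_ctrl = −iK/(1 − K), and the
threshold t_R = Φ⁻¹(1 − K_R) implied by the sibling recurrence risk K_R.

Defaults (configurable): K = 1/54 for males and 1/252 for females,
K_R = 0.259 and 0.096 — prevalence and sibling-recurrence figures for
autism spectrum disorder.  With these inputs Falconer's sibling estimate
h² = 2(t − t_R)/i is 1.18 for males and 0.91 for females; values above 1
are returned as-is but flagged, and the ratio v/h² is clamped to [0, 1]
with the clamp flagged, rather than silently renormalized.  A
Reich-corrected variant (threshold-shift correction) is available behind a
flag; Falconer is the default because it is the conventional first-line
estimate and because the difference is well within the uncertainty of the
recurrence inputs.

## Synthetic multiplex cohorts

`simulate_families` emulates the sampling design of multiplex-family
collections: two genotyped parents, 2–4 children (uniform; the real
distribution of "multiplex" sibship sizes is not published, so this is a
modelling choice), ascertainment on ≥ 2 affected children, diallelic SNPs
at Hardy-Weinberg proportions with MAF drawn in (0.05, 0.5), and
independent Mendelian transmission — so cohorts are Mendel-consistent by
construction and QC must be exercised by injecting error explicitly.

Child liability is Σ_c β_c (X_c − E[X_c]) + s + e with X_c the causal
genotype coded under that SNP's model, s ~ N(0, σ²_shared) identical for
all siblings, and e sized so total variance is 1.  Effects are specified on
the standardized liability scale, which keeps variance bookkeeping exact;
`liability_effect_for_or` converts a target per-genotype odds ratio to a
liability effect (numerically exact under the model), and
`causal_set_for_variance` builds equal-effect causal sets with a pinned
MAF so a scenario's joint variance is exact rather than
frequency-dependent.  Children's sexes are drawn 50:50; the ~4:1 affected
male:female ratio emerges from the two thresholds alone, mirroring a
differential-penetrance reading of the sex bias.  σ²_shared can be
calibrated to a target sibling recurrence through the exact
bivariate-normal relation (`liability_correlation_for_recurrence`); the
male figures (K = 1/54, K_R = 0.259) imply a sibling liability correlation
of 0.64.

What these cohorts do **not** emulate: linkage disequilibrium (every SNP
independent), rare variants and CNVs, assortative mating, population
stratification, genotyping batch effects, and curated literature evidence
(the evidence generator assigns favourable flags with probability p_true
for causal genes and p_false otherwise).  Passing tests therefore
demonstrate the correctness and calibration of the machinery under this
generative model, not robustness to the confounders of real array data.

## Transmission tests

For each SNP, coding, and stratum, the statistic sums coded genotypes of
target-status children and standardizes by the exact conditional moments
given parental genotypes (enumeration of the four equiprobable
transmissions; offspring treated as independent transmissions within a
family, families summed).  Families with a missing parental genotype at a
SNP are dropped for that SNP — the full sufficient-statistic conditioning
for missing parents is deliberately out of scope since the emulated
cohorts have genotyped parents.  Two-sided p-values use the normal
approximation; zero-variance SNPs return Z = 0, p = 1, flagged
non-informative.  For trios with a single heterozygous parent under the
additive coding, Z² reduces exactly to the classical TDT McNemar statistic
(b − c)²/(b + c), which the tests assert by enumeration.

The four analysis strata are affected/both, affected/male,
affected/female, unaffected/both.  Whether the original unaffected-sibling
analysis was sex-stratified is unclear; unstratified is the default and
the stratum set is configurable.  For reporting, the risk allele is the
overtransmitted allele in affected strata and the *under*transmitted
allele in the unaffected stratum; when the risk allele is the second
allele, dominant and recessive labels swap so that coded genotype groups
are preserved.

## Estimating equations

`gee_logistic` fits ordinary logistic maximum likelihood by IRLS
(coefficient tolerance 10⁻⁸, 100 iterations max) — the GEE point estimate
under working independence — and computes the cluster sandwich
A⁻¹BA⁻¹ with B accumulated from per-cluster summed scores.  Separation
(any |β| > 15) and constant predictors are *flagged* non-estimable rather
than raised, because bootstrap replicates routinely produce such designs
and must be redrawn, not crash.  With singleton clusters the sandwich
reduces exactly to HC0, asserted against an independent implementation.
"Nominal significance" in candidate selection is read as two-sided
p < 0.05 on the robust Wald test; direction concordance between the family
and sibling analyses is enforced explicitly, and no multiple-testing
correction is applied at the selection funnel — false-positive control is
the role of the evidence-scoring stage.

## Evidence scoring

Category points (caps): statistical 2 — GWAS p < 10⁻⁸ scores 1 versus 0.5
for [10⁻⁸, 10⁻⁵); sibling OR ≥ 1.5 scores 1; genomic 2 — within gene
± 5 kb, eQTL; previous reporting 1 — autism 1 versus related disorder 0.5;
physiological 4 — brain expression 1 versus lymphoblastoid 0.5, CNS-specific
role, mouse CNS model, pathway membership.  Alternatives within a line are
mutually exclusive (maximum taken); bands are half-open with the stricter
side winning (p exactly 10⁻⁸ earns 0.5, exactly 10⁻⁵ earns 0 — boundary
behaviour is unstated in the source material, so the conservative reading
was fixed).  Totals live on the half-point lattice [0, 9]; selection at
total ≥ 4 (closed bound).  When a SNP maps to two genes the maximum pair
score decides selection; summing across genes was rejected because it
would reward annotation density rather than evidence strength.

## Genetic scores and variance explained

Per sex, each prioritized SNP's coding is chosen by the marginal
criterion: the coding with the largest robust |z| in the discovery
stratum, after excluding codings with OR ≤ 1 when direction filtering is
on; ties (within 10⁻¹²) break additive > dominant > recessive.  A joint
search over 3^m model assignments was rejected as combinatorially
infeasible; the criterion function is a single pluggable point.  The GS is
the unweighted sum of coded risk-allele counts; missing genotypes
contribute the cohort mean coding (flagged, low-confidence above 50%
missing).  Model choices are frozen before validation and never
re-estimated there.

Discrimination is summarized by the Mann-Whitney AUC (ties counted half,
oriented ≥ 0.5 with the flip recorded).  For a random population sample,
the AUC of a score explaining liability variance v is

AUC = Φ( v(i − i_ctrl) / sqrt( v(1 − v·i(i − t)) + v(1 − v·i_ctrl(i_ctrl − t)) ) ),

inverted by monotone bisection to 10⁻⁸ (`auc_to_liability_v`).  This
relation assumes cases and controls are unrelated draws from the
population.  Validation cohorts here are nothing of the sort: controls are
the unaffected *siblings* of cases in families ascertained for ≥ 2
affected children, so both groups are enriched for risk alleles and the
within-family contrast is strongly attenuated — empirically the naive
inversion recovers only ~¼ of the generative v.  The evaluator therefore
defaults to a design-aware inversion: a Monte-Carlo forward model
simulates the score from its actual composition (risk-allele frequencies
estimated from validation founders, per-SNP codings, Mendelian
transmission), embeds it in liability with per-unit effect scaled to each
candidate v and a family-shared Gaussian sized to the (K, K_R)-implied
sibling correlation, re-ascertains on ≥ 2 affected (sibship sizes from the
cohort, sexes 50:50 since the cohort's own sex mix is already an
ascertainment product), and maps the observed AUC back through the
simulated curve (13-point grid, monotone interpolation, common random
numbers across the grid; simulation continues until ~30,000 ascertained
stratum children per grid point, configurable).  The uncorrected
population inversion is always reported alongside (`v_uncorrected`).
Calibration was verified by parameter recovery: with a perfectly specified
score explaining v = 0.10 in large simulated cohorts the corrected
estimate centres near 0.09–0.13 while the naive one centres near 0.025.
Known limitations: the forward model assumes equal per-unit liability
effects across the score's SNPs and no residual shared environment beyond
the single family Gaussian; AUC sampling noise at ~1,000 validation
families puts a standard deviation of roughly 0.03 on the per-sex
variance-explained estimate.

## Resampling

The resampling unit is always the family; replicates preserve the family
count and relabel repeated draws to keep clusters distinct.  Percentile
95% CIs use the adjacent-rank convention (lower = ⌈0.025B⌉-th, upper =
⌈0.975B⌉-th order statistic) — percentile rather than BCa, matching the
empirical-CI framing.  Non-estimable replicates are redrawn and counted;
more than 20% aborts.  The default B is 1,000; nested analyses
(reproducibility index, coverage experiments) run at B = 100–200 in the
test suite with the full B available via config.  The selection-inflation
audit re-runs direction-consistent model selection *inside* each
replicate, which under the null inflates the mean replicate GRR above an
unselected observed value — the phenomenon the bootstrap comparison is
designed to expose.

## Problem sizes used by the checks

The whole-method suite runs: 2,000 null transmission tests on cohorts of
300 families for type-I error; 1,000 null estimating-equation replicates
at 500 sib-pair families; v-recovery at 200,000 individuals and h²
recovery at 100,000 sibling pairs; 20 end-to-end replicates at 800
discovery / 1,000 validation families with five additive causal SNPs
jointly explaining 10% of liability (per-replicate estimate = mean of the
male and female values, which estimate the same quantity in this
scenario); bootstrap coverage over 200 outer replicates at B = 200.
These sizes keep each property estimable with useful precision while the
full suite completes in minutes on a single CPU.
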