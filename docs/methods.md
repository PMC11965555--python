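# Methods

## The statistic

Each signature is a set of CpGs with ±1 directionality weights. Its clock
value for a sample is the weighted mean of methylation beta values,

```
clock = Σᵢ (wᵢ · βᵢ) / n
```

with wᵢ ∈ {+1, −1} and n the number of CpGs. A CpG that gains methylation
with the process of interest (age, senescence, …) weights positively, one
that loses methylation weights negatively, so higher clock values always
read as "more of the process". No coefficients are trained: weighted means
avoid optimising a predictor for chronological age at the expense of
biological signal. By default the divisor is the number of signature
probes actually present and observed in a given matrix
(`missing_policy="available"`), so scores stay comparable across array
generations with different probe content; `strict` mode divides by the
full signature size and is what exact shift arithmetic (a δ shift along
the weight vector moves the score by exactly δ) holds for.

## Discovery criteria

* **Condition CpGs (senescence, proliferation).** Per-probe ordinary least
  squares of beta on a binary condition indicator plus dummy covariates
  for cell type and dataset; two-sided t test on the condition
  coefficient; Benjamini–Hochberg across all probes; autosomal probes with
  q < 0.05 kept with the sign of the coefficient. No delta-beta filter is
  applied — effect-size cutoffs are arbitrary and the clock aggregates the
  mean effect over many sites. The proliferation experiment treats cells
  by *inhibiting* proliferation, so the fitted coefficient's sign is
  negated before the overlap stage, which reasons in terms of increased
  proliferation.
* **Age CpGs.** Spearman correlation of beta with chronological age,
  separately in the immune compartment (blood) and the epithelial
  compartment (buccal/cervical samples with < 20 % inferred immune
  proportion). P-values use the large-sample t approximation with
  midranks for ties; BH within each compartment. Classes: `gen`
  (significant, |ρ| > 0.2 in both), `epi`/`imm` (significant and
  |ρ| > 0.2 in one, |ρ| < 0.02 in the other), `nonage` (|ρ| < 0.2 in
  both, no significance condition), else `unclassified`. The 0.02
  cross-compartment ceiling is a purity filter: at realistic sample sizes
  the sample correlation of a truly silent probe falls below 0.02 only
  ~15 % of the time, so the epi/imm classes are deliberately
  high-precision, low-recall. Recovery of planted compartment-specific
  probes is therefore assessed at the detection level (significant with
  |ρ| > 0.2 in the planted compartment), while the class rule itself is
  verified by boundary-value tests.
* **PCGT CpGs.** Promoter probes (≤ 200 bp from the TSS) of
  polycomb-target genes, required to be unmethylated (mean beta < 0.2) in
  a fetal reference; probes absent from the fetal reference are excluded
  (conservative). The occupancy-derived gene list is an input file, not
  computed here.

## Signature assembly

The full enumeration is AGE×{gen,epi,imm} + SEN×{gen,epi,imm,pure,nonage}
+ PCGT×{gen,epi,imm,pure,nonage} + PRO×{gen±,epi±,imm±,pure±,nonage} = 22
signatures. Concordance rules: SEN overlaps require the age-correlation
sign to equal the senescence direction; PCGT overlaps admit only
positively age-correlated sites (PCGT promoters start unmethylated, so
methylation gain is the only informative direction); PRO+ requires age and
increased-proliferation signs to agree, PRO− to disagree (high PRO− reads
as reduced proliferation with age). Weights are the age-correlation sign
for age-containing signatures and the functional direction for nonage
signatures (PCGTnonage: +1). `pure` draws from the union of the three age
classes and requires membership in exactly one functional set; AGE
signatures exclude all functional probes ("aging alone"). For
compartment-shared probes the two compartment signs must agree; discordant
probes are dropped with a warning. Empty overlaps are emitted flagged
unusable so the enumeration is stable. Design choices where the grouping
was open: PROnonage is one signature (not split by sign — the sign lives
in the weights); `pure` is not restricted to the gen class (maximises
coverage while honouring exclusivity); the condition model has no
interaction terms.

The mouse transfer maps human PCGT symbols to murine orthologs, filters
mouse array probes to TSS200, autosomal, fetal-unmethylated candidates,
regresses beta on tissue indicators, and correlates the residuals with age:
`mPCGTgen` = candidates with ρ > 0.2 and q < 0.05, `mPCGTnonage` =
candidates with |ρ| < 0.2; all weights +1.

## Evaluation

Scores are adjusted per contrast by OLS on the pooled reference +
comparison samples (covariates: chronological age and inferred immune
proportion unless the contrast opts out — e.g. reprogramming and
proliferation contrasts use none, paired before/after designs adjust for
immune proportion only). The AUC is P(score_comparison > score_reference)
+ ½·P(tie) over all cross-group pairs — identical to U/(n₁n₂) — and is
never reflected around 0.5, so AUC > 0.5 always means epigenetically older
than the reference. CIs use the asymptotic placement-variance (DeLong)
method, with a seeded percentile bootstrap when either arm has fewer than
10 samples (the normal approximation is poor there). Two-sided
Mann–Whitney p-values (Wilcoxon signed-rank on within-pair differences for
paired contrasts) are BH-adjusted across all signatures within one
contrast; a result is significant only if q < 0.05 *and* the CI excludes
0.5. Ties take midranks throughout.

Cell composition is estimated by non-negative least squares of each
sample's marker betas on reference profiles, renormalised to sum to one —
a deliberate simplification of robust-partial-correlation deconvolution
with the same contract (reference-based fractions). "0 % tumor" is
implemented as an estimated fraction below 1e-6 to absorb solver noise.

## The synthetic cohorts

Betas are generated on a latent Gaussian scale and mapped through the
logistic function, so values lie strictly in (0, 1) and monotone age
relationships survive the transform (Spearman-based discovery is
invariant to it). The latent slope for a target Spearman magnitude ρ_s
inverts ρ_s = (6/π)·asin(ρ_p/2) for the Pearson latent correlation and
scales by the noise SD; with zero noise any planted probe is exactly
rank-correlated (|ρ| = 1). Compartment-specific probes carry a near-zero
(target ρ ≈ 0.005, not exactly zero) slope in the other compartment so the
0.02 ceiling is exercised from both sides. Every sample has an immune
proportion p and its profile is the convex combination
(1−p)·epithelial + p·immune of two compartment profiles sharing the
per-probe baseline. Condition experiments shift planted probes by
±`condition_delta` on the beta scale in the treated arm and add per-dataset
and per-cell-type latent offsets with deliberately unbalanced arm
assignment, so a model ignoring the covariates is confounded. Case/control
cohorts shift case samples by ±`case_effect` along a signature's weight
vector with age and immune-proportion draws matched between arms; a probe
in several planted signatures takes its shift from the first in
enumeration order. A single integer seed expands into per-stage child
seeds via `SeedSequence(seed, spawn_key=(stage,))`, so every stage is
independently and byte-identically reproducible.

Default condition: 5 000 probes, 200 samples aged 20–80 (40 % blood,
60 % buccal/cervical with 0–15 % / 0–35 % immune contamination), 100
planted probes per age class at target ρ = 0.5, 200 senescence- and 200
proliferation-responsive probes at delta 0.2, 50 PCGT genes × 2 promoter
probes, latent noise SD 0.05, case effect 0.05. Effect-size distributions
of the original discovery sets are unpublished; these values are chosen so
that planted structure is clearly detectable at realistic cohort sizes
while null structure is not — they demonstrate correctness of the
machinery, not the power of any real study. The generator does not emulate
probe-type (Infinium I/II) bias, spatial artefacts, genetic polymorphisms
under probes, or realistic beta-value bimodality; passing recovery tests
therefore says nothing about preprocessing quality on real arrays.

## Problem sizes and numerics

The test and acceptance runs use the 5 000 × 200 standard condition for
discovery recovery, an 800-probe universe for the replicated evaluation
studies (100 + 100 directional replicates and 100 null replicates at
n = 50/50, case effect 0.05), 50 random instances for each statistic
oracle, and 200 samples for deconvolution recovery — sizes chosen to make
sampling error small relative to the tested margins while completing in
seconds. Degenerate inputs are handled explicitly: constant probes get
ρ/p undefined and class `unclassified`; zero-residual-variance condition
fits report p = 1 and direction 0; identical score multisets give
AUC = 0.5 and rank-test p = 1; rank-deficient references and constant
covariates raise errors naming the offender.

## Known limitations

* The deconvolution is NNLS on mean reference profiles, not
  robust-partial-correlation; absolute fractions on real arrays will
  differ even though the orderings driving the filters are stable.
* Signature transfer assumes shared probe identifiers within a species'
  array family; no cross-array probe harmonisation is attempted.
* No survival modelling: mortality-style outcomes enter only as binary
  group labels.
* The 22-group enumeration fixes one reading of the published family
  structure (PROnonage unsplit, `pure` over the class union); alternative
  groupings would change membership at the margins but not the machinery.
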