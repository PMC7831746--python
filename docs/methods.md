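# Methods

This note documents the statistical procedures, the defaults and why they
were chosen, the synthetic-data design, and the numerical decisions made
where the underlying study report left the choice open.

## Phenotype model

Skeletal muscle mass uses the Janssen bioimpedance equation with height in
centimetres inside the impedance index (height²/R) and resistance in ohms;
sex is coded 1 = male, 0 = female, matching the equation's source
convention. The skeletal muscle index divides SMM by height squared in
metres. The equation as usually printed is unit-ambiguous; cm²/Ω is the
convention that reproduces plausible adult SMM values (20–35 kg), and the
implementation states it explicitly.

Classification follows the EWGSOP2 logic with the cutoffs used in the
study: *confirmed* sarcopenia requires both low grip strength (<27 kg men,
<16 kg women) and low SMI (<8.87 / 6.42 kg/m²); gait speed <0.8 m/s marks
*severe* sarcopenia rather than being required for case status. The
source report cites both the 2010 and 2019 EWGSOP consensus papers but
prints 2019-style cutoff values, and does not print the exact combination
rule; strength-AND-mass is the rule consistent with the cited cutoffs and
is the documented assumption here. Grip strength is expected already
collapsed to the best of attempts upstream. A record missing any required
measurement is returned `unclassified` with the reason, never guessed.

## Hardy-Weinberg testing and QC policy

The χ² test estimates the allele frequency from the data, compares
observed genotype counts with (np̂², 2np̂q̂, nq̂²) and refers Σ(obs−exp)²/exp
to χ² with 1 df. No continuity correction is applied — this keeps χ² = 0
attainable at exact HWE proportions and matches common practice. For small
counts an exact test is provided: all heterozygote counts compatible with
the observed allele counts are enumerated and the probabilities of
configurations no more probable than the observed one are summed.

QC policy: the test runs per group; a SNP whose **control** group deviates
at the configured α (default 0.05) is excluded from every downstream
table, while case-group deviation is reported but never excludes (it can
itself reflect true association). Control-group deviation is the
statistically defensible exclusion trigger because controls approximate
the source population. One subtlety the simulator makes visible: when a
strong genetic effect exists and the disease is common, *conditioning* on
control status itself perturbs Hardy-Weinberg proportions slightly, so at
sample sizes ten times the study scale the default α = 0.05 begins to
exclude true risk SNPs in perfectly clean data. For large cohorts the
conventional much stricter threshold (e.g. 10⁻⁶, as used in genome-wide
QC) is appropriate, and `RunConfig.hwe_alpha` exposes it.

## Association statistics

All contingency tests are Pearson χ² without continuity correction (with
a warning flag when an expected cell is below 5); the genotypic test uses
the full 2×3 table with 2 df. The allelic test treats each genotype as two
independent alleles. Odds ratios are cross-products with Woolf
(log-normal) 95% intervals; a zero cell triggers the Haldane–Anscombe
+0.5 correction on all four cells, reported via a flag; two zero cells on
a diagonal leave the OR undefined and raise. The choice of *no* continuity
correction is corroborated by count reconstruction: the published ACTN3
allele table (54/36 vs 123/167) reproduces the printed p = 0.003 only
without correction.

`counts_from_freq` converts printed percentage frequencies back to integer
counts (denominator 2n for alleles, n for genotypes), rounding half away
from zero; this reproduces all six published allele counts of the score
SNPs exactly.

No multiple-testing adjustment is applied by default (the study used
p < 0.05 per test); a Bonferroni-style correction can be applied by the
caller. The quantitative-trait comparison is one-way ANOVA with Tukey HSD,
sexes analysed separately by the caller; groups with fewer than two values
are dropped with a record, and identical group means short-circuit to
F = 0, p = 1 (the F statistic is otherwise 0/0 when within-group variance
is also zero).

## Logistic regression

Fitting is iteratively reweighted least squares written in-package: start
at β = 0, Newton steps with step-halving so the deviance path is
monotonically non-increasing, convergence at max|Δβ| < 10⁻⁸ or
|Δdeviance| < 10⁻¹⁰ within 50 iterations. Separation is flagged when a
coefficient passes |β| > 15 and is still growing — the error names the
offending term. Wald inference: z = β/SE, OR = exp(β),
CI = exp(β ± 1.96·SE). Covariates enter raw (age in years, male indicator,
physical activity per unit), so ORs are per raw unit. Complete-case
analysis per model, with the number of dropped rows always reported.

Both Cox-Snell R²CS = 1 − exp((2/n)(LL₀ − LL₁)) and Nagelkerke
R²N = R²CS ⁄ (1 − exp((2/n)LL₀)) are computed; Nagelkerke is the headline
value because it is the default "% of variance" pseudo-R² of the SPSS
logistic output that small clinical studies typically report. The suite
cross-checks coefficients, standard errors and likelihoods against
statsmodels to 10⁻⁶, and verifies the analytic identity that the
saturated single-predictor fit reproduces the 2×2 cross-product OR.

## Genetic risk score and ROC

The score is deliberately unweighted: risk-allele dosage 0/1/2 per SNP,
summed over the K score SNPs and rescaled by 100/(2K) to a 0–100 % scale
(for K = 3 this is the 100/6 formula; 100 % = homozygous risk at all three
loci). Scores therefore live on a lattice of 2K+1 values. Samples missing
any score genotype are excluded with a reason (strict mode; imputation is
deliberately not silently applied because at K = 3 a single imputed SNP
moves the score by up to a third of its range).

Risk alleles are oriented empirically: the case-enriched allele (allelic
OR > 1) becomes the risk allele, with the OR recorded; an OR of exactly 1
raises rather than guessing.

ROC conventions: prediction rule "score ≥ threshold ⇒ case"; candidate
thresholds at midpoints between consecutive distinct observed scores plus
sentinels beyond both extremes. The midpoint convention matters on a
lattice — between adjacent three-SNP scores 50 and 66.7 it places the
candidate cutoff at 58.3 %, the natural operating point between those two
profiles. AUC uses the Mann-Whitney rank formulation with ties counted ½
(verified to equal trapezoidal integration of the curve to 10⁻⁹ and to
match scikit-learn), with a Hanley–McNeil normal-approximation CI — chosen
over DeLong for self-containment; the method is recorded in the result.
The Youden cutoff maximizes J = sens + spec − 1, breaking ties toward
higher sensitivity (screening framing) and then lower threshold.

## Power calculation

Parameterization: risk-allele frequency p, prevalence K, genotype relative
risks g₁, g₂. Baseline penetrance f₀ = K/(q² + 2pq·g₁ + p²·g₂); group
genotype frequencies by Bayes' rule; the allelic 1-df non-centrality uses
the unpooled two-proportion variance on 2N alleles per group (a pooled
variant is selectable and recorded in the result); power is the
non-central χ² upper tail beyond the central critical value. The marker is
treated as the causal variant (no LD attenuation). At the study's printed
design (50/150, p = 0.4, K = 0.25, g = 1.5/2.5, α = 0.05) this yields
power ≈ 0.754 under the allelic test; standard formulations give
0.75–0.77 for these inputs, so the report's round "80 %" presumably
reflects an unstated calculator setting and is not treated as a
reproducible target.

## Synthetic cohorts

The generator emulates the study's structure: 45 cases / 145 controls,
67 men / 123 women, age normal 78.3 ± 9.6 y reflected at the 65-y
eligibility floor, 6.5 % missing genotypes (the assay's 93.5 % call rate)
and a 2 % single-allele call-error rate.

*Disease model.* Genotypes are drawn per SNP under HWE in a large source
population (default 100× the cohort); disease is assigned by a logistic
liability with offsets ln g₁ / ln g₂ for het / hom-risk genotypes, the
intercept solved by bisection to the target prevalence, and the requested
numbers of cases and controls subsampled — group sizes are exact by
construction. The logistic form was chosen over exact multiplicative
penetrances because covariates enter coherently on the same scale; at the
study's effect sizes the implied genotype relative risks agree with the
multiplicative ones to within a few percent.

*Calibration.* The default scenario's three effect SNPs are calibrated so
that the **marginal** control allele frequencies (0.283, 0.424, 0.486) and
allelic ORs (3.317, 2.037, 1.915) hold with all six SNPs in the liability
simultaneously. This matters: single-SNP calibration is biased once other
strong effects coexist in the same liability. The calibration enumerates
the 3^K joint genotype lattice exactly, and coordinate-wise bisection over
(population frequency, multiplicative GRR) per SNP converges in a few
sweeps. Three null SNPs sit at the published total-sample frequencies.

*Phenotypes.* Grip, SMI and gait are drawn from status- and
sex-conditional normals placed mostly on the correct side of the EWGSOP
cutoffs (e.g. male case grip 21 ± 3 kg vs control 34 ± 5 kg), truncated at
physiologic minima; BIA resistance is back-solved through the Janssen
equation so the drawn SMI is reproduced exactly. The defaults give ≈ 95 %
agreement between EWGSOP classification and the generating status — the
distributions deliberately overlap so classification is non-trivial. The
published study reports no phenotype distributions beyond age, so these
are the package's own documented choices, fully overridable.

*Determinism.* One seed governs everything through deterministically
spawned substreams; same spec + seed ⇒ byte-identical cohort CSV.

*Fast replicates.* Operating-characteristic studies (type-I error, CI
coverage, analytic-vs-simulated power) draw case/control genotype counts
directly from the exact status-conditional distributions of the penetrance
model — the distribution the full generator converges to — making
thousands of replicates cheap. The suite uses study-scale problem sizes
(190–8 000 participants, 500–2 000 replicates), chosen so each check
completes in seconds while retaining enough resolution for the asserted
bands.

*What passing tests do not show.* The generator has no linkage
disequilibrium between SNPs, no genotype-phenotype pathway other than the
case/control label, Gaussian phenotypes, and missingness completely at
random; agreement of the pipeline with generating parameters here does not
certify behaviour under informative missingness, population structure or
related samples.

## Known limitations

- No Firth correction for separated logistic fits; separation raises.
- The exact HWE test enumerates heterozygote configurations and is
  intended for panel-scale data, not genome-wide scans.
- The Hanley–McNeil AUC variance mildly misestimates coverage for very
  small or very unbalanced samples compared with DeLong.
- VCF import matches panel SNPs by rsID only and requires biallelic
  records.
- The physical-activity covariate has no defined scale; it is treated as
  a dimensionless score and simulated standard-normal with zero effect by
  default.
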