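# Methods

This note documents the models behind `onsetprs`, the defaults and why
they were chosen, what the synthetic cohorts do and do not emulate, and the
numerical decisions a maintainer would want written down.

## Survival framework

All association models run on the **age timescale**: a subject enters the
risk set at `entry_age` (enrolment) and leaves at `exit_age` (diagnosis if
`event == 1`, censoring otherwise), so the risk interval is
`(entry_age, exit_age]` and left truncation is handled exactly. The
early-onset / late-onset (EO/LO) split is by exit age with a closed upper
boundary: exit ≤ 55 is EO, exit > 55 is LO. Arbitrary age bins
(`split_by_bins`) support piecewise age-group fits.

### Partial-likelihood engine

`onsetprs.coxph.fit_cox` maximises the Cox partial likelihood by
Newton–Raphson with:

* **Efron tie handling** — the common default; simulated ages are
  continuous so ties are rare, but integer-rounded ages work correctly.
* **Convergence**: at most 25 iterations, tolerance 1e-8 on the log
  partial likelihood, step-halving on overshoot. Non-convergence is
  recorded per variant in scans (never fatal); monomorphic variants are
  flagged with missing estimates. A fit with zero events is a hard error.
* **Weights**: the weighted partial likelihood in the R `survival`
  convention — a tied-death group contributes its mean case weight times
  the Efron-averaged log denominator.
* **Variance**: inverse observed information by default. With sampling
  weights the weighting induces a pseudo-likelihood, so the sandwich
  (infinitesimal-jackknife) variance is reported; score residuals use
  Breslow-form baseline-hazard increments, which is exact for untied event
  times and verified against R `survival` (to ~1e-7) including left
  truncation. lifelines agrees on estimates everywhere and on robust SEs
  in the untruncated case; its residuals ignore entry times, which is why
  the truncated robust check is frozen against `survival` instead.
* **Missing dosages**: complete-case per variant (dropping a sample only
  for variants where its call is missing), matching per-variant call-rate
  semantics. Rows with missing covariates are dropped for all variants
  and reflected in the per-variant `n`.

The engine is validated against a dense grid-search maximiser of an
independently coded partial likelihood (to 1e-4) and against lifelines.

### Variant QC

Retention requires MAF ≥ 0.01, exact Hardy–Weinberg p ≥ 1e-6 and call
rate > 95% (strict). The HWE test is the exact conditional test with
two-sided point-probability summation, computed in log space because the
unnormalised pmf overflows at biobank-scale counts; a chi-square
approximation misbehaves at the 1e-6 tail. The implementation is checked
against a full-enumeration oracle.

## Scores

Clumping is greedy: the lowest-p unassigned variant below the index
threshold (suggestive 1e-5 by default) becomes an index; unassigned
variants on the same chromosome within 10 Mb with dosage r² ≥ 0.8 join its
clump and are discarded for scoring. Ties on p are broken by smaller
(chr, pos), which makes the output invariant to input row order. r² is
composite LD from unphased dosages over pairwise-complete samples — no
phasing is available or needed at this scale.

Scoring aligns each model entry's effect allele to the genotype matrix
(allele swap ⇒ dosage → 2 − dosage) and imputes a missing call as
2 × effect-allele frequency, the standard scoring behaviour; per-sample
imputation counts are reported. Flipping an entry's alleles and negating
its weight shifts every score by a constant 2β (tested), which cancels in
any location-invariant downstream use. Quintiles use the reference
population's 20/40/60/80 percentiles with left-open, right-closed
intervals (lowest closed): a score exactly on the 40th-percentile cut is
quintile 2.

The merged score keeps every reported entry (weight `ln` reported OR) and
adds scan hits whose r² with all reported variants is below 0.8; a hit in
LD ≥ 0.8 with any reported variant is dropped ("replaced"). When either
variant of a pair is absent from the reference genotypes its LD is
unknowable and the pair is treated as independent — the caller sees the
provenance column and can audit.

## Incidence weights

Banded registry rates (5-year bands, per 100,000 person-years) are
anchored at **band midpoints** and linearly interpolated to integer ages,
flat beyond the outermost midpoints; band-start anchoring is available
behind `anchor="start"` since the choice is a convention, not a fact about
the data. `inc_t` enters the weights as a proportion (rate / 100,000);
cases get weight 1, non-cases `1/inc_t` at the integer part of their exit
age (clamped to the schedule's range). Any fixed rescaling of the weights
cancels in the partial likelihood (tested to 1e-8); optional
renormalisation of non-case weights to mean 1 is provided for effective
sample-size readability. Zero incidence at an age needed by a non-case is
a hard error rather than an infinite weight. Sub-population (EO/LO) fits
use the same all-ages schedule clamped to the stratum's age span.

## Heterogeneity

Fixed-effect Cochran's Q over `(β, SE)` pairs with weights `1/SE²`;
`I² = max(0, (Q − df)/Q)·100`; p from the chi-square upper tail. Printed
hazard ratios enter through the 95% Wald inversion
`SE = (ln hi − ln lo)/(2·1.96)`. When reproducing published statistics the
inputs are ratios printed to 2–3 significant figures, so agreement is
asserted to the nearest percent of I²; zero SEs are accepted only when all
point estimates coincide (the degenerate Q = 0 case).

## Time-dependent ROC

Cumulative-case / dynamic-control ROC at a landmark age `t` with the
Kaplan–Meier plug-in: for score cutpoint `c`,

    TPR(c) = [1 − S(t | X > c)] · P(X > c) / [1 − S(t)]
    FPR(c) = S(t | X > c) · P(X > c) / S(t)

with `S` the overall and within-stratum KM estimates. The cutpoint grid is
the descending unique scores with ±∞ sentinels, so the curve passes through
(0,0) and (1,1). The unsmoothed plug-in can leave [0,1] and be locally
non-monotone; values are clipped and made isotonic (cumulative maximum)
before the trapezoidal AUC, and the raw values are kept on the curve
object with a clip counter. With no censoring before `t` the estimator
reduces exactly to the empirical ROC and the AUC equals the Mann–Whitney
statistic (tested to 1e-10). Landmark construction mirrors the validation
design: no case exclusion at 65, cases diagnosed ≤ 55 removed at 70,
≤ 70 removed at 85, with birth as the follow-up origin — entry-age
truncation is deliberately ignored here to match that construction, a
documented limitation rather than an oversight.

## Two-sample MR

Instruments: exposure variants at p < 5e-8, clumped at r² < 0.001 within
10 Mb against a reference panel (the same greedy clumping as the PRS path,
different thresholds). Harmonization keeps matching alleles, sign-flips
swapped ones, resolves strand complements, aligns palindromic (A/T, G/C)
variants by allele frequency and drops them as ambiguous when
min(EAF, 1−EAF) > 0.42 (conventional, config-overridable).

Estimators per trait, over Wald ratios `r_i = β_out,i / β_exp,i` with
first-order SEs `se_out,i / |β_exp,i|` (exposure-side noise ignored, the
standard default):

* **IVW**: fixed-effect inverse-variance average; a multiplicative
  random-error variant (`method="mre"`) inflates the SE by
  `max(1, sqrt(Q/df))`.
* **Weighted median**: the ratio where normalised cumulative weight
  crosses 0.5 with linear interpolation; SE by seeded parametric bootstrap
  (1000 resamples of both beta sets from their normal errors).
* **MR-Egger**: WLS of sign-oriented outcome effects on |exposure effects|
  with intercept, weights `1/se_out²`; the intercept's two-sided t test at
  `k − 2` df indexes directional pleiotropy. The synthetic generator
  defines its pleiotropy in this orientation frame so the intercept is a
  recoverable parameter.
* **Cochran's Q** over ratios about the IVW estimate, `k − 1` df.

The high-confidence filter is exactly: sign(IVW) = sign(weighted median),
both p < 0.05 (strict), heterogeneity p ≥ 0.05 and Egger-intercept
p ≥ 0.05 (both inclusive). All boundaries are tested on a grid.

## Synthetic cohorts

The generator produces the structure the analysis assumes, not human
genetics in miniature:

* **Genotypes**: within an LD block, two latent haplotypes per subject
  follow an AR(1) Gaussian copula (correlation `within_block_rho`),
  thresholded at a MAF drawn uniformly from `maf_range`; blocks are
  independent and placed ≥ 20 Mb apart. Dichotomisation attenuates
  correlation: latent ρ = 0.95 at matched MAF 0.3 yields dosage r² ≈ 0.62
  (pilot across 100 seeds), and mismatched MAFs cap it lower.
* **Onset ages**: piecewise-constant baseline hazard by 5-year age band
  (default shaped like registry prostate-cancer incidence, scaled so the
  default cohort shows ≈ 3% cumulative incidence over a 8–14-year
  follow-up from enrolment at 40–69); per-subject multiplier
  `exp(g_shared + g_EO·1[a ≤ 55] + g_LO·1[a > 55])`; sampling by inversion
  of the cumulative hazard conditional on being event-free at entry.
  Censoring is the minimum of an administrative age (83) and a uniform
  loss age.
* **Family history**: Bernoulli with logistic link
  `logit(p) = logit(0.08) + 0.8·z(burden)` on the standardised total
  causal burden. The slope is a free parameter chosen to reproduce the
  observed enrichment of family history among early-onset cases
  (~2-fold); it is a plausibility device, not an estimate of any real
  quantity.
* **Incidence table**: the baseline hazard re-expressed as rates per
  100,000 in 5-year bands — i.e. the weights see the *null-subject*
  incidence, which is what a registry reports.
* **MR summary statistics**: true exposure effects uniform in
  ±[0.05, 0.15]; observed betas add noise at `1/sqrt(n)`; outcome betas
  are `effect × true` plus directional pleiotropy for the invalid
  fraction plus noise; a configurable fraction of instruments is coded
  palindromically.
* **Seeding**: one config seed; each stage derives its own deterministic
  generator from it (genotypes: `seed`, onset: `seed + 1`), so identical
  (config, seed) reproduces byte-identical outputs while each operation
  stays independently reproducible.

Not emulated: realistic LD maps, imputation uncertainty, relatedness,
population stratification, age-varying covariate effects. Passing tests
therefore demonstrate correctness of the estimators under the stated
generative model, and qualitative recoverability of age-window-specific
effects — not performance on real cohort data.

## Experiment sizes in the test-suite and acceptance script

* Parameter recovery: 10 seeds × (n = 20,000, 200 variants), six planted
  EO-specific log-hazards of 0.6–0.8. The early-onset stratum of a
  40–69-enrolment cohort holds only a few percent of events, so planted
  effects of this size are what makes an EO-specific signal detectable at
  the suggestive 1e-5 threshold at this n; the success criterion is the
  age-window signature (EO CI excludes 1, LO CI covers 1) in ≥ 8/10 seeds.
* Calibration: null cohorts of n = 2,000 with the baseline scaled ×6
  (~130 events), 200 replicates per model; Wald calibration is asymptotic
  in the event count, and ~23 events is visibly conservative.
* The pipeline demo runs at n = 6,000 with a relaxed index threshold
  (1e-3), since ~180 events cannot reach 1e-5; the library default stays
  at the suggestive 1e-5.

## Known limitations

* The weighted-Cox sandwich uses Breslow-form score residuals; with many
  tied event times and weights it is an approximation (exact when event
  times are untied).
* The time-dependent ROC ignores left truncation by design (see above)
  and implements only the unsmoothed KM plug-in, not nearest-neighbour
  smoothing or AUC-difference tests.
* `split_case_control` groups a prevalent+incident table by reference age
  but the package does not model prevalence bias itself; the logistic
  re-analysis is a sensitivity device.
* MR omits instrument-strength (F) statistics, MR-PRESSO and multivariable
  extensions; the screen is a filter, not a causal-inference endpoint.
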