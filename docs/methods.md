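# Methods

`mrmediate` implements a summary-level two-sample Mendelian randomization
(MR) screen with a two-step / multivariable mediation stage, of the kind used
to ask whether a circulating metabolite influences venous thromboembolism
(VTE) risk partly through an inflammatory cytokine such as PDGF-BB. This note
describes the statistical model, the defaults and why they were chosen, what
the synthetic-data generator does and does not emulate, and the numerical
conventions.

## Model and assumptions

For each variant j, summary statistics provide the SNP-exposure association
γ_j (SE σ_{γj}), optionally a SNP-mediator association δ_j, and the
SNP-outcome association Γ_j (SE σ_{Γj}), the latter on the log-odds scale for
case-control outcomes. Under the three instrumental-variable assumptions
(relevance, independence from confounders, exclusion restriction), each valid
instrument yields a Wald ratio Γ_j/γ_j estimating the causal effect β of the
exposure on the outcome.

### Instrument construction

1. **Selection:** retain variants with exposure p strictly below a threshold
   (default 1e-5 for metabolite-style panels; 5e-6 is the convention for
   small cytokine GWAS; 5e-8 for binary traits used as exposures in
   reverse-direction analyses).
2. **Clumping:** greedy LD pruning at r² ≤ 0.001 within 10,000 kb, sweeping
   variants by ascending p (ties broken by chromosome and position for
   determinism). A pair inside the window but absent from the supplied LD
   table is treated as correlated (drop the worse SNP) — conservative — or
   as independent, configurable. When no LD table is supplied at all the
   pipeline treats instruments as independent, since an absent table carries
   no information about any pair.
3. **Palindromes:** A/T and C/G variants with effect-allele frequency inside
   [0.42, 0.58] are removed (the frequency cannot resolve the strand there);
   the band is the dominant convention, the rule itself being standard.
4. **Confounder exclusion:** a user-supplied variant list (e.g. SNPs known to
   associate with BMI or smoking) is subtracted; no web-service lookups.
5. **Strength:** per-SNP explained variance R²_j = 2·MAF_j·(1−MAF_j)·(β_j/SD)²
   with SD = 1 for standardized traits (the only dimensionless, bounded form),
   and F_j = (N−2)·R²_j/(1−R²_j). Variants with F_j < 10 are removed; the
   set-level F ((N−k−1)/k)·ΣR²/(1−ΣR²) is reported for diagnostics only,
   since the F filter is defined per instrument.

Harmonization intersects datasets on variant id and aligns every trait to the
exposure's effect allele, flipping signs and complementing frequencies for
swapped or strand-flipped alleles; unresolvable combinations are dropped and
logged. Harmonization is idempotent.

### Estimators

* **IVW** (primary): inverse-variance-weighted mean of Wald ratios, identical
  to the weighted regression of Γ on γ through the origin with weights
  1/σ_Γ². Fixed-effect SE 1/√Σw; when Cochran's Q exceeds its df the SE is
  inflated by √(Q/df) (multiplicative random effects). The trigger Q/df > 1
  is used because the model only names "a random effects model when
  heterogeneity is present" without fixing the flavor; below the trigger the
  fixed-effect SE is reported.
* **MR-Egger:** weighted regression with a free intercept, instruments
  oriented to γ_j ≥ 0. The intercept estimates the mean directional
  pleiotropy; the slope is consistent under InSIDE. SEs carry a
  multiplicative overdispersion factor floored at 1; p-values use t with
  J−2 df. Because the overdispersion model is multiplicative while additive
  balanced pleiotropy is the usual truth, the intercept p-value is only
  approximately uniform under the null — the calibration test checks
  approximate, not exact, uniformity.
* **Weighted median:** Wald ratios ordered, inverse-variance weights
  normalized, estimate linearly interpolated at cumulative midpoint weight
  0.5; consistent when ≥50% of weight is valid. SE by seeded parametric
  bootstrap (default 1000 replicates) resampling (γ_j, Γ_j) from normals.
* **Weighted / simple mode:** Gaussian-kernel density over the Wald ratios
  (inverse-variance or uniform weights), argmax on a fixed 2048-point grid.
  Bandwidth 0.9·min(SD, MAD/0.6745)·J^{−1/5}, scaled by a user factor
  (default 1) — a robust Silverman rule; the method definition fixes no
  bandwidth. SE by the same parametric bootstrap.

Wald-ratio SEs use the first-order delta method (σ_{Γj}/|γ_j|), the standard
two-sample convention; the γ-noise term is negligible at the instrument
strengths the F filter enforces.

### Diagnostics

* **Cochran's Q:** Σ w_j (ratio_j − fit_j)² with w_j = γ_j²/σ_{Γj}²; fit is
  the pooled IVW estimate (df J−1) or the Egger fitted ratio (df J−2);
  chi-square upper-tail p. The IVW variant is, by construction, exactly the
  overdispersion statistic driving the random-effects fallback. Because the
  weights use estimated γ_j, the test shows mild type-I inflation at
  realistic instrument strengths (~0.06–0.07 at nominal 0.05 in our
  calibration), a known property of plug-in weights.
* **MR-PRESSO:** for each SNP the leave-one-out IVW slope gives a residual
  r_j = Γ_j − β̂₋j·γ_j; the observed weighted RSS is compared against
  parametric replicates Γ*_j ~ N(β̂₋j·γ_j, σ_{Γj}²) (default 1000), with
  p = (1+#{RSS* ≥ RSS})/(n_sim+1) so p is never exactly 0. Outlier testing
  runs only when the global test is significant: per-SNP simulation p,
  Bonferroni-adjusted by J. If outliers exist, the corrected estimate is IVW
  on the remainder and a distortion p compares the estimate shift against
  random same-size removals. Internally SNPs are processed in variant-id
  order so results are invariant to input row order.
* **Leave-one-out:** IVW re-estimated J times, one SNP held out each time.

Pipeline policy: an exposure whose post-outlier-correction IVW association is
no longer significant (p > 0.05) is excluded from downstream tables, so
pleiotropy-driven hits do not propagate into the FDR family or mediation
stage.

### Multiple testing

Benjamini-Hochberg step-up adjustment (delegated to
`statsmodels.stats.multitest`, with an optional explicit family size when the
supplied vector is a subset of a larger panel). The family is one outcome
across all exposures of a panel. Tiers: *significant* if adjusted p < 0.05,
*suggestive* if raw p < 0.05 but adjusted p ≥ 0.05, otherwise null.
Bonferroni is available as a stricter alternative.

### Mediation

Two-step gate: the three univariable IVW legs (exposure→mediator β_EM,
mediator→outcome β_MO, exposure→outcome β_EO) must all be significant at
0.05. Gated candidates go to MVMR: weighted regression of Γ on
(γ_exposure, γ_mediator) with no intercept and weights 1/σ_Γ², over the
union of both traits' instruments re-harmonized to the outcome and jointly
de-clumped (the union is the dominant convention when the instrument policy
is otherwise unspecified). SEs carry the same floored multiplicative
overdispersion; conditional instrument strength per exposure is reported as
Q_x/(J−2) from the weighted regression of one exposure's instrument effects
on the other's. A mediator column that is identically zero collapses the
model to univariable IVW rather than erroring, preserving the nested-model
identity.

Mediated effect: β_EMO = β_EM·β'_MO, with delta-method SE
√(β'_MO²·SE_EM² + β_EM²·SE'_MO²), 95% CI β_EMO ± 1.96·SE_EMO, p two-sided
normal on β_EMO/SE_EMO (computed from unrounded intermediates — the only
definition consistent with the delta-method SE), and mediated proportion
β_EMO/β_EO (undefined when β_EO = 0; flagged, not errored). Proportions are
reported even when the mediated-effect CI crosses zero, carrying an explicit
`CI_includes_zero` flag. Printed tables round half away from zero to 3
decimals for effects and use 2-decimal scientific notation for p-values.

## Synthetic data

The generator emulates the summary-statistic structure of a metabolite
GWAS (default N = 8,299), a cytokine GWAS (N = 8,293) and a FinnGen-scale
case-control endpoint (default 21,021 cases / 391,160 controls, effective
N = 4/(1/cases+1/controls)) under a known structural model: true exposure
effects γ_j ~ N(0, effect_sd²) with effect_sd = 0.2 on the standardized
scale, mediator effects δ_j = τ·γ_j plus the mediator's own instruments
(default 12, inside the published 4–17 cytokine range), outcome effects
Γ_j = θ_direct·γ_j + θ_mo·δ_j + α_j, and per-trait sampling noise with
SE = 1/√(2·MAF·(1−MAF)·N), MAF ~ U(0.05, 0.5). Pleiotropy α_j is zero,
balanced N(0, sd²), or directional with positive mean *relative to the
exposure-increasing allele* (the frame in which InSIDE and the Egger
intercept are defined). Optional outcome-specific susceptibility loci (no
exposure or mediator effect) support reverse-direction null experiments.

Crucially, the generator emulates instrument *selection*: candidates are
drawn and accepted only if their observed own-trait association passes the
selection threshold, exactly as a real analysis screens genome-wide
statistics. Selected instruments therefore carry per-SNP F ≈ 19.5 upward by
construction (F ≈ z² at the selection boundary), matching published
instrument-strength profiles, and the generator reproduces winner's curse —
which largely cancels in the mediated proportion because the same observed
γ_j enter numerator and denominator legs.

Not emulated: LD between instruments (the clumping logic is exercised with
explicit synthetic LD pair lists instead), allele-frequency differences
between cohorts, sample overlap, and population stratification. Passing
tests therefore demonstrate correctness of the statistical machinery under
the stated model, not robustness to those real-data complications.

Default default panel sizes in tests and drivers: 25 exposure instruments
(inside the published 7–73 range), 12 mediator instruments. Monte-Carlo
experiment sizes (200 replicates for parameter recovery, 1000 null sets for
Q calibration, 100 runs for MR-PRESSO power) keep the whole suite around
half a minute on one CPU while leaving Monte-Carlo SEs small enough for
3-SE recovery checks to be meaningful.

## Numerical conventions and edge cases

* Duplicate variants on read keep the smallest p (ties: first occurrence).
* p-value selection is strict (<); tier boundaries are strict as well.
* Monte-Carlo p-values use (1+count)/(n_sim+1).
* γ_j = 0 variants are excluded from Wald-ratio-based estimators with a
  warning; a mediator identical to the exposure surfaces an explicit
  collinearity error in MVMR and the pipeline skips the pair.
* All bootstrap and simulation randomness flows through
  `numpy.random.default_rng` seeded from the run configuration; per-pair
  seeds are derived deterministically from the run seed and pair index, so
  every output file is bit-identical under a fixed (inputs, config, seed).

## Known limitations

* Correlated instruments (generalized IVW) and robust/penalized MR variants
  are out of scope.
* The Egger intercept's null calibration is approximate (see above).
* The reverse-direction screen applies the continuous-trait R²/F formulas to
  log-odds effects, which is conventional but approximate for binary
  exposures.
* Published tables printed to 3 decimals cannot always be inverted exactly
  (e.g. a CI bound computed from unrounded inputs may differ by one unit in
  the last place from one recomputed from printed values); reproduction
  checks therefore target quantities that are stable under printing.
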