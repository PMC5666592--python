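# Methods

## Setting and assumptions

`vdmr` performs two-sample summary-data Mendelian randomisation: the
SNP–exposure associations (per-allele effects on circulating 25(OH)D in
nmol/L, with SEs) and the SNP–outcome associations (per-allele log odds
ratios for a cancer, with SEs) come from independent GWAS samples of
European-ancestry individuals and are combined at the summary level. The
causal parameter θ is a log-OR per nmol/L of 25(OH)D. Valid inference
requires the usual instrumental-variable assumptions: the variants are
robustly associated with 25(OH)D, affect cancer risk only through 25(OH)D
(no horizontal pleiotropy), and are independent of confounders. The package
assumes uncorrelated instruments (no linkage disequilibrium between them)
and no sample overlap between the two GWAS; neither is modelled.

The default instrument is the four-variant 25(OH)D score: rs2282679 (GC,
vitamin D binding protein), rs10741657 (CYP2R1, hepatic 25-hydroxylation),
rs12785878 (DHCR7/NADSYN1, cutaneous synthesis substrate), rs6013897
(CYP24A1, catabolism). Per-allele effects are 4.67, 1.72, 2.11 and 0.98
nmol/L in exposure-increasing orientation. The published table prints
p-values rather than SEs, so SEs are reconstructed as |β|/z with z the
normal quantile at p/2; `scipy`'s inverse survival function is accurate to
the smallest representable double (~1e-308), which covers the strongest
variant's printed bound of 3.4e-302. Printed bounds ("<p") are treated as
equalities: only a lower bound on instrument precision is needed, and the
IVW weight is insensitive at that extreme.

## Harmonization

Exposure and outcome tables are paired on rsID; each outcome effect is
re-expressed on the exposure's effect allele (negating the log-OR when the
coded alleles are swapped, complementing alleles across strands when
needed), and each pair is then oriented so the exposure effect is positive.
The exposure-increasing orientation is required for the MR-Egger intercept
to be identifiable and is harmless for the other estimators. Palindromic
variants (A/T, G/C), whose strand cannot be inferred from alleles, are
retained only when both allele frequencies are informative
(|EAF − 0.5| > 0.08 on both sides) and concordant; otherwise they are
excluded with a logged warning. When an "other allele" is missing on either
side, alignment falls back to an effect-allele match logged as "assumed
same strand". Irreconcilable allele pairs exclude the variant (never fatal
on their own); zero surviving variants is fatal. Every flip, exclusion and
reorientation is recorded in the instrument's orientation log.

## Estimators

- **Wald ratio** Γ̂_j/γ̂_j with first-order delta-method SE σ_yj/|γ̂_j|. The
  first-order SE deliberately ignores σ_x, matching the IVW weighting
  convention; the likelihood estimator is the route that honours σ_x, which
  keeps the IVW/likelihood contrast meaningful.
- **IVW** is the fixed-effect precision-weighted average of Wald ratios —
  algebraically weighted least squares through the origin — with no
  residual-variance inflation, matching the convention of pairing it with a
  fixed-parameter likelihood.
- **Likelihood**: γ̂_j ~ N(γ_j, σ_xj²), Γ̂_j ~ N(θγ_j, σ_yj²), with the
  within-variant correlation between γ̂_j and Γ̂_j set to zero, as is exact
  for non-overlapping samples. The nuisance γ_j are profiled in closed
  form, (γ̂_j/σ_xj² + θΓ̂_j/σ_yj²)/(1/σ_xj² + θ²/σ_yj²), and θ̂ is found by
  Brent minimisation of the profile deviance started at the IVW estimate
  (xtol 1e-12, 500-iteration budget; failure raises with diagnostics). The
  default SE is Wald-type from the numerical curvature of the profile
  log-likelihood (central differences, step 1e-5·(1+|θ̂|)); a
  profile-likelihood CI (deviance cutoff 3.84) is available by option since
  the published analyses do not state which was used.
- **MR-Egger** regresses Γ̂_j on γ̂_j with intercept, weights σ_yj⁻².
  Parameter SEs use multiplicative residual overdispersion floored at 1, the
  standard random-effect Egger convention (under-dispersion never tightens
  the fixed-effect SEs). The intercept test is two-sided normal by default;
  a t(J−2) option exists because with J = 4 the choice visibly matters and
  published practice varies.
- **Weighted median**: Wald ratios sorted ascending, weights the inverse
  Wald-ratio variances normalised to sum 1; the estimate is the 50% crossing
  of cumulative weight with breakpoints at (cumulative − half own weight)
  and linear interpolation, so equal weights with odd J give the plain
  median. The SE is a parametric bootstrap (default 2000 resamples of
  (γ̂_j, Γ̂_j) at their SEs; seed mandatory; fewer than 100 resamples only
  warns).
- **Allele scores**: IVW restricted to the synthesis (rs10741657,
  rs12785878) or metabolism (rs2282679, rs6013897) subset, as a sensitivity
  analysis against pathway-specific pleiotropy.
- **Rescaling**: θ is linear on the log-odds scale, so an estimate per
  1 nmol/L converts exactly to exp(±increment·θ) per increment, with the
  sign negated and CI bounds swapped for "per decrease". Default report
  increment: 25 nmol/L.

P-values are two-sided throughout with no multiple-testing adjustment
(estimates are reported per outcome at nominal significance). Display
rounding is 2 decimals for ORs, CIs and P; machine-readable outputs keep
full precision.

## Diagnostics

Cochran's Q = Σ_j w_j(θ_j − θ̂_IVW)² with w_j the IVW weights, df = J−1,
chi-square upper-tail p. The over-identification test — do all instruments
imply the same causal effect? — is realized as the same statistic under its
own label: in the fixed-effect summary-data setting a Sargan-style test is
equivalent up to parameterization, and a single implementation avoids
silent divergence between "goodness of fit" and "over-identification"
reports. Q equals the sum of squared standardized residuals from the IVW
fit (asserted as a test identity). The consistency report places methods
side by side at report rounding and flags pairs differing by more than 0.01
on the OR scale.

## Power

For a case-control design, the two-sided Wald test of the causal log-OR per
1 SD of exposure has approximate power Φ(√(N·R²·K(1−K))·|ln OR| − z₁₋α/₂);
inverting at target power gives |ln OR| = (z₁₋α/₂ + z_pow)/√(N·R²·K(1−K)),
reported as the reciprocal pair exp(∓|ln OR|). This symmetric log-scale
form reproduces the published minimum-detectable-OR cells for the largest
consortia at both R² values (e.g. 0.86/1.16 and 0.89/1.12 for 22 898 cases
/ 23 054 controls) and the protective side of nearly all other rows; a few
published risk-side cells (e.g. 1.39, 0.58/1.57) differ by 0.01–0.03,
indicating an asymmetric variant was used for those that this module does
not attempt to reverse-engineer. Quantiles are computed at full double
precision; rounding happens only at display.

## Synthetic data

The generator draws summary statistics directly at the estimate level —
γ̂_j ~ N(γ_j, σ_xj²), Γ̂_j ~ N(θγ_j + α_j, σ_yj²) with α_j per the
pleiotropy mode (none / balanced / directional) — which is exactly the
model the estimators assume and keeps every experiment at desk scale.
Defaults are the study conditions: the four published γ magnitudes, σ_x
from the printed p-values, and a constant per-allele outcome SE of 0.018,
typical of case-control GWAS of a few tens of thousands of subjects and
giving a pooled IVW CI width per 25 nmol/L (≈ ±0.16 on the OR scale)
comparable to the published cancer analyses. A configurable fraction of
outcome rows is emitted on the opposite allele coding to exercise
harmonization. Seeds are mandatory; identical configs produce byte-identical
tables.

What the generator does *not* emulate — LD between instruments, sample
overlap, winner's-curse selection of instruments, case-control ascertainment
effects on the logistic coefficients, population stratification — bounds
what passing tests show: they validate the estimators and diagnostics under
their own model, not robustness to violations of it.

## Monte-Carlo design of the validation suite

Simulation sizes follow the claims being checked: 200 replicates for
IVW/likelihood agreement at 2-decimal rounding, 2000 for CI coverage
(binomial SE ≈ 0.5 percentage points), 2000 for type-I error of the IVW and
over-identification tests, 2000 for Egger intercept recovery (asserted
within 4 Monte-Carlo SEs of the injected 0.02 log-OR), 1000 for
allele-score agreement. All are seeded and deterministic. The
supplementary-driven regression test uses a synthetic stand-in outcome
table constructed to carry a published-style summary signal (OR 0.92, CI
0.76–1.10, P 0.36 per 25 nmol/L), verifying that the pipeline reproduces
such a row end-to-end when per-variant outcome data are supplied.

## Numerical choices and edge cases

- Normal quantile at 0.975 used for all Wald CIs (1.959964, full
  precision); the scatter export freezes it as a constant for byte-stable
  files.
- `se_from_pvalue` raises for β = 0, p outside (0, 1], or p so large that
  z ≤ 0 (p = 1 has no finite SE).
- A degenerate zero SE requested from the simulator (noise-free limit, a
  testing device) is written as 1e-12 so records stay schema-valid without
  perturbing estimates.
- Exposure effects of exactly 0 cannot be oriented and are excluded during
  harmonization with a logged reason (the Wald ratio would be undefined).
- Weighted-median bootstrap SEs of exactly 0 (degenerate spread) are
  replaced by a tiny positive floor so the CI remains well-formed.
- Estimators are invariant to variant order; records preserve the exposure
  table's order for reproducible output.

## Known limitations

Fixed-effect IVW only (no random-effects inflation); no mode-based
estimators, MR-PRESSO, multivariable MR, leave-one-out scans or funnel
plots; no VCF parsing, liftover, LD-proxy search or covariate
stratification (summary data admit none). The likelihood model ignores
within-study correlation between exposure and outcome estimates, which is
correct only for non-overlapping samples. Real consortium outcome data are
not bundled; analyses of published cancers require the user to supply the
per-variant association tables in the documented format.
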