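# vdmr — two-sample Mendelian randomisation of vitamin D and cancer risk

`vdmr` implements a complete two-sample summary-data Mendelian
randomisation (MR) analysis of circulating 25-hydroxyvitamin D (25(OH)D)
and cancer risk, for epidemiologists who want the whole workflow — allele
harmonization, several causal estimators, pleiotropy diagnostics,
allele-score sensitivity analyses, effect rescaling, and a binary-outcome
power calculator — as a tested, scriptable Python package. A synthetic
summary-statistics generator lets every part of the pipeline run and be
validated without access to consortium data.

## The model

The instrument is a set of J genetic variants. From one GWAS sample we have
per-allele effects on 25(OH)D, γ̂_j (nmol/L) with SEs σ_xj; from an
independent case-control GWAS, per-allele log odds ratios on a cancer, Γ̂_j
with SEs σ_yj. If the variants affect cancer only through 25(OH)D, each
Wald ratio Γ̂_j/γ̂_j estimates the causal log-OR per nmol/L, θ. The package
provides:

- **IVW**: θ̂ = Σ_j γ̂_j Γ̂_j σ_yj⁻² / Σ_j γ̂_j² σ_yj⁻² — fixed-effect
  inverse-variance weighting, equivalently weighted least squares through
  the origin.
- **Likelihood**: the MLE of the bivariate measurement-error model
  γ̂_j ~ N(γ_j, σ_xj²), Γ̂_j ~ N(θγ_j, σ_yj²), which honours uncertainty in
  the SNP–exposure estimates (IVW is its "no measurement error" limit).
- **MR-Egger**: weighted regression of Γ̂_j on γ̂_j with a free intercept;
  a non-zero intercept indicates directional horizontal pleiotropy.
- **Weighted median**: consistent when valid instruments carry ≥ 50% of the
  weight; SE by parametric bootstrap.
- **Allele-score subsets**: IVW restricted to the vitamin D *synthesis*
  (rs10741657, rs12785878) or *metabolism* (rs2282679, rs6013897) pathway
  scores.
- **Diagnostics**: Cochran's Q / over-identification test on the
  variant-specific ratios, and the Egger intercept test.
- **Power**: for a case-control design with N subjects, case fraction K and
  instrument R², power = Φ(√(N·R²·K(1−K))·|ln OR| − z₁₋α/₂), inverted to
  give the minimum detectable OR per SD of exposure.

Reported odds ratios are rescaled to a conventional increment, by default
25 nmol/L (≈ 1 SD of circulating 25(OH)D).

## Worked example

Simulate one two-sample study at a true OR of 0.89 per 25 nmol/L
(θ = ln 0.89 / 25 ≈ −0.00466 per nmol/L), then analyse it:

```bash
$ vdmr simulate --theta -0.00466 --seed 7 --out-dir demo
wrote 1 replicate pair(s) to demo

$ vdmr estimate demo/exposure_0000.tsv demo/outcome_0000.tsv --seed 11
OR per 25 nmol/L increase (4 variants)
               ivw: 0.86 (0.73 to 1.01); 0.06
        likelihood: 0.86 (0.73 to 1.01); 0.06
       egger_slope: 0.78 (0.56 to 1.08); 0.13
   weighted_median: 0.86 (0.72 to 1.01); 0.07
   score_synthesis: 0.81 (0.58 to 1.12); 0.20
  score_metabolism: 0.87 (0.73 to 1.05); 0.15
         cochran_q: statistic=2.682 df=3 p=0.443
            overid: statistic=2.682 df=3 p=0.443
   egger_intercept: statistic=0.466 df=1 p=0.495
```

Each line is an odds ratio per 25 nmol/L *increase* in 25(OH)D with its 95%
CI and two-sided P. Here every estimator recovers the simulated protective
effect (true OR 0.89; the draw lands at 0.86), the two primary methods (IVW
and likelihood) agree to 2 decimals as expected for an instrument this
strong, and none of the diagnostics signals heterogeneity or pleiotropy —
which is correct, since none was simulated.

The power calculator reproduces the design sensitivity of the largest
consortium analysed (22 898 prostate-cancer cases, 23 054 controls,
R² = 0.03):

```bash
$ vdmr power --n-cases 22898 --n-controls 23054 --r2 0.03
minimum detectable OR per SD at 80% power: 0.86/1.16
```

The same functionality is available as a library (`vdmr.harmonize`,
`vdmr.ivw`, `vdmr.run_analysis`, ...) and via `vdmr harmonize` /
`vdmr report --config analysis.yaml` for multi-outcome runs. The
four-variant published instrument ships as a fixture
(`vdmr.published_exposure_associations()`).

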