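# Methods

This note documents the models, conventions, numerical choices and known
limitations of the package. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Lamina cribrosa depth measurement

A B-scan annotation consists of two Bruch's-membrane-opening (BMO)
landmarks and 1–8 anterior-lamina-cribrosa landmarks in physical
micrometres. The BMO reference line joins the two BMO points; its angle α
to the image horizontal is normalized to (−90°, 90°] because the line is
undirected. The scan-level depth is computed by rotating all landmarks by
−α (so the reference line is horizontal) and taking the maximum signed
axial offset of the LC landmarks — algebraically identical to the maximum
perpendicular point-to-line distance, and matching the rotate-then-measure
construction used with manual annotation interfaces. The two readouts
(rotated axial offset vs. implicit-line distance) are kept as independent
code paths, one in the implementation and one in the test oracle, and agree
to 10⁻⁹ μm over randomized annotations.

Conventions and consequences:

- **Sign.** Posterior displacement is positive; the per-file
  `axial_positive_is_posterior` flag makes the convention explicit. A scan
  whose LC landmarks all lie anterior to the BMO line yields a *negative*
  depth rather than an error, preserving information in degenerate or
  pathological annotations. No clipping at zero is applied.
- **Maximum, not mean.** The scan depth is the maximally depressed point;
  ties break to the lowest landmark index.
- **No surface interpolation.** Depth is evaluated on the marked landmarks
  only; fitting a curve through eight hand-placed points would add model
  assumptions the measurement does not need.
- **Rigid-motion invariance** holds for every rotation + translation that
  keeps the reference line's inclination inside the principal range, i.e.
  that preserves which image direction is posterior. A signed depth pinned
  to the image axial axis cannot be invariant under motions that turn the
  scan upside down; those are not meaningful acquisitions. Scaling all
  coordinates by s > 0 scales the depth by exactly s.

The eye-level LCD is the arithmetic mean over selected scans.
`select_central_scans(n_total, k, coverage)` restricts to the integer scan
indices inside the central `coverage` fraction of `[0, n_total − 1]`
(defaults: 75 scans, coverage 0.75), spreads `k` positions evenly across
that band, and rounds halves away from the central scan. In practice scans
were chosen manually where all landmarks could be placed without doubt, so
an explicit index list always overrides the policy. A warning (not an
error) is raised when the number of scans used leaves the customary 12–16
band.

## Rates and the progression rule

Rates divide the parameter difference by the elapsed time with exactly
1 month = 1/12 year; `monthly_change` maps an annual rate to its one-month
increment by dividing by 12. Internal values keep full precision; rounding
to one decimal happens only at the presentation layer.

Progression of the global RNFL is decided against the aging-adjusted
threshold `aging_mean − z·aging_sd` (defaults −0.54 − 1.96×0.23 = −0.9908
μm/year): an eye is *progressive* iff its annualized rate is strictly below
the threshold; the boundary value is non-progressive. The default decision
interval is baseline → final follow-up; the 6-month → follow-up variant is
available for sensitivity analyses. The rule is purely a threshold
comparison — no per-subject significance test is layered on top, since none
is defined for a two-point rate.

## Cohort statistics

**Mixed-effects trend.** `RandomInterceptTrend` fits
y_ij = (β₀ + b₀ᵢ) + β₁·T_ij + ε_ij with time in years, by REML via
statsmodels `MixedLM`; confidence intervals use normal quantiles on the
estimated fixed-effect covariance. Degenerate inputs collapse gracefully to
pooled OLS with a zero variance component and a warning: a single subject,
(near-)noise-free data, or an explicitly disabled random intercept (which
also serves as the pooled-OLS reduction check). If every optimizer fails,
the pooled OLS trend is reported rather than erroring.

**Rank tests.** Two-sided throughout, with the doubled smaller tail capped
at 1. For small samples (≤ 25 nonzero pairs for the signed-rank test,
pooled n ≤ 20 for the rank-sum test) the null distribution is computed
exactly *including ties*: midranks are doubled to integers, and the
distribution of the rank sum is built by shift-convolution (signed-rank)
or a count-and-sum dynamic program over group assignments (rank-sum).
Larger samples use the tie-corrected normal approximation (scipy). Zero
differences are dropped (Wilcoxon's convention); an all-zero sample reports
p = 1 with a warning. The exact implementations are verified against
brute-force enumeration of all 2ⁿ sign assignments / all C(n, n₁) splits.

**Regression.** Univariate regression reports the least-squares slope with
a t-based 95% CI (n − 2 df), Pearson R and the two-sided p. Stepwise
selection is bidirectional — forward entry at p_enter = 0.05, backward
removal at p_remove = 0.10 — applied to candidates that pass the univariate
screen at p ≤ 0.10 and a functional-dependence screen (a candidate that is
an exact linear image of an earlier candidate, |r| ≥ 0.9999, is dropped
with a warning). Selected predictors are reported `In` with their
final-model p; the rest `Out` with the p they would attain if added to the
final model. The exact stepwise dialect (direction and thresholds) follows
the defaults of the classic commercial implementations, since nothing
stronger is identifiable from two-point summaries; the univariate columns
are unambiguous. No multiplicity correction is applied by default; Holm
adjustment is available behind a flag.

**Time coding.** Mixed-model time is years since surgery (not visit
index); visit-wise summaries report the observed mean month per visit so
the non-equidistant schedule stays visible.

## Synthetic cohort generator

Each trajectory follows

value(t) = plateau + (baseline − plateau)·exp(−t/τ) + slope·(t/12) + swelling(t) + ε,

the simplest shape reproducing a fast post-surgical phase followed by a
slow linear drift, plus (RNFL only) a transient swelling bump centred at
1 month. Defaults, with provenance:

| parameter | default | rationale |
|---|---|---|
| subjects / schedule | 29; 0, 1, 3, 6 months + FU ~ U(12, 29) | emulated study design |
| IOP baseline | 24.0 ± 8.9 mmHg | cohort summary statistic |
| IOP plateau, τ, drift | 9 ± 2 mmHg, 0.4 mo, +2.2 ± 1 mmHg/yr | reproduces ~24 → ~12.7 mmHg at a ~20-month follow-up |
| LCD baseline | 465.3 ± 136.4 μm | cohort summary statistic |
| LCD fast drop | 62 ± 30 μm, τ = 0.5 mo | observed first-month LCD reduction |
| LCD slow slope | −53.2 ± 25 μm/yr | mixed-model slope; SD ≈ half the mean, mirroring the dispersion pattern of the published sector rates |
| RNFL baseline | 59.3 ± 15.8 μm | cohort summary statistic |
| RNFL net swelling at 1 mo | +5.6 ± 3 μm, width 0.4 mo | observed 1-month rise; the bump amplitude is solved so the *net* (1-month − baseline) difference equals the configured value after slope and bump-tail compensation |
| RNFL slope | −2.8 ± 4.0 μm/yr | published average thinning rate |
| corr(LCD slope, RNFL slope) | −0.6 | the studied rate–rate association |
| corr(IOP baseline, LCD slope) | −0.4 | higher preoperative pressure ↦ faster LC displacement |
| measurement noise | IOP 1.5 mmHg, LCD 15 μm, RNFL 2 μm | assumed repeatability; free parameters |

The three latents (LCD slope, RNFL slope, baseline IOP) are drawn from a
trivariate normal whose correlation matrix combines the two configured
pairwise correlations under conditional independence given the LCD slope;
it is validated positive semi-definite. RNFL sectors are the global value
plus fixed offsets with sector-specific thinning multipliers (temporal- and
nasal-inferior fastest). A configurable number of subjects can be flagged
lost to follow-up (all but one truncated to baseline, one followed to
6 months) to exercise missing-data paths.

**Model-matched recovery configuration.** `CohortGeneratorConfig.linear_trend()`
zeroes the fast phases, the swelling, *and* the per-subject slope SDs,
leaving exactly the random-intercept linear model plus noise. Parameter
recovery and CI-coverage experiments for the mixed-effects trend use this
configuration, because recovery of a configured slope — and nominal
coverage of its CI — is only well-defined when the generating process
matches the fitted model: fitting a linear trend to biphasic trajectories
estimates a different (steeper) quantity, and slope heterogeneity not in
the fitted model invalidates its standard errors. The default (biphasic,
heterogeneous) configuration remains the realistic cohort emulation.

**What the generator does not emulate:** visit-time jitter, floor effects
in advanced RNFL loss, segmentation failures, eye-level correlation between
sectors beyond a shared global component, or choroidal-thickness
confounding of the BMO reference plane. Passing tests therefore validate
the *analysis machinery* under the stated stochastic model, not the
clinical generalizability of any particular estimate.

The synthetic eye is a circular optic disc whose anterior LC surface is a
paraboloid (default apex depth 400 μm, BMO width 1500 μm, 75 scans); each
horizontal B-scan sees a chord with a parabolic LC profile. The apex is
forced into the 8-point landmark sample, so with zero jitter the measured
scan depth equals the per-scan true apex depth exactly, under any scan tilt
— which exercises the rotation invariance end to end. Landmark jitter is
i.i.d. Gaussian on both coordinates; because the apex is well separated
from its neighbours relative to realistic jitter, the max-statistic bias of
the measured depth stays below 1 μm at 5 μm jitter (checked by Monte
Carlo).

## Numerical and engineering choices

- Exact rank-test arithmetic uses integer doubled midranks and Python
  integers in the convolution tables, so tail counts are exact and the
  two-sided p equals the enumeration oracle's bit for bit.
- Reproducibility: all randomness flows through `numpy` PCG64 generators
  seeded explicitly; a fixed (config, seed) pair yields byte-identical
  cohort tables and report bundles. The pipeline stamps every output with
  the seed and a hash of the analysis-relevant configuration (the output
  directory is excluded from the hash).
- Problem sizes in the test suite and acceptance script — 20-seed recovery
  experiments, 10-seed calibration averages, 1000-annotation oracle sweeps,
  2000-subject moment checks — were chosen as the smallest sizes at which
  the Monte-Carlo error is comfortably below the tolerance being asserted.
- The supplementary-spreadsheet ingester is configuration-driven (a column
  mapping from sheet headers to the canonical cohort schema) because
  deposited spreadsheets do not share a fixed layout; required columns that
  cannot be mapped raise an error listing the sheet's candidates.

## Known limitations

- LCD is referenced to the BMO plane and therefore inherits choroidal-
  thickness changes after surgery; no compensation is attempted.
- The linear mixed model is a deliberate simplification for the IOP time
  course, which is strongly nonlinear early after surgery; the package
  reports the linear trend regardless, as the analysis convention dictates,
  and the generator's biphasic default makes the mismatch visible.
- Stepwise regression inherits the well-known instability of p-value-driven
  selection at n ≈ 29; the `In`/`Out` labels should be read as a screening
  report, not as a final model.
- The progression rule classifies on a two-point rate and is sensitive to
  measurement noise at short follow-up; no attempt is made to model
  within-eye rate uncertainty.
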