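# Methods

This note documents the statistical models implemented in `relpot`, the
numerical choices behind them, what the synthetic-data generator does and
does not emulate, and the package's known limitations.

## Joint parallel-curve model and relative potency factors

### Model

For an endpoint readout measured over a concentration series, the raw
response of substance *s* in independent experiment *e* at concentration
*x* (µM) is modelled as

    y_se(x) = a_se · c^(1 − exp(−(x / b_s)^d)) · exp(ε),   ε ~ N(0, σ²_s)

so log responses carry additive normal noise (a lognormal error model —
the standard choice for strictly positive continuous endpoints, which is
why zero or negative responses are rejected at the input boundary).
The parameters are

| parameter | varies per | units | meaning |
|---|---|---|---|
| `a_se` | substance × experiment | response units | background (response at x = 0) |
| `b_s`  | substance | µM | potency; smaller b = more potent |
| `c`    | shared | fold change | plateau relative to background (c < 1 for downward trends) |
| `d`    | shared | – | steepness on log concentration |
| `σ²_s` | substance | log scale | residual variance |

Because `c` and `d` are shared, all substances trace parallel curves on
log concentration and the relative potency factor RPF_s = b_index / b_s
is simultaneously the ratio of equi-effect concentrations at *every*
effect level. Backgrounds vary per experiment, so raw (non-normalised)
responses can be analysed directly: a multiplicative shift of one
experiment is absorbed entirely by its `a_se` (this is tested as an exact
equivariance).

### Fitting

Maximum likelihood with the nuisance parameters profiled in closed form:
given `(b, c, d)`, each `log a_se` is the mean of the partial residuals of
its experiment group, and each `σ²_s` the mean squared residual of its
substance. The optimiser therefore works in only `n_substances + 2`
dimensions (`+1` when `c` is fixed), using Powell's method from five
heuristic starts (potency starts at the geometric mean of each
substance's positive doses; the plateau start comes from the top-dose vs
control contrast), with deterministic jitter seeded from the
configuration. A tiny variance floor (1e-30) keeps the profiled
likelihood finite on noise-free data without affecting any realistic fit;
zero-noise parameter recovery is exact to ~1e-10 relative.

Bounds (as penalties): b ∈ [1e-6, 1e6] × max concentration,
d ∈ (1e-3, 10], c ∈ [1e-4, 1e4]. The parameter count used in
AIC = 2k − 2·loglik includes every estimated quantity: all backgrounds,
potencies, variances, the shared d and (when free) c.

### Plateau handling

The model is fitted twice: with `c` free and with `c` fixed to a large
fold change — |log c| = log(1e4), signed by the pooled direction of the
top-dose vs control contrast, since a "large" plateau only makes sense on
the response's side of 1. The fit with the lower AIC is kept (ties go to
the fixed-c fit, which has one parameter fewer). Data that level off
inside the tested range select the free plateau; data that keep rising
select the fixed one.

### Confidence intervals and determinability

90 % intervals for log RPF_s come from the profile likelihood: the RPF is
made an explicit parameter by tying log b_s = log b_index − ρ, all other
parameters (including every background and variance) are refitted at each
fixed ρ, and the interval is the set of ρ whose log-likelihood drop stays
within ½·χ²₁(0.90) = 1.3528. Roots are found by expanding brackets plus
Brent's method; each profile refit is run from both the global-MLE
configuration and the previous profile point, keeping the better, because
a stalled refit would overstate the drop and narrow the interval. A side
that fails to close within a factor 1e6 of the point estimate is reported
open: no lower bound, or a fully undetermined RPF if both sides fail.

A substance is *undetermined* when a likelihood-ratio test of its
response trend — full model versus a submodel in which that substance's
curve is flat (one df) — has p > 0.05, or when its potency sits at an
optimisation bound. Undetermined substances keep their row in every
output (never silently dropped) and are excluded pairwise from rank
correlations.

Monte-Carlo calibration (300 replicate intervals at true RPFs 0.1 and 10,
three experiments × triplicates × control + seven concentrations, each
substance dosed over a range-found grid) puts the empirical coverage of
the 90 % intervals near 0.88. With a single common grid for substances
spanning a 100-fold potency range, the extreme substance's potency falls
outside the tested concentrations and its coverage degrades to ~0.79 —
the practical reason concentration ranges are set per substance in this
kind of study, and why the calibration experiment does the same.

## Gene-wise benchmark concentrations

Expression values are already log2, so they are modelled with additive
normal errors directly (unlike the endpoint engine, which logs raw
responses).

1. **Prefilter.** One-way ANOVA across concentration groups per probe,
   Benjamini–Hochberg step-up across probes, keep adjusted p < 0.05. No
   fold-change cut at this stage. Probes with an undefined F statistic
   are excluded with a warning. Under a complete-null matrix the *raw*
   per-probe false-positive rate is the nominal α (this is the calibrated
   quantity); the BH-adjusted prefilter then rejects essentially nothing,
   since under the full null the step-up controls the familywise rate.
2. **Model suite.** Nine continuous mean functions (Exp2–Exp5, Linear,
   Poly2, Poly3, Hill, Power; EPA-BMDS-style parameterisations, see the
   module docstring) fitted per probe: polynomials in closed form, the
   rest by bounded trust-region least squares from two or three heuristic
   starts. Hill's midpoint k is bounded to [lowest positive dose/10,
   10 × max dose]; exponents to (0.3, 8]. AIC counts the mean parameters
   plus one variance.
3. **BMC.** The benchmark response is 1.021 × σ̂ on the log2 scale by
   default — the SD-multiple reading of the BMR factor; a fold-change
   reading (|Δlog2| = log2 1.021) is available as `bmr_mode="fold"`
   because the convention is ambiguous. The BMC is the *first*
   concentration in (0, 10 × max dose] where the fitted mean departs from
   its control value by the BMR (polynomials may be non-monotone; the
   first crossing is taken), found by a 400-point geometric scan plus
   Brent root-polishing. For the linear model this reproduces the closed
   form BMR·σ̂/|slope| to full precision.
4. **BMDL/BMDU.** Two-sided 90 % profile likelihood over the BMC. The
   BMR is anchored at the MLE σ̂ while profiling (σ stays free in the
   likelihood but fixed in the constraint); this decouples the constraint
   from the variance parameter so that, at each candidate BMC, one
   magnitude parameter can be eliminated from the constraint in closed
   form (e.g. the linear slope, Hill's v, Exp4's rate) and only the small
   remainder is refitted numerically. A side whose likelihood drop never
   reaches the threshold inside [1e-6, 10] × max dose is reported at the
   bracket end. Bounds are computed for the AIC-best model per probe —
   the only model whose bounds the downstream filters consume.
5. **Goodness of fit.** Likelihood ratio against the saturated
   group-means model, χ² with df = n_groups − n_mean_params; reported
   absent when df ≤ 0. Fits whose residuals sit at float precision are
   assigned p = 1 directly.
6. **Best model.** Lowest AIC among converged fits with a BMC; ties to
   fewer parameters, then to a fixed ordering of the nine names.
7. **Fold change and direction.** Per-group means minus the control mean
   on log2; the group with the largest |Δ| gives the signed linear-scale
   value sign(Δ)·2^|Δ|, whose sign is the probe's direction.

## Gene filters and category analysis

Probe-level results reduce to genes by: removing probes mapping to more
than one gene (promiscuous); requiring a BMC at or below the highest
tested dose; fit p ≥ 0.1 (a probe whose p is undefined is kept, counted
in the report); BMD/BMDL ≤ 20 and BMDU/BMDL ≤ 40 (boundary inclusive);
|max fold change| ≥ 1.2. A gene whose surviving probes split in direction
with minority fraction ≥ 0.5 (an exact split or worse) is removed as
conflicting; otherwise the gene takes the majority direction, the mean of
its probes' BMCs and the mean fold change.

Each catalog set is tested with the two-tailed Fisher exact test on the
2×2 table (regulated-in-set vs universe), where the universe is every
gene carried by at least one non-promiscuous probe on the platform — not
the whole catalog. The two-tailed p sums hypergeometric probabilities no
larger than the observed table's (verified against exact integer
enumeration to < 1e-12 across universes up to 200). A set is reported
when p ≤ 0.1, at least 5 regulated genes, and ≥ 20 % of platform members
regulated; its direction class is up/down at the inclusive 60 % majority
threshold, else mixed; its summary concentration is the median BMC over
regulated genes. No multiplicity correction is applied across sets at
this level. The minimum-gene and conflict thresholds are deliberately
config-exposed: both are tool-convention readings rather than uniquely
determined rules.

## Synthetic data: what it emulates, what it does not

**Endpoint generator.** Draws from exactly the parallel-curve model:
per-experiment lognormal background shifts (SD 0.3), per-substance
potency from a true RPF vector (defaults 1 / 0.1 / 10 around an index
potency of 50 µM), shared plateau (2-fold) and steepness (1), lognormal
response noise (σ = 0.15, a realistic ~15 % CV for plate-reader and qPCR
endpoints), three independent experiments with triplicate measurements
over control + 6.25…400 µM. Grids can be set per substance;
`range_found()` scales the base grid by 1/RPF, emulating the
dose-range-finding that precedes such studies. Because the generator *is*
the estimator's model, endpoint tests demonstrate correctness of the
estimator, not robustness to model misspecification.

**Expression generator.** 200 probes × (8 concentrations × 3 samples),
probe baselines N(8, 1.5²) log2 units, noise SD 0.25. Five of ten
disjoint 10-gene sets are regulated with alternating direction; each
regulated gene follows a Hill-shaped log2 shift (coefficient 3) reaching
1.5 log2 units, with its own benchmark concentration drawn lognormally
around 50 µM (log-SD 0.3). The Hill shape is deliberately *not* the
engine's exponential, so the screen is not validated against its own
generating family. Small fractions of promiscuous (3 %) and
direction-conflicting (2 %) probes exercise the quality filters. Not
emulated: probe-level intensity physics, normalisation artifacts,
correlated noise between genes, batch structure — so passing tests show
pipeline correctness on clean signal, not microarray-grade robustness.

## Problem sizes used in tests and the acceptance script

Calibration runs use 150 three-substance panels (300 profile intervals),
a 1000-probe null matrix, 400–500 random Fisher tables plus exhaustive
enumeration at small universes, and the 200-probe default matrix for the
end-to-end recovery check; these sizes give binomial/CLT error bars well
inside the asserted bands while keeping the whole suite desk-scale.

## Known limitations

- The parallel-curve engine fits one endpoint at a time; there is no
  information sharing across genes or readouts, and no covariates on `c`
  or `d`.
- Only the exponential family is offered for RPFs (no Hill-family
  alternative), and reporting is potency-ratio based, not
  benchmark-response based.
- BMDL/BMDU anchor the BMR at the MLE σ̂; a fully joint profile over the
  variance would widen bounds slightly for small samples.
- The trend/determinability test is a 1-df LRT at p > 0.05; with very
  many substances no multiplicity adjustment is applied to it.
- Profile-interval coverage is calibrated under the generator's
  conditions; designs whose tested concentrations miss a substance's
  active range will under-cover (measured ~0.79 for a 10-fold-potent
  substance dosed on the index's grid).
- Dichotomous endpoints, time-course designs and binary toolchain file
  formats are out of scope.
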