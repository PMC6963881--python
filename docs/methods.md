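# Methods

This note documents the statistical models chromaval implements, the
parameters that matter, the numerical choices made where conventions differ,
and what the synthetic-data generators do and do not emulate.

## System suitability

The suitability statistics are the half-height pharmacopoeial forms:
k′ = t_R/t₀ − 1, N = 5.54·(t_R/W½)², As = W₅%/(2F), where F is measured
from the leading-edge 5%-height crossing to the apex time. Repeatability is
the percent relative standard deviation with the (n−1)-denominator sample
standard deviation — the convention in validation practice; a population-SD
variant is deliberately not offered to avoid silent inconsistency between
laboratories.

k′, N and As are single-injection quantities. `assess_suitability` reports
them for the first (reference) injection, and additionally exposes per-peak
values and their mean, since monographs differ on whether a single injection
or an average is judged. The RSDs always pool all injections. Acceptance
limits (k′ > 2.0, N > 2000, 0.8 ≤ As ≤ 1.5, both RSDs < 5%) are
configuration with these defaults, so other monographs can override them
without code changes; all comparisons against limits are strict.

## Calibration model

The detector response is modeled as y = a·x + b over a working range of
0.5–7.0 mg/mL (eight levels, triplicate — the default grid of the simulator;
any ≥ 3-level balanced design is accepted). Replicates enter the regression
as individual points, not level means, so n = levels × replicates.

**Variance homogeneity.** The F-test compares the replicate variances at the
two extreme levels: F_calc puts the larger variance in the numerator (so
F_calc ≥ 1 and the result is invariant to level order), with degrees of
freedom (n−1, n−1) from the two replicate counts and a one-sided critical
value at 99% confidence (scipy's F quantile; (2,2) df gives 99.0).
Heteroscedasticity is declared when F_calc > F_crit. Only the two extreme
levels enter, which is the conventional quick test; it has low power with
triplicates — the residual plot (`residuals`) is the complementary visual
check.

**Weighted fits.** Raw weights 1, 1/y^0.5, 1/y, 1/y², 1/x^0.5, 1/x, 1/x² are
normalized to Σw = n before the normal equations. Normalization does not
change the fitted line (weights enter homogeneously) but makes the
mixed-moment form of the slope formula, which combines Σwxy with n·X̄wȲw,
internally consistent, and makes weights comparable across schemes. The
intercept is b_w = Ȳw − a_w·X̄w, the standard weighted intercept. The
weighted correlation coefficient uses the weighted product-moment form.
1/y weights use the *observed* responses in a single pass; no iterative
reweighting is performed, because the selection statistic below is defined
on the single-pass fits.

**Scheme selection.** Each fitted line back-calculates every calibration
point, C_exp = (y − b)/a, and %RE = 100·(C_exp − C_nominal)/C_nominal. The
selection statistic is Σ|%RE|: absolute values, because a signed sum would
reward cancellation of opposite errors rather than small errors. Ties break
by larger |r|, then by the conventional scheme order. %RE is on the percent
scale (×100).

**Residual scale and detection limits.** S_y defaults to the residual
standard error √(SSE/(n−2)), with the weighted SSE under a weight scheme.
LOD = 3.3·S_y/|a|, LOQ = 10·S_y/|a|, so LOQ/LOD ≡ 10/3.3 identically. ICH
Q2(R1) also sanctions the standard deviation of the intercept as the
"standard deviation of the response"; `detection_limits(fit,
basis="intercept")` provides that reading. Both are computed from the same
weighted design matrix.

**Degenerate inputs.** Fewer than three levels, non-positive concentrations,
or zero concentration variance are rejected. A zero replicate variance at an
extreme level makes the F-test undefined; the low-level `f_test_homoscedasticity`
raises, while the orchestrating `calibrate` records the test as undefined
(not heteroscedastic) so that noise-free data — exactly on a line — flow
through the full workflow.

## Accuracy, precision, robustness

ε_r = (C_nominal − C̄_determined)/C_nominal·100 is implemented exactly in
this orientation: a determined mean above nominal gives *negative* ε_r,
i.e. negative values mean over-estimation. The orientation is preserved
rather than flipped because sign conventions differ between laboratories and
silently re-orienting would corrupt comparisons; the magnitude is what the
5% limit judges. Precision is plain %RSD per level and day; inter-day
precision is a second labeled replicate set, not a variance-components
model — the quantity reported in routine validation is the per-day RSD.
Robustness relative errors are 100·(variant − baseline)/baseline per metric
with a 10% limit on every metric; a zero baseline metric yields a per-metric
"undefined" note (NaN) while the row is still emitted, and single-injection
rows are accepted (replication per condition is often not reported).

## Degradation kinetics

First-order decay: ln(P_t) = ln(P₀) − k·t, fitted by unweighted least
squares on (t, ln value); k is the negated slope, R² the squared correlation
of the same regression. Half-life uses the conventional rounded constant
0.693 rather than ln 2 = 0.69315…, because stability reports are computed
with 0.693 and a reader reconciling the package against such a report should
reproduce it to the printed digit; ln 2 is available via
`half_life_constant=math.log(2)` (a 0.02% difference). t₀.₅ is always
derived from the *unrounded* fitted k — rounding k first (e.g. 0.693/0.0049
= 141.4 h) loses roughly 1% of the half-life for rates of this magnitude.

Series with replicate measurements fit on per-time means by default;
`use_replicates=True` fits all points (identical slope in balanced designs,
lower R² because within-time scatter enters the residuals). A flat or rising
course is reported as k = 0 with infinite half-life and a `degrading=False`
flag rather than a negative rate.

The packaged reference courses (ampicillin in HEN/HEL/LEL TPN admixtures,
0–144 h at 4 °C, sampled every 24 h) are per-time mean contents in percent
of initial; their published per-time SDs are carried in the CSV for
reporting but do not enter the default fit. The published R² values for
these courses were evidently computed on replicate-level data that is not
available, so R² from the packaged means will not match them; the rate
constants and half-lives do.

## Synthetic data

`simulate_calibration` draws y = a·x + b + ε with
ε ~ N(0, σ₀² + (σ₁·μ)²): independent additive (σ₀, response units) and
proportional (σ₁, fraction of the noiseless response μ) components. Any
σ₁ > 0 makes the variance grow with response — the structure that the F-test
detects and weighting corrects. Defaults mirror the validation design this
package grew around: eight levels 0.5–7.0 mg/mL, triplicates, slope 1.2×10⁶
response units per mg/mL (the magnitude of a UV peak-area response at
analytical concentrations). σ₁ ≈ 0.03 gives realistic 2–3% response RSDs.

`simulate_decay` draws 100·exp(−k·t)·(1+ε), ε ~ N(0, noise_sd_frac²),
renormalized so the t = 0 mean is exactly 100. Multiplicative noise matches
the roughly constant relative SDs seen in stability assays (defaults:
k = 0.005 h⁻¹, 2% noise, the 7-point 0–144 h grid).

`simulate_trace` sums skew-normal-shaped peaks (one skew parameter; negative
skew fronts the peak) over a linear baseline with Gaussian detector noise.
A skew-normal profile was chosen over the exponentially-modified Gaussian
because only the qualitative fronting/tailing behavior is needed to exercise
the asymmetry measurement; it is not a physical detector model.
`measure_peak` locates the apex as the local maximum near a hint,
baseline-corrects with a straight line through the trace edges, interpolates
the 50%/5% threshold crossings linearly, and integrates the trapezoid
between the 5% crossings. On an analytic Gaussian this reproduces
W½ = 2.355σ and W₅%/W½ = √(ln 400/ln 4) ≈ 2.079 within 1% at 200
points/min.

What the generators do *not* emulate: gradient elution, co-elution and
matrix interference peaks, detector saturation, autocorrelated baseline
noise, and between-day drifts. Tests passing on synthetic data therefore
demonstrate the correctness of the computations under the stated noise
models, not the validity of any particular laboratory method.

## Pipeline

Stages run in the order suitability → linearity/limits → accuracy/precision
→ robustness → kinetics; each is independently optional and skipped with a
recorded reason when unconfigured. All thresholds (suitability limits, 5%
accuracy/precision, 10% robustness, 99% F-test confidence, the half-life
constant, the |r| ≥ 0.99 linearity verdict) are configuration recorded in
the report's provenance block together with input SHA-256 digests, the seed
and the package version. Verdicts are pure functions of the numeric results
and the configured limits. JSON output is machine precision; markdown is
rounded to report-table precision.

## Problem sizes

The test suite's simulation-based checks use 200–500 seeded replicates of
the default designs (24-point calibrations, 7-point decay courses), sizes at
which the Monte-Carlo checks are stable across seeds while the whole suite
runs in seconds.

## Known limitations

- Nonlinear calibration (quadratic, 4PL) and iteratively reweighted fitting
  are out of scope; the weight schemes are the six empirical ones.
- The F-test uses only the two extreme levels; Levene/Brown–Forsythe across
  all levels is not implemented.
- Inter-day precision is a labeled RSD, not a mixed model; no
  measurement-uncertainty budget.
- Kinetics covers first-order only — no zero/second-order alternatives,
  Arrhenius extrapolation or t90 shelf-life estimation.
- Peak measurement assumes a single resolvable peak near the hint; no
  deconvolution of overlapping peaks.
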