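# Methods

## Growth-curve kinetics

Optical density (OD) is treated as a biomass proxy that grows exponentially
during balanced growth. The estimator makes no parametric assumption about
the whole curve (no Gompertz/Baranyi/Richards fit): it enumerates every
contiguous run of samples whose time span is at least `min_window_h`
(default 3 h) and whose last sample lies at least `min_elapsed_h` (default
6 h) after the first sample of the curve, fits ln(OD) on time by ordinary
least squares within each window, and reports the largest slope as μ_max.
The elapsed-time rule is read as a constraint on the window's *end* time;
this is configurable because reasonable people could instead constrain the
window's start. Ties (within a 1e-9 relative tolerance) go to the earliest
window start, then the shortest span, which pins down a unique answer on
noiseless single-phase curves where every window has the same slope.

Two practical guards surround the window scan:

- **Blank handling.** `preprocess` subtracts a configurable blank OD
  (default 0) and floors the result at 1e-4 so logs stay finite. A curve
  whose every point lands on the floor is rejected as degenerate.
- **Window quality gate.** Near the detection limit, read noise is enormous
  in log space: a single low outlier followed by recovery can produce a
  steeper window than true growth, with an obviously poor fit. Windows with
  R² below `min_window_r2` (default 0.95) are therefore disqualified; a
  genuine exponential window is close to perfectly log-linear, so the gate
  costs nothing on clean data. If no admissible window qualifies (e.g. a
  non-growing well) the gate is dropped so the flat slope is still reported,
  with a `non_growth` flag.

Lag is the intersection of the winning window's extrapolated line with the
first (blank-subtracted) OD: λ = (ln OD₀ − intercept)/μ_max. Negative lags
are reported as-is — clamping would bias comparisons between fast- and
slow-starting strains. The doubling time is ln 2 / μ_max by identity.

Time-to-threshold interpolates the first crossing between bracketing
samples linearly in ln(OD), because growth is exponential through the
crossing region; linear-OD interpolation is available behind a flag for
sensitivity checks. A curve that never reaches the threshold raises an
error carrying the maximum OD attained, and the derived performance is
reported as missing rather than invented.

**Estimator bias.** Averaging a 3 h window over a logistic curve slightly
under-reads μ when the inoculum is a non-trivial fraction of the carrying
capacity: at x₀/K = 0.01 (a 1:65 dilution of a stationary culture, as in a
typical serial-transfer regime) the bias is ≈ 1.4%, falling to ≈ 0.5% at
x₀/K = 0.001. The window scan is validated two ways: exact agreement with a
brute-force enumeration oracle on both clean and noisy curves, and sub-1%
parameter recovery on dilute-inoculum (x₀/K = 0.001) noiseless sweeps where
the exponential phase is long enough for the procedure to be identifiable
at that precision.

## Viability and the death-only expectation

Spot-plating counts convert to viable density as
CFU/mL = colonies × dilution × (1000 / plated µL). Zero colonies return 0
with a detection-limit flag (one colony at that dilution and volume) rather
than an error — empty spots at high dilution are routine. Survival is the
ratio of paired before/after densities; replicate vectors are paired,
ratioed, then summarized as mean ± SEM. Ratios above 1 (counting noise) are
kept for statistics but flagged, and clamped to 1 only inside simulations.

The kill curve is modelled as log-linear inactivation with an optional
shoulder: ln N(t) = ln n₀ − k·(t − s)₊. For each candidate shoulder s
(every observed duration short of the longest) the two free parameters
(ln n₀, k) are fitted jointly by OLS on the hinge design, and the breakpoint
with the smallest residual sum of squares wins, ties going to the smallest
shoulder so a pure log-linear decline reports s = 0. Fitting the hinge
jointly — rather than a free pre-shoulder mean plus a separate post-shoulder
line — keeps every candidate at the same parameter count, so the breakpoint
search compares like with like. Input sizes are small enough that the
exhaustive search is exact and deterministic.

The *death-only expectation* answers: what would the post-shock curve look
like if killing were the shock's only effect? The surviving inoculum
S·OD₀ is grown under the untreated fit — flat through the untreated lag,
then exponential at the untreated μ_max, capped at the reference curve's
plateau (killing does not change the carrying capacity). Because the
survivors need log₂(1/S) extra doublings to regain the lost biomass, the
expectation is exactly the untreated curve delayed by
Δλ = t_d · log₂(1/S) throughout the exponential phase; at S = 1 it
reproduces the reference. `lag_attribution` then splits any *observed* lag
increase into this death component and an unexplained remainder
(physiological recovery; may be negative and is reported as-is).

## Performance and tradeoff statistics

Performance in regime x is P_x = t_ref / t_x, the time to reach a fixed OD
threshold under 30 °C reference growth divided by the time in the regime of
interest; P = 1 means no impairment, P = 0.5 means twice as slow. The
metric deliberately avoids growth-rate comparisons because stressed
cultures often fail to follow clean exponential or logistic dynamics. Each
replicate's ratio is computed against the same replicate's reference time,
and replicate ratios are then averaged (ratio first, average after).
Missing performances (threshold never reached) are dropped pairwise with a
logged count.

The threshold itself is a configuration choice. When unset, the pipeline
uses half the median fitted plateau of the reference-condition wells — a
mid-curve value robust to plateau noise — and records it in the run
manifest; it is always overridable.

Tradeoff lines are ordinary least squares of P_35 on P_HS across strains
(r² = 1 − SSE/SST, with the convention r² = 0 when SST = 0). Two cohorts'
slopes are compared by ANCOVA: the pooled model
y = b₀ + b₁x + b₂g + b₃(xg) with group indicator g, reporting the two-sided
t test on the interaction b₃ with n − 4 residual degrees of freedom (the
single-degree-of-freedom interaction F is its square). Per-group slopes
from separate fits coincide with b₁ and b₁ + b₃ by construction and are
reported alongside. Exactly collinear inputs (zero residual variance) are
resolved deterministically: p = 1 when the slopes agree, p = 0 with an
infinite-t flag when they differ.

"Student's t-test" is implemented in its classical pooled equal-variance
reading, with Welch available behind a flag. Zero pooled variance returns
t = 0, p = 1 for equal means and an infinite-t flag otherwise. No
multiple-testing correction is applied to per-isolate comparisons, matching
the plain α = 0.05 decision rule such experiments report; the statistics
layer exposes everything needed to add one downstream.

The regression treats P_HS as the covariate even though both axes carry
measurement noise; errors-in-variables or reduced-major-axis alternatives
are out of scope.

## Serial-transfer generation accounting

One cycle contributes log₂((V_fresh·1000 + V_transfer)/V_transfer)
generations from dilution regrowth plus log₂(1/S) from regrowing the killed
fraction. The dilution factor uses the post-mix total volume; the pre-mix
convention differs by < 0.02 generations at typical volumes, and the
convention is recorded in the output. Totals are kept as real numbers and
rounded only for presentation. For the default scheme (5 mL, 78 µL,
S = 0.5) this gives 6.02 + 1.00 ≈ 7 generations per cycle and ≈ 140 over
20 cycles.

## Synthetic data: what it emulates and what it does not

The generators exist so every stage has ground truth. Their defaults are
fixed at values representative of a mesophilic methylotroph assayed in a
plate reader:

| parameter | default | rationale |
|---|---|---|
| μ (growth rate) | 0.21 h⁻¹ | doubling time ≈ 3.3 h at the growth optimum |
| inoculum OD above blank | 0.01 | ~1:65 dilution of a stationary culture near OD 1 |
| plateau OD | 1.0 | typical minimal-medium carrying capacity |
| blank OD | 0.04–0.05 | plate + medium background |
| OD noise sd | 0.005 | additive plate-reader read noise, floored at 1e-4 |
| sampling interval | 0.25 h | a common plate-reader cadence (a convention, not a measured value) |
| kill curve n₀ | 1e9 CFU/mL | stationary-phase density |
| kill rate k | 0.12 min⁻¹ | ≈ 55% survival after a 5 min shock |
| cohort size / slope / scatter | 14 / −2.5 / 0.05 | an evolved-isolate-sized cohort with a steep tradeoff |
| P_HS range | 0.3–0.7 | shocked strains substantially slower than reference |
| reference time-to-threshold | 20 h | threshold OD 0.1 reached ~11 h after lag ends |

Growth curves are a hard time-shift lag followed by logistic growth —
deliberately the simplest model with the three visible phases, and the lag
convention that makes ground truth unambiguous. The fitting module never
assumes this form. Cohort performances are embedded by shifting lag at
fixed μ so that t_x = t_ref/P_x exactly; the prescribed performance range
must satisfy P ≤ t_ref/τ (τ = the climb time from inoculum to threshold,
≈ 11.4 h at the defaults), otherwise the required lag would be negative —
such lags are clamped to zero and logged, and the defaults leave headroom
(P up to 1.75). Performance values pushed below 0.05 by scatter are floored
and logged.

Deliberately not modelled: multiplicative or autocorrelated noise,
evaporation drift, diauxic or multi-phase growth, clumping artifacts,
temperature-dependent rate laws, and mutation/selection dynamics. Passing
the recovery tests therefore demonstrates correctness of the estimators
under clean three-phase kinetics with additive noise — not robustness to
every failure mode of real plate-reader data, which is precisely why the
time-to-threshold performance metric (robust to non-exponential dynamics)
exists alongside the growth-rate fit.

All randomness in a generator call flows from a single seeded
`numpy.random.Generator`; identical seeds give bit-identical outputs, and
seeds are recorded in run manifests along with config hashes and input
checksums, so identical manifests imply byte-identical result tables.

## Validation problem sizes

The test suite validates: estimator-vs-oracle equality (window scan against
brute-force enumeration; OLS, ANCOVA and t-tests against closed-form normal
equations and scipy) to 1e-10; μ within 1% and lag within one sampling
interval on a 25-point noiseless parameter sweep (μ ∈ [0.1, 0.5] h⁻¹,
lag ∈ [0, 10] h, x₀/K = 0.001); lag-recovery bias under read noise within
0.25 h over 100 seeded triplicate simulations; kill-curve (k, shoulder)
recovery exact on noiseless input and unbiased within 2 SE over 200 Poisson
replicates; end-to-end tradeoff-slope recovery unbiased within 2 SE over
100 seeded cohorts for slopes −2.5, −1.0 and 0; and ANCOVA type-I error
within [0.035, 0.065] at α = 0.05 over 1,000 null simulations. These sizes
keep the full suite under ten seconds while leaving the Monte-Carlo checks
enough resolution to detect calibration errors of practical magnitude.

## Known limitations

- The window fit inherits the mild logistic under-read of μ described
  above; dilute inocula or a smaller `min_window_h` reduce it.
- The shoulder estimate is restricted to observed durations; with sparse
  duration grids its sampling distribution is discrete.
- The ANCOVA assumes homoscedastic residuals across cohorts; strongly
  unequal scatter would call for a Welch-style slope comparison that is not
  implemented.
- Absolute performance values depend on the chosen OD threshold; only
  threshold-consistent comparisons across strains and cohorts are
  meaningful.
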