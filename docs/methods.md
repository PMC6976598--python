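# Methods

## Problem and model

The wound-healing (scratch) assay measures collective cell migration as
closure of a scratched gap in a monolayer, reported by live-imaging
instruments as relative wound density (RWD) over time.  Its central
confound is that cytotoxic drugs also delay closure: dead cells do not
migrate.  With proliferation suppressed (Mitomycin-C pre-treatment,
recorded here as a boolean well annotation) and apoptosis monitored
concurrently through an integrated caspase-3/7 reporter, the observed
closure delay can be decomposed into a migration and a death component.

Per stratum — one cell line at one seeding density and MMC state, sharing
one vehicle (DMSO) control — and per analysis window, each condition xi
gets AUC-based change metrics:

    WC_xi  = (AUC(RWD)_ctrl − AUC(RWD)_xi) / AUC(RWD)_ctrl
    WC_ind =  AUC(RWD)_xi / AUC(RWD)_ctrl              (WC_xi + WC_ind = 1)
    DC_xi  = (AUC(D)_xi − AUC(D)_ctrl) / AUC(D)_max

where D is the caspase trace and AUC(D)_max the stratum-wide maximum
(control included; the normalizer's scope is a documented choice — the
alternative, per-drug-series, would change DC by a constant factor within
a series and leave the fitted angles' ordering intact).  Negative DC is
clamped to 0 and the raw value kept; a drug cannot contribute negative
death to a delay.

The dose series traces a curve in the (DC, WC) plane from the control
origin.  It is fitted with the saturating first-order model

    WC = wc_max · (1 − e^(−k·DC))

by bounded nonlinear least squares (see Numerical choices), falling back
to a straight line DC = slope·WC through the origin when r² < 0.6, when
the series is degenerate-vertical (DC variance < 1e-12, the
Sorafenib-like no-death case), or when the optimizer fails.  At each dose
the tangent angle θ measured **from the vertical (WC) axis**,
θ = arctan(dDC/dWC), apportions the delay:

    Death_xi     = WC_xi · θ_xi / (π/2)
    Migration_xi = WC_xi − Death_xi

Axis orientation matters and is deliberate: a vertical landscape (death
never changes) must give θ = 0 and hence a pure-migration call, and a
horizontal one θ = π/2 and a pure-death call.  Only the
angle-from-vertical reading satisfies both limits.

Per-dose scores are summarized into "lumped" scores as trapezoidal AUCs
over the log2-concentration axis divided by the log2 range — i.e. mean
scores over the two-fold serial dose series — making series with
different dose ranges comparable.

## Analysis windows (endpoint criteria)

* **A** — the fixed experiment endpoint, default 72 h.
* **B** — the earliest time at which the vehicle control's closure rate
  has declined to ≤ `slope_threshold` (default 0.02 RWD-fraction/h),
  estimated by central differences smoothed with a 3-point moving
  average, searched only after the control RWD exceeds `slope_guard`
  (default 0.25) to skip the initial lag plateau.  One window per
  stratum.  Both the smoothing width and the guard are configuration
  fields.  The threshold is interpreted in fractional units per hour;
  percent-per-hour would place the endpoint at essentially full
  saturation and reduce B to A.
* **C** — the per-condition time at which RWD first reaches `rwd_target`
  (default 50%), by linear interpolation, falling back to the last
  observed time.  Because windows then differ between conditions, AUCs
  are divided by window length (time-averaged) before the WC/DC formulas.

Method B exists because closure speed depends on seeding density and on
intrinsic cell-line motility; ending the window when the control
saturates normalizes that variability, whereas a fixed 72-h window mixes
the informative closure phase with an uninformative saturated plateau in
density-dependent proportions.

## Phenotypic bias and robustness

In the (migration, death) plane the diagonal is the no-bias line.  Each
dose is summarized by the signed perpendicular distance
sin(π/4)·(death − migration) (positive = cytotoxic side) and by the
angular deviation arctan2(death, migration) − π/4 in [−π/4, π/4] (defined
as 0 at the origin).  Series are classified from lumped scores:
`inactive` below an activity floor (default 0.05 total), otherwise
`migrastatic`/`cytotoxic` by the sign of the lumped bias outside a dead
band (default 0.05), else `balanced`.  Both floors are configuration
fields; they are scoring conventions, not measured constants.

Density robustness is quantified by two-sample Kolmogorov–Smirnov tests
between the 8-value per-dose bias samples of two seeding densities, using
the exact small-sample null distribution whenever n_a·n_b ≤ 10⁴ (always,
for the 8-dose design).  Cell lines are grouped by agglomerative
hierarchical clustering (Euclidean, average linkage) of their lumped-bias
profiles across drugs; rows are processed in lexicographic order so the
assignment is deterministic.

## Synthetic-assay generator

The simulator provides ground-truth screens for testing.  With front
speed `v = v0·(density/density_ref)^density_exponent·(1 − emax_mig·H_mig(d))`
and death rate `δ = delta0 + dmax·H_death(d)` (Hill functions H of dose d),

    RWD(t)     = 1 − exp(−v·(1 − e^(−δt))/δ)     (δ→0 limit: 1 − e^(−vt))
    caspase(t) = baseline + gain·(1 − e^(−δt))

so death both slows closure and caps its plateau below 1 — reproducing
the confound the scoring must disentangle.  Noise is multiplicative
lognormal per sample (positive signals; additive Gaussian would allow
negative caspase values), seeded from a hash of (seed, condition) so any
subset of a screen regenerates identically.

Defaults: v0 = 0.06/h (50%-closure near 12 h at the reference density of
30 000 cells/well — an intermediate-motility line), density_exponent 0.5
(denser wells close faster, ~40% spread over 20k–40k), delta0 = 0.002/h,
motility Hill (emax 0.9, EC50 1 µM, slope 1.5), death Hill (0.08/h added
rate, EC50 2.5 µM, slope 1.5; above the motility EC50 so the mixed
scenario is low-dose migrastatic and high-dose cytotoxic), caspase
baseline 100 AU and gain 5000 AU, noise 2%, 2-h sampling over 72 h,
2 replicates, 8-dose two-fold series from 10 µM.  Scenarios zero the
relevant Hill amplitude: `pure_migrastatic` (no death effect),
`pure_cytotoxic` (no motility effect), `null` (neither), `mixed` (both).

What the simulator does **not** emulate: proliferation (MMC assumed
effective), spatial wound structure and edge effects, incomplete closure
of sub-confluent monolayers, density-dependent caspase scaling,
instrument drift, or well-to-well biological heterogeneity beyond the
noise model.  Passing tests therefore demonstrate the correctness of the
scoring machinery under the stated kinetic model, not the biology of any
particular cell line.

## Numerical choices

* Integration is trapezoidal on the native sampling grid, with linear
  interpolation at a window end falling between samples; exact for
  piecewise-linear traces.
* RWD is stored as a fraction in [0, 1]; percent appears only at file
  boundaries.  Instrument overshoot in (100, 105]% is clamped to 100% on
  read; larger values are errors.  The writer chooses a percent string
  whose parse-and-divide reproduces the stored fraction bit-exactly
  (searching a few ulps around fl(100x)), and the simulator snaps its
  RWD values onto the percent-representable grid, so write/read
  round-trips are bit-exact.
* First-order fit: `scipy.optimize.curve_fit` with bounds
  wc_max ∈ (0, 1.5], k ∈ (0, 10⁴]; initialized at wc_max₀ = max observed
  WC and k₀ = (initial secant dWC/dDC)/wc_max₀, floored at 10⁻³.  r² is
  computed on WC residuals; the linear fallback is accepted without a
  second quality gate.
* θ is evaluated at the point's projection onto the fitted curve (the
  fitted abscissa at the observed WC), which damps observation noise;
  observed WC at or beyond the fitted plateau clamps θ to π/2 with a
  warning.  Negative fallback-line slopes clamp θ to 0.
* Conditions with WC < 0 (closure enhancement) receive zero scores and a
  flag; the decomposition is only meaningful for delays.
* Replicates are averaged pointwise before scoring; time grids must match
  exactly within a stratum (no silent resampling).
* All CSV result tables are written with 9 significant digits for
  platform-stable regression comparisons; simulated raw data use
  shortest-round-trip representations.

## Problem sizes used in tests and the acceptance script

Simulated screens use the default design throughout: 8 doses × 2
replicates (+ vehicle) per stratum, 37 time points, one to three seeding
densities — at most 54 wells per screen.  The KS oracle enumerates all
C(16, 8) = 12 870 splits for the exact-p cross-check and all sample-size
pairs up to 8 for the statistic; the bias-geometry oracle uses 1000
random score pairs.  These sizes make every check run in seconds while
exercising the same code paths as a full screen.

## Known limitations

* The method-B window is found by a threshold crossing of a noisy slope
  estimate; when the slope approaches the threshold shallowly, the
  detected window can jitter by one sampling step between otherwise
  equivalent runs.  The window is shared across each stratum, so this
  shifts all of a stratum's scores coherently rather than scrambling a
  dose series.
* For a drug that kills without touching motility, low doses still
  receive a small migration share: the fitted landscape's tangent near
  the origin is not exactly horizontal.  The lumped migration score stays
  small (≤ 0.1 in the simulated pure-cytotoxic scenario) but is not
  exactly zero.
* Scores are point estimates; no uncertainty is propagated (a bootstrap
  over replicates would be the natural extension).
* Proliferation inhibitors are indistinguishable from cytotoxic drugs by
  construction, since growth is normalized away by the MMC annotation
  rather than modelled.
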