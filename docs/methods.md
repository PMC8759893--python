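# Methods

This note describes the models and numerical choices behind `shearwave`:
what the simulator emulates, how each speed estimator is defined, what the
statistics compute, and where the design was genuinely open.

## Wave model and simulator

Shear-wave elastography pushes tissue with an acoustic-radiation-force
impulse and tracks the transverse displacement wave it launches. The
simulator reproduces the *kinematics* of that experiment, not the full
elastodynamics: depth rows are independent (no axial coupling), there is no
push-beam acoustic field model, and reflections/guided waves are absent.

**Kinematic mode.** The field is a travelling pulse

    u(x, t) = A(x) · g(t − τ(x)),   τ(x) = ∫ ds / c(s),  c = √(μ/ρ),

with `g` a Gaussian of standard deviation `width_s` (default 0.3 ms, a
typical push-impulse time scale), `A(x)` an exponential lateral decay
(default 50 /m, ~30 % amplitude loss over a 7.5 mm aperture), and the
travel-time integral taken cell-by-cell over the stiffness map (each grid
node's speed applies from that node to the next, so piecewise-constant
profiles are integrated exactly). This mode supports arbitrary lateral
heterogeneity (layers, inclusions).

**Viscoelastic mode.** For laterally homogeneous media the field is
synthesized in the frequency domain through the Voigt transfer function
`exp(−i k(ω) |x − x₀|)` with complex wavenumber

    k(ω) = ω √( ρ / (μ + iωη) ),   Re k > 0,  Im k ≤ 0,

which produces physical dispersion and frequency-dependent attenuation.
The record is zero-padded to at least 4× its length to suppress circular
wrap-around, and the source pulse's negative-time half is wrapped to the
end of the padded buffer so a pulse centred at t = 0 is synthesized without
truncation. With η = 0 the transfer function is a pure delay and the two
modes agree to machine precision.

**Noise.** Depth-dependent signal degradation is modelled as additive
white Gaussian noise with a per-depth SNR (dB) computed against the depth
row's own mean-square signal. This emulates the *estimate-level* effect of
depth (weaker tracking signal) without any acoustic modelling; it does not
emulate speckle decorrelation, jitter correlated with the displacement
magnitude, reflections, or motion artefacts. Consequences for
interpretation are discussed under "Limitations".

**Default acquisition** (chosen as typical desk-scale values for a
research SWE sequence): tracking PRF 10 kHz, 12 channels at 0.5 mm pitch
starting 2 mm from the push, 12 ms records, tracked depth 25 mm. Phantom
stiffness presets for the graded series are 3, 9, 18 and 30 kPa — synthetic
stand-ins spanning soft-tissue to stiff-lesion values, increasing with
"conditioning cycle" the way cryogel phantoms stiffen with freeze–thaw
cycles; they are not measurements.

## Speed estimators

All four estimators are scikit-learn-style classes over one depth row of a
displacement field.

* **SPM (sample-resolution time-to-peak).** Arrival time per channel is
  the time sample of the displacement maximum (earliest sample on ties;
  boundary peaks and flat traces are flagged invalid). Speed is the slope
  of the ordinary least-squares regression of channel position (m) on
  arrival time (s). Regressing position on time makes the slope the speed
  directly; the reciprocal orientation (time on position, speed = 1/slope)
  is the documented alternative and is not used. Accuracy is floored by
  time quantization: worst-case speed bias ≈ c²·Δt / aperture.
* **TDPM (sub-sample time-to-peak).** The trace is upsampled by a
  not-a-knot cubic spline (factor 8 by default), the maximum is located on
  the fine grid within one original sample of the discrete peak, and the
  peak time is refined by a three-point parabolic fit — exact for a
  quadratic peak, hence the sub-sample resolution. With upsampling and
  refinement disabled it reduces exactly to SPM.
* **TSPM (time-shift estimation).** Adjacent-channel delays from the
  parabolically refined maximum of the cross-correlation within ±max_lag;
  cumulative delays against position go through the same regression. A
  pair whose correlation peak lands on the lag boundary is dropped; since
  that breaks the cumulative chain, only channels up to the first dropped
  pair contribute. The acronyms SPM/TDPM/TSPM follow the field's shorthand
  for these three time-to-peak variants; the exact constructions above are
  this package's conventions.
* **Radon-sum.** Group velocity from the straight space–time trajectory
  t = t₀ + (x − x_ref)/c maximizing the integrated absolute displacement,
  over 201 log-spaced candidate speeds and intercepts at every time sample.
  Resolution is one speed-grid step; a maximum on the speed boundary is an
  error (the range must bracket the truth). Its reported r² is a
  peak-contrast measure (peak minus grid median over peak), not a
  regression R².

**Regression details.** At least 3 valid channels are required; equal
arrival times (infinite slope) and non-positive slopes (non-physical
propagation) are errors. An opt-in robust pass (off by default) re-fits
once after discarding residuals beyond 3 standard deviations; it is off by
default so that SPM/TDPM differences are attributable to peak detection
alone. The reported intercept is the fitted arrival time at lateral
position zero.

## Monte-Carlo benchmark

`benchmark_methods` repeats noise → estimate over seeded realizations
(per-trial seeds spawned from one root seed; the clean field is simulated
once since it is deterministic) and reports bias, population standard
deviation, RMSE (so rmse² = bias² + std² exactly), mean R², failure counts
and — for multi-depth scenarios — the peak-to-peak spread of per-depth mean
estimates. A method failing on more than half the trials is marked failed
with its count rather than dropped. Default problem sizes (200 trials, 12
channels, 121 time samples) keep a full benchmark under half a minute while
giving ~7 % standard error on a std estimate.

Two robustness orderings are exercised at 20 dB SNR and PRF 10 kHz:
TDPM's random error is reliably below SPM's (quantization noise dominates
SPM's variance), and its mean R² is at least SPM's. The *depth* comparison
(spread of per-depth means over an SNR ramp 25 → 10 dB) is much more
delicate: because SPM and TDPM share the same discrete peak *detection*
and differ only in refinement, additive white noise degrades their
per-depth means almost identically, and converged spreads differ by only a
few percent — less than the Monte-Carlo error of affordable runs. The
depth test therefore verifies the weak ordering (TDPM not worse) at its
fixed seed and should be read as "no depth penalty for sub-sample
refinement", not as a large effect; a noise model with
displacement-correlated jitter or gross tracking failures would be needed
to separate the methods strongly by depth.

## Voigt viscoelastics

The Voigt (spring ∥ dashpot) complex modulus G* = μ + iωη gives the phase
velocity

    c(ω) = √( 2(μ² + ω²η²) / (ρ(μ + √(μ² + ω²η²))) ),

strictly increasing in ω for η > 0 and equal to √(μ/ρ) in the elastic
limit. `fit_voigt` is a bounded trust-region least squares
(`scipy.optimize.least_squares`, tolerances 1e−14, cap 500 evaluations)
over (μ, η ≥ 0), initialized from the lowest-frequency speed
(μ₀ = ρc₀², η₀ = 0.5 Pa·s); it requires ≥3 points spanning a factor ≥2 in
frequency, which is the minimum for the curvature of c(ω) to constrain η.

**Modulus convention.** Clinical systems report Young's modulus in kPa
without stating a conversion; this package fixes E = 3μ = 3ρc² (exact for
an incompressible solid, Poisson ratio 1/2, and the standard elastography
convention) and provides the exact inverse. Interface units are kPa for μ
and E, Pa·s for η; everything is SI internally, converted once at the
boundary.

## Agreement and diagnostic statistics

* **ICC.** Interobserver agreement defaults to the two-way
  random-effects, absolute-agreement, single-measure form ICC(2,1),
  computed from the two-way-layout mean squares; consistency ('3,1') and
  average-measure ('2,k') forms are exposed for sensitivity analysis.
  Complete-case matrices are required (pairwise deletion silently changes
  the estimand). Zero total variance is an error, not a 0 or 1.
* **ROC/AUC.** AUC is the Mann–Whitney statistic (ties ½), with the full
  threshold staircase; the Youden threshold maximizes sensitivity +
  specificity − 1 under the rule score ≥ threshold ⇒ positive, breaking
  ties toward higher specificity. A marker whose best Youden index is ≤ 0
  (e.g. inverted orientation) is *flagged*, never silently re-oriented —
  silent flips hide data errors.
* **2×2 metrics** report None (undefined), not 0, for empty denominators.
* No confidence intervals are produced in this version.

## Synthetic tables

`make_rater_matrix` draws subject stiffness uniformly on 10–150 kPa with
independent 6 kPa rater noise (ICC ≈ 0.97 by construction);
`make_cohort` draws benign scores from N(30, 12²) kPa and malignant from
N(90, 30²) kPa, overlapping enough for a realistic ROC. These emulate the
*structure* of clinical reading tables, not any particular cohort: passing
tests on them shows the statistics are computed correctly, not that any
clinical agreement or accuracy level is reproduced.

## Determinism and I/O

Every source of randomness takes an explicit seed (no global state);
benchmark trials use seeds spawned via `numpy` SeedSequence, so results
are bit-reproducible from (scenario, seed). HDF5 fields are written with
`track_times=False`, making files byte-identical for identical inputs and
the fixture manifest's checksums reproducible. Scenario configs reject
unknown keys and round-trip losslessly through JSON.

## Limitations

* No full elastodynamic solve: diffraction, mode conversion, reflections
  and guided-wave dispersion in thin layers are absent, so estimator
  rankings here reflect sampling/noise behaviour, not beam physics.
* The additive-white-noise model understates the gross tracking failures
  that drive method differences at depth in vivo (see the benchmark note
  above).
* The viscoelastic mode requires lateral homogeneity per depth row;
  heterogeneous dispersive media are out of scope.
* Clinical-scale quantities (reader ICCs, tissue goodness-of-fit values,
  diagnostic ROC of real cohorts) require data this package does not ship;
  only their computational machinery and qualitative orderings are
  testable here.
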