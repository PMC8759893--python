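# shearwave

A shear-wave elastography (SWE) computation toolkit for method developers
and reproducibility studies: it simulates acoustic-radiation-force
shear-wave displacement fields through elastic and Voigt-viscoelastic
phantoms, estimates the shear-wave speed by four standard methods, converts
speeds to Young's moduli, and provides the agreement/diagnostic statistics
used to evaluate elastography clinically — all offline, with no external
data.

## What it computes

In soft tissue a shear wave launched by an acoustic-radiation-force push
travels at c = √(μ/ρ); clinical systems report the Young's modulus
E = 3ρc² (incompressible convention). The toolkit implements:

* **Simulator** (`shearwave.simulate`): travelling-pulse fields
  u(x,t) = A(x)·g(t − τ(x)) with exact travel-time integration over
  heterogeneous stiffness maps, and Fourier synthesis through the Voigt
  transfer function exp(−i k(ω)|x−x₀|), k(ω) = ω√(ρ/(μ+iωη)), for
  dispersive media; seeded per-depth SNR noise.
* **Speed estimators** (`shearwave.estimators`), scikit-learn style
  (`fit`, fitted `speed_`, `r_squared_` attributes, `get_params`):
  * `SPMEstimator` — time-to-peak at sample resolution; speed from the
    slope of position-vs-arrival-time least squares;
  * `TDPMEstimator` — sub-sample time-to-peak (cubic-spline upsampling +
    parabolic peak refinement);
  * `TSPMEstimator` — adjacent-channel cross-correlation time shifts;
  * `RadonSumEstimator` — group velocity from the space–time trajectory
    maximizing integrated amplitude.
* **Voigt viscoelastics** (`shearwave.viscoelastic`): complex wavenumber,
  the dispersion curve c(ω) = √(2(μ²+ω²η²)/(ρ(μ+√(μ²+ω²η²)))), bounded
  least-squares parameter recovery, and E = 3ρc² conversions.
* **Statistics** (`shearwave.stats`): interobserver ICC(2,1) (plus 3,1 /
  2,k forms), repeated-measurement summaries, Mann–Whitney ROC/AUC, Youden
  threshold, 2×2 diagnostic metrics.
* **Monte-Carlo benchmark** (`shearwave.benchmark`): bias / random error /
  RMSE / mean R² / depth spread per method, bit-reproducible from a seed.

See `docs/methods.md` for model assumptions, defaults and limitations.

## Worked example

```python
import shearwave as sw

# a 4 kPa (c = 2 m/s) homogeneous phantom, 10 kHz tracking PRF
cfg = sw.ScenarioConfig(
    phantom={"kind": "homogeneous", "mu_kpa": 4.0},
    acquisition={"prf_hz": 10_000, "duration_ms": 12.0, "n_channels": 12,
                 "channel_start_mm": 2.0, "channel_pitch_mm": 0.5,
                 "tracked_depths_mm": [25.0]},
)
field = sw.simulate_displacement(cfg.build_medium(), cfg.build_push(),
                                 cfg.build_grid())
for model in (sw.SPMEstimator(), sw.TDPMEstimator(), sw.TSPMEstimator(),
              sw.RadonSumEstimator(speed_range=(1, 4))):
    est = model.estimate(field)
    print(f"{est.method:5s} {est.speed:.4f} m/s  R^2={est.r_squared:.4f}")
print("E =", sw.young_modulus_from_speed(2.0), "kPa")
```

prints

```
SPM   1.9886 m/s  R^2=0.9984
TDPM  2.0000 m/s  R^2=1.0000
TSPM  2.0000 m/s  R^2=1.0000
RADON 2.0000 m/s  R^2=1.0000
E = 12.0 kPa
```

i.e. the sample-resolution method carries a small time-quantization bias
(bounded by c²Δt/aperture ≈ 0.07 m/s here), the sub-sample and
correlation methods recover the truth to machine-level accuracy, and a
2 m/s wave corresponds to 12 kPa Young's modulus. Under 20 dB noise the
benchmark shows the sub-sample method's random error is reliably below the
sample-resolution method's:

```python
res = sw.benchmark_methods(cfg.to_dict() | {"noise": {"snr_db": 20.0}},
                           methods=("spm", "tdpm"), n_trials=200, seed=1)
# SPM  std ~ 0.024 m/s   TDPM std ~ 0.018 m/s
```

## Command line

```
swe simulate --config scenario.json --out field.h5
swe estimate --field field.h5 --method tdpm
swe bench    --config scenario.json --trials 200 --seed 1 --out bench.csv
swe voigt-fit --curve curve.csv --density 1000
swe stats icc --in raters.csv ;  swe stats roc --in cohort.csv
swe fixtures --out fixtures/ --seed 1
```

Exit codes: 0 success, 2 input/schema error, 3 numerical failure.

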