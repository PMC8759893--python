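"""Monte-Carlo benchmarking of the speed estimators.

Repeats a simulate -> add-noise -> estimate pipeline over seeded noise
realizations and summarizes each method's bias, random error (standard
deviation), RMSE, mean goodness of fit and, for multi-depth scenarios, the
across-depth spread of the per-depth mean estimates. The clean field is
deterministic given the scenario, so it is simulated once and only the
noise is redrawn per trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field as _dcfield

import numpy as np
import pandas as pd

from .config import ScenarioConfig
from .errors import SchemaError, ShearwaveError
from .estimators import ESTIMATORS
from .simulate import add_noise, simulate_displacement

__all__ = ["BenchResult", "benchmark_methods", "results_to_frame"]


@dataclass
class BenchResult:
    """Monte-Carlo summary for one estimation method.

    bias = mean(estimate) - true speed; std is the population standard
    deviation of the estimates, so rmse^2 = bias^2 + std^2 holds exactly.
    per_depth_spread is the peak-to-peak range of per-depth mean estimates
    (None for single-depth scenarios). A method failing on more than half
    of the trials is marked ``failed`` with its failure count rather than
    being dropped.
    """

    method: str
    true_speed: float
    bias: float
    std: float
    rmse: float
    mean_r_squared: float
    n_trials: int
    n_failures: int = 0
    failed: bool = False
    per_depth_spread: float | None = None
    per_depth_means: dict = _dcfield(default_factory=dict)


def _true_speed(medium) -> float:
    c = medium.shear_speed
    if np.ptp(c) > 1e-9 * c.flat[0]:
        raise SchemaError(
            "benchmark scenarios need a single known true speed; "
            "got a heterogeneous medium"
        )
    return float(c.flat[0])


def benchmark_methods(scenario, methods=("spm", "tdpm", "tspm", "radon"),
                      n_trials: int = 100, seed: int = 0,
                      estimator_params: dict | None = None) -> list[BenchResult]:
    """Run the Monte-Carlo benchmark for a scenario.

    Parameters
    ----------
    scenario : ScenarioConfig or dict
        Must resolve to a homogeneous medium (known true speed).
    methods : iterable of {'spm','tdpm','tspm','radon'}
    n_trials : int
        Number of noise realizations (>= 2).
    seed : int
        Root seed; per-trial seeds are spawned from it, so the whole table
        is reproducible from (scenario, seed).
    estimator_params : dict, optional
        Per-method constructor overrides, e.g. {'radon': {'speed_range': (1, 4)}}.
    """
    if n_trials < 2:
        raise SchemaError("n_trials must be >= 2")
    cfg = scenario if isinstance(scenario, ScenarioConfig) else ScenarioConfig.from_dict(scenario)
    methods = [m.lower() for m in methods]
    for m in methods:
        if m not in ESTIMATORS:
            raise SchemaError(f"unknown method {m!r}")
    params = estimator_params or {}

    medium = cfg.build_medium()
    true_speed = _true_speed(medium)
    push, grid = cfg.build_push(), cfg.build_grid()
    clean = simulate_displacement(medium, push, grid, mode=cfg.mode)
    snr = cfg.noise_snr_db()
    n_depths = clean.n_depths

    trial_seeds = np.random.SeedSequence(seed).generate_state(n_trials)

    # estimates[method][depth] -> list of speeds
    speeds = {m: [[] for _ in range(n_depths)] for m in methods}
    r2s = {m: [] for m in methods}
    failures = {m: 0 for m in methods}

    for trial in range(n_trials):
        if snr is None:
            field = clean
        else:
            field = add_noise(clean, snr, int(trial_seeds[trial]))
        for m in methods:
            try:
                for d in range(n_depths):
                    kw = dict(params.get(m, {}))
                    if m == "radon" and "speed_range" not in kw:
                        kw["speed_range"] = (true_speed / 3.0, true_speed * 3.0)
                    est = ESTIMATORS[m](depth_index=d, **kw).estimate(field)
                    speeds[m][d].append(est.speed)
                    r2s[m].append(est.r_squared)
            except ShearwaveError:
                failures[m] += 1

    results = []
    for m in methods:
        all_speeds = np.concatenate([np.asarray(s) for s in speeds[m]]) \
            if any(speeds[m]) else np.array([])
        failed = failures[m] > n_trials / 2
        if all_speeds.size == 0 or failed:
            results.append(BenchResult(
                method=m.upper(), true_speed=true_speed, bias=float("nan"),
                std=float("nan"), rmse=float("nan"), mean_r_squared=float("nan"),
                n_trials=n_trials, n_failures=failures[m], failed=True,
            ))
            continue
        bias = float(all_speeds.mean() - true_speed)
        std = float(all_speeds.std(ddof=0))
        rmse = float(np.sqrt(np.mean((all_speeds - true_speed) ** 2)))
        depth_means = {d: float(np.mean(s)) for d, s in enumerate(speeds[m]) if s}
        spread = (float(np.ptp(list(depth_means.values())))
                  if len(depth_means) > 1 else None)
        results.append(BenchResult(
            method=m.upper(), true_speed=true_speed, bias=bias, std=std, rmse=rmse,
            mean_r_squared=float(np.mean(r2s[m])), n_trials=n_trials,
            n_failures=failures[m], failed=False,
            per_depth_spread=spread, per_depth_means=depth_means,
        ))
    return results


def results_to_frame(results: list[BenchResult]) -> pd.DataFrame:
    """Flatten benchmark results to a CSV-ready table."""
    rows = []
    for r in results:
        rows.append({
            "method": r.method, "true_speed_m_s": r.true_speed, "bias_m_s": r.bias,
            "std_m_s": r.std, "rmse_m_s": r.rmse, "mean_r_squared": r.mean_r_squared,
            "n_trials": r.n_trials, "n_failures": r.n_failures, "failed": r.failed,
            "per_depth_spread_m_s": r.per_depth_spread,
        })
    return pd.DataFrame(rows)
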