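import numpy as np
import pytest

import shearwave as sw


def homogeneous_config(mu_kpa=4.0, depths_mm=(25.0,), snr_db=None, **push):
    """Standard single-push scenario on a homogeneous phantom."""
    noise = None if snr_db is None else (
        {"depth_snr_db": list(snr_db)} if np.ndim(snr_db) else {"snr_db": float(snr_db)}
    )
    return sw.ScenarioConfig(
        phantom={"kind": "homogeneous", "mu_kpa": mu_kpa},
        push=push,
        acquisition={"prf_hz": 10_000.0, "duration_ms": 12.0, "channel_start_mm": 2.0,
                     "channel_pitch_mm": 0.5, "n_channels": 12,
                     "tracked_depths_mm": list(depths_mm)},
        noise=noise,
    )


def simulate_from_config(cfg, mode="kinematic"):
    medium = cfg.build_medium()
    return sw.simulate_displacement(medium, cfg.build_push(), cfg.build_grid(), mode)


@pytest.fixture(scope="session")
def clean_field_2ms():
    """Noiseless kinematic field through a 4 kPa (2 m/s) phantom."""
    return simulate_from_config(homogeneous_config())


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)


def synthetic_gaussian_traces(peak_times, dt=1e-4, n_t=120, width=0.3e-3,
                              pitch=0.5e-3, amplitudes=None):
    """Hand-built DisplacementField with Gaussian pulses at given peak times."""
    peak_times = np.asarray(peak_times, dtype=float)
    t = np.arange(n_t) * dt
    amps = np.ones(peak_times.size) if amplitudes is None else np.asarray(amplitudes)
    values = amps[:, None] * np.exp(-((t[None, :] - peak_times[:, None]) ** 2)
                                    / (2 * width**2))
    x = 2e-3 + np.arange(peak_times.size) * pitch
    return sw.DisplacementField(values[:, None, :], x, np.array([25e-3]), t)
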