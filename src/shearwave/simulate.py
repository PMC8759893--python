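"""Synthetic shear-wave displacement fields.

An acoustic-radiation-force push deposits a localized impulse at a lateral
position; the resulting shear wave propagates laterally and is tracked at a
set of channel positions and depths (each depth row propagates
independently — there is no axial coupling, which matches how per-depth
speed readings are taken in practice at desk scale).

Two propagation modes are provided:

* ``kinematic`` — a travelling pulse u(x,t) = A(x) g(t - tau(x)) whose
  arrival time tau(x) is the travel-time integral of the local slowness
  1/c(s), c = sqrt(mu/rho), along the lateral ray from the push; A(x)
  applies an optional exponential lateral attenuation. Exact for
  piecewise-constant speed profiles and cheap enough for Monte Carlo.
* ``viscoelastic`` — per depth row (laterally homogeneous media only),
  Fourier synthesis of the Voigt-medium transfer function
  exp(-i k(omega) |x - x0|), k = omega sqrt(rho/(mu + i omega eta)),
  which produces physical dispersion and frequency-dependent attenuation.

Noise is added separately by :func:`add_noise` (global or per-depth SNR in
dB), so depth-dependent signal degradation can be emulated without any
acoustic-field modelling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import NumericalError, SchemaError
from .field import DisplacementField
from .medium import MediumModel
from .viscoelastic import VoigtParams, voigt_wavenumber

__all__ = [
    "PushPulse",
    "AcquisitionGrid",
    "simulate_displacement",
    "add_noise",
    "travel_time",
]


@dataclass(frozen=True)
class PushPulse:
    """Acoustic-radiation-force push: where, when, and what it looks like.

    The temporal profile is a Gaussian of standard deviation ``width_s``
    centred on ``push_time_s``; ``amplitude_um`` is the peak displacement at
    the push location and ``attenuation_per_m`` an exponential lateral decay
    applied in kinematic mode only (the viscoelastic mode derives its own
    attenuation from the dashpot).
    """

    lateral_position_m: float = 0.0
    push_time_s: float = 0.0
    width_s: float = 0.3e-3
    amplitude_um: float = 10.0
    attenuation_per_m: float = 50.0

    def __post_init__(self) -> None:
        if not self.width_s > 0:
            raise SchemaError("push width must be positive")
        if self.amplitude_um < 0:
            raise SchemaError("push amplitude must be non-negative")
        if self.attenuation_per_m < 0:
            raise SchemaError("attenuation must be non-negative")

    def profile(self, t: np.ndarray) -> np.ndarray:
        """Unit-amplitude Gaussian g(t - push_time)."""
        return np.exp(-((t - self.push_time_s) ** 2) / (2.0 * self.width_s**2))


@dataclass(frozen=True)
class AcquisitionGrid:
    """Tracking geometry: temporal sampling (1/PRF), duration, channels."""

    sampling_interval_s: float
    duration_s: float
    lateral_positions_m: tuple
    depths_m: tuple

    def __post_init__(self) -> None:
        if not self.sampling_interval_s > 0:
            raise SchemaError("sampling interval must be positive")
        if not self.duration_s > 0:
            raise SchemaError("duration must be positive")
        object.__setattr__(self, "lateral_positions_m", tuple(float(x) for x in self.lateral_positions_m))
        object.__setattr__(self, "depths_m", tuple(float(z) for z in self.depths_m))
        if len(self.lateral_positions_m) < 1 or len(self.depths_m) < 1:
            raise SchemaError("need at least one channel and one depth")
        if np.any(np.diff(self.lateral_positions_m) <= 0):
            raise SchemaError("channel positions must be strictly increasing")

    @classmethod
    def from_prf(cls, prf_hz: float, duration_s: float, channel_start_m: float,
                 channel_pitch_m: float, n_channels: int, depths_m) -> "AcquisitionGrid":
        lat = tuple(channel_start_m + i * channel_pitch_m for i in range(n_channels))
        return cls(1.0 / prf_hz, duration_s, lat, tuple(depths_m))

    @property
    def time_axis(self) -> np.ndarray:
        n = int(math.floor(self.duration_s / self.sampling_interval_s)) + 1
        return np.arange(n) * self.sampling_interval_s


def _depth_row(medium: MediumModel, depth_m: float) -> int:
    return int(np.argmin(np.abs(medium.depth_positions - depth_m)))


def travel_time(medium: MediumModel, depth_m: float, x_from: float, x_to) -> np.ndarray:
    """Lateral shear-wave travel time (s) from x_from to x_to at one depth.

    The medium is treated as piecewise constant per grid cell (each node's
    speed applies from that node to the next), so the cumulative travel time
    is piecewise linear in position and linear interpolation is exact.
    """
    xg = medium.lateral_positions
    j = _depth_row(medium, depth_m)
    slowness = 1.0 / medium.shear_speed[:, j]
    cum = np.concatenate(([0.0], np.cumsum(slowness[:-1] * np.diff(xg))))
    x_to = np.asarray(x_to, dtype=float)
    lo, hi = xg[0], xg[-1]
    if not (lo <= x_from <= hi) or np.any(x_to < lo) or np.any(x_to > hi):
        raise SchemaError("travel-time endpoints must lie inside the lateral grid")
    t = np.abs(np.interp(x_to, xg, cum) - np.interp(x_from, xg, cum))
    return t if t.ndim else float(t)


def _check_duration(grid: AcquisitionGrid, push: PushPulse, tau_max: float) -> None:
    required = push.push_time_s + tau_max + 3.0 * push.width_s
    if grid.duration_s < required:
        raise SchemaError(
            f"acquisition duration {grid.duration_s * 1e3:.2f} ms is too short to "
            f"contain the farthest arrival; need at least {required * 1e3:.2f} ms"
        )


def simulate_displacement(medium: MediumModel, push: PushPulse, grid: AcquisitionGrid,
                          mode: str = "kinematic") -> DisplacementField:
    """Propagate the push through the medium and sample the displacement.

    Returns a noiseless :class:`DisplacementField` of shape
    (n_channels, n_depths, n_time) in micrometres. See the module docstring
    for the two propagation models.
    """
    if mode not in ("kinematic", "viscoelastic"):
        raise SchemaError(f"unknown mode {mode!r}")
    x0 = push.lateral_position_m
    xg = medium.lateral_positions
    if not xg[0] <= x0 <= xg[-1]:
        raise SchemaError("push position lies outside the medium's lateral grid")
    xs = np.asarray(grid.lateral_positions_m)
    t = grid.time_axis
    n_t = t.size
    values = np.zeros((xs.size, len(grid.depths_m), n_t))

    tau_max = 0.0
    for j, z in enumerate(grid.depths_m):
        tau_max = max(tau_max, float(np.max(travel_time(medium, z, x0, xs))))
    _check_duration(grid, push, tau_max)

    if mode == "kinematic":
        for j, z in enumerate(grid.depths_m):
            tau = travel_time(medium, z, x0, xs)
            amp = push.amplitude_um * np.exp(-push.attenuation_per_m * np.abs(xs - x0))
            values[:, j, :] = amp[:, None] * np.exp(
                -((t[None, :] - push.push_time_s - tau[:, None]) ** 2)
                / (2.0 * push.width_s**2)
            )
    else:
        # zero-pad to >=4x the record to suppress circular wrap-around
        n_fft = 1 << max(int(np.ceil(np.log2(4 * n_t))), 3)
        dt = grid.sampling_interval_s
        omega = 2.0 * np.pi * np.fft.rfftfreq(n_fft, dt)
        # wrap the source's negative-time half to the end of the padded
        # buffer so a pulse centred near t=0 is synthesized without truncation
        t_src = np.arange(n_fft) * dt
        t_src = np.where(t_src > n_fft * dt / 2.0, t_src - n_fft * dt, t_src)
        src = push.profile(t_src)
        spectrum = np.fft.rfft(src)
        for j, z in enumerate(grid.depths_m):
            row = _depth_row(medium, z)
            mu_row = medium.shear_modulus[:, row]
            eta_row = medium.viscosity[:, row]
            if np.ptp(mu_row) > 1e-9 * mu_row[0] or np.ptp(eta_row) > 1e-12:
                raise SchemaError(
                    "viscoelastic mode requires a laterally homogeneous medium "
                    f"at each tracked depth (violated at depth {z * 1e3:.1f} mm)"
                )
            p = VoigtParams(mu_row[0] / 1e3, float(eta_row[0]), medium.density)
            k = np.zeros(omega.size, dtype=complex)
            k[1:] = voigt_wavenumber(p, omega[1:])
            r = np.abs(xs - x0)
            transfer = np.exp(-1j * np.outer(r, k))
            values[:, j, :] = push.amplitude_um * np.fft.irfft(
                spectrum[None, :] * transfer, n=n_fft
            )[:, :n_t]

    return DisplacementField(
        values=values,
        lateral_axis=xs,
        depth_axis=np.asarray(grid.depths_m),
        time_axis=t,
        noise_seed=None,
        provenance=f"simulate_displacement mode={mode} medium={medium.label or 'unnamed'}",
        mode=mode,
    )


def add_noise(field: DisplacementField, snr_db, seed: int,
              allow_stacking: bool = False) -> DisplacementField:
    """Additive zero-mean Gaussian noise at a prescribed SNR.

    ``snr_db`` may be a scalar (one SNR for the whole field) or a sequence
    of one value per depth row, which emulates depth-dependent signal
    quality. The noise variance is set from the field's own mean-square
    signal so that 10 log10(P_signal / P_noise) = snr_db. ``snr_db = inf``
    is the explicit no-noise sentinel and returns an unchanged copy.
    Bit-reproducible for a given seed; the input field is not modified.
    """
    snr = np.asarray(snr_db, dtype=float)
    if np.any(np.isnan(snr)) or np.any(snr == -np.inf):
        raise SchemaError(f"snr_db must be finite or +inf, got {snr_db}")
    if field.noise_seed is not None and not allow_stacking:
        raise SchemaError(
            "field already carries a noise realization; pass allow_stacking=True "
            "to layer more noise"
        )
    if np.all(np.isinf(snr)):
        return field.copy()
    if snr.ndim == 0:
        snr = np.full(field.n_depths, float(snr))
    elif snr.shape != (field.n_depths,):
        raise SchemaError(
            f"snr_db must be scalar or one value per depth ({field.n_depths}), "
            f"got shape {snr.shape}"
        )
    rng = np.random.default_rng(seed)
    out = field.values.copy()
    for j, s in enumerate(snr):
        p_sig = float(np.mean(field.values[:, j, :] ** 2))
        if p_sig == 0.0:
            raise NumericalError(f"depth row {j} carries no signal; SNR is undefined")
        if np.isinf(s):
            continue
        sigma = math.sqrt(p_sig / 10.0 ** (s / 10.0))
        out[:, j, :] += rng.normal(0.0, sigma, size=out[:, j, :].shape)
    new = field.copy(values=out)
    new.noise_seed = int(seed)
    new.provenance = field.provenance + f" + noise snr_db={np.round(snr, 3).tolist()} seed={seed}"
    return new
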