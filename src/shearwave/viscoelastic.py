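"""Voigt-model shear mechanics and modulus conversion.

The Voigt (Kelvin–Voigt) rheology — a spring of shear modulus mu in parallel
with a dashpot of shear viscosity eta — gives a complex shear modulus
G*(omega) = mu + i*omega*eta and hence a dispersive (frequency-dependent)
shear-wave phase velocity:

    c(omega) = sqrt( 2 (mu^2 + omega^2 eta^2)
                     / ( rho (mu + sqrt(mu^2 + omega^2 eta^2)) ) )

With eta = 0 this collapses to the non-dispersive elastic speed
c = sqrt(mu/rho). Clinical elastography reports Young's modulus; for soft,
nearly incompressible tissue (Poisson ratio 1/2) E = 3 mu = 3 rho c^2, which
is the conversion convention adopted throughout this package.

Interface units: mu in kPa, eta in Pa·s, rho in kg/m^3, speeds in m/s.
Internally mu is carried in Pa.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

from .errors import NumericalError, SchemaError

__all__ = [
    "VoigtParams",
    "DispersionCurve",
    "voigt_wavenumber",
    "voigt_phase_velocity",
    "VoigtDispersionModel",
    "fit_voigt",
    "young_modulus_from_speed",
    "speed_from_young_modulus",
]

KPA = 1e3


@dataclass(frozen=True)
class VoigtParams:
    """Voigt constituents: spring mu (kPa), dashpot eta (Pa·s), density rho."""

    mu_kpa: float
    eta_pa_s: float = 0.0
    density: float = 1000.0

    def __post_init__(self) -> None:
        if not self.mu_kpa > 0:
            raise SchemaError("mu_kpa must be positive")
        if self.eta_pa_s < 0:
            raise SchemaError("eta_pa_s must be non-negative")
        if not self.density > 0:
            raise SchemaError("density must be positive")

    @property
    def mu_pa(self) -> float:
        return self.mu_kpa * KPA


@dataclass
class DispersionCurve:
    """Phase-velocity samples c(omega) with optional fit weights."""

    angular_frequencies: np.ndarray  # rad/s, strictly increasing, positive
    phase_speeds: np.ndarray  # m/s
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.angular_frequencies = np.asarray(self.angular_frequencies, dtype=float)
        self.phase_speeds = np.asarray(self.phase_speeds, dtype=float)
        w = self.angular_frequencies
        if w.ndim != 1 or w.size == 0 or np.any(w <= 0) or np.any(np.diff(w) <= 0):
            raise SchemaError("angular_frequencies must be positive and strictly increasing")
        if self.phase_speeds.shape != w.shape or np.any(self.phase_speeds <= 0):
            raise SchemaError("phase_speeds must be positive and match frequencies")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != w.shape or np.any(self.weights < 0):
                raise SchemaError("weights must be non-negative and match frequencies")


def voigt_wavenumber(params: VoigtParams, omega):
    """Complex shear wavenumber k(omega) = omega*sqrt(rho/(mu + i omega eta)).

    Branch: Re(k) > 0 and Im(k) <= 0 (outgoing wave that decays under the
    e^{i(omega t - k x)} convention; |Im k| is the attenuation in 1/m).
    Continuous in omega; accepts scalars or arrays.
    """
    omega = np.asarray(omega, dtype=float)
    if np.any(omega <= 0):
        raise SchemaError("omega must be positive")
    g_star = params.mu_pa + 1j * omega * params.eta_pa_s
    # principal sqrt of rho/G* already lands in the fourth quadrant closure
    k = omega * np.sqrt(params.density / g_star)
    return k if k.ndim else complex(k)


def voigt_phase_velocity(params: VoigtParams, omega):
    """Voigt phase velocity c(omega) in m/s (closed form; see module docs).

    Equals omega / Re(voigt_wavenumber) and is strictly increasing in omega
    when eta > 0; for eta = 0 it is the constant sqrt(mu/rho).
    """
    omega = np.asarray(omega, dtype=float)
    if np.any(omega <= 0):
        raise SchemaError("omega must be positive")
    mu, eta, rho = params.mu_pa, params.eta_pa_s, params.density
    mag = np.sqrt(mu**2 + omega**2 * eta**2)
    c = np.sqrt(2.0 * mag**2 / (rho * (mu + mag)))
    return c if c.ndim else float(c)


class VoigtDispersionModel(BaseEstimator):
    """Fit Voigt parameters (mu, eta) to a measured dispersion curve.

    Bounded nonlinear least squares of :func:`voigt_phase_velocity` against
    phase-speed samples; mu and eta constrained non-negative. Deterministic
    given the data and the initial guess (default: mu from the
    lowest-frequency speed via mu = rho c0^2, eta = 0.5 Pa·s).

    Parameters
    ----------
    density : float
        Medium density in kg/m^3 (known, not fitted).
    initial : VoigtParams, optional
        Starting point for the optimiser.
    max_iter : int
        Iteration cap for the trust-region solver.

    Attributes
    ----------
    params_ : VoigtParams
        Fitted parameters (mu in kPa, eta in Pa·s).
    residual_norm_ : float
        2-norm of the weighted speed residuals at the solution.
    """

    def __init__(self, density: float = 1000.0, initial: VoigtParams | None = None,
                 max_iter: int = 500):
        self.density = density
        self.initial = initial
        self.max_iter = max_iter

    def fit(self, X, y=None):
        """Fit to X = DispersionCurve, or X = omega array with y = speeds."""
        if isinstance(X, DispersionCurve):
            curve = X
        else:
            curve = DispersionCurve(np.asarray(X, dtype=float).ravel(), np.asarray(y, dtype=float))
        w = curve.angular_frequencies
        if w.size < 3:
            raise SchemaError("need at least 3 frequency points to fit a Voigt model")
        if w[-1] / w[0] < 2.0:
            raise SchemaError("frequencies must span at least a factor of 2")
        weights = np.ones_like(w) if curve.weights is None else curve.weights
        sw = np.sqrt(weights)

        if self.initial is not None:
            x0 = np.array([self.initial.mu_pa, self.initial.eta_pa_s])
        else:
            x0 = np.array([self.density * curve.phase_speeds[0] ** 2, 0.5])

        rho = float(self.density)

        def resid(x):
            p = VoigtParams(max(x[0], 1e-12) / KPA, max(x[1], 0.0), rho)
            return sw * (voigt_phase_velocity(p, w) - curve.phase_speeds)

        sol = least_squares(
            resid, x0, bounds=([1e-9, 0.0], [np.inf, np.inf]),
            xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=self.max_iter,
        )
        if not sol.success:
            raise NumericalError(
                f"Voigt fit did not converge within {self.max_iter} evaluations: "
                f"{sol.message}; last iterate mu={sol.x[0] / KPA:.4g} kPa, "
                f"eta={sol.x[1]:.4g} Pa·s, residual={np.linalg.norm(sol.fun):.4g}"
            )
        self.params_ = VoigtParams(sol.x[0] / KPA, sol.x[1], rho)
        self.residual_norm_ = float(np.linalg.norm(sol.fun))
        return self

    def predict(self, omega):
        """Phase velocity of the fitted model at the given omega (rad/s)."""
        if not hasattr(self, "params_"):
            raise NumericalError("model is not fitted")
        return voigt_phase_velocity(self.params_, omega)


def fit_voigt(curve: DispersionCurve, density: float = 1000.0,
              initial: VoigtParams | None = None) -> VoigtParams:
    """Functional wrapper over :class:`VoigtDispersionModel`."""
    return VoigtDispersionModel(density=density, initial=initial).fit(curve).params_


def young_modulus_from_speed(speed, density: float = 1000.0):
    """Young's modulus E = 3 rho c^2 in kPa (incompressible convention)."""
    speed = np.asarray(speed, dtype=float)
    if np.any(speed <= 0) or not density > 0:
        raise SchemaError("speed and density must be positive")
    e = 3.0 * density * speed**2 / KPA
    return e if e.ndim else float(e)


def speed_from_young_modulus(young_kpa, density: float = 1000.0):
    """Inverse of :func:`young_modulus_from_speed`: c = sqrt(E/(3 rho))."""
    young_kpa = np.asarray(young_kpa, dtype=float)
    if np.any(young_kpa <= 0) or not density > 0:
        raise SchemaError("modulus and density must be positive")
    c = np.sqrt(young_kpa * KPA / (3.0 * density))
    return c if c.ndim else float(c)
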