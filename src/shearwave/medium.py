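"""Virtual phantoms: 2-D maps of shear modulus and viscosity.

A :class:`MediumModel` is the simulation ground truth — shear modulus (Pa)
and shear viscosity (Pa·s) on a lateral x depth node grid, with a scalar
density. Shear moduli are accepted in kPa at every public interface and
converted to Pa once, here.

``build_phantom`` constructs the standard test geometries: a homogeneous
block, lateral layers, a stiff circular inclusion, and a graded stiffness
series that emulates a cryogel phantom set stiffened by successive
freeze–thaw cycles (the preset moduli are synthetic stand-ins, not measured
values).
"""

from __future__ import annotations

from dataclasses import dataclass, field as _dcfield

import numpy as np

from .errors import SchemaError

__all__ = ["MediumModel", "build_phantom", "GRADED_SERIES_PRESETS_KPA"]

KPA = 1e3

#: Synthetic stiffness presets (kPa) standing in for a freeze–thaw series;
#: one preset per cycle count, monotonically increasing.
GRADED_SERIES_PRESETS_KPA = (3.0, 9.0, 18.0, 30.0)


@dataclass
class MediumModel:
    """Elastic / Voigt-viscoelastic medium on a regular lateral x depth grid.

    shear_modulus and viscosity are node-wise arrays of shape
    (n_lateral, n_depth); density is a scalar (kg/m^3).
    """

    lateral_positions: np.ndarray  # metres, uniform, strictly increasing
    depth_positions: np.ndarray  # metres, uniform, strictly increasing
    shear_modulus: np.ndarray  # Pa, (n_lat, n_depth)
    viscosity: np.ndarray  # Pa s, (n_lat, n_depth)
    density: float = 1000.0  # kg/m^3
    label: str = ""
    attrs: dict = _dcfield(default_factory=dict)

    def __post_init__(self) -> None:
        self.lateral_positions = np.asarray(self.lateral_positions, dtype=float)
        self.depth_positions = np.asarray(self.depth_positions, dtype=float)
        shape = (self.lateral_positions.size, self.depth_positions.size)
        self.shear_modulus = np.broadcast_to(
            np.asarray(self.shear_modulus, dtype=float), shape
        ).copy()
        self.viscosity = np.broadcast_to(
            np.asarray(self.viscosity, dtype=float), shape
        ).copy()
        for name, axis in (
            ("lateral_positions", self.lateral_positions),
            ("depth_positions", self.depth_positions),
        ):
            d = np.diff(axis)
            if axis.size < 2 or np.any(d <= 0):
                raise SchemaError(f"{name} must be strictly increasing with >=2 nodes")
            if not np.allclose(d, d[0], rtol=1e-9, atol=1e-15):
                raise SchemaError(f"{name} must have constant spacing")
        if np.any(self.shear_modulus <= 0):
            raise SchemaError("shear_modulus must be positive everywhere")
        if np.any(self.viscosity < 0):
            raise SchemaError("viscosity must be non-negative")
        if not self.density > 0:
            raise SchemaError("density must be positive")

    @property
    def shear_speed(self) -> np.ndarray:
        """Elastic shear-wave speed c = sqrt(mu/rho), m/s, node-wise."""
        return np.sqrt(self.shear_modulus / self.density)


def _grid(params: dict) -> tuple[np.ndarray, np.ndarray]:
    lat_extent = float(params.get("lateral_extent_mm", 15.0)) * 1e-3
    dep_lo = float(params.get("depth_start_mm", 10.0)) * 1e-3
    dep_hi = float(params.get("depth_end_mm", 40.0)) * 1e-3
    lat_step = float(params.get("lateral_step_mm", 0.25)) * 1e-3
    dep_step = float(params.get("depth_step_mm", 2.5)) * 1e-3
    if lat_extent <= 0 or dep_hi <= dep_lo or lat_step <= 0 or dep_step <= 0:
        raise SchemaError("phantom grid extents and steps must be positive")
    n_lat = int(round(lat_extent / lat_step)) + 1
    n_dep = int(round((dep_hi - dep_lo) / dep_step)) + 1
    lat = np.arange(n_lat) * lat_step
    dep = dep_lo + np.arange(n_dep) * dep_step
    return lat, dep


_GRID_KEYS = {
    "lateral_extent_mm",
    "depth_start_mm",
    "depth_end_mm",
    "lateral_step_mm",
    "depth_step_mm",
    "density",
    "eta_pa_s",
}

_KIND_KEYS = {
    "homogeneous": {"mu_kpa"},
    "layered": {"layer_boundaries_mm", "layer_mu_kpa"},
    "inclusion": {
        "background_mu_kpa",
        "inclusion_mu_kpa",
        "center_lateral_mm",
        "center_depth_mm",
        "radius_mm",
    },
    "graded_series": {"mu_presets_kpa"},
}


def build_phantom(kind: str, parameters: dict | None = None):
    """Construct a :class:`MediumModel` (or a list for ``graded_series``).

    Parameters
    ----------
    kind : {'homogeneous', 'layered', 'inclusion', 'graded_series'}
    parameters : dict
        Geometry and stiffness, millimetres / kPa at this interface.
        Unknown keys are rejected.

    Returns
    -------
    MediumModel, or list of MediumModel for ``graded_series`` (one per
    stiffness preset, strictly increasing in shear modulus).
    """
    params = dict(parameters or {})
    if kind not in _KIND_KEYS:
        raise SchemaError(f"unknown phantom kind {kind!r}")
    unknown = set(params) - _GRID_KEYS - _KIND_KEYS[kind]
    if unknown:
        raise SchemaError(f"unknown phantom parameter(s): {sorted(unknown)}")

    lat, dep = _grid(params)
    rho = float(params.get("density", 1000.0))
    eta = float(params.get("eta_pa_s", 0.0))
    shape = (lat.size, dep.size)

    if kind == "homogeneous":
        mu = float(params.get("mu_kpa", 4.0))
        if mu <= 0:
            raise SchemaError("mu_kpa must be positive")
        return MediumModel(lat, dep, np.full(shape, mu * KPA), np.full(shape, eta), rho,
                           label=f"homogeneous {mu} kPa")

    if kind == "layered":
        bounds = np.asarray(params.get("layer_boundaries_mm", [5.0]), dtype=float) * 1e-3
        mus = np.asarray(params.get("layer_mu_kpa", [4.0, 16.0]), dtype=float)
        if mus.size != bounds.size + 1:
            raise SchemaError("layer_mu_kpa must have one more entry than layer_boundaries_mm")
        if np.any(mus <= 0):
            raise SchemaError("layer moduli must be positive")
        if np.any(np.diff(bounds) <= 0):
            raise SchemaError("layer boundaries must be strictly increasing")
        if bounds.size and (bounds[0] <= lat[0] or bounds[-1] >= lat[-1]):
            raise SchemaError(
                f"layer boundaries {bounds * 1e3} mm must lie strictly inside the "
                f"lateral grid [{lat[0] * 1e3}, {lat[-1] * 1e3}] mm"
            )
        layer_index = np.searchsorted(bounds, lat, side="right")
        mu_map = np.repeat((mus[layer_index] * KPA)[:, None], dep.size, axis=1)
        return MediumModel(lat, dep, mu_map, np.full(shape, eta), rho, label="layered")

    if kind == "inclusion":
        bg = float(params.get("background_mu_kpa", 3.0))
        inc = float(params.get("inclusion_mu_kpa", 12.0))
        cx = float(params.get("center_lateral_mm", 7.5)) * 1e-3
        cz = float(params.get("center_depth_mm", 25.0)) * 1e-3
        r = float(params.get("radius_mm", 3.0)) * 1e-3
        if bg <= 0 or inc <= 0 or r <= 0:
            raise SchemaError("moduli and radius must be positive")
        if not (lat[0] <= cx - r and cx + r <= lat[-1] and dep[0] <= cz - r and cz + r <= dep[-1]):
            raise SchemaError(
                f"inclusion (center ({cx * 1e3}, {cz * 1e3}) mm, radius {r * 1e3} mm) "
                "extends outside the phantom grid"
            )
        X, Z = np.meshgrid(lat, dep, indexing="ij")
        inside = (X - cx) ** 2 + (Z - cz) ** 2 <= r**2
        mu_map = np.where(inside, inc, bg) * KPA
        m = MediumModel(lat, dep, mu_map, np.full(shape, eta), rho, label="inclusion")
        m.attrs["inclusion_mask"] = inside
        return m

    # graded_series
    presets = np.asarray(
        params.get("mu_presets_kpa", GRADED_SERIES_PRESETS_KPA), dtype=float
    )
    if np.any(presets <= 0) or np.any(np.diff(presets) <= 0):
        raise SchemaError("mu_presets_kpa must be positive and strictly increasing")
    return [
        MediumModel(lat, dep, np.full(shape, mu * KPA), np.full(shape, eta), rho,
                    label=f"graded preset {i}: {mu} kPa")
        for i, mu in enumerate(presets)
    ]
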