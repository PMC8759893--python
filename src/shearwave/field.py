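"""Space-time shear-wave displacement fields.

A :class:`DisplacementField` is the central in-memory container: particle
displacement u (micrometres) sampled on a (lateral, depth, time) grid, as
produced by the simulator or read from an HDF5 container. Lateral positions
are metres relative to the transducer frame; time starts at zero with a
constant step equal to the inverse tracking pulse-repetition frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field as _dcfield, replace

import numpy as np

from .errors import SchemaError

__all__ = ["DisplacementField"]


@dataclass
class DisplacementField:
    """Sampled particle displacement u(lateral, depth, time).

    Parameters
    ----------
    values : ndarray, shape (n_lateral, n_depth, n_time)
        Displacement in micrometres.
    lateral_axis : ndarray
        Tracked lateral positions in metres, strictly increasing.
    depth_axis : ndarray
        Tracked depths in metres.
    time_axis : ndarray
        Sample times in seconds; starts at 0 with a constant step.
    noise_seed : int or None
        Seed of the additive-noise realization, or None for a clean field.
    provenance : str
        Free-text description of how the field was produced.
    """

    values: np.ndarray
    lateral_axis: np.ndarray
    depth_axis: np.ndarray
    time_axis: np.ndarray
    noise_seed: int | None = None
    provenance: str = ""
    mode: str = "kinematic"
    attrs: dict = _dcfield(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.lateral_axis = np.asarray(self.lateral_axis, dtype=float)
        self.depth_axis = np.asarray(self.depth_axis, dtype=float)
        self.time_axis = np.asarray(self.time_axis, dtype=float)
        if self.values.ndim != 3:
            raise SchemaError(
                f"values must be 3-D (lateral, depth, time), got shape {self.values.shape}"
            )
        expected = (self.lateral_axis.size, self.depth_axis.size, self.time_axis.size)
        if self.values.shape != expected:
            raise SchemaError(
                f"axis lengths {expected} do not match values shape {self.values.shape}"
            )
        if self.lateral_axis.size >= 2 and np.any(np.diff(self.lateral_axis) <= 0):
            raise SchemaError("lateral_axis must be strictly increasing")
        if self.time_axis.size:
            if abs(self.time_axis[0]) > 1e-12:
                raise SchemaError("time_axis must start at 0")
            steps = np.diff(self.time_axis)
            if steps.size and not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-15):
                raise SchemaError("time_axis must have a constant step")

    # -- convenience ----------------------------------------------------

    @property
    def dt(self) -> float:
        """Temporal sampling interval in seconds (1 / PRF)."""
        return float(self.time_axis[1] - self.time_axis[0])

    @property
    def n_channels(self) -> int:
        return int(self.lateral_axis.size)

    @property
    def n_depths(self) -> int:
        return int(self.depth_axis.size)

    def traces(self, depth_index: int = 0) -> np.ndarray:
        """2-D (lateral x time) slice at one tracked depth."""
        n = self.n_depths
        if not -n <= depth_index < n:
            raise SchemaError(f"depth_index {depth_index} out of range for {n} depths")
        return self.values[:, depth_index, :]

    def copy(self, **changes) -> "DisplacementField":
        out = replace(self, **changes)
        if "values" not in changes:
            out.values = self.values.copy()
        out.attrs = dict(self.attrs)
        return out
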