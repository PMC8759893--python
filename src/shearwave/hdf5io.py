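"""HDF5 container for displacement fields.

Layout (schema_version "1"): datasets ``displacement`` (lateral x depth x
time, micrometres), ``lateral_axis``, ``depth_axis``, ``time_axis``; root
attributes ``schema_version``, ``mode``, ``provenance`` and, for noisy
fields, ``noise_seed``. Datasets are written with ``track_times=False`` so
identical fields produce byte-identical files.
"""

from __future__ import annotations

import h5py
import numpy as np

from .errors import SchemaError
from .field import DisplacementField

__all__ = ["read_field", "write_field"]

SCHEMA_VERSION = "1"
_DATASETS = ("displacement", "lateral_axis", "depth_axis", "time_axis")


def write_field(field: DisplacementField, path) -> None:
    """Serialize a field; write-then-read is bit-exact."""
    with h5py.File(path, "w") as f:
        f.create_dataset("displacement", data=field.values, track_times=False)
        f.create_dataset("lateral_axis", data=field.lateral_axis, track_times=False)
        f.create_dataset("depth_axis", data=field.depth_axis, track_times=False)
        f.create_dataset("time_axis", data=field.time_axis, track_times=False)
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["mode"] = field.mode
        f.attrs["provenance"] = field.provenance
        if field.noise_seed is not None:
            f.attrs["noise_seed"] = int(field.noise_seed)


def read_field(path) -> DisplacementField:
    """Load a field, validating schema version, datasets and axis lengths."""
    with h5py.File(path, "r") as f:
        version = f.attrs.get("schema_version")
        if version not in (SCHEMA_VERSION,):
            raise SchemaError(f"unsupported field schema_version {version!r}")
        for name in _DATASETS:
            if name not in f:
                raise SchemaError(f"missing dataset {name!r} in {path}")
        values = np.asarray(f["displacement"])
        axes = {name: np.asarray(f[name]) for name in _DATASETS[1:]}
        expected = (axes["lateral_axis"].size, axes["depth_axis"].size,
                    axes["time_axis"].size)
        if values.ndim != 3 or values.shape != expected:
            raise SchemaError(
                f"dataset 'displacement' shape {values.shape} does not match "
                f"axis lengths {expected}"
            )
        seed = f.attrs.get("noise_seed")
        return DisplacementField(
            values=values,
            lateral_axis=axes["lateral_axis"],
            depth_axis=axes["depth_axis"],
            time_axis=axes["time_axis"],
            noise_seed=None if seed is None else int(seed),
            provenance=str(f.attrs.get("provenance", "")),
            mode=str(f.attrs.get("mode", "kinematic")),
        )
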