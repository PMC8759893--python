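"""Scenario configuration: validated JSON in, simulation objects out.

A scenario bundles everything needed to reproduce a synthetic acquisition:
phantom geometry/stiffness, push pulse, acquisition grid, noise level(s)
and a seed. Configs round-trip losslessly through JSON; unknown keys are
rejected so typos fail loudly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field as _dcfield

import numpy as np

from .errors import SchemaError
from .medium import build_phantom
from .simulate import AcquisitionGrid, PushPulse

__all__ = ["ScenarioConfig", "config_hash"]

SCHEMA_VERSION = "1"

_TOP_KEYS = {"schema_version", "seed", "phantom", "push", "acquisition", "noise", "mode"}
_PUSH_KEYS = {"lateral_position_mm", "time_ms", "width_ms", "amplitude_um", "attenuation_per_m"}
_ACQ_KEYS = {"prf_hz", "duration_ms", "channel_start_mm", "channel_pitch_mm",
             "n_channels", "tracked_depths_mm"}
_NOISE_KEYS = {"snr_db", "depth_snr_db"}


def _reject_unknown(section: dict, allowed: set, where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise SchemaError(f"unknown key(s) in {where}: {sorted(unknown)}")


@dataclass
class ScenarioConfig:
    phantom: dict
    push: dict = _dcfield(default_factory=dict)
    acquisition: dict = _dcfield(default_factory=dict)
    noise: dict | None = None
    seed: int | None = None
    mode: str = "kinematic"
    schema_version: str = SCHEMA_VERSION

    def __post_init__(self) -> None:
        if str(self.schema_version) != SCHEMA_VERSION:
            raise SchemaError(f"unsupported scenario schema_version {self.schema_version!r}")
        if "kind" not in self.phantom:
            raise SchemaError("phantom section needs a 'kind'")
        if self.mode not in ("kinematic", "viscoelastic"):
            raise SchemaError(f"unknown mode {self.mode!r}")
        _reject_unknown(self.push, _PUSH_KEYS, "push")
        _reject_unknown(self.acquisition, _ACQ_KEYS, "acquisition")
        if self.noise is not None:
            _reject_unknown(self.noise, _NOISE_KEYS, "noise")
            if len(self.noise) != 1:
                raise SchemaError("noise section takes exactly one of snr_db / depth_snr_db")

    # -- construction ---------------------------------------------------

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        _reject_unknown(d, _TOP_KEYS, "scenario")
        return cls(
            phantom=dict(d.get("phantom") or {}),
            push=dict(d.get("push") or {}),
            acquisition=dict(d.get("acquisition") or {}),
            noise=None if d.get("noise") is None else dict(d["noise"]),
            seed=d.get("seed"),
            mode=d.get("mode", "kinematic"),
            schema_version=str(d.get("schema_version", SCHEMA_VERSION)),
        )

    @classmethod
    def from_json(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "seed": self.seed,
            "mode": self.mode,
            "phantom": dict(self.phantom),
            "push": dict(self.push),
            "acquisition": dict(self.acquisition),
            "noise": None if self.noise is None else dict(self.noise),
        }

    # -- resolution to simulation objects -------------------------------

    def build_medium(self):
        p = dict(self.phantom)
        kind = p.pop("kind")
        return build_phantom(kind, p)

    def build_push(self) -> PushPulse:
        p = self.push
        return PushPulse(
            lateral_position_m=float(p.get("lateral_position_mm", 0.0)) * 1e-3,
            push_time_s=float(p.get("time_ms", 0.0)) * 1e-3,
            width_s=float(p.get("width_ms", 0.3)) * 1e-3,
            amplitude_um=float(p.get("amplitude_um", 10.0)),
            attenuation_per_m=float(p.get("attenuation_per_m", 50.0)),
        )

    def build_grid(self) -> AcquisitionGrid:
        a = self.acquisition
        depths_mm = a.get("tracked_depths_mm", [25.0])
        return AcquisitionGrid.from_prf(
            prf_hz=float(a.get("prf_hz", 10_000.0)),
            duration_s=float(a.get("duration_ms", 12.0)) * 1e-3,
            channel_start_m=float(a.get("channel_start_mm", 2.0)) * 1e-3,
            channel_pitch_m=float(a.get("channel_pitch_mm", 0.5)) * 1e-3,
            n_channels=int(a.get("n_channels", 12)),
            depths_m=[float(z) * 1e-3 for z in depths_mm],
        )

    def noise_snr_db(self):
        """None (no noise), a scalar dB value, or a per-depth array."""
        if self.noise is None:
            return None
        if "snr_db" in self.noise:
            return float(self.noise["snr_db"])
        return np.asarray(self.noise["depth_snr_db"], dtype=float)


def config_hash(config: ScenarioConfig | dict) -> str:
    """Short stable hash of a scenario (canonical-JSON SHA-256 prefix)."""
    d = config.to_dict() if isinstance(config, ScenarioConfig) else config
    blob = json.dumps(d, sort_keys=True, separators=(",", ":")).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
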