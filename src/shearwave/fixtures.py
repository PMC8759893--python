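"""Seeded fixture generator: the standard offline test-data set.

Emits, reproducibly from one seed: the graded stiffness series (four
presets, noiseless and 20 dB variants), a stiff-inclusion field, a
depth-graded-SNR field, a synthetic two-rater stiffness matrix and a
synthetic benign/malignant scored cohort, plus a manifest of SHA-256
checksums. All tables are synthetic data drawn here — no clinical readings
are bundled.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ScenarioConfig
from .errors import SchemaError
from .hdf5io import write_field
from .medium import GRADED_SERIES_PRESETS_KPA, build_phantom
from .simulate import add_noise, simulate_displacement

__all__ = ["generate_fixtures", "make_rater_matrix", "make_cohort"]

_ACQ = {
    "prf_hz": 10_000.0,
    "duration_ms": 12.0,
    "channel_start_mm": 2.0,
    "channel_pitch_mm": 0.5,
    "n_channels": 12,
    "tracked_depths_mm": [25.0],
}

DEPTH_SNR_DB = (25.0, 21.25, 17.5, 13.75, 10.0)


def make_rater_matrix(rng: np.random.Generator, n_subjects: int = 30,
                      n_raters: int = 2) -> pd.DataFrame:
    """Synthetic maximum-stiffness readings (kPa) by several raters.

    Subjects span benign-to-malignant stiffness (10–150 kPa); raters add
    independent measurement noise (sd 6 kPa), giving high but imperfect
    interobserver agreement.
    """
    truth = rng.uniform(10.0, 150.0, size=n_subjects)
    readings = truth[:, None] + rng.normal(0.0, 6.0, size=(n_subjects, n_raters))
    return pd.DataFrame(readings, columns=[f"rater_{i + 1}" for i in range(n_raters)])


def make_cohort(rng: np.random.Generator, n_benign: int = 35,
                n_malignant: int = 30) -> pd.DataFrame:
    """Synthetic scored cohort: stiffness score (kPa) per lesion plus label.

    Benign lesions centre near 30 kPa, malignant near 90 kPa, with enough
    overlap that sensitivity/specificity trade off realistically.
    """
    benign = rng.normal(30.0, 12.0, size=n_benign).clip(min=2.0)
    malignant = rng.normal(90.0, 30.0, size=n_malignant).clip(min=2.0)
    return pd.DataFrame({
        "label": np.r_[np.zeros(n_benign, int), np.ones(n_malignant, int)],
        "score": np.round(np.r_[benign, malignant], 3),
    })


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def generate_fixtures(out_dir, seed: int, force: bool = False) -> dict:
    """Write the standard fixture set to ``out_dir``; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if any(out.iterdir()) and not force:
        raise SchemaError(f"{out} is not empty; pass force=True to overwrite")

    rng_children = np.random.SeedSequence(seed).generate_state(8)
    files: list[Path] = []

    # graded stiffness series, noiseless and 20 dB
    media = build_phantom("graded_series", {})
    for i, medium in enumerate(media):
        cfg = ScenarioConfig(phantom={"kind": "homogeneous",
                                      "mu_kpa": GRADED_SERIES_PRESETS_KPA[i]},
                             acquisition=dict(_ACQ))
        clean = simulate_displacement(medium, cfg.build_push(), cfg.build_grid())
        p = out / f"graded_{i}_clean.h5"
        write_field(clean, p)
        files.append(p)
        noisy = add_noise(clean, 20.0, int(rng_children[i]))
        p = out / f"graded_{i}_snr20.h5"
        write_field(noisy, p)
        files.append(p)

    # stiff inclusion phantom
    inc = build_phantom("inclusion", {"background_mu_kpa": 3.0, "inclusion_mu_kpa": 12.0,
                                      "center_lateral_mm": 7.5, "center_depth_mm": 25.0,
                                      "radius_mm": 3.0})
    cfg = ScenarioConfig(phantom={"kind": "homogeneous"}, acquisition=dict(_ACQ))
    field = simulate_displacement(inc, cfg.build_push(), cfg.build_grid())
    p = out / "inclusion.h5"
    write_field(field, p)
    files.append(p)

    # depth-graded SNR scenario
    acq = dict(_ACQ)
    acq["tracked_depths_mm"] = [15.0, 20.0, 25.0, 30.0, 35.0]
    cfg = ScenarioConfig(phantom={"kind": "homogeneous", "mu_kpa": 9.0},
                         acquisition=acq)
    clean = simulate_displacement(cfg.build_medium(), cfg.build_push(), cfg.build_grid())
    noisy = add_noise(clean, np.asarray(DEPTH_SNR_DB), int(rng_children[4]))
    p = out / "depth_snr.h5"
    write_field(noisy, p)
    files.append(p)

    # synthetic clinical-style tables
    raters = make_rater_matrix(np.random.default_rng(int(rng_children[5])))
    p = out / "raters_synthetic.csv"
    raters.to_csv(p, index=False)
    files.append(p)
    cohort = make_cohort(np.random.default_rng(int(rng_children[6])))
    p = out / "cohort_synthetic.csv"
    cohort.to_csv(p, index=False)
    files.append(p)

    manifest = {
        "seed": int(seed),
        "files": {f.name: _sha256(f) for f in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
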