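"""Config loading and gridded-field / tabular export.

Fields (pressure magnitude/phase, intensity, temperature, dose) export to
NIfTI with the voxel spacing in the affine; the axial axis convention is
the package-wide one (focus at z = 0, z increasing away from the
transducer).  Plans and summaries export as CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .acoustic import AcousticMedium
from .phantom import TissuePhantom, generate_phantom
from .sonication import SonicationParameters, TreatmentPlan, preset

__all__ = [
    "load_config",
    "phantom_from_config",
    "params_from_config",
    "save_field_nifti",
    "save_plan_csv",
]


DEFAULT_CONFIG = {
    "transducer": {
        "focal_length_mm": 130.0,
        "aperture_radius_mm": 64.0,
        "frequency_mhz": 1.0,
    },
    "grid": {"domain_mm": [28.0, 28.0, 40.0], "voxel_mm": 0.5},
    "lesion": {"semi_axes_mm": [8.0, 8.0, 12.0]},
    "scenario": "adenomyosis-myometrium",
    "preset": "B",
}


def load_config(path: str | Path | None) -> dict:
    """YAML/JSON config with defaults filled in for missing blocks."""
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for key, val in user.items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    return cfg


def phantom_from_config(cfg: dict) -> TissuePhantom:
    return generate_phantom(
        domain_mm=tuple(cfg["grid"]["domain_mm"]),
        voxel_mm=float(cfg["grid"]["voxel_mm"]),
        lesion_semi_axes_mm=tuple(cfg["lesion"]["semi_axes_mm"]),
        scenario=cfg["scenario"],
    )


def params_from_config(cfg: dict, preset_label: str | None = None) -> SonicationParameters:
    if preset_label is not None:
        return preset(preset_label)
    if "parameters" in cfg:
        return SonicationParameters(**cfg["parameters"])
    return preset(cfg.get("preset", "B"))


def save_field_nifti(
    array: np.ndarray, voxel_mm: float, path: str | Path
) -> None:
    """Write a real 3-D grid to NIfTI (complex fields: save |p| and phase
    as two separate volumes)."""
    import nibabel as nib

    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(array, dtype=np.float32), affine), str(path))


def save_plan_csv(plan: TreatmentPlan, path: str | Path) -> None:
    import pandas as pd

    df = pd.DataFrame(plan.points_mm, columns=["x_mm", "y_mm", "z_mm"])
    df.insert(0, "order", np.arange(len(df)))
    df.to_csv(path, index=False)
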