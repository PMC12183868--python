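"""NIfTI-1 and tabular input/output.

Volumes are read and written through nibabel; per-frame metadata that NIfTI
has no standard slot for (saturation offsets in ppm, dynamic frame times in
seconds, flip angles in degrees) travels in a sidecar JSON next to the image
file. Masks are written uint8, parameter maps float32.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "ConfigError",
    "DataError",
    "read_volume",
    "write_volume",
    "sidecar_path",
    "read_stack",
    "write_stack",
    "read_json",
    "write_json",
    "read_cohort_csv",
    "write_cohort_csv",
]

COHORT_COLUMNS = ["tumor_id", "group", "volume_mm3", "day", "ph_e",
                  "acidity_score", "ktrans", "vp", "tgr"]


class ConfigError(ValueError):
    """Invalid or unresolvable configuration (CLI exit code 2)."""


class DataError(ValueError):
    """Malformed or inconsistent input data (CLI exit code 3)."""


def read_volume(path) -> tuple[np.ndarray, np.ndarray]:
    """Load a 3-D or 4-D NIfTI volume; returns (data, affine)."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"input volume not found: {path}")
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
    except Exception as exc:  # nibabel raises several format error types
        raise DataError(f"not a readable NIfTI file: {path} ({exc})") from exc
    if data.ndim not in (3, 4):
        raise DataError(f"expected 3-D or 4-D volume, got {data.ndim}-D: {path}")
    return data, img.affine


def write_volume(data: np.ndarray, path, affine: np.ndarray | None = None) -> Path:
    """Write a volume as NIfTI-1; uint8 for boolean data, float32 otherwise."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.asarray(data)
    if data.dtype == bool:
        data = data.astype(np.uint8)
    elif data.dtype.kind == "f":
        data = data.astype(np.float32)
    if affine is None:
        affine = np.eye(4)
    nib.save(nib.Nifti1Image(data, affine), str(path))
    return path


def sidecar_path(image_path) -> Path:
    p = Path(image_path)
    name = p.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return p.with_name(name[: -len(suffix)] + ".json")
    return p.with_suffix(".json")


def write_stack(data: np.ndarray, path, sidecar: dict,
                affine: np.ndarray | None = None) -> Path:
    """Write a 4-D stack plus its per-frame sidecar JSON."""
    if np.asarray(data).ndim != 4:
        raise DataError("stack must be 4-D")
    out = write_volume(data, path, affine)
    write_json(sidecar, sidecar_path(out))
    return out


def read_stack(path) -> tuple[np.ndarray, np.ndarray, dict]:
    """Read a 4-D stack and its sidecar; returns (data, affine, sidecar)."""
    data, affine = read_volume(path)
    if data.ndim != 4:
        raise DataError(f"expected 4-D stack: {path}")
    sc_path = sidecar_path(path)
    if not sc_path.exists():
        raise ConfigError(f"missing sidecar JSON for stack: {sc_path}")
    sidecar = read_json(sc_path)
    for key in ("offsets_ppm", "frame_times_s", "flip_angles_deg"):
        if key in sidecar and len(sidecar[key]) != data.shape[3]:
            raise DataError(
                f"sidecar {key} length {len(sidecar[key])} != frames {data.shape[3]}"
            )
    return data, affine, sidecar


def read_json(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"JSON file not found: {path}")
    try:
        return json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise DataError(f"malformed JSON: {path} ({exc})") from exc


def write_json(obj: dict, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
    return path


def read_cohort_csv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"cohort CSV not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"cohort CSV missing columns: {missing}")
    return df


def write_cohort_csv(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path
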