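"""Standard-format I/O: NIfTI-1 volumes, CSV feature tables, JSON reports.

Conventions: NIfTI-1 with an RAS-positive diagonal affine carrying the
voxel size in mm; CSV is UTF-8, comma-delimited, period decimal; the
feature-table layout is ``sample_id, group, <roi>_<metric>...``.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = ["save_nifti", "load_nifti", "save_feature_table",
           "load_feature_table", "save_json", "load_json", "file_sha256"]


class ArtifactParseError(ValueError):
    """Raised when a file written by this package cannot be read back."""


def save_nifti(data: np.ndarray, path: str | Path,
               voxel_size: tuple[float, float, float] = (0.1, 0.1, 0.1)) -> Path:
    """Write a scalar, label, or multi-component volume as .nii or .nii.gz."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.asarray(data)
    affine = np.diag(list(voxel_size) + [1.0])
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine)
    img.header.set_zooms(voxel_size + (1.0,) * (data.ndim - 3) if data.ndim > 3
                         else voxel_size)
    nib.save(img, str(path))
    return path


def load_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a NIfTI volume; returns (data, affine)."""
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # noqa: BLE001
        raise ArtifactParseError(f"cannot read NIfTI file {path}: {exc}") from exc
    return np.asarray(img.get_fdata()), img.affine


def save_feature_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
    return path


def load_feature_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001
        raise ArtifactParseError(f"cannot parse CSV table {path}: {exc}") from exc
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise ArtifactParseError(
                f"{path}: feature table lacks required column {col!r}")
    return df


def save_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_jsonable)
    return path


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")


def load_json(path: str | Path):
    path = Path(path)
    try:
        with open(path) as fh:
            return json.load(fh)
    except Exception as exc:  # noqa: BLE001
        raise ArtifactParseError(f"cannot parse JSON file {path}: {exc}") from exc


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
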