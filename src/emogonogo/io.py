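"""NIfTI and table I/O helpers.

Volumes are NIfTI-1 via nibabel with affines preserved; voxel indices are
0-based internally and converted to mm through the affine for reporting.
Tables are TSV; nested results JSON; configs YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "read_volume",
    "write_volume",
    "voxel_to_mm",
    "read_table",
    "write_table",
    "write_json",
    "read_yaml",
    "write_yaml",
]


def read_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray, dict]:
    """Load a NIfTI volume: (data, affine, header metadata)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    meta = {"tr": float(img.header.get_zooms()[3]) if data.ndim == 4 else None,
            "voxel_size_mm": tuple(float(z) for z in img.header.get_zooms()[:3])}
    return data, img.affine.copy(), meta


def write_volume(
    path: str | Path,
    data: np.ndarray,
    affine: np.ndarray | None = None,
    voxel_size_mm: float = 3.0,
    tr: float | None = None,
) -> None:
    """Write a NIfTI-1 volume; default affine is diagonal voxel scaling."""
    if affine is None:
        affine = np.diag([voxel_size_mm] * 3 + [1.0])
    img = nib.Nifti1Image(np.asarray(data), affine)
    zooms = list(img.header.get_zooms())
    if data.ndim == 4 and tr is not None:
        img.header.set_zooms(tuple(zooms[:3]) + (tr,))
        img.header.set_xyzt_units("mm", "sec")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))


def voxel_to_mm(voxel_index: np.ndarray, affine: np.ndarray) -> np.ndarray:
    """0-based voxel indices -> mm coordinates via the affine."""
    vi = np.atleast_2d(np.asarray(voxel_index, dtype=float))
    out = (affine @ np.column_stack([vi, np.ones(len(vi))]).T).T[:, :3]
    return out[0] if np.asarray(voxel_index).ndim == 1 else out


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def write_json(obj: dict, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def default(o):
        if isinstance(o, np.generic):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=default) + "\n")


def read_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_yaml(obj: dict, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(obj, sort_keys=True))
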