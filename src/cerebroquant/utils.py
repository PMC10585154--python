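"""Small shared numerics and IO helpers."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np


def wrap_phase(phi):
    """Wrap phase values into (-pi, pi]."""
    return -np.mod(-np.asarray(phi, dtype=float) + np.pi, 2.0 * np.pi) + np.pi


def save_json(obj, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")
    Path(path).write_text(json.dumps(obj, indent=2, default=_default) + "\n")


def json_dumps_stable(obj) -> str:
    """Deterministic JSON: sorted keys, floats rounded to 10 significant digits."""
    def _round(o):
        if isinstance(o, float):
            return float(f"{o:.10g}")
        if isinstance(o, dict):
            return {k: _round(v) for k, v in sorted(o.items())}
        if isinstance(o, (list, tuple)):
            return [_round(v) for v in o]
        if isinstance(o, (np.floating, np.integer)):
            return _round(o.item())
        return o
    return json.dumps(_round(obj), sort_keys=True, indent=2)


def config_hash(obj) -> str:
    """Short stable hash of a JSON-serializable configuration."""
    return hashlib.sha256(json_dumps_stable(obj).encode()).hexdigest()[:12]


def save_nifti(data: np.ndarray, path: str | Path,
               voxel_sizes=(0.75, 0.75, 8.0)) -> None:
    """Write an array as NIfTI with pixel dimensions in the header."""
    import nibabel as nib

    arr = np.asarray(data)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    affine = np.diag(list(voxel_sizes[:3]) + [1.0])
    img = nib.Nifti1Image(arr.astype(np.float64)
                          if arr.dtype.kind == "f" else arr, affine)
    img.header.set_zooms(voxel_sizes[:arr.ndim])
    nib.save(img, str(path))


def load_nifti(path: str | Path):
    """Read a NIfTI volume; returns (array, voxel_sizes)."""
    import nibabel as nib

    img = nib.load(str(path))
    return np.asarray(img.dataobj), tuple(float(z) for z in img.header.get_zooms())
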