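"""File I/O: NIfTI rasters, CSV tables, JSON sidecars with provenance.

All raster data (DWI stacks, metric maps, masks) travel as NIfTI with a
2D-slice affine built from the world frame (mm, voxel-center origin);
tabular data as CSV; structured results and ground truth as JSON.
Every sidecar carries provenance: tool version, configuration hash, and
seed.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np

from . import __version__
from .grid import Frame

__all__ = [
    "frame_to_affine",
    "affine_to_frame",
    "save_map",
    "load_map",
    "save_json",
    "load_json",
    "provenance",
]


def frame_to_affine(frame: Frame, slice_thickness: float = 1.0) -> np.ndarray:
    """NIfTI affine for a single-slice 2D frame.

    Data are stored (cols, rows, 1): the first NIfTI axis maps to world
    x, the second to world y, so the affine is diagonal.
    """
    aff = np.diag([frame.spacing, frame.spacing, slice_thickness, 1.0])
    aff[0, 3] = frame.origin[0]
    aff[1, 3] = frame.origin[1]
    return aff


def affine_to_frame(affine: np.ndarray, shape_xy: tuple[int, int]) -> Frame:
    return Frame(
        origin=(float(affine[0, 3]), float(affine[1, 3])),
        spacing=float(affine[0, 0]),
        shape=(shape_xy[1], shape_xy[0]),  # (rows, cols)
    )


def save_map(path, data: np.ndarray, frame: Frame) -> None:
    """Save a (rows, cols) map or (rows, cols, m) stack as NIfTI."""
    data = np.asarray(data)
    if data.ndim == 2:
        arr = data.T[:, :, None]  # -> (cols, rows, 1)
    elif data.ndim == 3:
        arr = np.transpose(data, (1, 0, 2))[:, :, None, :]
    else:
        raise ValueError("expected a 2D map or a 3D (rows, cols, m) stack")
    img = nib.Nifti1Image(arr.astype(np.float64), frame_to_affine(frame))
    nib.save(img, str(path))


def load_map(path) -> tuple[np.ndarray, Frame]:
    img = nib.load(str(path))
    arr = np.asarray(img.dataobj)
    frame = affine_to_frame(img.affine, arr.shape[:2])
    if arr.ndim == 3:
        return arr[:, :, 0].T, frame
    return np.transpose(arr[:, :, 0, :], (1, 0, 2)), frame


def provenance(config: dict | None = None, seed: int | None = None) -> dict:
    cfg_json = json.dumps(config or {}, sort_keys=True, default=str)
    return {
        "tool": "cortiq",
        "version": __version__,
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest()[:16],
        "seed": seed,
    }


def save_json(path, payload: dict, config: dict | None = None,
              seed: int | None = None) -> None:
    out = {"provenance": provenance(config, seed), **payload}
    Path(path).write_text(json.dumps(out, indent=2, default=_jsonify))


def load_json(path) -> dict:
    return json.loads(Path(path).read_text())


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
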