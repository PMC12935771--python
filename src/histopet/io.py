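"""Readers/writers for the pipeline's on-disk artifacts.

Volumes and heatmap stacks go to NIfTI-1 (spacing carried in the affine;
2D slabs stored as single-slice volumes), masks and probability maps to
single-channel TIFF, landmarks to CSV, everything tabular/structured to
CSV/JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import tifffile

from .registration import Volume3D

__all__ = [
    "save_volume_nifti", "load_volume_nifti",
    "save_image_tiff", "load_image_tiff",
    "save_json", "load_json",
]


def save_volume_nifti(vol: Volume3D | np.ndarray, path, spacing_mm=None) -> None:
    if isinstance(vol, Volume3D):
        data, spacing = vol.data, vol.spacing_mm
    else:
        data = np.asarray(vol)
        spacing = spacing_mm if spacing_mm is not None else (1.0, 1.0, 1.0)
    if data.ndim == 2:
        data = data[None, ...]
    affine = np.diag([*spacing, 1.0])
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    img.header.set_zooms(spacing)
    nib.save(img, str(path))


def load_volume_nifti(path) -> Volume3D:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(float)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume3D(data=data, spacing_mm=spacing)


def save_image_tiff(image: np.ndarray, path) -> None:
    tifffile.imwrite(str(path), np.asarray(image, dtype=np.float32))


def load_image_tiff(path) -> np.ndarray:
    return np.asarray(tifffile.imread(str(path)), dtype=float)


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, (np.bool_,)):
            return bool(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return super().default(obj)


def save_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, cls=_NumpyEncoder,
                                     sort_keys=True, allow_nan=True))


def load_json(path):
    return json.loads(Path(path).read_text())
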