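"""NIfTI-1 reading and writing (thin wrappers around nibabel).

Conventions: arrays are (x, y, slice) with the slice index on the third
axis, 0-based; the affine is diagonal with the voxel dimensions in mm.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .morphometry import NerveLabelMap
from .relaxometry import EchoPairVolume, PT2StarMap

__all__ = [
    "save_volume",
    "save_labels",
    "save_pt2star_map",
    "load_volume",
    "load_echo_pair",
    "load_labels",
]


def _affine(voxel_mm: tuple[float, float, float]) -> np.ndarray:
    return np.diag([voxel_mm[0], voxel_mm[1], voxel_mm[2], 1.0])


def save_volume(data: np.ndarray, voxel_mm: tuple[float, float, float], path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), _affine(voxel_mm))
    nib.save(img, str(path))


def save_labels(mask: NerveLabelMap, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.labels.astype(np.int16), _affine(mask.voxel_mm))
    nib.save(img, str(path))


def save_pt2star_map(pmap: PT2StarMap, values_path: str | Path, valid_path: str | Path) -> None:
    save_volume(np.nan_to_num(pmap.values, nan=0.0), pmap.voxel_mm, values_path)
    img = nib.Nifti1Image(pmap.valid.astype(np.uint8), _affine(pmap.voxel_mm))
    nib.save(img, str(valid_path))


def load_volume(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    voxel = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.dataobj, dtype=float), voxel  # type: ignore[return-value]


def load_echo_pair(path1: str | Path, path2: str | Path, te1_ms: float, te2_ms: float) -> EchoPairVolume:
    e1, vox = load_volume(path1)
    e2, vox2 = load_volume(path2)
    if vox != vox2:
        raise ValueError(f"echo voxel sizes differ: {vox} vs {vox2}")
    return EchoPairVolume(echo1=e1, echo2=e2, te1_ms=te1_ms, te2_ms=te2_ms, voxel_mm=vox)


def load_labels(path: str | Path) -> NerveLabelMap:
    img = nib.load(str(path))
    voxel = tuple(float(z) for z in img.header.get_zooms()[:3])
    labels = np.asarray(img.dataobj).astype(np.int64)
    return NerveLabelMap(labels=labels, voxel_mm=voxel)  # type: ignore[arg-type]
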