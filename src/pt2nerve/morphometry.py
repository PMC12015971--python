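"""Cross-sectional morphometry of nerve label maps.

Areas are pixel-counting areas: voxels of a structure on an axial slice
times the in-plane voxel area (dx * dy), with no contour interpolation or
sub-voxel correction — matching how manual ROI areas are exported by
common segmentation tools at this resolution. The per-subject aggregate
is the arithmetic mean over the analysis slices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import LABEL_EPINEURIUM, LABEL_FASCICLE

__all__ = ["NerveLabelMap", "AreaProfile", "csa_per_slice", "aggregate_areas", "area_profile"]

_VALID_LABELS = frozenset({0, LABEL_EPINEURIUM, LABEL_FASCICLE})


@dataclass
class NerveLabelMap:
    """Integer label volume: 0 background/muscle, 1 inner epineurium,
    2 fascicles; the whole nerve is the union of labels {1, 2}."""

    labels: np.ndarray
    voxel_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("label map must be 3D (x, y, slice)")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integers")
        present = set(np.unique(self.labels).tolist())
        if not present <= _VALID_LABELS:
            raise ValueError(f"unknown labels present: {sorted(present - _VALID_LABELS)}")
        if any(v <= 0 for v in self.voxel_mm):
            raise ValueError("voxel dims must be positive")

    @property
    def nslices(self) -> int:
        return self.labels.shape[2]

    @property
    def pixel_area_mm2(self) -> float:
        return self.voxel_mm[0] * self.voxel_mm[1]


@dataclass
class AreaProfile:
    """Per-slice and aggregate areas (mm^2) of nerve sub-structures."""

    per_slice: pd.DataFrame  # columns: slice, whole_nerve_mm2, fascicular_mm2, epineurium_mm2
    csa_mm2: float
    fascicular_area_mm2: float
    epineurium_area_mm2: float

    @property
    def fascicular_fraction(self) -> float:
        return self.fascicular_area_mm2 / self.csa_mm2


def csa_per_slice(mask: NerveLabelMap, structure: Iterable[int]) -> np.ndarray:
    """Pixel-counting area of ``structure`` on each axial slice, mm^2."""
    structure = set(structure)
    if not structure <= _VALID_LABELS:
        raise ValueError(f"unknown labels requested: {sorted(structure - _VALID_LABELS)}")
    counts = np.isin(mask.labels, list(structure)).sum(axis=(0, 1))
    return counts * mask.pixel_area_mm2


def aggregate_areas(per_slice_areas: np.ndarray, slices: Sequence[int]) -> float:
    """Arithmetic mean of per-slice areas over the analysis slices."""
    slices = list(slices)
    if not slices:
        raise ValueError("slice set is empty")
    per_slice_areas = np.asarray(per_slice_areas, dtype=float)
    if min(slices) < 0 or max(slices) >= per_slice_areas.shape[0]:
        raise ValueError("slice index out of range")
    return float(per_slice_areas[slices].mean())


def area_profile(mask: NerveLabelMap, slices: Sequence[int]) -> AreaProfile:
    """Whole-nerve CSA, fascicular area and inner-epineurium area.

    Per slice the three areas satisfy fascicular + epineurium = whole
    nerve exactly, because the labels partition the nerve voxels.
    """
    whole = csa_per_slice(mask, {LABEL_EPINEURIUM, LABEL_FASCICLE})
    fasc = csa_per_slice(mask, {LABEL_FASCICLE})
    epi = csa_per_slice(mask, {LABEL_EPINEURIUM})
    table = pd.DataFrame(
        {
            "slice": np.arange(mask.nslices),
            "whole_nerve_mm2": whole,
            "fascicular_mm2": fasc,
            "epineurium_mm2": epi,
        }
    )
    return AreaProfile(
        per_slice=table,
        csa_mm2=aggregate_areas(whole, slices),
        fascicular_area_mm2=aggregate_areas(fasc, slices),
        epineurium_area_mm2=aggregate_areas(epi, slices),
    )
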