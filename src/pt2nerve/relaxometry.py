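"""Two-point pseudo-T2* relaxometry.

A dual-echo gradient-echo acquisition with echo times TE1 < TE2 samples a
mono-exponential decay ``S(t) = S0 * exp(-t / T2*)`` at two points. The
ratio of the two echo intensities then yields the two-point estimate

    pT2* = -dTE / ln(iTE2 / iTE1),    dTE = TE2 - TE1,

called pseudo-T2* because with only two echoes it is an effective decay
time, not a fitted multi-compartment T2*. The estimate is invariant to
any common scaling of the two echoes, so proton density and T1/TR/flip-
angle weighting cancel.

Voxels where the ratio is not a valid decay (non-positive intensities, or
iTE2 >= iTE1 as happens in the noise floor) have no defined pT2* and are
flagged invalid rather than clipped; ROI summaries report the fraction of
valid voxels so the exclusion is never silent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "EchoPairVolume",
    "PT2StarMap",
    "ROISummary",
    "compute_pt2star",
    "pt2star_from_intensities",
    "select_analysis_slices",
    "roi_mean_pt2star",
    "roi_pt2star_from_mean_signal",
]


@dataclass
class EchoPairVolume:
    """Two co-registered 3D magnitude volumes with their echo times."""

    echo1: np.ndarray
    echo2: np.ndarray
    te1_ms: float
    te2_ms: float
    voxel_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.echo1 = np.asarray(self.echo1, dtype=float)
        self.echo2 = np.asarray(self.echo2, dtype=float)
        if self.echo1.shape != self.echo2.shape:
            raise ValueError(
                f"echo shapes differ: {self.echo1.shape} vs {self.echo2.shape}"
            )
        if self.echo1.ndim != 3:
            raise ValueError("echo volumes must be 3D (x, y, slice)")
        if not (0 < self.te1_ms < self.te2_ms):
            raise ValueError(f"need 0 < te1 < te2, got {self.te1_ms}, {self.te2_ms}")
        if not (np.all(np.isfinite(self.echo1)) and np.all(np.isfinite(self.echo2))):
            raise ValueError("echo intensities must be finite")
        if (self.echo1 < 0).any() or (self.echo2 < 0).any():
            raise ValueError("echo intensities must be non-negative")

    @property
    def delta_te_ms(self) -> float:
        return self.te2_ms - self.te1_ms

    @property
    def nslices(self) -> int:
        return self.echo1.shape[2]


@dataclass
class PT2StarMap:
    """Voxelwise pseudo-T2* (ms) with a validity mask."""

    values: np.ndarray
    valid: np.ndarray
    delta_te_ms: float
    voxel_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if self.values.shape != self.valid.shape:
            raise ValueError("values and valid mask must share a shape")


@dataclass
class ROISummary:
    """Mean pT2* over a labelled region restricted to the analysis slices."""

    structure: str
    mean_ms: float
    voxel_count: int
    valid_fraction: float
    slices: tuple[int, ...] = field(default_factory=tuple)


def pt2star_from_intensities(i1: float, i2: float, delta_te_ms: float) -> float:
    """Scalar two-point estimate; nan when the pair is not a valid decay."""
    if delta_te_ms <= 0:
        raise ValueError("delta TE must be positive")
    if i1 <= 0 or i2 <= 0 or i2 >= i1:
        return float("nan")
    return -delta_te_ms / np.log(i2 / i1)


def compute_pt2star(vol: EchoPairVolume) -> PT2StarMap:
    """Voxelwise pseudo-T2* map from a dual-echo volume.

    A voxel is valid iff ``echo1 > 0`` and ``0 < echo2 < echo1``; elsewhere
    the value is NaN and the validity mask is False.
    """
    e1, e2 = vol.echo1, vol.echo2
    valid = (e1 > 0) & (e2 > 0) & (e2 < e1)
    values = np.full(e1.shape, np.nan)
    ratio = np.divide(e2, e1, out=np.ones_like(e1), where=valid)
    with np.errstate(divide="ignore", invalid="ignore"):
        values[valid] = -vol.delta_te_ms / np.log(ratio[valid])
    return PT2StarMap(values=values, valid=valid, delta_te_ms=vol.delta_te_ms, voxel_mm=vol.voxel_mm)


def select_analysis_slices(nslices: int) -> tuple[int, ...]:
    """Analysis slices after excluding the first and last slice of the
    acquisition (edge slices suffer field-inhomogeneity signal changes):
    0-based indices 1 .. nslices-2 inclusive, e.g. 12 slices -> the 10
    central ones."""
    if nslices < 3:
        raise ValueError(f"need at least 3 slices to exclude first and last, got {nslices}")
    return tuple(range(1, nslices - 1))


class EmptyROIError(ValueError):
    """The requested structure has no voxels on the analysis slices."""


def _roi_mask(labels: np.ndarray, structure: Iterable[int], slices: Sequence[int], shape: tuple) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.shape != shape:
        raise ValueError(f"label map shape {labels.shape} != map shape {shape}")
    slices = tuple(slices)
    if not slices:
        raise ValueError("slice set is empty")
    if min(slices) < 0 or max(slices) >= shape[2]:
        raise ValueError(f"slice indices {slices} out of range for {shape[2]} slices")
    mask = np.isin(labels, list(structure))
    keep = np.zeros(shape[2], dtype=bool)
    keep[list(slices)] = True
    return mask & keep[None, None, :]


def roi_mean_pt2star(
    pmap: PT2StarMap,
    labels: np.ndarray,
    structure: Iterable[int],
    slices: Sequence[int],
    structure_name: str = "",
) -> ROISummary:
    """Mean pT2* over the valid voxels of a labelled structure.

    ``structure`` is a set of integer labels (the whole nerve is the union
    of the epineurium and fascicle labels). Invalid voxels are excluded
    from the mean and surfaced through ``valid_fraction``; an ROI with no
    voxels at all raises :class:`EmptyROIError`.
    """
    roi = _roi_mask(labels, structure, slices, pmap.values.shape)
    count = int(roi.sum())
    if count == 0:
        raise EmptyROIError(f"structure {tuple(structure)} has no voxels on slices {tuple(slices)}")
    valid = roi & pmap.valid
    nvalid = int(valid.sum())
    mean = float(np.mean(pmap.values[valid])) if nvalid else float("nan")
    return ROISummary(
        structure=structure_name or str(tuple(sorted(set(structure)))),
        mean_ms=mean,
        voxel_count=count,
        valid_fraction=nvalid / count,
        slices=tuple(slices),
    )


def roi_pt2star_from_mean_signal(
    vol: EchoPairVolume,
    labels: np.ndarray,
    structure: Iterable[int],
    slices: Sequence[int],
    structure_name: str = "",
) -> ROISummary:
    """Alternative reduction: estimate one pT2* from the ROI-averaged echo
    intensities instead of averaging voxelwise estimates. Agrees with the
    voxelwise route on noiseless uniform ROIs; provided because either
    reading of "ROI pT2*" is defensible."""
    roi = _roi_mask(labels, structure, slices, vol.echo1.shape)
    count = int(roi.sum())
    if count == 0:
        raise EmptyROIError(f"structure {tuple(structure)} has no voxels on slices {tuple(slices)}")
    m1 = float(vol.echo1[roi].mean())
    m2 = float(vol.echo2[roi].mean())
    value = pt2star_from_intensities(m1, m2, vol.delta_te_ms)
    return ROISummary(
        structure=structure_name or str(tuple(sorted(set(structure)))),
        mean_ms=value,
        voxel_count=count,
        valid_fraction=1.0 if np.isfinite(value) else 0.0,
        slices=tuple(slices),
    )
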