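"""Inter-rater agreement: Dice overlap of segmentations and the
intraclass correlation coefficient (ICC) of derived measurements.

The ICC variant is the two-way random-effects, absolute-agreement,
single-measurement form ICC(2,1) by default — the question being whether
two raters' absolute measurements are interchangeable, not merely
proportional. The consistency form ICC(3,1) is available as an option.
Both are computed from the two-way ANOVA mean squares, which are returned
alongside the estimate for auditability.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .morphometry import NerveLabelMap

__all__ = ["ICCResult", "dice", "icc_two_rater"]


@dataclass
class ICCResult:
    """ICC estimate with its ANOVA mean-square components.

    ``degenerate`` flags a constant table (zero total variance), where no
    ICC is defined; the value is NaN in that case.
    """

    value: float
    variant: str
    n_subjects: int
    n_raters: int
    ms_rows: float
    ms_cols: float
    ms_error: float
    degenerate: bool = False


def dice(
    mask_a: NerveLabelMap | np.ndarray,
    mask_b: NerveLabelMap | np.ndarray,
    structure: Iterable[int],
) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A| + |B|) of a structure's
    voxel sets in two label maps.

    When both sets are empty the coefficient is defined as 1.0 (the
    raters agree the structure is absent); this convention avoids
    undefined values for structures missing from a slice.
    """
    la = mask_a.labels if isinstance(mask_a, NerveLabelMap) else np.asarray(mask_a)
    lb = mask_b.labels if isinstance(mask_b, NerveLabelMap) else np.asarray(mask_b)
    if la.shape != lb.shape:
        raise ValueError(f"mask shapes differ: {la.shape} vs {lb.shape}")
    labels = list(structure)
    a = np.isin(la, labels)
    b = np.isin(lb, labels)
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def icc_two_rater(table: np.ndarray, variant: str = "icc2_1") -> ICCResult:
    """ICC of an n-subjects x 2-raters measurement table.

    ICC(2,1) (absolute agreement):
        (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)
    ICC(3,1) (consistency):
        (MSR - MSE) / (MSR + (k-1) MSE)

    where MSR, MSC, MSE are the subject, rater and residual mean squares
    of the two-way ANOVA, n the number of subjects and k = 2 raters.
    """
    data = np.asarray(table, dtype=float)
    if data.ndim != 2 or data.shape[1] != 2:
        raise ValueError(f"expected an (n, 2) table, got shape {data.shape}")
    n, k = data.shape
    if n < 2:
        raise ValueError("ICC needs at least 2 subjects")
    if not np.all(np.isfinite(data)):
        raise ValueError("measurement table contains missing/non-finite cells")
    if variant not in ("icc2_1", "icc3_1"):
        raise ValueError(f"unknown ICC variant {variant!r}")

    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_total = ((data - grand) ** 2).sum()
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    if ss_total <= 0:
        return ICCResult(float("nan"), variant, n, k, msr, msc, mse, degenerate=True)

    if variant == "icc2_1":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    else:
        denom = msr + (k - 1) * mse
    value = (msr - mse) / denom if denom != 0 else float("nan")
    return ICCResult(float(value), variant, n, k, float(msr), float(msc), float(mse))
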