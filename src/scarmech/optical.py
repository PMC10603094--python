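"""Cross-polarized OCT quantification and threshold-based area measurement.

CP-OCT acquires two co-registered amplitude images of the same tissue: one in
which the detected light retains the incident polarization (``A_co``) and one
in which it is rotated into the orthogonal state (``A_cross``).  From these,

    R     = sqrt(A_co**2 + A_cross**2)          (sample reflectivity)
    delta = A_co / (A_co + A_cross)             (co-polarization ratio)

``delta`` is the fraction of backscattered amplitude with preserved
polarization; it rises when tissue becomes structurally disorganized, e.g.
in a spinal lesion site.  Pixels with zero total amplitude carry no
polarization information and are masked out of all ROI means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PolarizedStack",
    "StructureResult",
    "reflectivity_and_ratio",
    "average_intensity_projection",
    "roi_mean_ratio",
    "mean_threshold_area",
]


@dataclass
class PolarizedStack:
    """Co-registered co- and cross-polarized amplitude stacks.

    Arrays may be 2-D (single image) or 3-D with the stack axis first.
    """

    a_co: np.ndarray
    a_cross: np.ndarray
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        self.a_co = np.asarray(self.a_co, dtype=float)
        self.a_cross = np.asarray(self.a_cross, dtype=float)
        if self.a_co.shape != self.a_cross.shape:
            raise ValueError(
                f"shape mismatch: co {self.a_co.shape} vs cross {self.a_cross.shape}"
            )
        if (self.a_co < 0).any() or (self.a_cross < 0).any():
            raise ValueError("amplitudes must be non-negative")


@dataclass
class StructureResult:
    reflectivity: np.ndarray
    ratio: np.ndarray            # delta, NaN where invalid
    valid: np.ndarray            # bool mask, A_co + A_cross > 0
    pixel_size_um: float = 1.0


def average_intensity_projection(stack: np.ndarray) -> np.ndarray:
    """Per-pixel arithmetic mean along the stack axis (axis 0).

    A 2-D input is returned unchanged (single-slice stack).
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim == 2:
        return stack.copy()
    if stack.ndim != 3:
        raise ValueError("stack must be 2-D or 3-D")
    if stack.shape[0] == 0:
        raise ValueError("empty stack")
    return stack.mean(axis=0)


def reflectivity_and_ratio(stack: PolarizedStack, *, project_first: bool = True) -> StructureResult:
    """Pixelwise reflectivity R and co-polarization ratio delta.

    With ``project_first`` (default) 3-D stacks are reduced to their averaged
    intensity projection before R and delta are computed, matching the
    acquisition-software convention of quantifying the projected image.  With
    ``project_first=False`` the ratio is computed per slice and then averaged.
    """
    a_co, a_cross = stack.a_co, stack.a_cross
    if project_first and a_co.ndim == 3:
        a_co = average_intensity_projection(a_co)
        a_cross = average_intensity_projection(a_cross)

    total = a_co + a_cross
    valid = total > 0
    reflectivity = np.sqrt(a_co ** 2 + a_cross ** 2)
    ratio = np.full(a_co.shape, np.nan)
    np.divide(a_co, total, out=ratio, where=valid)

    if not project_first and ratio.ndim == 3:
        with np.errstate(invalid="ignore"):
            ratio = np.nanmean(ratio, axis=0)
        reflectivity = average_intensity_projection(reflectivity)
        valid = np.isfinite(ratio)
    return StructureResult(reflectivity=reflectivity, ratio=ratio, valid=valid,
                           pixel_size_um=stack.pixel_size_um)


def _resolve_roi(shape: tuple[int, int], roi) -> np.ndarray:
    """ROI as a boolean mask from a mask, slice pair, or None (whole image)."""
    if roi is None:
        return np.ones(shape, dtype=bool)
    if isinstance(roi, np.ndarray) and roi.dtype == bool:
        if roi.shape != shape:
            raise ValueError("ROI mask shape mismatch")
        return roi
    rs, cs = roi
    mask = np.zeros(shape, dtype=bool)
    mask[rs, cs] = True
    if not mask.any():
        raise ValueError("ROI selects no pixels")
    return mask


def roi_mean_ratio(result: StructureResult, roi=None) -> float:
    """Mean co-polarization ratio over the valid pixels of an ROI.

    ``roi`` may be a boolean mask, a ``(row_slice, col_slice)`` pair, or None
    for the whole image.

    Raises
    ------
    ValueError
        If every ROI pixel is invalid (zero total amplitude).
    """
    mask = _resolve_roi(result.ratio.shape, roi)
    sel = result.ratio[mask & result.valid]
    if sel.size == 0:
        raise ValueError("ROI contains no valid pixels")
    return float(sel.mean())


def mean_threshold_area(image: np.ndarray, roi=None, *, pixel_size_um: float = 1.0):
    """Foreground area by mean-of-grey-levels thresholding.

    The threshold is the mean grey level over the ROI; foreground pixels are
    those strictly greater than it (so a uniform image yields zero
    foreground).  Returns ``(pixel_count, area_um2)``.
    """
    image = np.asarray(image, dtype=float)
    mask = _resolve_roi(image.shape, roi)
    sel = image[mask]
    if sel.size == 0:
        raise ValueError("empty ROI")
    threshold = sel.mean()
    count = int((sel > threshold).sum())
    return count, count * pixel_size_um ** 2
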