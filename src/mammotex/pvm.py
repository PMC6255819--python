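"""Partial-view patch extraction.

A partial-view mammogram (PVM) is a fixed-size square crop focused on the
diagnostically relevant part of an image.  For annotated images the square
is centered on the single ROI and the image is skipped when the ROI has
multiple components, sticks out of the square, or the square leaves the
image.  Unannotated (normal) images have no ROI, so the square is centered
on the most salient pixel of the most salient region of a center-surround
intensity-contrast saliency map, clamped to the image bounds so that a
normal image always yields a patch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .exceptions import InputError

__all__ = [
    "PVMRecord",
    "Skip",
    "SKIP_REASONS",
    "connected_components",
    "extract_pvm_roi",
    "saliency_map",
    "extract_pvm_salient",
    "salient_region_mask",
]

#: Machine-readable skip reasons for ROI-centered extraction.
SKIP_REASONS = ("multiple_rois", "roi_outside_square", "square_out_of_bounds")

# 8-connectivity structuring element shared by all labeling here.
_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class PVMRecord:
    """An extracted patch with provenance."""

    crop: np.ndarray
    source_id: str
    class_label: str
    center: tuple[int, int]  # (row, col) in source coordinates
    provenance: str  # "roi" | "saliency"


@dataclass(frozen=True)
class Skip:
    """Extraction declined; ``reason`` is one of :data:`SKIP_REASONS`."""

    reason: str
    source_id: str = ""


def connected_components(mask) -> tuple[int, np.ndarray]:
    """8-connected component count and label raster (raster-scan label order)."""
    m = np.asarray(mask)
    if m.ndim != 2:
        raise InputError("mask must be 2-D")
    labels, count = ndimage.label(m != 0, structure=_STRUCT8)
    return int(count), labels


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def extract_pvm_roi(image, mask, w: int, class_label: str,
                    source_id: str = "") -> PVMRecord | Skip:
    """Crop a ``w x w`` square centered on the single-component ROI.

    The center is the rounded mass centroid of the ROI. Returns
    :class:`Skip` when the mask has != 1 components, when any ROI pixel
    falls outside the square, or when the square would leave the image
    (no padding — fabricating border tissue is worse than skipping).
    """
    img = np.asarray(image, dtype=float)
    m = np.asarray(mask)
    if m.shape != img.shape:
        raise InputError("mask shape must match image shape")
    if w < 2:
        raise InputError("crop size w must be >= 2")
    if not (m != 0).any():
        raise InputError("ROI mask is empty")

    count, _labels = connected_components(m)
    if count != 1:
        return Skip("multiple_rois", source_id)

    rows, cols = np.nonzero(m)
    cr = _round_half_up(rows.mean())
    cc = _round_half_up(cols.mean())
    r0, c0 = cr - w // 2, cc - w // 2
    if r0 < 0 or c0 < 0 or r0 + w > img.shape[0] or c0 + w > img.shape[1]:
        return Skip("square_out_of_bounds", source_id)
    if (rows < r0).any() or (rows >= r0 + w).any() or (cols < c0).any() or (cols >= c0 + w).any():
        return Skip("roi_outside_square", source_id)
    return PVMRecord(
        crop=img[r0:r0 + w, c0:c0 + w].copy(),
        source_id=source_id,
        class_label=class_label,
        center=(cr, cc),
        provenance="roi",
    )


def saliency_map(image) -> np.ndarray:
    """Center-surround intensity-contrast saliency.

    A single-channel simplification of the classic bottom-up conspicuity
    map: ``S = smooth( sum_{s in {1,2,4}} maxnorm(|G_s * I - G_{4s} * I|) )``
    where ``G_s`` is Gaussian blur at scale ``s`` px and the final smoothing
    uses sigma 2.  The result is max-normalized to [0,1]; a contrast-free
    (constant) image maps to identically zero.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.shape[0] < 32 or img.shape[1] < 32:
        raise InputError("saliency needs a 2-D image at least 32x32")
    acc = np.zeros_like(img)
    for s in (1.0, 2.0, 4.0):
        center = ndimage.gaussian_filter(img, s, mode="nearest")
        surround = ndimage.gaussian_filter(img, 4.0 * s, mode="nearest")
        term = np.abs(center - surround)
        peak = term.max()
        if peak > 1e-12:
            acc += term / peak
    sal = ndimage.gaussian_filter(acc, 2.0, mode="nearest")
    peak = sal.max()
    if peak <= 1e-12:
        return np.zeros_like(img)
    return sal / peak


def extract_pvm_salient(image, w: int, class_label: str,
                        source_id: str = "") -> PVMRecord:
    """Crop a ``w x w`` square at the most salient pixel of the most salient region.

    The most salient region is the 8-connected component of pixels with
    saliency >= 0.9 * max that contains the global argmax; the center is
    that argmax (ties broken by smallest row-major index).  The square is
    clamped (shifted) into the image bounds so a patch is always produced.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.shape[0] < w or img.shape[1] < w:
        raise InputError(f"image must be at least {w}x{w}")
    sal = saliency_map(img)
    flat_arg = int(np.argmax(sal))  # row-major first maximum: the tie-break
    cr, cc = np.unravel_index(flat_arg, sal.shape)
    # region membership is informational here: the argmax is inside it by
    # construction, and the crop center is the argmax itself
    r0 = int(np.clip(cr - w // 2, 0, img.shape[0] - w))
    c0 = int(np.clip(cc - w // 2, 0, img.shape[1] - w))
    return PVMRecord(
        crop=img[r0:r0 + w, c0:c0 + w].copy(),
        source_id=source_id,
        class_label=class_label,
        center=(int(cr), int(cc)),
        provenance="saliency",
    )


def salient_region_mask(image) -> np.ndarray:
    """The most salient region: 8-connected component of pixels with
    saliency >= 0.9 * max containing the global argmax."""
    sal = saliency_map(image)
    if sal.max() <= 0.0:
        return np.zeros(sal.shape, dtype=bool)
    thresh = sal >= 0.9 * sal.max()
    labels, _ = ndimage.label(thresh, structure=_STRUCT8)
    cr, cc = np.unravel_index(int(np.argmax(sal)), sal.shape)
    return labels == labels[cr, cc]
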