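"""Pupa segmentation and standard cropping.

The segmentation pipeline mirrors the classical recipe for a dark pupa on a
light background: luminance grayscale -> global (Otsu) threshold -> inversion
so the pupa is foreground -> morphological opening to shed thin molt debris ->
connected-component contour extraction -> area filtering -> largest survivor.
The retained body is then cropped to a fixed 320x320 window centred on the
filled-contour centroid.

Coordinate convention throughout the package: 0-based ``(row, col)`` pixel
coordinates, half-open crop windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import measure, morphology

__all__ = [
    "PupaContour",
    "CropResult",
    "SegmentationError",
    "CROP_SIZE",
    "DEFAULT_AREA_THRESHOLD_FRAC",
    "rgb_to_gray",
    "segment_pupa",
    "crop_centered",
]

#: Side length of the standard crop, px.
CROP_SIZE = 320

#: Minimum surviving-contour area as a fraction of the full image area.
DEFAULT_AREA_THRESHOLD_FRAC = 0.02

#: Luminance weights used for graying.
_GRAY_WEIGHTS = np.array([0.299, 0.587, 0.114])

#: Elliptical structuring element for the opening step (5x5 disk).
_OPENING_FOOTPRINT = morphology.disk(2)


class SegmentationError(ValueError):
    """Raised when no pupa-sized contour survives segmentation."""


def fill_polygon(points: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Filled boolean mask of a closed ``(row, col)`` polygon.

    Even-odd scanline fill at subpixel precision: a pixel is set when its
    center lies inside or on the polygon.  The crossing computation is
    vectorized over edges x scanlines, which matters for the dense
    ~1000-vertex contours produced by marching squares.
    """
    pts = np.asarray(points, dtype=float)
    r1, c1 = pts[:, 0], pts[:, 1]
    r2, c2 = np.roll(r1, -1), np.roll(c1, -1)
    keep = r1 != r2  # horizontal edges never cross a scanline
    r1, r2, c1, c2 = r1[keep], r2[keep], c1[keep], c2[keep]
    mask = np.zeros(shape, dtype=bool)
    if r1.size == 0:
        return mask
    ys = np.arange(shape[0], dtype=float)[:, None]
    lo, hi = np.minimum(r1, r2), np.maximum(r1, r2)
    crosses = (ys >= lo) & (ys < hi)  # half-open: vertex counted once
    xs = c1 + (ys - r1) / (r2 - r1) * (c2 - c1)
    ncols = shape[1]
    for y in range(shape[0]):
        xr = np.sort(xs[y][crosses[y]])
        for i in range(0, len(xr) - 1, 2):
            left = max(int(np.ceil(xr[i])), 0)
            right = min(int(np.floor(xr[i + 1])), ncols - 1)
            if left <= right:
                mask[y, left : right + 1] = True
    return mask


@dataclass
class PupaContour:
    """Closed, ordered boundary of a segmented pupa body.

    ``points`` is an ``(N, 2)`` float array of ``(row, col)`` coordinates in
    marching-squares subpixel precision; the sequence is closed (the polygon
    edge from the last point back to the first is implicit).
    """

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
            raise ValueError("contour needs an (N>=3, 2) point array")
        # drop an explicit duplicate closing point
        if np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]
        self.points = pts

    def filled_mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Rasterize the closed polygon as a filled boolean mask."""
        return fill_polygon(self.points, shape)

    @property
    def area_px(self) -> float:
        """Enclosed area by the shoelace formula (px^2)."""
        r, c = self.points[:, 0], self.points[:, 1]
        return float(abs(np.dot(r, np.roll(c, -1)) - np.dot(c, np.roll(r, -1))) / 2.0)

    @property
    def centroid(self) -> np.ndarray:
        """Area centroid of the filled polygon, ``(row, col)``."""
        r, c = self.points[:, 0], self.points[:, 1]
        r2, c2 = np.roll(r, -1), np.roll(c, -1)
        cross = r * c2 - r2 * c
        area6 = 3.0 * np.sum(cross)
        if abs(area6) < 1e-12:  # degenerate; fall back to vertex mean
            return self.points.mean(axis=0)
        cr = np.sum((r + r2) * cross) / area6
        cc_ = np.sum((c + c2) * cross) / area6
        return np.array([cr, cc_])

    @property
    def perimeter(self) -> float:
        """Closed polyline arc length (px)."""
        diffs = np.diff(np.vstack([self.points, self.points[:1]]), axis=0)
        return float(np.sum(np.hypot(diffs[:, 0], diffs[:, 1])))

    def translated(self, dr: float, dc: float) -> "PupaContour":
        return PupaContour(self.points + np.array([dr, dc]))


@dataclass
class CropResult:
    """A 320x320 crop of the pupa plus its mask and contour in crop coords."""

    crop_rgb: np.ndarray
    crop_mask: np.ndarray
    contour: PupaContour
    offset: tuple[int, int]
    truncated: bool = False

    def __post_init__(self) -> None:
        if self.crop_rgb.shape[:2] != (CROP_SIZE, CROP_SIZE):
            raise ValueError("crop_rgb must be 320x320")
        if self.crop_mask.shape != (CROP_SIZE, CROP_SIZE):
            raise ValueError("crop_mask must be 320x320")

    @property
    def gray(self) -> np.ndarray:
        return rgb_to_gray(self.crop_rgb)


def rgb_to_gray(rgb: np.ndarray) -> np.ndarray:
    """Luminance grayscale (0.299 R + 0.587 G + 0.114 B), float, source scale."""
    rgb = np.asarray(rgb, dtype=float)
    if rgb.ndim == 2:
        return rgb
    return rgb[..., :3] @ _GRAY_WEIGHTS


def _otsu_threshold(gray: np.ndarray) -> float:
    from skimage.filters import threshold_otsu

    return float(threshold_otsu(gray))


def _largest_external_contour(mask: np.ndarray) -> PupaContour:
    """Outer boundary of a (hole-filled) boolean region as a closed polygon."""
    filled = ndi.binary_fill_holes(mask)
    contours = measure.find_contours(filled.astype(float), 0.5)
    if not contours:
        raise SegmentationError("no contour found in region")
    pts = max(contours, key=len)
    return PupaContour(pts)


def segment_pupa(
    image: np.ndarray,
    area_threshold_frac: float = DEFAULT_AREA_THRESHOLD_FRAC,
) -> PupaContour:
    """Segment the single pupa body from a light-background image.

    Parameters
    ----------
    image
        RGB (or grayscale) raster, any numeric dtype.
    area_threshold_frac
        Connected components with area below this fraction of the whole
        image area are discarded as molt debris.

    Returns
    -------
    PupaContour
        Boundary of the largest surviving dark region.

    Raises
    ------
    SegmentationError
        If no component survives the area threshold ("no pupa found").
    """
    image = np.asarray(image)
    if image.size == 0:
        raise SegmentationError("empty image")
    gray = rgb_to_gray(image)
    if np.ptp(gray) == 0:
        raise SegmentationError("no pupa found: image is uniform")
    thresh = _otsu_threshold(gray)
    # inversion: the pupa is darker than the background, so foreground = below
    foreground = gray <= thresh
    opened = ndi.binary_opening(foreground, structure=_OPENING_FOOTPRINT)
    labels, n = ndi.label(opened)
    if n == 0:
        raise SegmentationError("no pupa found: nothing survives opening")
    areas = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    min_area = area_threshold_frac * gray.size
    keep = np.flatnonzero(areas >= min_area) + 1
    if keep.size == 0:
        raise SegmentationError(
            f"no pupa found: largest component ({int(areas.max())} px) is below "
            f"the area threshold ({min_area:.0f} px)"
        )
    best = keep[np.argmax(areas[keep - 1])]
    return _largest_external_contour(labels == best)


def _background_median_color(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    outside = ~mask
    if not outside.any():
        outside = np.ones_like(mask)
    if image.ndim == 2:
        return np.median(image[outside])
    return np.median(image[outside], axis=0)


def crop_centered(image: np.ndarray, contour: PupaContour) -> CropResult:
    """Crop a 320x320 window centred on the filled-contour centroid.

    Windows falling partly outside the image are padded with the background's
    median color.  A body wider/taller than 320 px is cropped anyway: the mask
    is truncated, a warning is emitted and ``truncated`` is set on the result.
    """
    image = np.asarray(image)
    h, w = image.shape[:2]
    full_mask = contour.filled_mask((h, w))

    extent = contour.points.max(axis=0) - contour.points.min(axis=0)
    truncated = bool((extent >= CROP_SIZE).any())
    if truncated:
        warnings.warn(
            "pupa contour exceeds the 320 px crop window; mask truncated",
            stacklevel=2,
        )

    cr, cc = contour.centroid
    r0 = int(round(cr)) - CROP_SIZE // 2
    c0 = int(round(cc)) - CROP_SIZE // 2

    bg = _background_median_color(image, full_mask)
    if image.ndim == 2:
        crop = np.full((CROP_SIZE, CROP_SIZE), bg, dtype=image.dtype)
    else:
        crop = np.empty((CROP_SIZE, CROP_SIZE, image.shape[2]), dtype=image.dtype)
        crop[...] = np.asarray(bg, dtype=image.dtype)
    mask = np.zeros((CROP_SIZE, CROP_SIZE), dtype=bool)

    # overlap of the half-open window [r0, r0+320) x [c0, c0+320) with the image
    rs, re = max(r0, 0), min(r0 + CROP_SIZE, h)
    cs, ce = max(c0, 0), min(c0 + CROP_SIZE, w)
    if rs < re and cs < ce:
        crop[rs - r0 : re - r0, cs - c0 : ce - c0] = image[rs:re, cs:ce]
        mask[rs - r0 : re - r0, cs - c0 : ce - c0] = full_mask[rs:re, cs:ce]

    return CropResult(
        crop_rgb=crop,
        crop_mask=mask,
        contour=contour.translated(-r0, -c0),
        offset=(r0, c0),
        truncated=truncated,
    )
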