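"""SD-PSF: the 37-dimensional pupal shape descriptor.

The descriptor combines 14 global shape statistics of the segmented body
contour with a 23-point curvature profile (KMM).  The contour is first
rotated so the moment-fitted ellipse's major axis is horizontal; the head and
tail are then disambiguated by comparing the summed chord widths of the two
body halves (TL1 = anterior, TL2 = posterior) and mirroring the contour when
TL2 > TL1, so the wider (head) end is always leftmost.  KMM entry K is the
vertical chord of the filled, aligned silhouette at horizontal position K/24
of its axis-aligned bounding-box width, K = 1..23.

Absolute scale is intentionally not normalized: body size is an informative
trait (species and sexes differ systematically in size and weight).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon

from .preprocess import PupaContour, fill_polygon

__all__ = [
    "AlignedContour",
    "KmmProfile",
    "SdpsfFeatures",
    "SDPSF_FEATURE_NAMES",
    "KMM_POINTS",
    "align_contour",
    "compute_kmm",
    "compute_sdpsf",
]

#: Number of chord samples in the curvature profile.
KMM_POINTS = 23

#: Frozen feature order of the 37-vector.
SDPSF_FEATURE_NAMES: tuple[str, ...] = (
    "perimeter",
    "area",
    "dispersity",
    "min_radius",
    "avg_radius",
    "max_radius",
    "radius_ratio",
    "major_axis",
    "minor_axis",
    "aspect_ratio",
    "rectangularity",
    "circularity",
    "compactness",
    "eccentricity",
) + tuple(f"kmm_{k:02d}" for k in range(1, KMM_POINTS + 1))


@dataclass
class AlignedContour:
    """Contour rotated so the fitted-ellipse major axis is horizontal."""

    points: np.ndarray  # (N, 2) float (row, col)
    major_len: float
    minor_len: float
    eccentricity: float

    @property
    def bbox(self) -> tuple[float, float, float, float]:
        """Straight-edge bounding rectangle ``(rmin, cmin, rmax, cmax)``."""
        rmin, cmin = self.points.min(axis=0)
        rmax, cmax = self.points.max(axis=0)
        return float(rmin), float(cmin), float(rmax), float(cmax)


@dataclass
class KmmProfile:
    """The 23 sampled chord widths plus the head/tail decision record."""

    widths: np.ndarray  # (23,) float, px
    tl1: float
    tl2: float
    flipped: bool

    def __post_init__(self) -> None:
        self.widths = np.asarray(self.widths, dtype=float)
        if self.widths.shape != (KMM_POINTS,):
            raise ValueError(f"KMM profile must have {KMM_POINTS} widths")


@dataclass
class SdpsfFeatures:
    perimeter: float
    area: float
    dispersity: float
    min_radius: float
    avg_radius: float
    max_radius: float
    radius_ratio: float
    major_axis: float
    minor_axis: float
    aspect_ratio: float
    rectangularity: float
    circularity: float
    compactness: float
    eccentricity: float
    kmm: np.ndarray

    def to_vector(self) -> np.ndarray:
        """The 37 features in the ``SDPSF_FEATURE_NAMES`` order."""
        head = np.array([getattr(self, n) for n in SDPSF_FEATURE_NAMES[:14]])
        return np.concatenate([head, np.asarray(self.kmm, dtype=float)])


def _fit_ellipse_moments(mask: np.ndarray) -> tuple[np.ndarray, float, float, float]:
    """Moment-based ellipse fit of a boolean region.

    Returns (centroid(row,col), angle, major_len, minor_len); ``angle`` is the
    major-axis angle versus the horizontal (column) axis, in (-pi/2, pi/2].
    A perfect circle (equal eigenvalues) resolves to angle 0.
    """
    r, c = np.nonzero(mask)
    if r.size == 0:
        raise ValueError("empty mask")
    cent = np.array([r.mean(), c.mean()])
    dr, dc = r - cent[0], c - cent[1]
    # +1/12 per axis: variance of the unit pixel square, so a one-pixel-thick
    # line still has nonzero thickness and a circle fits its true diameter
    cov = np.array(
        [
            [np.mean(dr * dr) + 1.0 / 12.0, np.mean(dr * dc)],
            [np.mean(dr * dc), np.mean(dc * dc) + 1.0 / 12.0],
        ]
    )
    evals, evecs = np.linalg.eigh(cov)  # ascending
    lam_minor, lam_major = float(evals[0]), float(evals[1])
    if lam_major <= 1e-9:
        raise ValueError("degenerate contour: zero extent")
    if lam_major - lam_minor < 1e-9:
        angle = 0.0  # circle: orientation tie resolves to horizontal
    else:
        v = evecs[:, 1]  # (dr, dc) of the major axis
        angle = float(np.arctan2(v[0], v[1]))
        if angle <= -np.pi / 2:
            angle += np.pi
        elif angle > np.pi / 2:
            angle -= np.pi
    return cent, angle, 4.0 * np.sqrt(lam_major), 4.0 * np.sqrt(lam_minor)


def _rasterize(points: np.ndarray, pad: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Fill a closed contour in a local frame; returns (mask, origin)."""
    origin = np.floor(points.min(axis=0)) - pad
    local = points - origin
    shape = tuple((np.ceil(local.max(axis=0)) + pad + 1).astype(int))
    return fill_polygon(local, shape), origin


def align_contour(contour: PupaContour) -> AlignedContour:
    """Rotate the contour about its centroid so the major axis is horizontal.

    The fit is the moment (covariance) ellipse of the filled contour; rotation
    is by minus the fitted major-axis angle.  Raises ``ValueError`` for
    degenerate (collinear or < 5 point) contours.
    """
    pts = np.asarray(contour.points, dtype=float)
    if len(pts) < 5:
        raise ValueError("contour needs >= 5 points for an ellipse fit")
    mask, origin = _rasterize(pts)
    cent_local, angle, major, minor = _fit_ellipse_moments(mask)
    if minor < 2.0:  # thinner than ~2 px: no meaningful ellipse fit
        raise ValueError("degenerate (collinear) contour")
    cent = cent_local + origin
    cos_a, sin_a = np.cos(angle), np.sin(angle)
    d = pts - cent
    # rotate by -angle in the image plane: (dr, dc) -> (dr*cos - dc*sin is for
    # +angle); applying R(-angle) to (dc, dr) treated as (x, y)
    dc_new = d[:, 1] * cos_a + d[:, 0] * sin_a
    dr_new = -d[:, 1] * sin_a + d[:, 0] * cos_a
    aligned = np.column_stack([dr_new + cent[0], dc_new + cent[1]])
    ecc = float(np.sqrt(max(0.0, 1.0 - (minor / major) ** 2)))
    return AlignedContour(
        points=aligned, major_len=float(major), minor_len=float(minor),
        eccentricity=ecc,
    )


def _column_widths(mask: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Chord width (max row - min row + 1) of mask pixels in each pixel column."""
    widths = np.zeros(len(cols))
    for i, c in enumerate(cols):
        rows = np.flatnonzero(mask[:, c])
        if rows.size:
            widths[i] = rows[-1] - rows[0] + 1
    return widths


def _kmm_from_mask(mask: np.ndarray) -> np.ndarray:
    cols = np.flatnonzero(mask.any(axis=0))
    cmin, cmax = cols[0], cols[-1]
    width = cmax - cmin + 1
    if width < 24:
        raise ValueError(f"bounding box width {width} px < 24 px")
    # K/24 positions along the discrete axis cmin..cmax; the (width-1) span
    # keeps the sampling mirror-symmetric (K and 24-K sample mirror columns)
    ks = np.arange(1, KMM_POINTS + 1)
    sample_cols = cmin + np.round(ks * (width - 1) / 24.0).astype(int)
    return _column_widths(mask, sample_cols)


def _canonical_mask(points: np.ndarray) -> np.ndarray:
    """Rasterize with the bbox corner at a fixed subpixel phase.

    Anchoring the bounding-box corner at a fixed half-integer coordinate
    makes the raster reproducible under rigid motions of the input contour,
    and keeps the marching-squares boundary (which runs midway between pixel
    centers) off the pixel-center grid so boundary ties are not double
    counted.
    """
    local = points - points.min(axis=0) + 2.5
    shape = tuple((np.ceil(local.max(axis=0)) + 3).astype(int))
    return fill_polygon(local, shape)


def compute_kmm(aligned: AlignedContour) -> KmmProfile:
    """Sample the 23 KMM chords and canonicalize head/tail orientation.

    TL1 sums the anterior-half chords (K = 1..11), TL2 the posterior half
    (K = 13..23).  If TL2 > TL1 the silhouette is mirrored horizontally and
    the chords are re-sampled, so the wider end always sits at K = 1.
    """
    widths = _kmm_from_mask(_canonical_mask(aligned.points))
    tl1 = float(widths[:11].sum())
    tl2 = float(widths[12:].sum())
    flipped = tl2 > tl1
    if flipped:
        # mirror the aligned contour horizontally and re-sample through the
        # same canonical rasterization, so a 180-degree-rotated input lands on
        # the identical silhouette raster as its unrotated twin
        mirrored = aligned.points.copy()
        cmin, cmax = mirrored[:, 1].min(), mirrored[:, 1].max()
        mirrored[:, 1] = (cmin + cmax) - mirrored[:, 1]
        widths = _kmm_from_mask(_canonical_mask(mirrored))
    return KmmProfile(widths=widths, tl1=tl1, tl2=tl2, flipped=flipped)


def _boundary_arc_length(points: np.ndarray) -> float:
    """Closed-polyline arc length after suppressing the rasterization staircase.

    The marching-squares boundary zigzags at the half-pixel scale, inflating
    the raw arc length of smooth shapes by ~6% (a digital circle would read a
    circularity of ~0.89 instead of 1).  Simplifying the polyline with a 1-px
    tolerance before measuring removes the staircase while following every
    real feature of the outline.
    """
    from skimage.measure import approximate_polygon

    closed = np.vstack([points, points[:1]])
    simplified = approximate_polygon(closed, tolerance=1.0)
    diffs = np.diff(simplified, axis=0)
    return float(np.sum(np.hypot(diffs[:, 0], diffs[:, 1])))


def compute_sdpsf(contour: PupaContour) -> SdpsfFeatures:
    """Compute the full 37-dimensional SD-PSF vector for a body contour.

    Scalars: perimeter (closed polyline arc length), area (filled-mask pixel
    count), dispersity (coefficient of variation of the centroid-to-boundary
    radii), min/avg/max radius and their min/max ratio, fitted-ellipse major
    and minor axes, aspect ratio and eccentricity, rectangularity (area over
    minimum rotated bounding-rectangle area), circularity (4*pi*A/P^2) and
    compactness (P^2/A); then the 23 canonically oriented KMM chords.
    """
    pts = np.asarray(contour.points, dtype=float)
    perimeter = _boundary_arc_length(pts)
    mask, _ = _rasterize(pts)
    area = float(mask.sum())

    cent = contour.centroid
    radii = np.hypot(pts[:, 0] - cent[0], pts[:, 1] - cent[1])
    min_r, avg_r, max_r = float(radii.min()), float(radii.mean()), float(radii.max())
    dispersity = float(radii.std() / avg_r) if avg_r > 0 else 0.0

    aligned = align_contour(contour)
    aspect = aligned.major_len / aligned.minor_len

    min_rect_area = Polygon(pts).minimum_rotated_rectangle.area
    rectangularity = float(area / min_rect_area) if min_rect_area > 0 else 0.0

    circularity = float(4.0 * np.pi * area / perimeter**2)
    compactness = float(perimeter**2 / area)

    kmm = compute_kmm(aligned)
    return SdpsfFeatures(
        perimeter=float(perimeter),
        area=area,
        dispersity=dispersity,
        min_radius=min_r,
        avg_radius=avg_r,
        max_radius=max_r,
        radius_ratio=min_r / max_r,
        major_axis=aligned.major_len,
        minor_axis=aligned.minor_len,
        aspect_ratio=float(aspect),
        rectangularity=rectangularity,
        circularity=circularity,
        compactness=compactness,
        eccentricity=aligned.eccentricity,
        kmm=kmm.widths,
    )
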