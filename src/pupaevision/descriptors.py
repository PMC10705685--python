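"""Standard texture/shape/color descriptors at fixed output dimensions.

Five descriptors complement the SD-PSF shape vector, each with a frozen
output length: HOG (1296), Hu moments (7), uniform ("equivalent") LBP (59),
GLCM statistics (20) and an HSV color histogram (768).  All are
deterministic; LBP, GLCM and the color histogram are restricted to the pupa
mask so background pixels carry no class signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import color as skcolor
from skimage import feature as skfeature
from skimage import measure as skmeasure
from skimage import transform as sktransform

from .preprocess import CropResult

__all__ = [
    "DescriptorConfig",
    "HOG_DIM",
    "HU_DIM",
    "LBP_DIM",
    "GLCM_DIM",
    "COLOR_DIM",
    "compute_hog",
    "compute_hu",
    "compute_eqlbp",
    "compute_glcm",
    "compute_color_hist",
    "glcm_matrix",
    "glcm_stats",
]

HOG_DIM = 1296
HU_DIM = 7
LBP_DIM = 59
GLCM_DIM = 20
COLOR_DIM = 768

#: GLCM pixel offsets (dr, dc) for the four angles, distance 1.
GLCM_OFFSETS: dict[int, tuple[int, int]] = {
    0: (0, 1),
    45: (-1, 1),
    90: (-1, 0),
    135: (-1, -1),
}


@dataclass(frozen=True)
class DescriptorConfig:
    """Parameterization of the five descriptors.

    Defaults reproduce the frozen output dimensions: a 210x210 HOG input with
    30-px cells and 2x2-cell blocks gives 6*6 blocks * 4 cells * 9 bins
    = 1296; 64 GLCM gray levels at 4 angles * 5 statistics = 20; radius-1
    8-neighbor uniform LBP = 59 bins; 3 HSV channels * 256 bins = 768.
    """

    hog_resize_px: int = 210
    hog_cell_px: int = 30
    hog_cells_per_block: int = 2
    hog_bins: int = 9
    glcm_levels: int = 64
    glcm_angles: tuple[int, ...] = (0, 45, 90, 135)
    glcm_distance: int = 1
    lbp_radius: int = 1
    lbp_neighbors: int = 8
    color_bins: int = 256
    masked: bool = True


DEFAULT_CONFIG = DescriptorConfig()


def _crop_gray(crop: CropResult) -> np.ndarray:
    g = crop.gray
    return np.clip(g, 0, 255)


def compute_hog(crop: CropResult, cfg: DescriptorConfig = DEFAULT_CONFIG) -> np.ndarray:
    """1296-dim histogram of oriented gradients of the grayscale crop.

    The crop is resized to 210x210 so the 30-px cell / 2x2-cell block layout
    yields a 7x7 cell grid, 6x6 overlapping blocks (stride one cell) and
    6*6*2*2*9 = 1296 L2-Hys-normalized features.  Gradients are unsigned.
    """
    gray = _crop_gray(crop) / 255.0
    n = cfg.hog_resize_px
    resized = sktransform.resize(gray, (n, n), anti_aliasing=True)
    vec = skfeature.hog(
        resized,
        orientations=cfg.hog_bins,
        pixels_per_cell=(cfg.hog_cell_px, cfg.hog_cell_px),
        cells_per_block=(cfg.hog_cells_per_block, cfg.hog_cells_per_block),
        block_norm="L2-Hys",
        feature_vector=True,
    )
    return np.asarray(vec, dtype=float)


def compute_hu(mask: np.ndarray) -> np.ndarray:
    """Seven Hu invariant moments of the binary silhouette, signed-log scaled.

    h' = -sign(h) * log10(|h| + eps) compresses the enormous dynamic range
    while keeping the sign (the seventh moment flips sign under mirroring).
    """
    mask = np.asarray(mask)
    if not mask.any():
        raise ValueError("empty mask")
    m = skmeasure.moments_central(mask.astype(float))
    nu = skmeasure.moments_normalized(m)
    hu = skmeasure.moments_hu(nu)
    eps = 1e-30
    return -np.sign(hu) * np.log10(np.abs(hu) + eps)


# ----------------------------------------------------------------------------
# uniform LBP
# ----------------------------------------------------------------------------


def _uniform_lut(p: int = 8) -> np.ndarray:
    """Map 2^p LBP codes to 58 uniform-pattern bins + 1 catch-all (= bin 58)."""
    uniform_codes = []
    for code in range(2**p):
        bits = [(code >> i) & 1 for i in range(p)]
        transitions = sum(bits[i] != bits[(i + 1) % p] for i in range(p))
        if transitions <= 2:
            uniform_codes.append(code)
    lut = np.full(2**p, len(uniform_codes), dtype=int)  # catch-all bin
    for idx, code in enumerate(uniform_codes):
        lut[code] = idx
    return lut


_LBP_LUT = _uniform_lut(8)

#: 3x3 neighbor offsets in circular order (bit i of the LBP code).
LBP_NEIGHBOR_OFFSETS: tuple[tuple[int, int], ...] = (
    (0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1),
)


def lbp_codes(gray: np.ndarray) -> np.ndarray:
    """Classic 3x3-neighborhood LBP code per interior pixel.

    Bit i is set when the i-th circular neighbor is >= the center pixel;
    border pixels (whose neighborhood leaves the image) get code -1.
    """
    g = np.asarray(gray, dtype=float)
    codes = np.zeros(g.shape, dtype=int)
    center = g[1:-1, 1:-1]
    for bit, (dr, dc) in enumerate(LBP_NEIGHBOR_OFFSETS):
        nb = g[1 + dr : g.shape[0] - 1 + dr, 1 + dc : g.shape[1] - 1 + dc]
        codes[1:-1, 1:-1] |= (nb >= center).astype(int) << bit
    codes[0, :] = codes[-1, :] = -1
    codes[:, 0] = codes[:, -1] = -1
    return codes


def compute_eqlbp(crop: CropResult, cfg: DescriptorConfig = DEFAULT_CONFIG) -> np.ndarray:
    """59-bin uniform LBP histogram over the pupa mask, normalized to sum 1.

    Codes are classic 8-neighbor, radius-1 (3x3) local binary patterns; the
    58 patterns with at most two circular 0/1 transitions get their own bins
    and everything else falls into the 59th catch-all bin.
    """
    gray = _crop_gray(crop)
    mask = crop.crop_mask if cfg.masked else np.ones(gray.shape, dtype=bool)
    if mask.sum() < 9:
        raise ValueError("mask smaller than 9 px")
    codes = lbp_codes(gray)
    valid = mask & (codes >= 0)
    hist = np.bincount(_LBP_LUT[codes[valid]], minlength=LBP_DIM).astype(float)
    return hist / hist.sum()


# ----------------------------------------------------------------------------
# GLCM
# ----------------------------------------------------------------------------


def _quantize(gray: np.ndarray, levels: int) -> np.ndarray:
    """Uniformly quantize 0..255 intensities into ``levels`` gray levels."""
    q = (np.clip(gray, 0, 255) * levels / 256.0).astype(int)
    return np.clip(q, 0, levels - 1)


def glcm_matrix(
    quantized: np.ndarray,
    mask: np.ndarray,
    offset: tuple[int, int],
    levels: int,
) -> np.ndarray:
    """Symmetric, normalized co-occurrence matrix restricted to ``mask``.

    Counts ordered pairs (p, p+offset) with both pixels inside the mask, adds
    the transpose, and normalizes to sum 1 (all-zero if no pair exists).
    """
    dr, dc = offset
    h, w = quantized.shape
    r0s, r0e = max(0, -dr), min(h, h - dr)
    c0s, c0e = max(0, -dc), min(w, w - dc)
    a = quantized[r0s:r0e, c0s:c0e]
    b = quantized[r0s + dr : r0e + dr, c0s + dc : c0e + dc]
    m = mask[r0s:r0e, c0s:c0e] & mask[r0s + dr : r0e + dr, c0s + dc : c0e + dc]
    pairs = np.bincount(
        (a[m] * levels + b[m]).ravel(), minlength=levels * levels
    ).reshape(levels, levels)
    glcm = pairs + pairs.T
    total = glcm.sum()
    return glcm / total if total > 0 else glcm.astype(float)


def glcm_stats(p: np.ndarray) -> np.ndarray:
    """[ASM, contrast, entropy, correlation, IDM] of one normalized GLCM."""
    levels = p.shape[0]
    i = np.arange(levels)[:, None]
    j = np.arange(levels)[None, :]
    asm = float(np.sum(p**2))
    contrast = float(np.sum((i - j) ** 2 * p))
    nz = p > 0
    entropy = float(-np.sum(p[nz] * np.log2(p[nz])))
    mu_i = float(np.sum(i * p))
    mu_j = float(np.sum(j * p))
    var_i = float(np.sum((i - mu_i) ** 2 * p))
    var_j = float(np.sum((j - mu_j) ** 2 * p))
    if var_i <= 1e-12 or var_j <= 1e-12:
        correlation = 0.0  # single gray level: correlation undefined -> 0
    else:
        correlation = float(
            (np.sum(i * j * p) - mu_i * mu_j) / np.sqrt(var_i * var_j)
        )
    idm = float(np.sum(p / (1.0 + (i - j) ** 2)))
    return np.array([asm, contrast, entropy, correlation, idm])


def compute_glcm(crop: CropResult, cfg: DescriptorConfig = DEFAULT_CONFIG) -> np.ndarray:
    """20 GLCM texture statistics: 4 angles x [ASM, contrast, entropy,
    correlation, IDM], angle-major order, after 64-level quantization."""
    gray = _crop_gray(crop)
    mask = crop.crop_mask if cfg.masked else np.ones(gray.shape, dtype=bool)
    q = _quantize(gray, cfg.glcm_levels)
    feats = []
    for angle in cfg.glcm_angles:
        dr, dc = GLCM_OFFSETS[angle]
        offset = (dr * cfg.glcm_distance, dc * cfg.glcm_distance)
        p = glcm_matrix(q, mask, offset, cfg.glcm_levels)
        feats.append(glcm_stats(p))
    return np.concatenate(feats)


def compute_color_hist(
    crop: CropResult, cfg: DescriptorConfig = DEFAULT_CONFIG
) -> np.ndarray:
    """768-dim HSV histogram: 256 bins per channel over the pupa mask,
    each channel normalized to sum 1, concatenated H || S || V."""
    mask = crop.crop_mask if cfg.masked else np.ones(crop.crop_mask.shape, bool)
    if not mask.any():
        raise ValueError("empty mask")
    hsv = skcolor.rgb2hsv(np.clip(crop.crop_rgb, 0, 255).astype(np.uint8))
    out = []
    for ch in range(3):
        vals = hsv[..., ch][mask]
        hist, _ = np.histogram(vals, bins=cfg.color_bins, range=(0.0, 1.0))
        out.append(hist / hist.sum())
    return np.concatenate(out)
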