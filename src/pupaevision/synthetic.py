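"""Synthetic pupa-image generator.

Renders single-pupa images that emulate the structure of a real silkworm-pupa
photo set: five species differing in body length, elongation, coloration and
cuticle texture; two sexes differing in posterior (tail) taper, overall size
and weight; three imaging postures (back, abdomen, side) of the same physical
pupa; a light background; and optional dark molt-debris fragments for
segmentation stress-tests.

The body is an elongated super-ellipse with a longitudinal taper so the head
end is blunt and the tail end narrows — the asymmetry the head/tail
orientation logic of the shape descriptor needs.  Every image carries its
ground-truth contour so segmentation and shape features can be tested against
an exact oracle.

All randomness is driven by explicit integer seeds; identical seeds yield
bit-identical images.
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from skimage import measure
from skimage.draw import ellipse as draw_ellipse

from .preprocess import PupaContour

__all__ = [
    "SpeciesProfile",
    "SexEffect",
    "PupaImage",
    "SEXES",
    "POSTURES",
    "DEFAULT_SEX_EFFECT",
    "default_profiles",
    "well_separated_profiles",
    "identical_profiles",
    "generate_pupa",
    "add_debris",
    "generate_dataset",
    "write_dataset",
    "manifest_from_images",
]

SEXES = ("female", "male")
POSTURES = ("back", "abdomen", "side")

_CANVAS = 480  # default canvas side; 320-crop never clips a default body
_BG_LEVEL = 235
_SUPERELLIPSE_N = 2.5
_BASE_TAIL_TAPER = 0.18


@dataclass(frozen=True)
class SpeciesProfile:
    """Morphometric and color parameters of one species.

    ``body_length_px`` / ``aspect_ratio`` are (mean, sd) pairs; ``aspect_ratio``
    is major/minor of the body silhouette.  ``base_color_hsv`` is in [0, 1]^3.
    ``texture_grain`` scales the cuticle noise amplitude (gray levels).
    """

    name: str
    body_length_px: tuple[float, float]
    aspect_ratio: tuple[float, float]
    base_color_hsv: tuple[float, float, float]
    texture_grain: float = 6.0

    def __post_init__(self) -> None:
        if self.body_length_px[0] <= 0:
            raise ValueError("body length mean must be > 0")
        if self.aspect_ratio[0] <= 1:
            raise ValueError("aspect ratio mean must be > 1")
        if self.body_length_px[1] < 0 or self.aspect_ratio[1] < 0:
            raise ValueError("sd values must be >= 0")
        if self.texture_grain < 0:
            raise ValueError("texture_grain must be >= 0")


@dataclass(frozen=True)
class SexEffect:
    """Deterministic male-vs-female morphology and weight offsets.

    ``tail_taper_delta`` adds to the posterior taper of males (narrower tail);
    ``size_delta`` is a multiplicative body-scale offset for males (negative =
    smaller); ``weight_shift`` is added to male weights (grams, negative =
    lighter); ``value_shift`` darkens the male cuticle slightly (HSV value),
    mirroring the fact that appearance-based color features separate the
    sexes well on real pupae.
    """

    tail_taper_delta: float = 0.14
    size_delta: float = -0.05
    weight_shift: float = -0.18
    value_shift: float = -0.035

    @classmethod
    def none(cls) -> "SexEffect":
        """No sexual dimorphism at all (null-model datasets)."""
        return cls(0.0, 0.0, 0.0, 0.0)


DEFAULT_SEX_EFFECT = SexEffect()


@dataclass
class PupaImage:
    """One rendered pupa image with its labels and ground truth."""

    pixels: np.ndarray
    species: str
    sex: str
    posture: str
    pupa_id: str
    weight: float
    truth_contour: PupaContour


def default_profiles() -> list[SpeciesProfile]:
    """Five species profiles with realistic, partially overlapping variation."""
    return [
        SpeciesProfile("sp7532", (285.0, 8.0), (2.00, 0.08), (0.080, 0.55, 0.46), 6.0),
        SpeciesProfile("sp871", (255.0, 8.0), (2.30, 0.08), (0.105, 0.50, 0.52), 9.0),
        SpeciesProfile("sp872", (300.0, 6.0), (1.85, 0.08), (0.060, 0.62, 0.40), 4.0),
        SpeciesProfile("furong", (240.0, 8.0), (2.55, 0.08), (0.125, 0.44, 0.56), 12.0),
        SpeciesProfile("haoyue", (270.0, 8.0), (2.15, 0.08), (0.092, 0.38, 0.34), 7.0),
    ]


def well_separated_profiles() -> list[SpeciesProfile]:
    """Near-zero within-class spread and large between-class deltas."""
    return [
        SpeciesProfile("sp7532", (285.0, 1.0), (2.00, 0.01), (0.080, 0.55, 0.46), 5.0),
        SpeciesProfile("sp871", (250.0, 1.0), (2.40, 0.01), (0.110, 0.50, 0.55), 10.0),
        SpeciesProfile("sp872", (305.0, 1.0), (1.80, 0.01), (0.055, 0.65, 0.38), 3.0),
        SpeciesProfile("furong", (230.0, 1.0), (2.70, 0.01), (0.135, 0.42, 0.60), 14.0),
        SpeciesProfile("haoyue", (290.0, 1.0), (2.20, 0.01), (0.095, 0.35, 0.30), 7.0),
    ]


def identical_profiles() -> list[SpeciesProfile]:
    """Five identically distributed 'species' — the null for chance-level tests."""
    base = dict(
        body_length_px=(270.0, 12.0),
        aspect_ratio=(2.1, 0.1),
        base_color_hsv=(0.09, 0.5, 0.45),
        texture_grain=7.0,
    )
    return [SpeciesProfile(name=f"null{i}", **base) for i in range(5)]


# ----------------------------------------------------------------------------
# body geometry
# ----------------------------------------------------------------------------


def _taper_profile(t: np.ndarray, tau: float) -> np.ndarray:
    """Longitudinal half-width multiplier: 1 at the head (t=-1), 1-tau at the tail."""
    return 1.0 - tau * ((t + 1.0) / 2.0) ** 2


def _half_width_unit(t: np.ndarray, tau: float) -> np.ndarray:
    """Half-width profile for unit semi-minor axis on t in [-1, 1]."""
    t = np.clip(t, -1.0, 1.0)
    cross = (1.0 - np.abs(t) ** _SUPERELLIPSE_N) ** (1.0 / _SUPERELLIPSE_N)
    return _taper_profile(t, tau) * cross


def _moment_aspect(tau: float) -> float:
    """Moment-fitted major/minor ratio of the unit body (a=1, b=1).

    For a region with half-width h(x), pixel weights are proportional to h,
    the minor variance is E[h^2]/3 and the major variance is Var(x); the
    fitted axis ratio is sigma_x / sigma_y.
    """
    t = np.linspace(-1.0, 1.0, 4001)
    h = _half_width_unit(t, tau)
    w = np.trapezoid(h, t)
    mx = np.trapezoid(t * h, t) / w
    sx2 = np.trapezoid((t - mx) ** 2 * h, t) / w
    sy2 = np.trapezoid(h**3, t) / (3.0 * w)
    return float(np.sqrt(sx2 / sy2))


def _render_body(
    canvas: np.ndarray,
    center: tuple[float, float],
    a: float,
    b: float,
    tau: float,
    angle: float,
    posture: str,
    color_hsv: tuple[float, float, float],
    grain: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Rasterize the body into ``canvas`` in place; return the body mask."""
    h, w = canvas.shape[:2]
    cr, cc = center
    # bounding box of the rotated body, with margin
    bmax = b * 1.4
    corners = np.array(
        [[sx * a, sy * bmax] for sx in (-1, 1) for sy in (-1, 1)], dtype=float
    )
    cos_t, sin_t = np.cos(angle), np.sin(angle)
    rot = np.array([[cos_t, -sin_t], [sin_t, cos_t]])
    rc = corners @ rot.T
    r0 = max(int(np.floor(cr + rc[:, 1].min())) - 2, 0)
    r1 = min(int(np.ceil(cr + rc[:, 1].max())) + 3, h)
    c0 = max(int(np.floor(cc + rc[:, 0].min())) - 2, 0)
    c1 = min(int(np.ceil(cc + rc[:, 0].max())) + 3, w)

    rr, cc_idx = np.mgrid[r0:r1, c0:c1]
    dx = cc_idx - cc
    dy = rr - cr
    # body frame: x along the major axis (head at -a), y across
    x = dx * cos_t + dy * sin_t
    y = -dx * sin_t + dy * cos_t
    t = x / a
    inside_x = np.abs(t) <= 1.0
    hw = np.zeros_like(t)
    hw[inside_x] = b * _half_width_unit(t[inside_x], tau)

    upper = hw.copy()  # extent toward negative y (dorsal)
    lower = hw.copy()
    if posture == "side":
        # dorsal bulge: asymmetric bump over the anterior-middle back
        bump = 0.22 * np.exp(-(((t + 0.25) / 0.35) ** 2))
        upper *= 1.0 + bump
        lower *= 0.92
    elif posture == "abdomen":
        # segmented ventral side reads slightly flatter and wider
        lower *= 1.0 + 0.08 * np.exp(-((t / 0.6) ** 2))

    mask_local = inside_x & (y >= -upper) & (y <= lower) & (hw > 0)

    # coloring: cylindrical shading + cuticle grain + faint segment banding
    base_rgb = np.array(colorsys.hsv_to_rgb(*color_hsv)) * 255.0
    depth = np.zeros_like(t)
    span = np.where(y < 0, upper, lower)
    nz = mask_local & (span > 0)
    depth[nz] = 1.0 - (np.abs(y[nz]) / span[nz]) ** 2
    shade = 0.72 + 0.28 * np.sqrt(np.clip(depth, 0.0, 1.0))
    band = 1.0 + 0.05 * np.sin(t * np.pi * 7.0)
    noise = rng.normal(0.0, 1.0, size=t.shape) * grain
    body = (
        base_rgb[None, None, :] * (shade * band)[..., None]
        + noise[..., None]
    )
    region = canvas[r0:r1, c0:c1]
    region[mask_local] = np.clip(body[mask_local], 0, 200).astype(np.uint8)

    mask = np.zeros((h, w), dtype=bool)
    mask[r0:r1, c0:c1] = mask_local
    return mask


def _mask_contour(mask: np.ndarray) -> PupaContour:
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        raise RuntimeError("generated body produced no contour")
    return PupaContour(max(contours, key=len))


def _pupa_latents(
    profile: SpeciesProfile,
    sex: str,
    seed: int,
    sex_effect: SexEffect,
) -> dict:
    """Per-pupa draws shared across the three postures (posture-independent)."""
    rng = np.random.default_rng(seed)
    length = max(rng.normal(*profile.body_length_px), 40.0)
    aspect = max(rng.normal(*profile.aspect_ratio), 1.05)
    hue_jit = rng.normal(0.0, 0.004)
    sat_jit = rng.normal(0.0, 0.015)
    val_jit = rng.normal(0.0, 0.015)
    angle = rng.uniform(-np.pi / 2, np.pi / 2)
    center_jit = rng.normal(0.0, 6.0, size=2)
    weight_noise = rng.normal(0.0, 0.06)
    if sex == "male":
        length *= 1.0 + sex_effect.size_delta
        val_jit += sex_effect.value_shift
    tau = _BASE_TAIL_TAPER + (sex_effect.tail_taper_delta if sex == "male" else 0.0)
    # weight ~ lognormal around a length-cubed scale, plus the additive sex shift
    base_w = 1.25 * (length / 300.0) ** 3
    weight = float(np.exp(np.log(base_w) + weight_noise))
    if sex == "male":
        weight += sex_effect.weight_shift
    weight = max(weight, 0.05)
    return dict(
        length=length,
        aspect=aspect,
        hsv=(
            float(np.clip(profile.base_color_hsv[0] + hue_jit, 0, 1)),
            float(np.clip(profile.base_color_hsv[1] + sat_jit, 0, 1)),
            float(np.clip(profile.base_color_hsv[2] + val_jit, 0.05, 0.75)),
        ),
        angle=float(angle),
        center_jit=center_jit,
        tau=float(tau),
        weight=weight,
    )


def generate_pupa(
    species_profile: SpeciesProfile,
    sex: str,
    posture: str,
    seed: int,
    sex_effect: SexEffect = DEFAULT_SEX_EFFECT,
    canvas_size: int = _CANVAS,
    pupa_id: str | None = None,
) -> PupaImage:
    """Render one pupa image.

    The per-pupa morphology (size, elongation, color, pose angle, weight) is a
    deterministic function of ``(species_profile, sex, seed)``; ``posture``
    modulates the silhouette (dorsal-bulge asymmetry, width) and the pixel
    noise only, so the three postures of one seed depict the same pupa.
    """
    if sex not in SEXES:
        raise ValueError(f"sex must be one of {SEXES}, got {sex!r}")
    if posture not in POSTURES:
        raise ValueError(f"posture must be one of {POSTURES}, got {posture!r}")

    lat = _pupa_latents(species_profile, sex, seed, sex_effect)
    a = lat["length"] / 2.0
    # For half-width b*h_unit(t) the moment-fitted major/minor ratio is
    # (a/b) * M(tau) with M from _moment_aspect, so b = a*M(tau)/aspect makes
    # the fitted ratio equal the drawn aspect exactly (back posture).
    b = a * _moment_aspect(lat["tau"]) / lat["aspect"]
    width_scale = {"back": 1.0, "abdomen": 1.0, "side": 0.88}[posture]
    b *= width_scale

    side = canvas_size
    if side < 2 * a + 40:
        side = int(np.ceil(2 * a + 40))
    canvas = np.empty((side, side, 3), dtype=np.uint8)

    # posture-specific pixel noise stream, independent of the pupa latents
    posture_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(POSTURES.index(posture),))
    )
    # light background with coarse low-amplitude mottle
    q = side // 4 + 1
    mottle = posture_rng.normal(0.0, 2.0, size=(q, q))
    mottle = np.repeat(np.repeat(mottle, 4, axis=0), 4, axis=1)[:side, :side]
    bg = np.clip(_BG_LEVEL + mottle, 220, 250).astype(np.uint8)
    canvas[...] = bg[..., None]

    center = (
        side / 2.0 + lat["center_jit"][0],
        side / 2.0 + lat["center_jit"][1],
    )
    mask = _render_body(
        canvas,
        center,
        a,
        b,
        lat["tau"],
        lat["angle"],
        posture,
        lat["hsv"],
        species_profile.texture_grain,
        posture_rng,
    )
    contour = _mask_contour(mask)
    if pupa_id is None:
        pupa_id = f"{species_profile.name}_{sex}_{seed:010d}"
    return PupaImage(
        pixels=canvas,
        species=species_profile.name,
        sex=sex,
        posture=posture,
        pupa_id=pupa_id,
        weight=lat["weight"],
        truth_contour=contour,
    )


# ----------------------------------------------------------------------------
# debris
# ----------------------------------------------------------------------------


def add_debris(
    image: PupaImage,
    n_fragments: int,
    max_area_frac: float = 0.005,
    seed: int = 0,
    max_tries: int = 200,
) -> PupaImage:
    """Scatter dark molt-debris fragments that never touch the body.

    Each fragment is a small dark ellipse of pixel area below
    ``max_area_frac * H * W``; placement avoids a 5-px safety margin around the
    body so the ground-truth contour is untouched.  Returns a new PupaImage;
    ``n_fragments=0`` returns the input unchanged.
    """
    if n_fragments == 0:
        return image
    from scipy import ndimage as ndi

    h, w = image.pixels.shape[:2]
    body = image.truth_contour.filled_mask((h, w))
    forbidden = ndi.binary_dilation(body, iterations=5)
    rng = np.random.default_rng(seed)
    pixels = image.pixels.copy()

    max_area = max_area_frac * h * w
    for _ in range(n_fragments):
        for attempt in range(max_tries):
            area = rng.uniform(0.25, 0.85) * max_area
            ar = rng.uniform(1.2, 3.0)
            # ellipse area = pi * ra * rc -> pick radii below the cap
            rb = np.sqrt(area / (np.pi * ar))
            ra_, rc_ = rb * ar, rb
            ang = rng.uniform(0, np.pi)
            r = rng.uniform(ra_ + 2, h - ra_ - 2)
            c = rng.uniform(ra_ + 2, w - ra_ - 2)
            rr, cc = draw_ellipse(r, c, ra_, rc_, shape=(h, w), rotation=ang)
            if rr.size == 0 or rr.size >= max_area:
                continue
            if forbidden[rr, cc].any():
                continue
            shade = rng.uniform(40, 90)
            frag = shade + rng.normal(0, 8, size=(rr.size, 3))
            pixels[rr, cc] = np.clip(frag, 0, 255).astype(np.uint8)
            break
        else:
            raise RuntimeError(
                f"could not place debris fragment without body overlap "
                f"after {max_tries} tries"
            )
    return PupaImage(
        pixels=pixels,
        species=image.species,
        sex=image.sex,
        posture=image.posture,
        pupa_id=image.pupa_id,
        weight=image.weight,
        truth_contour=image.truth_contour,
    )


# ----------------------------------------------------------------------------
# dataset assembly
# ----------------------------------------------------------------------------


def _pupa_seed(root_seed: int, species_idx: int, sex_idx: int, pupa_idx: int) -> int:
    ss = np.random.SeedSequence(
        entropy=root_seed, spawn_key=(species_idx, sex_idx, pupa_idx)
    )
    return int(ss.generate_state(1)[0] % (2**31))


def generate_dataset(
    profiles: Sequence[SpeciesProfile],
    pupae_per_class: int,
    seed: int,
    sex_effect: SexEffect = DEFAULT_SEX_EFFECT,
    canvas_size: int = _CANVAS,
) -> Iterator[PupaImage]:
    """Yield a full labeled image set, lazily.

    Every (species, sex) class contributes ``pupae_per_class`` physical pupae,
    each imaged in the three postures, so the total is
    ``len(profiles) * 2 * pupae_per_class * 3`` images.  With five profiles and
    120 pupae per class this reproduces the 3600-image / 10-class / 360-per-
    class structure of the study design.
    """
    if len(profiles) < 5:
        raise ValueError(f"need at least 5 species profiles, got {len(profiles)}")
    if pupae_per_class <= 0:
        raise ValueError("pupae_per_class must be > 0")
    for si, profile in enumerate(profiles):
        for xi, sex in enumerate(SEXES):
            for pi in range(pupae_per_class):
                pupa_seed = _pupa_seed(seed, si, xi, pi)
                pupa_id = f"{profile.name}_{sex}_{pi:04d}"
                for posture in POSTURES:
                    yield generate_pupa(
                        profile,
                        sex,
                        posture,
                        pupa_seed,
                        sex_effect=sex_effect,
                        canvas_size=canvas_size,
                        pupa_id=pupa_id,
                    )


def manifest_from_images(images: Iterable[PupaImage]) -> pd.DataFrame:
    """Label/weight table (one row per image) for splitting and bookkeeping."""
    rows = [
        dict(
            pupa_id=im.pupa_id,
            species=im.species,
            sex=im.sex,
            posture=im.posture,
            weight=im.weight,
        )
        for im in images
    ]
    return pd.DataFrame(rows)


def write_dataset(
    root: str | Path,
    profiles: Sequence[SpeciesProfile],
    pupae_per_class: int,
    seed: int,
    sex_effect: SexEffect = DEFAULT_SEX_EFFECT,
) -> pd.DataFrame:
    """Write PNGs as ``<root>/<species>_<sex>/<pupa_id>_<posture>.png`` + manifest CSV."""
    import imageio.v3 as iio

    root = Path(root)
    rows = []
    for im in generate_dataset(profiles, pupae_per_class, seed, sex_effect):
        class_dir = root / f"{im.species}_{im.sex}"
        class_dir.mkdir(parents=True, exist_ok=True)
        path = class_dir / f"{im.pupa_id}_{im.posture}.png"
        iio.imwrite(path, im.pixels)
        rows.append(
            dict(
                pupa_id=im.pupa_id,
                species=im.species,
                sex=im.sex,
                posture=im.posture,
                weight=im.weight,
                path=str(path.relative_to(root)),
            )
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(root / "manifest.csv", index=False)
    return manifest
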