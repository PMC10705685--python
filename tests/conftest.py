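"""Shared fixtures: analytic shapes and (expensive) pipeline runs."""

from __future__ import annotations

import numpy as np
import pytest
from skimage.measure import find_contours

from pupaevision.modeling import ClassifierSpec
from pupaevision.pipeline import extract_descriptor_features, run_experiment
from pupaevision.preprocess import PupaContour, crop_centered, segment_pupa
from pupaevision.synthetic import (
    SexEffect,
    default_profiles,
    generate_dataset,
    generate_pupa,
    identical_profiles,
    well_separated_profiles,
)


def raster_shape_contour(inside_fn, size: int) -> PupaContour:
    """Boundary of an implicit region rasterized on a size x size grid."""
    rr, cc = np.mgrid[0:size, 0:size]
    mask = inside_fn(rr.astype(float), cc.astype(float))
    return PupaContour(max(find_contours(mask.astype(float), 0.5), key=len))


def ellipse_contour(a: float, b: float, angle: float = 0.0, size: int = 400) -> PupaContour:
    """Marching-squares contour of a rasterized rotated ellipse."""

    def inside(rr, cc):
        dr, dc = rr - size / 2, cc - size / 2
        x = dc * np.cos(angle) + dr * np.sin(angle)
        y = -dc * np.sin(angle) + dr * np.cos(angle)
        return (x / a) ** 2 + (y / b) ** 2 <= 1

    return raster_shape_contour(inside, size)


@pytest.fixture(scope="session")
def pupa_image():
    return generate_pupa(default_profiles()[0], "female", "back", seed=1)


@pytest.fixture(scope="session")
def pupa_crop(pupa_image):
    contour = segment_pupa(pupa_image.pixels)
    return crop_centered(pupa_image.pixels, contour)


@pytest.fixture(scope="session")
def separable_experiment():
    """{SD-PSF + color histogram + SVM} on a well-separated 10-class set."""
    images = generate_dataset(well_separated_profiles(), 20, seed=1)
    manifest, feats = extract_descriptor_features(images, ("sdpsf", "color_hist"))
    return run_experiment(
        manifest, feats, task="species_sex",
        classifier=ClassifierSpec("SVM"), seed=1,
    )


@pytest.fixture(scope="session")
def null_experiment():
    """Same pipeline on identically distributed classes (chance level)."""
    images = generate_dataset(
        identical_profiles(), 20, seed=2, sex_effect=SexEffect.none()
    )
    manifest, feats = extract_descriptor_features(images, ("sdpsf", "color_hist"))
    return run_experiment(
        manifest, feats, task="species_sex",
        classifier=ClassifierSpec("SVM"), seed=2,
    )
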