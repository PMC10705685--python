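"""End-to-end glue: images -> features -> split/fuse/train -> evaluation."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from . import descriptors as D
from .deep import TinyTestBackbone, extract_features
from .evaluation import ClassCurve, EvalReport, compute_metrics, pr_roc_curves
from .modeling import (
    ClassifierSpec,
    FeatureFusion,
    FusionSpec,
    SplitSpec,
    TrainedModel,
    grid_search_train,
    make_labels,
    predict,
    split_dataset,
)
from .preprocess import CropResult, crop_centered, segment_pupa
from .sdpsf import compute_sdpsf
from .synthetic import PupaImage

__all__ = [
    "DESCRIPTOR_REGISTRY",
    "ExperimentResult",
    "extract_descriptor_features",
    "run_experiment",
]


def _sdpsf_vec(crop: CropResult) -> np.ndarray:
    return compute_sdpsf(crop.contour).to_vector()


DESCRIPTOR_REGISTRY: dict[str, Callable[[CropResult], np.ndarray]] = {
    "sdpsf": _sdpsf_vec,
    "hog": D.compute_hog,
    "hu": lambda crop: D.compute_hu(crop.crop_mask),
    "eqlbp": D.compute_eqlbp,
    "glcm": D.compute_glcm,
    "color_hist": D.compute_color_hist,
    "deep_tiny": lambda crop: extract_features(TinyTestBackbone(0), crop),
}


def extract_descriptor_features(
    images: Iterable[PupaImage],
    descriptors: Sequence[str] = ("sdpsf", "color_hist"),
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Segment, crop and featurize a stream of images.

    Returns the label manifest (one row per image, in stream order) and a
    dict of feature matrices, one ``(n_images, dim)`` array per descriptor.
    """
    unknown = set(descriptors) - set(DESCRIPTOR_REGISTRY)
    if unknown:
        raise KeyError(f"unknown descriptors {sorted(unknown)}")
    rows = []
    feats: dict[str, list[np.ndarray]] = {name: [] for name in descriptors}
    for im in images:
        contour = segment_pupa(im.pixels)
        crop = crop_centered(im.pixels, contour)
        for name in descriptors:
            feats[name].append(DESCRIPTOR_REGISTRY[name](crop))
        rows.append(
            dict(pupa_id=im.pupa_id, species=im.species, sex=im.sex,
                 posture=im.posture, weight=im.weight)
        )
    manifest = pd.DataFrame(rows)
    return manifest, {name: np.stack(v) for name, v in feats.items()}


@dataclass
class ExperimentResult:
    task: str
    classes: list[str]
    model: TrainedModel
    report: EvalReport
    curves: list[ClassCurve]
    test_accuracy: float
    manifest: pd.DataFrame  # with the split column


def run_experiment(
    manifest: pd.DataFrame,
    features: dict[str, np.ndarray],
    task: str = "species_sex",
    members: Sequence[str] | None = None,
    classifier: ClassifierSpec = ClassifierSpec("SVM"),
    split: SplitSpec = SplitSpec("8:2"),
    seed: int = 0,
) -> ExperimentResult:
    """Split by weight, fuse descriptors (train-fitted), train and evaluate.

    The fusion reducer and scalers are fitted on the training rows only and
    applied unchanged to the test rows.
    """
    members = tuple(members or features.keys())
    with_split = split_dataset(manifest, split, seed=seed)
    y, classes = make_labels(with_split, task)
    is_train = (with_split["split"] == "train").to_numpy()
    is_test = (with_split["split"] == "test").to_numpy()

    fusion = FeatureFusion(FusionSpec(members)).fit(
        {m: features[m][is_train] for m in members}
    )
    x_train = fusion.transform({m: features[m][is_train] for m in members})
    x_test = fusion.transform({m: features[m][is_test] for m in members})

    model = grid_search_train(x_train, y[is_train], classifier)
    y_pred, scores = predict(model, x_test)
    report = compute_metrics(y[is_test], y_pred, n_classes=len(classes))
    curves = pr_roc_curves(y[is_test], scores, n_classes=len(classes))
    report.curves = curves
    return ExperimentResult(
        task=task,
        classes=classes,
        model=model,
        report=report,
        curves=curves,
        test_accuracy=report.plain_accuracy,
        manifest=with_split,
    )
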