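"""Dataset partitioning, descriptor fusion and grid-searched classifiers.

Partitioning is weight-stratified systematic sampling: within each class the
physical pupae are ordered by weight and every 5th (8:2) or every 10th
(8:1:1, one for calibration and one for testing) is held out, so the weight
distributions of the splits match.  All three posture images of a pupa stay
in one split (grouped assignment — no identity leakage).

Fusion compresses every descriptor with more than 500 dimensions to exactly
500 with a variance-maximizing linear projection (PCA) fitted on the training
split only, after per-descriptor z-scoring, then concatenates in a fixed
member order.

Three classifier families are supported with their fixed settings and
hyperparameter grids (MLP with ReLU/L-BFGS, RBF-kernel SVM one-vs-rest,
Gini random forest; random_state 9 everywhere); grids are searched
exhaustively by accuracy in stratified five-fold cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "SplitSpec",
    "FusionSpec",
    "ClassifierSpec",
    "FeatureFusion",
    "TrainedModel",
    "TASKS",
    "RANDOM_STATE",
    "FUSION_TARGET_DIM",
    "split_dataset",
    "make_labels",
    "fuse",
    "grid_search_train",
    "predict",
]

RANDOM_STATE = 9
FUSION_TARGET_DIM = 500
TASKS = ("species", "sex", "species_sex")


# ----------------------------------------------------------------------------
# weight-stratified grouped splitting
# ----------------------------------------------------------------------------


@dataclass(frozen=True)
class SplitSpec:
    """Train/test (8:2) or train/calibration/test (8:1:1) partitioning."""

    ratios: str = "8:2"

    def __post_init__(self) -> None:
        if self.ratios not in ("8:2", "8:1:1"):
            raise ValueError("ratios must be '8:2' or '8:1:1'")


def split_dataset(
    manifest: pd.DataFrame,
    spec: SplitSpec = SplitSpec(),
    seed: int = 0,
) -> pd.DataFrame:
    """Assign every image row to a split, grouped by pupa and class.

    ``manifest`` needs columns pupa_id, species, sex, weight.  Within each
    (species, sex) class the pupae are sorted by weight (pupa_id breaks ties)
    and assigned systematically: for 8:2 every 5th pupa (offset 2) goes to
    test; for 8:1:1 every 10th goes to calibration (offset 2) and every 10th
    to test (offset 7).  Returns a copy of the manifest with a ``split``
    column; all postures of one pupa share the split.
    """
    required = {"pupa_id", "species", "sex", "weight"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest lacks columns {sorted(missing)}")
    del seed  # systematic assignment is deterministic; kept for API symmetry

    assignment: dict[str, str] = {}
    for _, group in manifest.groupby(["species", "sex"], sort=False):
        pupae = (
            group.drop_duplicates("pupa_id")
            .sort_values(["weight", "pupa_id"])
            .reset_index(drop=True)
        )
        n = len(pupae)
        if n < 5:
            raise ValueError(
                f"class {group.name if hasattr(group, 'name') else ''} has {n} pupae; "
                "need at least 5 for weight-stratified splitting"
            )
        for i, pid in enumerate(pupae["pupa_id"]):
            if spec.ratios == "8:2":
                assignment[pid] = "test" if i % 5 == 2 else "train"
            else:
                if i % 10 == 2:
                    assignment[pid] = "calibration"
                elif i % 10 == 7:
                    assignment[pid] = "test"
                else:
                    assignment[pid] = "train"
    out = manifest.copy()
    out["split"] = out["pupa_id"].map(assignment)
    return out


def make_labels(manifest: pd.DataFrame, task: str) -> tuple[np.ndarray, list[str]]:
    """Integer class codes and class names for one of the three tasks."""
    if task not in TASKS:
        raise ValueError(f"task must be one of {TASKS}")
    if task == "species":
        raw = manifest["species"]
    elif task == "sex":
        raw = manifest["sex"]
    else:
        raw = manifest["species"] + "_" + manifest["sex"]
    classes = sorted(raw.unique())
    lookup = {c: i for i, c in enumerate(classes)}
    return raw.map(lookup).to_numpy(), classes


# ----------------------------------------------------------------------------
# fusion
# ----------------------------------------------------------------------------


@dataclass(frozen=True)
class FusionSpec:
    """Ordered descriptor members and the compression target."""

    members: tuple[str, ...]
    target_dim: int = FUSION_TARGET_DIM


class FeatureFusion:
    """Train-fitted z-score + PCA-to-500 compression, then concatenation.

    Descriptors at or below ``target_dim`` dimensions pass through (after
    z-scoring); larger ones are projected onto the leading ``target_dim``
    principal axes of the training split.  When the training split has fewer
    rows than ``target_dim`` the remaining axes carry no variance and are
    completed with zero columns, keeping the output dimension exact.
    """

    def __init__(self, spec: FusionSpec) -> None:
        self.spec = spec
        self._scalers: dict[str, StandardScaler] = {}
        self._pcas: dict[str, PCA | None] = {}
        self._fitted = False

    def _check_members(self, features: dict[str, np.ndarray]) -> None:
        for name in self.spec.members:
            if name not in features:
                raise KeyError(f"descriptor {name!r} missing from feature dict")
            if np.isnan(features[name]).any():
                row = int(np.flatnonzero(np.isnan(features[name]).any(axis=1))[0])
                raise ValueError(f"sample {row} has no {name!r} features")

    def fit(self, train_features: dict[str, np.ndarray]) -> "FeatureFusion":
        self._check_members(train_features)
        for name in self.spec.members:
            x = np.asarray(train_features[name], dtype=float)
            scaler = StandardScaler().fit(x)
            self._scalers[name] = scaler
            if x.shape[1] > self.spec.target_dim:
                k = min(self.spec.target_dim, x.shape[0], x.shape[1])
                self._pcas[name] = PCA(n_components=k, random_state=0).fit(
                    scaler.transform(x)
                )
            else:
                self._pcas[name] = None
        self._fitted = True
        return self

    def member_dim(self, name: str) -> int:
        pca = self._pcas[name]
        if pca is None:
            return self._scalers[name].mean_.shape[0]
        return self.spec.target_dim

    def projection_matrix(self, name: str) -> np.ndarray | None:
        """The fitted (d, target_dim) projection of a compressed member."""
        pca = self._pcas[name]
        if pca is None:
            return None
        comp = pca.components_.T  # (d, k)
        if comp.shape[1] < self.spec.target_dim:
            pad = np.zeros((comp.shape[0], self.spec.target_dim - comp.shape[1]))
            comp = np.hstack([comp, pad])
        return comp

    def transform(self, features: dict[str, np.ndarray]) -> np.ndarray:
        if not self._fitted:
            raise RuntimeError("fit the fusion on the training split first")
        self._check_members(features)
        blocks = []
        for name in self.spec.members:
            x = self._scalers[name].transform(np.asarray(features[name], float))
            pca = self._pcas[name]
            if pca is not None:
                z = pca.transform(x)
                if z.shape[1] < self.spec.target_dim:
                    z = np.hstack(
                        [z, np.zeros((z.shape[0], self.spec.target_dim - z.shape[1]))]
                    )
                x = z
            blocks.append(x)
        return np.hstack(blocks)


def fuse(
    features_by_descriptor: dict[str, np.ndarray],
    spec: FusionSpec,
    fitted_on: dict[str, np.ndarray] | FeatureFusion,
) -> np.ndarray:
    """Compress-and-concatenate features with a train-fitted reducer.

    ``fitted_on`` is either the training feature dict (the reducer is fitted
    on it) or an already fitted :class:`FeatureFusion` (applied with no refit).
    """
    if isinstance(fitted_on, FeatureFusion):
        fusion = fitted_on
    else:
        fusion = FeatureFusion(spec).fit(fitted_on)
    return fusion.transform(features_by_descriptor)


# ----------------------------------------------------------------------------
# classifiers
# ----------------------------------------------------------------------------

_MLP_HIDDEN = [25, 50, 75, 100, 125, 150, (25, 25), (50, 50), (75, 75), (100, 100)]
_MLP_ALPHA = [1e-1, 1e-2, 1e-3, 1e-4, 1e-5, 1e-6]
_SVM_C = [2.0**k for k in range(-5, 6)]
_SVM_GAMMA = [2.0**k for k in range(-15, 6, 2)]
_RF_TREES = list(range(200, 801, 10))


@dataclass(frozen=True)
class ClassifierSpec:
    """One of the three classifier families, grid-searched or fixed.

    ``mode='grid'`` uses the hyperparameter grids of the traditional-feature
    protocol; ``mode='fixed'`` uses the settings of the deep-feature protocol
    (MLP hidden 120 / alpha 1e-5, linear SVM C=1, RF with 500 trees).
    """

    kind: str
    mode: str = "grid"

    def __post_init__(self) -> None:
        if self.kind not in ("MLP", "SVM", "RF"):
            raise ValueError("kind must be MLP, SVM or RF")
        if self.mode not in ("grid", "fixed"):
            raise ValueError("mode must be 'grid' or 'fixed'")

    def build_estimator(self):
        if self.kind == "MLP":
            est = MLPClassifier(
                activation="relu", solver="lbfgs", random_state=RANDOM_STATE,
                max_iter=3000,
            )
            if self.mode == "fixed":
                est.set_params(hidden_layer_sizes=120, alpha=1e-5)
            return est
        if self.kind == "SVM":
            est = SVC(
                decision_function_shape="ovr", random_state=RANDOM_STATE, degree=3
            )
            if self.mode == "fixed":
                est.set_params(kernel="linear", C=1.0)
            else:
                est.set_params(kernel="rbf")
            return est
        est = RandomForestClassifier(
            criterion="gini", min_samples_split=2, min_samples_leaf=1,
            random_state=RANDOM_STATE,
        )
        if self.mode == "fixed":
            est.set_params(n_estimators=500)
        return est

    def param_grid(self) -> dict[str, list]:
        if self.mode == "fixed":
            return {}
        if self.kind == "MLP":
            return {"hidden_layer_sizes": list(_MLP_HIDDEN), "alpha": list(_MLP_ALPHA)}
        if self.kind == "SVM":
            return {"C": list(_SVM_C), "gamma": list(_SVM_GAMMA)}
        return {"n_estimators": list(_RF_TREES)}


@dataclass
class TrainedModel:
    estimator: object
    cv_table: pd.DataFrame | None
    best_params: dict
    best_cv_accuracy: float | None
    classes_: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.classes_ = np.asarray(self.estimator.classes_)


def grid_search_train(
    features: np.ndarray,
    labels: np.ndarray,
    spec: ClassifierSpec,
    n_folds: int = 5,
    n_jobs: int = 1,
    param_grid: dict | None = None,
) -> TrainedModel:
    """Exhaustive grid search with stratified five-fold CV scored by accuracy.

    The best configuration is refitted on the full training data; the full CV
    table is recorded.  ``param_grid=None`` uses the spec's protocol grid; a
    fixed-mode spec (empty grid) is a direct fit.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < n_folds:
        raise ValueError(
            f"need >= {n_folds} samples per class for {n_folds}-fold CV "
            f"(smallest class has {counts.min()})"
        )
    grid = spec.param_grid() if param_grid is None else param_grid
    est = spec.build_estimator()
    if not grid:
        est.fit(x, y)
        return TrainedModel(est, None, {}, None)
    search = GridSearchCV(
        est,
        grid,
        scoring="accuracy",
        cv=StratifiedKFold(n_splits=n_folds),
        n_jobs=n_jobs,
        refit=True,
    )
    search.fit(x, y)
    return TrainedModel(
        estimator=search.best_estimator_,
        cv_table=pd.DataFrame(search.cv_results_),
        best_params=dict(search.best_params_),
        best_cv_accuracy=float(search.best_score_),
    )


def predict(model: TrainedModel, features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hard labels plus per-class scores for curve plotting.

    Scores are class probabilities when the estimator provides them and raw
    one-vs-rest decision values otherwise; the hard label is the argmax class
    of the score row in either case.
    """
    x = np.asarray(features, dtype=float)
    est = model.estimator
    n_feat = getattr(est, "n_features_in_", None)
    if n_feat is not None and x.shape[1] != n_feat:
        raise ValueError(f"feature dim {x.shape[1]} != model dim {n_feat}")
    if hasattr(est, "predict_proba"):
        scores = est.predict_proba(x)
    else:
        scores = est.decision_function(x)
        if scores.ndim == 1:  # binary: one-vs-rest pair of signed distances
            scores = np.column_stack([-scores, scores])
    labels = model.classes_[np.argmax(scores, axis=1)]
    return labels, scores
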