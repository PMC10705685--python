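"""CNN-style feature extraction with a transfer-learning training protocol.

A backbone maps a normalized 224x224 RGB crop to a 1000-dimensional feature
vector (the ImageNet-head output).  Training follows a fixed protocol: SGD
with momentum 0.9, cross-entropy loss, batch size 64, initial learning rate
1e-4 decayed by x0.8 every five epochs, and a two-phase early-stopping rule —
convergence begins once the training loss fluctuates by < 0.001 over five
epochs, and training halts when the validation loss then shifts by < 0.005
over another five epochs.  The checkpoint with peak validation accuracy is
returned.

The always-available ``tiny-test`` backbone is a small randomly initialized
numpy network with the same 1000-dim output contract, so the whole protocol
is exercised without pretrained weights or a deep-learning framework.  The
six named ImageNet backbones (VGG16, ResNet101, DenseNet169, MobileNetV3-L,
RegNetX-8GF, ConvNeXt-S) are an optional plug-in that requires torchvision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import transform as sktransform

from .preprocess import CropResult

__all__ = [
    "BackboneSpec",
    "TrainProtocol",
    "AugmentConfig",
    "BackboneWeightsError",
    "FinetuneResult",
    "BACKBONE_NAMES",
    "FEATURE_DIM",
    "lr_at_epoch",
    "early_stop_epoch",
    "augment",
    "load_backbone",
    "extract_features",
    "finetune",
]

FEATURE_DIM = 1000
INPUT_PX = 224

BACKBONE_NAMES = (
    "VGG16",
    "ResNet101",
    "DenseNet169",
    "MobileNetV3-L",
    "RegNetX-8GF",
    "ConvNeXt-S",
    "tiny-test",
)

_IMAGENET_MEAN = np.array([0.485, 0.456, 0.406])
_IMAGENET_STD = np.array([0.229, 0.224, 0.225])


class BackboneWeightsError(RuntimeError):
    """Raised when a backbone's weights cannot be loaded."""


@dataclass(frozen=True)
class BackboneSpec:
    """Contract of a feature-extraction backbone."""

    name: str
    input_px: int = INPUT_PX
    output_dim: int = FEATURE_DIM

    def __post_init__(self) -> None:
        if self.name not in BACKBONE_NAMES:
            raise ValueError(f"unknown backbone {self.name!r}; one of {BACKBONE_NAMES}")


@dataclass(frozen=True)
class TrainProtocol:
    """Fine-tuning hyperparameters (defaults are the study protocol)."""

    momentum: float = 0.9
    batch_size: int = 64
    lr0: float = 1e-4
    lr_factor: float = 0.8
    lr_step: int = 5
    train_flux_tol: float = 0.001
    val_shift_tol: float = 0.005
    stop_window: int = 5
    max_epochs: int = 200


@dataclass(frozen=True)
class AugmentConfig:
    """Magnitude bounds of the four augmentation families."""

    flip: bool = True
    max_translate_px: int = 12
    max_rotate_deg: float = 12.0
    max_brightness: float = 0.12

    @classmethod
    def identity(cls) -> "AugmentConfig":
        return cls(flip=False, max_translate_px=0, max_rotate_deg=0.0, max_brightness=0.0)


# ----------------------------------------------------------------------------
# schedule and stopping rules (pure functions)
# ----------------------------------------------------------------------------


def lr_at_epoch(epoch: int, protocol: TrainProtocol = TrainProtocol()) -> float:
    """Learning rate at a (0-based) epoch: lr0 * factor ** floor(epoch/step)."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    return protocol.lr0 * protocol.lr_factor ** (epoch // protocol.lr_step)


def early_stop_epoch(
    train_losses,
    val_losses,
    protocol: TrainProtocol = TrainProtocol(),
) -> int | None:
    """Epoch (0-based) where the two-phase early-stopping rule fires, else None.

    Phase 1 (convergence begins): the first epoch ``i`` whose trailing
    ``window`` training losses fluctuate (max - min) by less than
    ``train_flux_tol``.  Phase 2 (fully converged): the first epoch
    ``j >= i + window`` whose trailing ``window`` validation losses shift by
    less than ``val_shift_tol`` — so the validation window covers epochs
    strictly after phase 1.  Training halts at ``j``.
    """
    train = np.asarray(train_losses, dtype=float)
    val = np.asarray(val_losses, dtype=float)
    if train.shape != val.shape:
        raise ValueError("train and validation loss traces differ in length")
    w = protocol.stop_window
    phase1 = None
    for i in range(w - 1, len(train)):
        if np.ptp(train[i - w + 1 : i + 1]) < protocol.train_flux_tol:
            phase1 = i
            break
    if phase1 is None:
        return None
    for j in range(phase1 + w, len(val)):
        if np.ptp(val[j - w + 1 : j + 1]) < protocol.val_shift_tol:
            return j
    return None


# ----------------------------------------------------------------------------
# augmentation
# ----------------------------------------------------------------------------


def augment(
    image: np.ndarray,
    seed: int,
    cfg: AugmentConfig = AugmentConfig(),
) -> np.ndarray:
    """Apply a seeded random subset of flip/translate/rotate/brightness.

    Each family is drawn independently (probability 1/2) with a magnitude
    uniform within the config bounds.  All-zero magnitudes (and ``flip=False``)
    give the identity; the same seed always gives the same output; output
    shape equals input shape.
    """
    rng = np.random.default_rng(seed)
    out = np.asarray(image).astype(float)
    apply_flip, apply_shift, apply_rot, apply_bright = rng.random(4) < 0.5
    flip_axis = int(rng.integers(0, 2))
    shift = rng.integers(-cfg.max_translate_px, cfg.max_translate_px + 1, size=2)
    angle = rng.uniform(-cfg.max_rotate_deg, cfg.max_rotate_deg)
    bright = rng.uniform(-cfg.max_brightness, cfg.max_brightness)

    if cfg.flip and apply_flip:
        out = np.flip(out, axis=flip_axis)
    if apply_shift and (shift != 0).any():
        out = np.roll(out, tuple(shift), axis=(0, 1))
    if apply_rot and angle != 0.0:
        out = sktransform.rotate(out / 255.0, angle, mode="edge") * 255.0
    if apply_bright and bright != 0.0:
        out = out * (1.0 + bright)
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


# ----------------------------------------------------------------------------
# tiny-test backbone (numpy)
# ----------------------------------------------------------------------------


def _preprocess_crop(crop: CropResult) -> np.ndarray:
    """Resize to 224x224, scale to [0,1], channel-normalize, pool to 588 dims."""
    img = np.clip(np.asarray(crop.crop_rgb, dtype=float), 0, 255) / 255.0
    img = sktransform.resize(img, (INPUT_PX, INPUT_PX, 3), anti_aliasing=True)
    img = (img - _IMAGENET_MEAN) / _IMAGENET_STD
    # 16x16 average pooling -> 14x14x3
    pooled = img.reshape(14, 16, 14, 16, 3).mean(axis=(1, 3))
    return pooled.ravel()


class TinyTestBackbone:
    """Small randomly initialized network with the 1000-dim output contract.

    Input 224x224x3 -> 16x16 average pooling (588 dims) -> 64 ReLU units ->
    1000-dim linear head.  Deterministic in evaluation; trainable with the
    protocol's SGD via :func:`finetune`.
    """

    spec = BackboneSpec("tiny-test")

    def __init__(self, init_seed: int = 0) -> None:
        rng = np.random.default_rng(init_seed)
        d_in, d_h = 588, 64
        self.w1 = rng.normal(0, np.sqrt(2.0 / d_in), (d_in, d_h))
        self.b1 = np.zeros(d_h)
        self.w2 = rng.normal(0, np.sqrt(2.0 / d_h), (d_h, FEATURE_DIM))
        self.b2 = np.zeros(FEATURE_DIM)

    def parameters(self) -> dict[str, np.ndarray]:
        return {"w1": self.w1, "b1": self.b1, "w2": self.w2, "b2": self.b2}

    def load_parameters(self, params: dict[str, np.ndarray]) -> None:
        self.w1, self.b1 = params["w1"].copy(), params["b1"].copy()
        self.w2, self.b2 = params["w2"].copy(), params["b2"].copy()

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        h = np.maximum(x @ self.w1 + self.b1, 0.0)
        return h, h @ self.w2 + self.b2

    def extract(self, crop: CropResult) -> np.ndarray:
        _, f = self.forward(_preprocess_crop(crop)[None, :])
        return f[0]


def load_backbone(name: str, init_seed: int = 0):
    """Instantiate a backbone by name.

    ``tiny-test`` is always available.  The six ImageNet architectures need
    torchvision and pretrained weights; without them a
    :class:`BackboneWeightsError` naming the backbone is raised.
    """
    BackboneSpec(name)  # validates the name
    if name == "tiny-test":
        return TinyTestBackbone(init_seed)
    try:  # pragma: no cover - exercised only with the optional extra
        import torchvision  # noqa: F401
    except ImportError as exc:
        raise BackboneWeightsError(
            f"cannot load pretrained weights for backbone {name!r}: "
            "torchvision is not installed (optional 'torch' extra)"
        ) from exc
    raise BackboneWeightsError(
        f"pretrained plug-in for backbone {name!r} is not wired up in this build"
    )


def extract_features(backbone, crop: CropResult) -> np.ndarray:
    """1000-dim feature vector of one crop (deterministic, eval mode)."""
    vec = backbone.extract(crop)
    if vec.shape != (FEATURE_DIM,):
        raise ValueError(f"backbone returned shape {vec.shape}, expected (1000,)")
    return vec


# ----------------------------------------------------------------------------
# fine-tuning
# ----------------------------------------------------------------------------


@dataclass
class FinetuneResult:
    backbone: TinyTestBackbone
    log: pd.DataFrame
    stopped_epoch: int | None
    best_epoch: int
    best_val_accuracy: float


def _softmax_ce(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    n = len(y)
    loss = float(-np.mean(np.log(p[np.arange(n), y] + 1e-12)))
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    return loss, grad / n


def finetune(
    backbone: TinyTestBackbone,
    train_set: tuple[list[CropResult], np.ndarray],
    val_set: tuple[list[CropResult], np.ndarray],
    protocol: TrainProtocol = TrainProtocol(),
    seed: int = 0,
) -> FinetuneResult:
    """Fine-tune the tiny-test backbone plus a temporary classification head.

    A linear head maps the 1000-dim feature output to the task classes; the
    whole stack trains with the protocol's SGD-momentum/cross-entropy recipe,
    the x0.8-every-5-epochs LR schedule and the two-phase early-stopping rule.
    The returned backbone carries the parameters of the epoch with peak
    validation accuracy; ``log`` has one row per epoch
    (epoch, lr, train_loss, val_loss, val_accuracy).
    """
    crops_tr, y_tr = train_set
    crops_va, y_va = val_set
    if len(crops_tr) == 0 or len(crops_va) == 0:
        raise ValueError("empty training or validation split")
    y_tr = np.asarray(y_tr, dtype=int)
    y_va = np.asarray(y_va, dtype=int)
    n_classes = int(max(y_tr.max(), y_va.max())) + 1

    x_tr = np.stack([_preprocess_crop(c) for c in crops_tr])
    x_va = np.stack([_preprocess_crop(c) for c in crops_va])

    rng = np.random.default_rng(seed)
    wc = rng.normal(0, np.sqrt(2.0 / FEATURE_DIM), (FEATURE_DIM, n_classes))
    bc = np.zeros(n_classes)
    params = {**backbone.parameters(), "wc": wc, "bc": bc}
    velocity = {k: np.zeros_like(v) for k, v in params.items()}

    def forward(x):
        h = np.maximum(x @ params["w1"] + params["b1"], 0.0)
        f = h @ params["w2"] + params["b2"]
        return h, f, f @ params["wc"] + params["bc"]

    best = {"acc": -1.0, "epoch": -1, "params": None}
    rows: list[dict] = []
    train_losses: list[float] = []
    val_losses: list[float] = []
    stopped = None

    for epoch in range(protocol.max_epochs):
        lr = lr_at_epoch(epoch, protocol)
        order = rng.permutation(len(x_tr))
        for start in range(0, len(order), protocol.batch_size):
            idx = order[start : start + protocol.batch_size]
            xb, yb = x_tr[idx], y_tr[idx]
            h, f, logits = forward(xb)
            _, dlogits = _softmax_ce(logits, yb)
            grads = {
                "wc": f.T @ dlogits,
                "bc": dlogits.sum(axis=0),
            }
            df = dlogits @ params["wc"].T
            grads["w2"] = h.T @ df
            grads["b2"] = df.sum(axis=0)
            dh = (df @ params["w2"].T) * (h > 0)
            grads["w1"] = xb.T @ dh
            grads["b1"] = dh.sum(axis=0)
            for k in params:
                velocity[k] = protocol.momentum * velocity[k] - lr * grads[k]
                params[k] = params[k] + velocity[k]

        _, _, logits_tr = forward(x_tr)
        train_loss, _ = _softmax_ce(logits_tr, y_tr)
        _, _, logits_va = forward(x_va)
        val_loss, _ = _softmax_ce(logits_va, y_va)
        val_acc = float(np.mean(logits_va.argmax(axis=1) == y_va))
        train_losses.append(train_loss)
        val_losses.append(val_loss)
        rows.append(
            dict(epoch=epoch, lr=lr, train_loss=train_loss, val_loss=val_loss,
                 val_accuracy=val_acc)
        )
        if val_acc > best["acc"]:
            best = {"acc": val_acc, "epoch": epoch,
                    "params": {k: v.copy() for k, v in params.items()}}
        stop = early_stop_epoch(train_losses, val_losses, protocol)
        if stop is not None and stop == epoch:
            stopped = epoch
            break

    tuned = TinyTestBackbone()
    tuned.load_parameters(best["params"])
    return FinetuneResult(
        backbone=tuned,
        log=pd.DataFrame(rows),
        stopped_epoch=stopped,
        best_epoch=best["epoch"],
        best_val_accuracy=best["acc"],
    )
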