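"""Segmentation model construction, training, inference, XAI and latency.

Two independent binary segmenters (iris, eyebrow) share one architecture: a
U-Net-style encoder-decoder (:class:`periomet.nn.UNet`) taking 3-channel
64x64 inputs and emitting a single-channel logit map.  The training recipe
follows the clinical study's: batch size 16, Adam, BCE-with-logits, initial
learning rate 0.005 halved whenever validation loss fails to improve for 10
consecutive epochs, best-validation-loss weights retained.

The explainability utilities mirror the usual gradient-based procedures:
``saliency_map`` is the normalized input-gradient magnitude of the summed
foreground logit; ``grad_cam`` is the channel-weighted, rectified activation
map of a chosen decoder depth, upsampled and min-max normalized.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from skimage.transform import resize as _sk_resize

from .exceptions import ConfigurationError, InputError, TrainingError
from .nn import Adam, UNet, bce_with_logits, sigmoid

INPUT_SIZE = (64, 64)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters (defaults follow the study recipe)."""

    batch_size: int = 16
    max_epochs: int = 1000
    initial_lr: float = 0.005
    scheduler_patience: int = 10
    scheduler_factor: float = 0.5
    input_size: tuple[int, int] = INPUT_SIZE
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 1:
            raise ConfigurationError("batch_size must be >= 1")
        if not 0.0 < self.scheduler_factor < 1.0:
            raise ConfigurationError("scheduler_factor must be in (0, 1)")
        if self.initial_lr <= 0:
            raise ConfigurationError("initial_lr must be positive")
        if self.max_epochs < 1:
            raise ConfigurationError("max_epochs must be >= 1")


@dataclass
class LatencyStats:
    """Per-image forward-pass wall-time statistics (milliseconds)."""

    mean_ms: float
    median_ms: float
    p90_ms: float
    n_images: int
    threads: int | None = None


class ReduceLROnPlateau:
    """Halve the learning rate after ``patience`` epochs without improvement.

    "Improvement" means the validation loss decreased by more than
    ``threshold`` below the best seen so far.  The stagnation counter resets
    both on improvement and after each reduction.
    """

    def __init__(self, initial_lr: float, patience: int = 10,
                 factor: float = 0.5, threshold: float = 1e-6):
        self.lr = float(initial_lr)
        self.patience = int(patience)
        self.factor = float(factor)
        self.threshold = float(threshold)
        self.best = float("inf")
        self.num_bad_epochs = 0

    def step(self, val_loss: float) -> float:
        if val_loss < self.best - self.threshold:
            self.best = float(val_loss)
            self.num_bad_epochs = 0
        else:
            self.num_bad_epochs += 1
            if self.num_bad_epochs >= self.patience:
                self.lr *= self.factor
                self.num_bad_epochs = 0
        return self.lr


# ---------------------------------------------------------------------------
# Model construction
# ---------------------------------------------------------------------------

def build_model(pretrained: bool = False, width: int = 8, seed: int = 0) -> UNet:
    """Build the segmentation network.

    ``pretrained=False`` gives a seeded random initialization.  No pretrained
    encoder weights ship with this package, so ``pretrained=True`` raises;
    the synthetic task trains well from scratch at these widths.
    """
    if pretrained:
        raise NotImplementedError(
            "no pretrained encoder weights are bundled; "
            "use pretrained=False (seeded random initialization)")
    return UNet(width=width, seed=seed)


# ---------------------------------------------------------------------------
# Input preprocessing
# ---------------------------------------------------------------------------

def preprocess_image(image: np.ndarray,
                     input_size: tuple[int, int] = INPUT_SIZE) -> np.ndarray:
    """RGB (H, W, 3) -> float32 (1, 3, h, w) in [0, 1], bilinear resize."""
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise InputError(f"expected an RGB (H, W, 3) image, got {arr.shape}")
    arr = arr.astype(np.float32)
    if arr.max() > 1.0:
        arr = arr / 255.0
    if arr.shape[:2] != tuple(input_size):
        arr = _sk_resize(arr, input_size, order=1, anti_aliasing=True,
                         preserve_range=True).astype(np.float32)
    return np.ascontiguousarray(arr.transpose(2, 0, 1)[None])


def downscale_mask(mask: np.ndarray,
                   input_size: tuple[int, int] = INPUT_SIZE) -> np.ndarray:
    """Nearest-neighbor downscale of a binary mask to the model grid."""
    m = np.asarray(mask) != 0
    if m.shape == tuple(input_size):
        return m
    out = _sk_resize(m.astype(np.float32), input_size, order=0,
                     anti_aliasing=False, preserve_range=True)
    return out > 0.5


def upscale_mask(mask: np.ndarray, out_shape) -> np.ndarray:
    """Nearest-neighbor upscale of a binary mask to ``out_shape`` (H, W)."""
    m = np.asarray(mask) != 0
    out = _sk_resize(m.astype(np.float32), out_shape, order=0,
                     anti_aliasing=False, preserve_range=True)
    return out > 0.5


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _check_sets(train_set, val_set):
    xt, yt = train_set
    xv, yv = val_set
    for name, (x, y) in (("train", (xt, yt)), ("validation", (xv, yv))):
        if len(x) == 0 or len(y) == 0:
            raise InputError(f"{name} set is empty")
        if len(x) != len(y):
            raise InputError(f"{name} images/masks length mismatch")
    train_keys = {x.tobytes() for x in np.asarray(xt)}
    val_keys = {x.tobytes() for x in np.asarray(xv)}
    if train_keys & val_keys:
        raise InputError("train and validation sets overlap")


def train(model: UNet, train_set, val_set,
          config: TrainConfig | None = None) -> tuple[UNet, pd.DataFrame]:
    """Train a segmenter; returns (model with best-val weights, history).

    ``train_set``/``val_set`` are ``(X, Y)`` pairs with X float32
    (N, 3, h, w) in [0, 1] and Y (N, 1, h, w) in {0, 1}.  The history frame
    has one row per epoch: epoch, train_loss, val_loss, lr (the rate used
    during that epoch).  Deterministic for fixed seeds and inputs.
    """
    config = config or TrainConfig()
    _check_sets(train_set, val_set)
    x_train = np.ascontiguousarray(train_set[0], dtype=np.float32)
    y_train = np.ascontiguousarray(train_set[1], dtype=np.float32)
    x_val = np.ascontiguousarray(val_set[0], dtype=np.float32)
    y_val = np.ascontiguousarray(val_set[1], dtype=np.float32)

    opt = Adam(model.params(), lr=config.initial_lr)
    sched = ReduceLROnPlateau(config.initial_lr, config.scheduler_patience,
                              config.scheduler_factor)
    rng = np.random.default_rng(config.seed)
    n = len(x_train)
    best_val = float("inf")
    best_state = model.state_dict()
    history = []

    for epoch in range(config.max_epochs):
        lr_used = sched.lr
        opt.lr = lr_used
        perm = rng.permutation(n)
        total, seen = 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = perm[start:start + config.batch_size]
            logits = model.forward(x_train[idx])
            loss, dlogits = bce_with_logits(logits, y_train[idx])
            if not np.isfinite(loss):
                raise TrainingError(
                    f"non-finite training loss at epoch {epoch}", epoch=epoch)
            model.zero_grad()
            model.backward(dlogits)
            opt.step()
            total += loss * len(idx)
            seen += len(idx)
        train_loss = total / seen

        val_loss = evaluate_loss(model, x_val, y_val, config.batch_size)
        if not np.isfinite(val_loss):
            raise TrainingError(
                f"non-finite validation loss at epoch {epoch}", epoch=epoch)
        history.append({"epoch": epoch, "train_loss": train_loss,
                        "val_loss": val_loss, "lr": lr_used})
        if val_loss < best_val:
            best_val = val_loss
            best_state = model.state_dict()
        sched.step(val_loss)

    model.load_state_dict(best_state)
    return model, pd.DataFrame(history)


def evaluate_loss(model: UNet, x: np.ndarray, y: np.ndarray,
                  batch_size: int = 16) -> float:
    total, seen = 0.0, 0
    for start in range(0, len(x), batch_size):
        logits = model.forward(x[start:start + batch_size])
        loss, _ = bce_with_logits(logits, y[start:start + batch_size])
        total += loss * len(logits)
        seen += len(logits)
    return total / seen


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------

def predict_mask(model: UNet, image: np.ndarray, threshold: float = 0.5,
                 full_size: bool = False):
    """Segment one RGB image; returns (probability map, binary mask).

    The probability map lives on the model grid (64x64).  With
    ``full_size=True`` the mask is upscaled back to the input image size by
    nearest neighbor.
    """
    x = preprocess_image(image)
    prob = sigmoid(model.forward(x))[0, 0]
    mask = prob >= threshold
    if full_size:
        mask = upscale_mask(mask, np.asarray(image).shape[:2])
    return prob, mask


# ---------------------------------------------------------------------------
# Explainability
# ---------------------------------------------------------------------------

def saliency_map(model: UNet, image: np.ndarray) -> np.ndarray:
    """Input-gradient saliency of the summed foreground logit, in [0, 1].

    The heatmap is the per-pixel L2 magnitude of d(sum of logits)/d(input),
    max-normalized (all-zero when the gradient vanishes identically) and
    resized to the input image size.
    """
    x = preprocess_image(image)
    logits = model.forward(x)
    dx = model.backward(np.ones_like(logits), need_input_grad=True)
    heat = np.sqrt((dx[0] ** 2).sum(axis=0))
    peak = heat.max()
    if peak > 0:
        heat = heat / peak
    out_shape = np.asarray(image).shape[:2]
    if tuple(out_shape) != heat.shape:
        heat = _sk_resize(heat, out_shape, order=1, anti_aliasing=False,
                          preserve_range=True)
    return np.clip(heat, 0.0, 1.0)


def grad_cam(model: UNet, image: np.ndarray,
             layer: str = "bottleneck") -> np.ndarray:
    """Grad-CAM heatmap in [0, 1] at a decoder depth selector.

    Channel weights are the spatial means of the gradient of the summed
    foreground logit; the weighted activation sum is rectified, upsampled to
    the image size, and min-max normalized.
    """
    if layer not in UNet.GRADCAM_LAYERS:
        raise InputError(
            f"unknown layer {layer!r}; choose from {UNet.GRADCAM_LAYERS}")
    x = preprocess_image(image)
    logits = model.forward(x)
    model.backward(np.ones_like(logits), record=(layer,))
    acts = model.activations[layer][0]
    grads = model.activation_grads[layer][0]
    weights = grads.mean(axis=(1, 2))
    cam = np.maximum((weights[:, None, None] * acts).sum(axis=0), 0.0)
    out_shape = np.asarray(image).shape[:2]
    cam = _sk_resize(cam, out_shape, order=1, anti_aliasing=False,
                     preserve_range=True)
    lo, hi = cam.min(), cam.max()
    if hi > lo:
        cam = (cam - lo) / (hi - lo)
    else:
        cam = np.zeros_like(cam)
    return np.clip(cam, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Latency
# ---------------------------------------------------------------------------

def measure_latency(model: UNet, images, threads: int | None = None,
                    warmup: int = 5) -> LatencyStats:
    """Model-only forward-pass latency over a set of images.

    Preprocessing happens before the clock starts; ``warmup`` extra passes
    are excluded from the statistics.  ``threads`` is recorded for context
    (numpy's BLAS thread count is process-global and set at import time).
    """
    batches = [preprocess_image(im) for im in images]
    if not batches:
        raise InputError("measure_latency requires at least one image")
    for _ in range(warmup):
        model.forward(batches[0])
    times_ms = []
    for x in batches:
        t0 = time.perf_counter()
        model.forward(x)
        times_ms.append((time.perf_counter() - t0) * 1e3)
    arr = np.asarray(times_ms)
    return LatencyStats(
        mean_ms=float(arr.mean()),
        median_ms=float(np.median(arr)),
        p90_ms=float(np.percentile(arr, 90)),
        n_images=len(arr),
        threads=threads,
    )


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: UNet, path, config: TrainConfig | None = None) -> None:
    """Single-file checkpoint: parameters + architecture + train config."""
    meta = {
        "width": model.width,
        "in_channels": model.in_channels,
        "config": asdict(config) if config is not None else None,
    }
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **model.state_dict())


def load_checkpoint(path) -> tuple[UNet, TrainConfig | None]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    model = UNet(width=meta["width"], in_channels=meta["in_channels"])
    model.load_state_dict(state)
    cfg = meta.get("config")
    if cfg is not None:
        cfg["input_size"] = tuple(cfg["input_size"])
        return model, TrainConfig(**cfg)
    return model, None
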