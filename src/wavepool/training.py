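"""Training protocol and per-run evaluation for the compact CNN.

Optimization: cross-entropy over the 2-way softmax (the two-class form of
binary cross-entropy on one-hot targets), Adam (lr 1e-3, betas 0.9/0.999),
L2 weight decay 1e-4, reduce-on-plateau halving after 5 non-improving
validation epochs, early stopping with patience 10 (max 100 epochs) and
restoration of the best-validation-loss weights.

Augmentation (training data only) is geometric: horizontal flip p=0.5,
rotation +-15 deg, translation up to 10% of each dimension, isotropic zoom
in [0.9, 1.1]; no intensity jitter.  Noise injection precedes the optional
despeckling step at both training and evaluation time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from . import metrics as _metrics
from .despeckle import DenoiseConfig, denoise_image
from .model import WaveletCNN
from .nn import Adam, softmax
from .noise import add_speckle

LOG_EPS = 1e-12


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-3
    betas: Tuple[float, float] = (0.9, 0.999)
    weight_decay: float = 1e-4
    max_epochs: int = 100
    early_stop_patience: int = 10
    plateau_patience: int = 5
    plateau_factor: float = 0.5
    batch_size: int = 8
    seed: int = 0
    noise_level: float = 0.0
    preprocess: bool = False
    augment: bool = True

    def __post_init__(self) -> None:
        if self.early_stop_patience < 1 or self.plateau_patience < 1:
            raise ValueError("patience values must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


def bce_loss(probs: np.ndarray, labels_onehot: np.ndarray) -> float:
    """Mean over the batch of -sum_c y_c log p_c (two-class cross-entropy)."""
    p = np.asarray(probs, dtype=np.float64)
    y = np.asarray(labels_onehot, dtype=np.float64)
    return float(-np.mean(np.sum(y * np.log(np.clip(p, LOG_EPS, 1.0)), axis=-1)))


def one_hot(labels: np.ndarray, num_classes: int = 2) -> np.ndarray:
    y = np.asarray(labels).astype(int)
    out = np.zeros((y.size, num_classes))
    out[np.arange(y.size), y] = 1.0
    return out


def draw_augment_params(rng: np.random.Generator) -> Dict[str, float]:
    """Sample one set of geometric augmentation parameters."""
    return {
        "flip": bool(rng.random() < 0.5),
        "angle": float(rng.uniform(-15.0, 15.0)),
        "ty_frac": float(rng.uniform(-0.1, 0.1)),
        "tx_frac": float(rng.uniform(-0.1, 0.1)),
        "zoom": float(rng.uniform(0.9, 1.1)),
    }


def apply_augment(image: np.ndarray, params: Dict[str, float]) -> np.ndarray:
    """Apply a geometric transform; identity parameters return the input."""
    img = np.asarray(image, dtype=np.float64)
    h, w = img.shape
    if params["flip"]:
        img = img[:, ::-1]
    if (params["angle"] == 0 and params["ty_frac"] == 0
            and params["tx_frac"] == 0 and params["zoom"] == 1):
        return img.copy()
    ty = params["ty_frac"] * h
    tx = params["tx_frac"] * w
    zoom = params["zoom"]
    a = np.deg2rad(params["angle"])
    rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]]) / zoom
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    offset = center - rot @ center + np.array([ty, tx])
    out = ndimage.affine_transform(img, rot, offset=offset, order=1, mode="nearest")
    return np.clip(out, 0.0, 1.0)


def augment(image: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One random geometric augmentation of a [0, 1] image."""
    return apply_augment(image, draw_augment_params(rng))


class PlateauScheduler:
    """Halve the learning rate after `patience` non-improving epochs."""

    def __init__(self, optimizer: Adam, patience: int = 5, factor: float = 0.5,
                 min_lr: float = 1e-6):
        self.opt = optimizer
        self.patience = patience
        self.factor = factor
        self.min_lr = min_lr
        self.best = np.inf
        self.bad_epochs = 0

    def step(self, val_loss: float) -> None:
        if val_loss < self.best - 1e-12:
            self.best = val_loss
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
            if self.bad_epochs >= self.patience:
                self.opt.lr = max(self.opt.lr * self.factor, self.min_lr)
                self.bad_epochs = 0


class EarlyStopper:
    """Stop after `patience` epochs without a new best validation loss.

    Tracks the epoch and a snapshot of the best weights so training can
    restore them; never returns weights from an epoch after the best one.
    """

    def __init__(self, patience: int = 10):
        self.patience = patience
        self.best_loss = np.inf
        self.best_epoch = -1
        self.best_state: Optional[Dict[str, np.ndarray]] = None

    def update(self, epoch: int, val_loss: float, state: Dict[str, np.ndarray]) -> bool:
        """Record this epoch; return True when training should stop."""
        if val_loss < self.best_loss:
            self.best_loss = val_loss
            self.best_epoch = epoch
            self.best_state = state
            return False
        return epoch - self.best_epoch >= self.patience


def _prepare_inputs(x: np.ndarray, noise_level: float, preprocess: bool,
                    rng: np.random.Generator,
                    denoise_cfg: Optional[DenoiseConfig]) -> np.ndarray:
    """Corrupt then optionally despeckle a stack of images."""
    out = np.empty_like(x, dtype=np.float64)
    for i in range(x.shape[0]):
        img = x[i]
        if noise_level > 0:
            img = add_speckle(img, noise_level, rng)
        if preprocess:
            img = denoise_image(img, denoise_cfg or DenoiseConfig())
        out[i] = img
    return out


def train_model(model: WaveletCNN, x_train: np.ndarray, y_train: np.ndarray,
                x_val: np.ndarray, y_val: np.ndarray,
                config: TrainConfig) -> Dict[str, List[float]]:
    """Train in place; returns the per-epoch history.

    Inputs are stacks of [0, 1] grayscale images (N, H, W).  Noise
    injection, optional despeckling and augmentation happen on the fly,
    all driven by a single seeded generator so a run is reproducible.
    """
    if x_train.size == 0 or x_val.size == 0:
        raise ValueError("datasets must be nonempty")
    rng = np.random.default_rng(config.seed)
    denoise_cfg = DenoiseConfig(order=model.config.pooling.order or 2)
    opt = Adam(model.net.params(), lr=config.lr, betas=config.betas,
               weight_decay=config.weight_decay)
    sched = PlateauScheduler(opt, config.plateau_patience, config.plateau_factor)
    stopper = EarlyStopper(config.early_stop_patience)
    history: Dict[str, List[float]] = {"train_loss": [], "val_loss": [], "lr": []}

    xv = _prepare_inputs(x_val, config.noise_level, config.preprocess,
                         np.random.default_rng(config.seed + 1), denoise_cfg)
    yv1h = one_hot(y_val)
    y1h = one_hot(y_train)

    n = x_train.shape[0]
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb = _prepare_inputs(x_train[idx], config.noise_level,
                                 config.preprocess, rng, denoise_cfg)
            if config.augment:
                xb = np.stack([augment(im, rng) for im in xb])
            yb = y1h[idx]
            model.net.zero_grad()
            logits = model.logits(xb[:, None], train=True, rng=rng)
            probs = softmax(logits)
            loss = bce_loss(probs, yb)
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
            dlogits = ((probs - yb) / xb.shape[0]).astype(model.config.dtype)
            model.net.backward(dlogits, start=len(model.net.layers))
            opt.step()
            epoch_loss += loss * len(idx)
        epoch_loss /= n

        val_probs = _batched_probs(model, xv)
        val_loss = bce_loss(val_probs, yv1h)
        if not np.isfinite(val_loss):
            raise FloatingPointError(f"non-finite validation loss at epoch {epoch}")
        history["train_loss"].append(epoch_loss)
        history["val_loss"].append(val_loss)
        history["lr"].append(opt.lr)
        stop = stopper.update(epoch, val_loss, model.net.state_dict())
        sched.step(val_loss)
        if stop:
            break

    if stopper.best_state is not None:
        model.net.load_state_dict(stopper.best_state)
    history["best_epoch"] = [stopper.best_epoch]
    return history


def _batched_probs(model: WaveletCNN, x: np.ndarray, batch: int = 64) -> np.ndarray:
    out = []
    for start in range(0, x.shape[0], batch):
        out.append(model.predict_proba(x[start:start + batch, None]))
    return np.concatenate(out, axis=0)


def evaluate(model: WaveletCNN, x: np.ndarray, y: np.ndarray,
             noise_levels: Sequence[float], preprocess: bool = False,
             seed: int = 0, threshold: float = 0.5) -> List[_metrics.MetricsReport]:
    """Per noise level: corrupt -> optional despeckle -> forward -> metrics.

    Evaluation is side-effect free (weights untouched); the decision rule
    is argmax, i.e. positive probability >= 0.5, unless a threshold is
    given.
    """
    if x.size == 0:
        raise ValueError("empty evaluation dataset")
    denoise_cfg = DenoiseConfig(order=model.config.pooling.order or 2)
    reports = []
    for level in noise_levels:
        rng = np.random.default_rng(seed)
        xi = _prepare_inputs(x, level, preprocess, rng, denoise_cfg)
        probs = _batched_probs(model, xi)[:, 1]
        reports.append(_metrics.full_report(y, probs, threshold=threshold))
    return reports
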