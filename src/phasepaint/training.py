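"""Losses, augmentation, cross-validation, and the optimization loop.

The segmentation loss combines a focal term, which up-weights
hard-to-classify pixels through a ``(1 - p)^gamma`` modulating factor, with a
Dice overlap term written in its negative form (minimum -1 at a perfect
nonempty match):

    L_FL   = -mean_i[ (1-p_i)^g y_i log p_i + p_i^g (1-y_i) log(1-p_i) ]
    L_DICE = -(2 sum y_i p_i) / (sum y_i^2 + sum p_i^2)

The focal sum is divided by the pixel count so the loss scale is
batch-size-invariant; the optimum is unchanged.  Optimization uses Adam with
an initial learning rate of 3e-4, divided by 10 after epochs 10 and 20, under
5-fold cross-validation by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize
from sklearn.model_selection import KFold

from . import nn
from .errors import ConfigurationError, DataError, DimensionError, TrainingError
from .nn import Tensor
from .segnet import NetworkConfig, SegNet

EPS = 1e-7


@dataclass
class AugmentConfig:
    """Toggle set and ranges for paired data augmentation."""

    crop: bool = True
    hflip: bool = True
    vflip: bool = True
    scale: bool = True
    brightness: bool = True
    contrast: bool = True
    noise: bool = True
    crop_fraction: tuple[float, float] = (0.8, 1.0)
    scale_range: tuple[float, float] = (0.9, 1.1)
    brightness_delta: float = 0.1
    contrast_range: tuple[float, float] = (0.8, 1.2)
    noise_sd: float = 0.02

    @classmethod
    def none(cls) -> "AugmentConfig":
        return cls(
            crop=False, hflip=False, vflip=False, scale=False,
            brightness=False, contrast=False, noise=False,
        )


@dataclass
class TrainConfig:
    """Optimization hyperparameters.

    Defaults follow the full-scale recipe (lr 3e-4 divided by 10 after epochs
    10 and 20, batch 24, 30 epochs, 5 folds); :meth:`desk` returns a preset
    sized for CPU-scale experiments (batch 8, 15 epochs).
    """

    learning_rate: float = 3e-4
    lr_milestones: tuple[int, ...] = (10, 20)
    n_epochs: int = 30
    batch_size: int = 24
    gamma: float = 2.0
    loss_weights: tuple[float, float] = (1.0, 1.0)
    k_folds: int = 5
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be positive")
        if self.gamma <= 0:
            raise ConfigurationError("gamma must be positive")
        if self.k_folds < 2:
            raise ConfigurationError("k_folds must be >= 2")
        wf, wd = self.loss_weights
        if wf < 0 or wd < 0 or (wf == 0 and wd == 0):
            raise ConfigurationError("loss weights must be >= 0 and not both zero")

    @classmethod
    def desk(cls, **overrides) -> "TrainConfig":
        kw = dict(n_epochs=15, batch_size=8)
        kw.update(overrides)
        return cls(**kw)

    def lr_at_epoch(self, epoch: int) -> float:
        """Learning rate during 1-based ``epoch`` (drops take effect after
        each milestone epoch completes)."""
        drops = sum(1 for m in self.lr_milestones if epoch > m)
        return self.learning_rate * 0.1**drops


@dataclass
class TrainingHistory:
    epoch_loss: list[float] = field(default_factory=list)
    val_dice: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------


def _as_tensor_pair(pred, target):
    wrap = isinstance(pred, Tensor)
    p = pred if wrap else Tensor(np.asarray(pred, dtype=np.float64))
    t = target if isinstance(target, Tensor) else Tensor(np.asarray(target, dtype=p.dtype))
    if p.shape != t.shape:
        raise DimensionError(f"prediction shape {p.shape} != target shape {t.shape}")
    return p, t, wrap


def focal_loss(pred, target, gamma: float = 2.0):
    """Mean focal loss over pixels; returns a float for array inputs."""
    if gamma <= 0:
        raise ConfigurationError("gamma must be positive")
    p, y, wrap = _as_tensor_pair(pred, target)
    p = p.clip(EPS, 1.0 - EPS)
    pos = ((1.0 - p) ** gamma) * y * p.log()
    neg = (p**gamma) * (1.0 - y) * (1.0 - p).log()
    loss = -(pos + neg).mean()
    return loss if wrap else float(loss.data)


def dice_loss(pred, target, eps: float = EPS):
    """Negative Dice overlap, in [-1, 0]; -1 iff a perfect nonempty match."""
    p, y, wrap = _as_tensor_pair(pred, target)
    num = 2.0 * (y * p).sum()
    den = (y**2).sum() + (p**2).sum() + eps
    loss = -(num / den)
    return loss if wrap else float(loss.data)


def combined_loss(pred, target, config: TrainConfig):
    """w_focal * focal + w_dice * dice with the configured weights."""
    wf, wd = config.loss_weights
    p, y, wrap = _as_tensor_pair(pred, target)
    terms = []
    if wf:
        terms.append(wf * focal_loss(p, y, config.gamma))
    if wd:
        terms.append(wd * dice_loss(p, y))
    total = terms[0] if len(terms) == 1 else terms[0] + terms[1]
    return total if wrap else float(total.data)


def dice_coefficient(pred_mask: np.ndarray, target_mask: np.ndarray) -> float:
    """Plain overlap Dice between two binary masks (evaluation helper)."""
    a = np.asarray(pred_mask, bool)
    b = np.asarray(target_mask, bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------


def hflip(arr: np.ndarray) -> np.ndarray:
    return arr[:, ::-1].copy()


def vflip(arr: np.ndarray) -> np.ndarray:
    return arr[::-1, :].copy()


def _resize_pair(img, mask, shape):
    img = resize(img, shape, order=1, preserve_range=True, anti_aliasing=False)
    mask = resize(mask, shape, order=0, preserve_range=True, anti_aliasing=False)
    return img, mask.astype(mask.dtype)


def augment(
    phase_tile: np.ndarray,
    target_mask: np.ndarray,
    seed: int | np.random.Generator = 0,
    config: AugmentConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply paired augmentation; output shapes equal input shapes.

    Geometric transforms (crop, flips, scaling) hit both members with the
    same parameters; photometric transforms (brightness, contrast, Gaussian
    noise) hit the phase tile only.  Masks are interpolated nearest-neighbor
    so they stay binary.
    """
    cfg = config if config is not None else AugmentConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    img = np.asarray(phase_tile, dtype=np.float64).copy()
    mask = np.asarray(target_mask).copy()
    if img.shape != mask.shape:
        raise DimensionError("phase tile and mask must have identical shapes")
    h, w = img.shape

    if cfg.crop:
        f = rng.uniform(*cfg.crop_fraction)
        ch, cw = max(1, int(round(h * f))), max(1, int(round(w * f)))
        if ch > h or cw > w:
            raise ConfigurationError("crop larger than tile")
        r0 = rng.integers(0, h - ch + 1)
        c0 = rng.integers(0, w - cw + 1)
        img, mask = _resize_pair(img[r0 : r0 + ch, c0 : c0 + cw],
                                 mask[r0 : r0 + ch, c0 : c0 + cw], (h, w))
    if cfg.hflip and rng.random() < 0.5:
        img, mask = hflip(img), hflip(mask)
    if cfg.vflip and rng.random() < 0.5:
        img, mask = vflip(img), vflip(mask)
    if cfg.scale:
        s = rng.uniform(*cfg.scale_range)
        sh, sw = max(1, int(round(h * s))), max(1, int(round(w * s)))
        img, mask = _resize_pair(img, mask, (sh, sw))
        if s >= 1.0:  # center crop back
            r0, c0 = (sh - h) // 2, (sw - w) // 2
            img = img[r0 : r0 + h, c0 : c0 + w]
            mask = mask[r0 : r0 + h, c0 : c0 + w]
        else:  # pad back with edge values / background
            pr, pc = h - sh, w - sw
            pad = ((pr // 2, pr - pr // 2), (pc // 2, pc - pc // 2))
            img = np.pad(img, pad, mode="edge")
            mask = np.pad(mask, pad, mode="constant")
    if cfg.brightness:
        img = img + rng.uniform(-cfg.brightness_delta, cfg.brightness_delta)
    if cfg.contrast:
        c = rng.uniform(*cfg.contrast_range)
        img = img.mean() + c * (img - img.mean())
    if cfg.noise:
        img = img + cfg.noise_sd * rng.standard_normal(img.shape)
    if cfg.brightness or cfg.contrast or cfg.noise:
        img = np.clip(img, 0.0, 1.0)
    return img, mask


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


def make_folds(n_items: int, k: int = 5, seed: int = 0) -> list[tuple[np.ndarray, np.ndarray]]:
    """Disjoint, exhaustive, shuffled k-fold train/validation index splits."""
    if n_items < k:
        raise ConfigurationError(f"cannot split {n_items} items into {k} folds")
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, va) for tr, va in kf.split(np.arange(n_items))]


# ---------------------------------------------------------------------------
# the optimization loop
# ---------------------------------------------------------------------------


def _validate(model: SegNet, x_val: np.ndarray, y_val: np.ndarray, batch: int) -> float:
    scores = []
    for i in range(0, len(x_val), batch):
        probs = model.predict(x_val[i : i + batch])
        for p, y in zip(probs, y_val[i : i + batch]):
            scores.append(dice_coefficient(p > 0.5, y[0] > 0.5))
    return float(np.mean(scores))


def train(
    dataset: tuple[np.ndarray, np.ndarray],
    net_config: NetworkConfig | None = None,
    train_config: TrainConfig | None = None,
    val_dataset: tuple[np.ndarray, np.ndarray] | None = None,
    model: SegNet | None = None,
) -> tuple[SegNet, TrainingHistory]:
    """Minibatch Adam optimization of the combined focal+Dice loss.

    ``dataset`` is ``(x, y)`` with x of shape (N, H, W) or (N, 1, H, W) in
    [0, 1] and y binary of the same geometry.  Augmentation is applied
    on-the-fly per sample; validation Dice (threshold 0.5) is recorded per
    epoch when ``val_dataset`` is given.
    """
    net_config = net_config if net_config is not None else NetworkConfig()
    cfg = train_config if train_config is not None else TrainConfig()

    x, y = dataset
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.ndim == 3:
        x, y = x[:, None], y[:, None]
    n = x.shape[0]
    if n == 0:
        raise DataError("empty training dataset")
    if cfg.batch_size > n:
        raise DataError(f"batch_size {cfg.batch_size} exceeds dataset size {n}")

    if model is None:
        if net_config.norm == "batch" and cfg.batch_size < 8:
            # degenerate batch statistics: fall back to group normalization
            net_config = NetworkConfig(**{**net_config.__dict__, "norm": "group"})
        model = SegNet(net_config)
    model.train()

    opt = nn.Adam(model.parameters(), lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)
    history = TrainingHistory()

    for epoch in range(1, cfg.n_epochs + 1):
        opt.lr = cfg.lr_at_epoch(epoch)
        order = rng.permutation(n)
        losses = []
        for start in range(0, n - cfg.batch_size + 1, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb = np.empty((len(idx), 1, x.shape[2], x.shape[3]), dtype=nn.DEFAULT_DTYPE)
            yb = np.empty_like(xb)
            for j, i in enumerate(idx):
                xi, yi = augment(x[i, 0], y[i, 0], rng, cfg.augment)
                xb[j, 0], yb[j, 0] = xi, yi
            pred = model(Tensor(xb))
            loss = combined_loss(pred, Tensor(yb), cfg)
            if not np.isfinite(loss.data):
                raise TrainingError(f"non-finite loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history.epoch_loss.append(float(np.mean(losses)))
        history.lr.append(opt.lr)
        if val_dataset is not None:
            xv, yv = val_dataset
            xv = np.asarray(xv, dtype=np.float64)
            yv = np.asarray(yv, dtype=np.float64)
            if xv.ndim == 3:
                xv, yv = xv[:, None], yv[:, None]
            history.val_dice.append(_validate(model, xv, yv, cfg.batch_size))
            model.train()
    model.eval()
    return model, history
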