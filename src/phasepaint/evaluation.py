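"""Virtual-painting fidelity metrics and paired statistics.

Four per-image scores compare a generated channel with its ground-truth
fluorescent image, all on the 0-255 intensity scale:

* Dice and Recall over a tolerance-based pixel classification: a generated
  signal pixel is a true positive when the ground truth is also signal there
  and the two intensities differ by at most ``tolerance`` gray levels
  (default 2 on 0-255); otherwise it is a false positive, and unmatched
  ground-truth signal pixels are false negatives.
* SSIM with the canonical Gaussian-weighted window (sigma 1.5, 11x11 kernel,
  K1=0.01, K2=0.03, population covariance).
* Pixel-wise MSE on intensities rescaled to [0, 1].

Per-image score vectors from two methods are compared with the two-sided
Wilcoxon signed-rank test (exact null distribution for n <= 25).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skimage.metrics import structural_similarity
from sklearn.metrics import mean_squared_error

from .errors import ConfigurationError, DimensionError
from .imaging_io import ChannelSpec, RasterImage

DEFAULT_TOLERANCE = 2


def _to_levels(img) -> np.ndarray:
    """Coerce an image to float intensities on the 0-255 scale."""
    if isinstance(img, RasterImage):
        return img.to_float() * 255.0
    arr = np.asarray(img, dtype=np.float64)
    if arr.max(initial=0.0) <= 1.0 and arr.dtype.kind == "f":
        return arr * 255.0
    return arr


@dataclass
class PixelClassification:
    """TP/FP/FN pixel counts under the intensity-tolerance matching rule."""

    tp: int
    fp: int
    fn: int
    tolerance: int = DEFAULT_TOLERANCE


def classify_pixels(
    generated,
    truth,
    spec: ChannelSpec | None = None,
    tolerance: int = DEFAULT_TOLERANCE,
    threshold: float | None = None,
    rule: str = "tolerance",
) -> PixelClassification:
    """Classify each generated pixel as TP, FP, or FN.

    Signal pixels are those above the background threshold (from ``spec`` or
    ``threshold``, on the 0-255 scale; default 0 = any nonzero intensity).
    Under the primary ``"tolerance"`` rule a TP additionally requires the two
    intensities to agree within ``tolerance`` gray levels; ``"overlap"``
    counts plain mask overlap.
    """
    if rule not in ("tolerance", "overlap"):
        raise ConfigurationError(f"unknown classification rule {rule!r}")
    g = _to_levels(generated)
    t = _to_levels(truth)
    if g.shape != t.shape:
        raise DimensionError(f"shape mismatch: {g.shape} vs {t.shape}")
    thr = 0.0
    if threshold is not None:
        thr = float(threshold)
    elif spec is not None and spec.background_threshold is not None:
        thr = float(spec.background_threshold)
    g_sig = g > thr
    t_sig = t > thr
    if rule == "overlap":
        close = np.ones_like(g_sig)
    else:
        close = np.abs(g - t) <= tolerance
    tp = g_sig & t_sig & close
    fp = g_sig & ~tp
    fn = t_sig & ~tp
    return PixelClassification(
        tp=int(tp.sum()), fp=int(fp.sum()), fn=int(fn.sum()), tolerance=tolerance
    )


def dice_score(c: PixelClassification) -> float | None:
    """2TP / (2TP + FP + FN); None when undefined (no pixels in play)."""
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:
        return None
    return 2.0 * c.tp / denom


def recall_score(c: PixelClassification) -> float | None:
    """TP / (TP + FN); None when the ground truth has no signal."""
    denom = c.tp + c.fn
    if denom == 0:
        return None
    return c.tp / denom


def ssim_score(generated, truth, data_range: float = 255.0) -> float:
    """Mean SSIM with the canonical Gaussian-weighted window."""
    g = _to_levels(generated)
    t = _to_levels(truth)
    if g.shape != t.shape:
        raise DimensionError(f"shape mismatch: {g.shape} vs {t.shape}")
    return float(
        structural_similarity(
            g,
            t,
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
            data_range=data_range,
        )
    )


def mse_score(generated, truth) -> float:
    """Mean squared error on intensities rescaled to [0, 1]."""
    g = _to_levels(generated) / 255.0
    t = _to_levels(truth) / 255.0
    if g.shape != t.shape:
        raise DimensionError(f"shape mismatch: {g.shape} vs {t.shape}")
    return float(mean_squared_error(t.ravel(), g.ravel()))


# ---------------------------------------------------------------------------
# paired statistics
# ---------------------------------------------------------------------------


@dataclass
class PairedTestResult:
    p_value: float | None
    statistic: float | None
    degenerate: bool = False


def paired_test(scores_a, scores_b) -> PairedTestResult:
    """Two-sided Wilcoxon signed-rank test on paired per-image scores.

    Uses the exact null distribution for n <= 25 pairs and the normal
    approximation beyond.  All-tied inputs are flagged as degenerate rather
    than assigned a p-value.
    """
    a = np.asarray(scores_a, dtype=np.float64)
    b = np.asarray(scores_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise DimensionError("paired score vectors must be 1-D and equal length")
    if len(a) < 5:
        raise ConfigurationError("need at least 5 pairs for the signed-rank test")
    diffs = a - b
    if np.all(diffs == 0):
        return PairedTestResult(p_value=None, statistic=None, degenerate=True)
    method = "exact" if len(a) <= 25 else "approx"
    res = stats.wilcoxon(a, b, alternative="two-sided", method=method)
    return PairedTestResult(p_value=float(res.pvalue), statistic=float(res.statistic))


# ---------------------------------------------------------------------------
# dataset-level reports
# ---------------------------------------------------------------------------

METRIC_COLUMNS = ("dice", "recall", "ssim", "mse")


@dataclass
class MetricsReport:
    """Per-image metric table plus per-channel summary statistics."""

    scores: pd.DataFrame  # columns: image, channel, dice, recall, ssim, mse

    @property
    def n_images(self) -> int:
        return self.scores["image"].nunique()

    def summary(self) -> pd.DataFrame:
        return self.scores.groupby("channel")[list(METRIC_COLUMNS)].agg(
            ["mean", "std"]
        )

    def to_csv(self, path) -> None:
        self.scores.to_csv(path, index=False)


def evaluate_pair(
    generated,
    truth,
    spec: ChannelSpec | None = None,
    tolerance: int = DEFAULT_TOLERANCE,
    threshold: float | None = None,
) -> dict:
    c = classify_pixels(generated, truth, spec, tolerance, threshold)
    return {
        "dice": dice_score(c),
        "recall": recall_score(c),
        "ssim": ssim_score(generated, truth),
        "mse": mse_score(generated, truth),
    }


def evaluate_dataset(
    pairs,
    spec: ChannelSpec | None = None,
    tolerance: int = DEFAULT_TOLERANCE,
    threshold: float | None = None,
) -> MetricsReport:
    """Score a collection of ``(generated, truth)`` pairs for one channel."""
    pairs = list(pairs)
    if not pairs:
        raise ConfigurationError("evaluate_dataset requires at least one pair")
    channel = spec.channel_name if spec is not None else "unknown"
    rows = []
    for i, (gen, tru) in enumerate(pairs):
        row = {"image": i, "channel": channel}
        row.update(evaluate_pair(gen, tru, spec, tolerance, threshold))
        rows.append(row)
    return MetricsReport(scores=pd.DataFrame(rows))
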