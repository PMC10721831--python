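"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as explicit per-pixel Python loops with no shared
code with the package, so agreement is evidence of correctness rather than
tautology.
"""

import math

import numpy as np


def classify_loop(g, t, threshold=0.0, tolerance=2):
    """Pixel-loop TP/FP/FN classification on 0-255 images."""
    tp = fp = fn = 0
    for i in range(g.shape[0]):
        for j in range(g.shape[1]):
            gs = g[i, j] > threshold
            ts = t[i, j] > threshold
            match = gs and ts and abs(float(g[i, j]) - float(t[i, j])) <= tolerance
            if match:
                tp += 1
            else:
                if gs:
                    fp += 1
                if ts:
                    fn += 1
    return tp, fp, fn


def dice_loop(tp, fp, fn):
    d = 2 * tp + fp + fn
    return None if d == 0 else 2.0 * tp / d


def recall_loop(tp, fn):
    d = tp + fn
    return None if d == 0 else tp / d


def mse_loop(g, t):
    """Mean squared error on [0,1]-rescaled 0-255 images, scalar loop."""
    acc = 0.0
    for i in range(g.shape[0]):
        for j in range(g.shape[1]):
            acc += ((float(g[i, j]) - float(t[i, j])) / 255.0) ** 2
    return acc / g.size


def _gaussian_kernel(sigma=1.5, truncate=3.5):
    r = int(truncate * sigma + 0.5)
    k = [math.exp(-0.5 * (x / sigma) ** 2) for x in range(-r, r + 1)]
    s = sum(k)
    k1 = [v / s for v in k]
    return np.outer(k1, k1), r


def ssim_loop(g, t, data_range=255.0, sigma=1.5):
    """Mean Gaussian-weighted SSIM by explicit window loops.

    Uses the canonical truncated Gaussian window (radius 5 at sigma 1.5),
    symmetric boundary handling, population (weighted) covariance, and
    averages the SSIM map with the filter-radius strip cropped away.
    """
    K, r = _gaussian_kernel(sigma)
    gp = np.pad(np.asarray(g, float), r, mode="symmetric")
    tp_ = np.pad(np.asarray(t, float), r, mode="symmetric")
    C1 = (0.01 * data_range) ** 2
    C2 = (0.03 * data_range) ** 2
    h, w = g.shape
    S = np.empty((h, w))
    for i in range(h):
        for j in range(w):
            wg = gp[i : i + 2 * r + 1, j : j + 2 * r + 1]
            wt = tp_[i : i + 2 * r + 1, j : j + 2 * r + 1]
            ux = (wg * K).sum()
            uy = (wt * K).sum()
            vx = (wg * wg * K).sum() - ux * ux
            vy = (wt * wt * K).sum() - uy * uy
            vxy = (wg * wt * K).sum() - ux * uy
            S[i, j] = ((2 * ux * uy + C1) * (2 * vxy + C2)) / (
                (ux**2 + uy**2 + C1) * (vx + vy + C2)
            )
    pad = r
    return S[pad : h - pad, pad : w - pad].mean()


def focal_loop(pred, target, gamma, eps=1e-7):
    """Scalar-loop focal loss with mean reduction."""
    p = pred.ravel()
    y = target.ravel()
    acc = 0.0
    for pi, yi in zip(p, y):
        pi = min(max(float(pi), eps), 1.0 - eps)
        acc -= (1.0 - pi) ** gamma * yi * math.log(pi) + pi**gamma * (
            1.0 - yi
        ) * math.log(1.0 - pi)
    return acc / len(p)


def dice_loss_loop(pred, target, eps=1e-7):
    """Scalar-loop negative-Dice loss."""
    num = den_y = den_p = 0.0
    for pi, yi in zip(pred.ravel(), target.ravel()):
        num += float(yi) * float(pi)
        den_y += float(yi) ** 2
        den_p += float(pi) ** 2
    return -(2.0 * num) / (den_y + den_p + eps)


def signed_rank_exact_p(diffs):
    """Exact two-sided signed-rank p-value by enumerating all sign vectors."""
    d = [x for x in diffs if x != 0]
    n = len(d)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_obs = sum(r for r, x in zip(ranks, d) if x > 0)
    count = 0
    total = 2**n
    stats = []
    for bits in range(total):
        w = sum(ranks[i] for i in range(n) if (bits >> i) & 1)
        stats.append(w)
    mean_w = n * (n + 1) / 4.0
    obs_dev = abs(w_obs - mean_w)
    count = sum(1 for w in stats if abs(w - mean_w) >= obs_dev - 1e-12)
    return count / total
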