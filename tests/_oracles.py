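"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately written as plain Python loops over pixels /
samples, sharing no code path with the package, so agreement is meaningful.
"""

from __future__ import annotations

import math

import numpy as np


def gray(px) -> float:
    r, g, b = px
    return (float(r) + float(g) + float(b)) / 3.0


def mean_intensity_loop(region) -> float:
    return sum(gray(px) for px in region) / len(region)


def mean_rg_ratio_loop(region) -> float:
    mr = sum(float(px[0]) for px in region) / len(region)
    mg = sum(float(px[1]) for px in region) / len(region)
    return mr / mg


def mean_rg_diff_loop(region) -> float:
    mr = sum(float(px[0]) for px in region) / len(region)
    mg = sum(float(px[1]) for px in region) / len(region)
    return mr - mg


def std_intensity_loop(region) -> float:
    vals = [gray(px) for px in region]
    mu = sum(vals) / len(vals)
    return math.sqrt(sum((v - mu) ** 2 for v in vals) / len(vals))


def entropy_loop(region) -> float:
    counts = [0] * 256
    for px in region:
        counts[int(math.floor(gray(px) + 0.5))] += 1
    n = len(region)
    h = 0.0
    for c in counts:
        if c > 0:
            p = c / n
            h -= p * math.log2(p)
    return h


def hsi_pixel(px):
    """HSI of one 8-bit RGB pixel: (hue degrees, saturation, intensity)."""
    r, g, b = (float(v) for v in px)
    total = r + g + b
    i = total / (3 * 255.0)
    if total == 0:
        return 0.0, 0.0, 0.0
    s = 1.0 - 3.0 * min(r, g, b) / total
    if s <= 0:
        return 0.0, 0.0, i
    num = 0.5 * ((r - g) + (r - b))
    den = math.sqrt((r - g) ** 2 + (r - b) * (g - b))
    theta = math.degrees(math.acos(max(-1.0, min(1.0, num / den)))) if den > 0 else 0.0
    h = 360.0 - theta if b > g else theta
    if h >= 360.0:
        h = 0.0
    return h, s, i


def high_hue_ratio_loop(region, tau_h: float = 300.0) -> float:
    hits = 0
    for px in region:
        h, s, _ = hsi_pixel(px)
        if s > 0 and h >= tau_h:
            hits += 1
    return hits / len(region)


def red_pixel_pct_loop(region, delta: float = 70.0) -> float:
    hits = 0
    for px in region:
        r, g, b = (float(v) for v in px)
        if r > g and r > b and r - max(g, b) >= delta:
            hits += 1
    return hits / len(region)


def auc_trapezoid(y_true, scores) -> float:
    """ROC AUC by an exhaustive threshold sweep and trapezoidal integration.

    Thresholds are every distinct score (plus sentinels); a point (FPR, TPR)
    is produced per threshold and the polyline is integrated.
    """
    y_true = np.asarray(y_true, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(y_true.sum())
    n_neg = int((~y_true).sum())
    thresholds = np.unique(scores)[::-1]
    pts = [(0.0, 0.0)]
    for t in thresholds:
        pred = scores >= t
        tpr = (pred & y_true).sum() / n_pos
        fpr = (pred & ~y_true).sum() / n_neg
        pts.append((float(fpr), float(tpr)))
    pts.append((1.0, 1.0))
    area = 0.0
    for (x0, y0), (x1, y1) in zip(pts, pts[1:]):
        area += (x1 - x0) * (y0 + y1) / 2.0
    return area


def nearest_center_assignment(points, centers):
    """Exhaustive nearest-centroid assignment (squared Euclidean, ties → lowest)."""
    out = []
    for p in points:
        d2 = [sum((pi - ci) ** 2 for pi, ci in zip(p, c)) for c in centers]
        out.append(int(np.argmin(d2)))
    return np.asarray(out)
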