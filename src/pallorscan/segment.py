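"""Conjunctiva localization and segmentation.

The segmentation route mirrors field practice for pallor imaging: localize a
region of interest around the (reddish) palpebral conjunctiva, then cluster
the ROI's pixels by color with K-means in the CIELAB a*b* plane and keep the
reddest cluster as the conjunctiva mask.  Luminance (L*) is excluded from
clustering: the a*/b* chroma plane carries all of the color information that
separates vascular tissue from sclera and skin, while L* mostly encodes
illumination.

An external detector or segmenter (e.g. a trained object detector or a
promptable segmentation model) can replace either stage: bounding boxes and
binary PNG masks are ingested through :func:`crop` and
:func:`load_external_mask`.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from PIL import Image, UnidentifiedImageError

from .errors import (
    BoundsError,
    DetectionError,
    EmptyRegionError,
    ImageFormatError,
    MaskAlignmentError,
    ValidationError,
)
from .imgio import rgb_to_lab

__all__ = [
    "BoundingBox",
    "ClusterModel",
    "detect_roi_baseline",
    "crop",
    "kmeans_ab",
    "select_conjunctiva_cluster",
    "load_external_mask",
    "apply_mask",
]


@dataclass(frozen=True)
class BoundingBox:
    """Half-open pixel box: columns [x_min, x_max), rows [y_min, y_max)."""

    x_min: int
    y_min: int
    x_max: int
    y_max: int

    def __post_init__(self) -> None:
        if not (0 <= self.x_min < self.x_max and 0 <= self.y_min < self.y_max):
            raise BoundsError(f"degenerate bounding box {self}")

    @property
    def width(self) -> int:
        return self.x_max - self.x_min

    @property
    def height(self) -> int:
        return self.y_max - self.y_min


@dataclass
class ClusterModel:
    """Result of K-means in the a*b* plane.

    ``assignment`` maps every pixel to the index of its nearest centroid
    (Euclidean distance in (a*, b*)); ``objective_history`` records the sum of
    squared distances after each Lloyd iteration and is non-increasing.
    """

    k: int
    centroids: np.ndarray  # (k, 2) float64, (a*, b*)
    assignment: np.ndarray  # (H, W) int32
    counts: np.ndarray  # (k,) int64 pixels per cluster
    objective_history: list = field(default_factory=list)


def detect_roi_baseline(
    img: np.ndarray,
    *,
    percentile: float = 80.0,
    min_a_star: float = 5.0,
    margin: int = 0,
) -> BoundingBox:
    """Baseline conjunctiva detector: tight box of the reddest pixels.

    A pixel passes the redness prior when its a* value (CIELAB) strictly
    exceeds both the image's ``percentile``-th a* percentile and the absolute
    floor ``min_a_star`` (which keeps noisy gray images from "detecting"
    noise).  Isolated noise pixels inevitably pass a percentile threshold, so
    the detector keeps only the largest 8-connected component of passing
    pixels; its tight box is padded by ``margin`` pixels and clipped to the
    image bounds.

    Raises
    ------
    DetectionError
        If no pixel passes the prior.
    """
    from skimage import measure

    lab = rgb_to_lab(img)
    a = lab[..., 1]
    thr = max(float(np.percentile(a, percentile)), float(min_a_star))
    passing = a > thr
    if not passing.any():
        raise DetectionError("no pixel passes the conjunctiva redness prior")
    labels = measure.label(passing, connectivity=2)
    largest = int(np.argmax(np.bincount(labels.ravel())[1:])) + 1
    rows, cols = np.nonzero(labels == largest)
    h, w = a.shape
    return BoundingBox(
        x_min=max(int(cols.min()) - margin, 0),
        y_min=max(int(rows.min()) - margin, 0),
        x_max=min(int(cols.max()) + 1 + margin, w),
        y_max=min(int(rows.max()) + 1 + margin, h),
    )


def crop(img: np.ndarray, box: BoundingBox) -> np.ndarray:
    """Extract the sub-image under ``box``; pixels are copied unmodified."""
    h, w = img.shape[:2]
    if box.x_max > w or box.y_max > h:
        raise BoundsError(f"box {box} exceeds image bounds {w}x{h}")
    return img[box.y_min : box.y_max, box.x_min : box.x_max].copy()


def _kmeans_pp_init(points: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding (D^2 weighting) over (n, 2) points."""
    n = points.shape[0]
    centers = np.empty((k, 2), dtype=np.float64)
    centers[0] = points[rng.integers(n)]
    d2 = np.sum((points - centers[0]) ** 2, axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total <= 0:  # all points coincide with chosen centers
            centers[j] = points[rng.integers(n)]
            continue
        centers[j] = points[rng.choice(n, p=d2 / total)]
        d2 = np.minimum(d2, np.sum((points - centers[j]) ** 2, axis=1))
    return centers


def _lloyd(points: np.ndarray, k: int, rng: np.random.Generator, max_iter: int):
    """One Lloyd run from a k-means++ seeding; returns (centers, assign, history)."""
    n = points.shape[0]
    centers = _kmeans_pp_init(points, k, rng)
    assign = np.full(n, -1, dtype=np.int32)
    history: list[float] = []
    for _ in range(max_iter):
        # squared Euclidean distance to each center, (n, k)
        d2 = ((points[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        new_assign = np.argmin(d2, axis=1).astype(np.int32)
        history.append(float(d2[np.arange(n), new_assign].sum()))
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
        for j in range(k):
            members = points[assign == j]
            if members.shape[0] == 0:
                # re-seed to the point farthest from its current centroid
                far = int(np.argmax(d2[np.arange(n), assign]))
                centers[j] = points[far]
            else:
                centers[j] = members.mean(axis=0)
    return centers, assign, history


def kmeans_ab(
    img_lab: np.ndarray,
    k: int = 3,
    seed: int = 0,
    *,
    max_iter: int = 300,
    n_init: int = 8,
) -> ClusterModel:
    """Lloyd's K-means on the per-pixel (a*, b*) chroma pairs.

    Each of the ``n_init`` restarts is k-means++-seeded from a stream derived
    deterministically from ``seed`` and iterates assignment/update until the
    assignment reaches a fixed point or ``max_iter`` iterations; the restart
    with the lowest final objective wins (ties: first).  Restarts matter
    here: the conjunctiva is small but chromatically extreme, so a single
    k-means++ draw can place two seeds inside it and Lloyd then sticks in a
    local optimum that splits it.  An empty cluster is re-seeded to the point
    farthest from its assigned centroid.  The same seed yields a
    bit-identical model.
    """
    img_lab = np.asarray(img_lab, dtype=np.float64)
    if img_lab.ndim != 3 or img_lab.shape[2] != 3:
        raise ImageFormatError(f"expected (H, W, 3) Lab array, got {img_lab.shape}")
    h, w = img_lab.shape[:2]
    points = img_lab[..., 1:3].reshape(-1, 2)
    n = points.shape[0]
    if k < 1:
        raise ValidationError("k must be >= 1")
    if k > n:
        raise ValidationError(f"k={k} exceeds pixel count {n}")

    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(int(n_init), 1)):
        centers, assign, history = _lloyd(points, k, rng, max_iter)
        if best is None or history[-1] < best[2][-1]:
            best = (centers, assign, history)
    centers, assign, history = best

    counts = np.bincount(assign, minlength=k).astype(np.int64)
    return ClusterModel(
        k=k,
        centroids=centers.copy(),
        assignment=assign.reshape(h, w),
        counts=counts,
        objective_history=history,
    )


def select_conjunctiva_cluster(model: ClusterModel) -> np.ndarray:
    """Mask of the reddest cluster (maximum centroid a*).

    Exact a* ties are broken by larger pixel count, then lower cluster index.
    Returns a boolean ``(H, W)`` mask.
    """
    a_star = model.centroids[:, 0]
    best = max(
        range(model.k), key=lambda j: (a_star[j], model.counts[j], -j)
    )
    return model.assignment == best


def load_external_mask(path: str | os.PathLike, img: np.ndarray) -> np.ndarray:
    """Read a single-channel PNG mask aligned to ``img``; nonzero → True."""
    try:
        with Image.open(path) as im:
            if im.mode not in ("L", "1", "I", "I;16", "P"):
                raise ImageFormatError(
                    f"mask must be single-channel, got mode {im.mode!r}: {path}"
                )
            arr = np.asarray(im.convert("I"))
    except UnidentifiedImageError as exc:
        raise ImageFormatError(f"not a decodable mask image: {path}") from exc
    if arr.shape != img.shape[:2]:
        raise MaskAlignmentError(
            f"mask shape {arr.shape} does not match image {img.shape[:2]}"
        )
    return arr != 0


def apply_mask(img: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Collect the region's (R, G, B) pixels in scan (row-major) order.

    Returns an ``(N, 3)`` uint8 array; ``N`` is the region pixel count.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != img.shape[:2]:
        raise MaskAlignmentError(
            f"mask shape {mask.shape} does not match image {img.shape[:2]}"
        )
    region = img[mask]
    if region.shape[0] == 0:
        raise EmptyRegionError("mask selects no pixels; features are undefined")
    return region
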