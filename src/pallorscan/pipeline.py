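"""End-to-end screening pipeline: image file → predicted anemia class.

Chains ROI detection, crop, a*b* K-means segmentation (or an external mask),
feature extraction and MLP prediction.  Errors are re-raised with a stage
tag (``[detect] ...``, ``[segment] ...``) so a batch driver can report where
an image failed.
"""

from __future__ import annotations

from contextlib import contextmanager
from dataclasses import dataclass
from datetime import datetime, timezone

import numpy as np

from .errors import PallorscanError
from .features import (
    DEFAULT_DELTA_RED,
    DEFAULT_TAU_H,
    FeatureVector,
    extract_feature_vector,
)
from .imgio import read_image, rgb_to_lab
from .segment import (
    BoundingBox,
    crop,
    detect_roi_baseline,
    kmeans_ab,
    load_external_mask,
    select_conjunctiva_cluster,
)

__all__ = ["StageError", "segment_conjunctiva", "extract_from_image", "run_screening"]


class StageError(PallorscanError):
    """A pipeline failure tagged with the stage that raised it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.cause = cause


@contextmanager
def _stage(name: str):
    try:
        yield
    except PallorscanError as exc:
        raise StageError(name, exc) from exc


def segment_conjunctiva(
    img: np.ndarray, *, k: int = 3, seed: int = 0, roi_margin: int = 12
) -> tuple[np.ndarray, BoundingBox]:
    """Detect the ROI and segment the conjunctiva by a*b* K-means.

    Returns the boolean conjunctiva mask in full-image coordinates together
    with the detected bounding box.
    """
    with _stage("detect"):
        box = detect_roi_baseline(img, margin=roi_margin)
    roi = crop(img, box)
    with _stage("segment"):
        model = kmeans_ab(rgb_to_lab(roi), k=k, seed=seed)
        roi_mask = select_conjunctiva_cluster(model)
    mask = np.zeros(img.shape[:2], dtype=bool)
    mask[box.y_min : box.y_max, box.x_min : box.x_max] = roi_mask
    return mask, box


def extract_from_image(
    img: np.ndarray,
    *,
    mask: np.ndarray | None = None,
    k: int = 3,
    seed: int = 0,
    tau_h: float = DEFAULT_TAU_H,
    delta_red: float = DEFAULT_DELTA_RED,
) -> tuple[FeatureVector, np.ndarray]:
    """Feature vector of an image, segmenting with K-means unless a mask is given."""
    if mask is None:
        mask, _ = segment_conjunctiva(img, k=k, seed=seed)
    with _stage("features"):
        fv = extract_feature_vector(img, mask, tau_h=tau_h, delta_red=delta_red)
    return fv, mask


def feature_table(
    manifest,
    *,
    k: int = 3,
    seed: int = 0,
    mask_source: str = "kmeans",
    mask_dir: str | None = None,
    tau_h: float = DEFAULT_TAU_H,
    delta_red: float = DEFAULT_DELTA_RED,
) -> "pd.DataFrame":
    """Feature rows for every manifest record.

    ``manifest`` is a DataFrame with at least ``image_path``, ``label`` and
    ``lighting`` columns (the schema written by the synthetic generator).
    With ``mask_source="kmeans"`` each image is segmented by the baseline
    ROI + a*b* K-means route; with ``"external"`` a same-named single-channel
    PNG from ``mask_dir`` is used instead.  Per-image K-means seeds are
    derived deterministically from ``seed``.
    """
    import os

    import pandas as pd

    from .segment import load_external_mask
    from .synth import load_record_image

    if mask_source not in ("kmeans", "external"):
        raise ValueError(f"mask_source must be 'kmeans' or 'external', got {mask_source!r}")
    rows = []
    for i, rec in enumerate(manifest.to_dict("records")):
        img = load_record_image(rec)
        ext = None
        if mask_source == "external":
            name = os.path.splitext(os.path.basename(rec["image_path"]))[0] + ".png"
            ext = load_external_mask(os.path.join(mask_dir or "", name), img)
        fv, _ = extract_from_image(
            img, mask=ext, k=k, seed=(seed + 7919 * i) % (2**31),
            tau_h=tau_h, delta_red=delta_red,
        )
        row = {"image_path": rec["image_path"], "label": rec.get("label")}
        row.update({name: getattr(fv, name) for name in fv.__dataclass_fields__})
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ScreeningResult:
    record_id: str
    predicted_label: str
    probability: float  # probability of the predicted class
    probabilities: tuple  # all three, in canonical class order
    features: FeatureVector
    latitude: float | None = None
    longitude: float | None = None
    timestamp: str = ""


def run_screening(
    image_path: str,
    model,
    *,
    record_id: str | None = None,
    mask_path: str | None = None,
    k: int = 3,
    seed: int = 0,
    latitude: float | None = None,
    longitude: float | None = None,
) -> ScreeningResult:
    """Screen one image file with a trained model.

    When ``mask_path`` is given the K-means stage is skipped and the external
    binary mask is used directly, so features equal a direct
    :func:`~pallorscan.features.extract_feature_vector` call on that mask.
    """
    from .classify import predict_class

    with _stage("read"):
        img = read_image(image_path)
    ext_mask = None
    if mask_path is not None:
        with _stage("mask"):
            ext_mask = load_external_mask(mask_path, img)
    fv, _ = extract_from_image(img, mask=ext_mask, k=k, seed=seed)
    with _stage("predict"):
        label, probs = predict_class(model, fv)
    return ScreeningResult(
        record_id=record_id or image_path,
        predicted_label=label,
        probability=float(probs.max()),
        probabilities=tuple(float(p) for p in probs),
        features=fv,
        latitude=latitude,
        longitude=longitude,
        timestamp=datetime.now(timezone.utc).isoformat(timespec="seconds"),
    )
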