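"""Synthetic eye-image generator.

Renders labeled conjunctiva images whose statistical structure emulates the
kind of dataset a pallor-screening study collects: a skin-tone background, a
pale sclera ellipse, and a lower-lid conjunctiva crescent whose color
encodes the anemia class.  Physiologically, pallor is reduced capillary
perfusion: the anemic conjunctiva drifts from saturated vascular red toward
pale pink.  The class color model reproduces that ordering — redness
(red-green separation) decreases and the tissue pales from normal through
moderate to anemic — so threshold-based redness features (red-pixel
percentage, high-hue ratio) decrease monotonically with severity.

Each render carries its exact ground-truth conjunctiva mask, and each record
a hemoglobin value drawn uniformly inside its class's sex-specific grading
interval, so the label is re-derivable from (sex, hb) by construction.

The generator is deliberately simple: no eyelashes, specular highlights,
motion blur, or camera optics.  Renders are deterministic given a seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .imgio import LIGHTING_PRESETS, apply_white_balance, write_image
from PIL import Image

__all__ = ["SyntheticSpec", "render_eye_image", "sample_records", "generate_dataset"]

#: Default study-scale class counts for the three-class screening problem.
DEFAULT_COUNTS = {"anemic": 132, "moderate": 169, "normal": 310}

#: Mean conjunctiva RGB per class.  Red-green separation falls 130 → 95 → 75
#: from normal to anemic (loss of vascular red), while the blue excess over
#: green falls 12 → 5 → 2, moving the dominant hue from the red-magenta band
#: toward neutral pink.
CLASS_COLORS = {
    "normal": (190.0, 60.0, 72.0),
    "moderate": (195.0, 100.0, 105.0),
    "anemic": (200.0, 125.0, 127.0),
}

#: Uniform Hb sampling intervals (g/dL) per class and sex, strictly inside
#: the grading bands so sampled labels always re-derive to the class.
HB_RANGES = {
    ("anemic", "male"): (6.0, 10.45),
    ("anemic", "female"): (6.0, 10.45),
    ("moderate", "male"): (10.5, 13.5),
    ("moderate", "female"): (10.5, 12.0),
    ("normal", "male"): (13.55, 17.5),
    ("normal", "female"): (12.05, 15.5),
}

_SKIN = np.array([206.0, 176.0, 128.0])
_SCLERA = np.array([242.0, 238.0, 225.0])


@dataclass(frozen=True)
class SyntheticSpec:
    """Configuration of the synthetic study dataset."""

    n_per_class: dict = field(default_factory=lambda: dict(DEFAULT_COUNTS))
    image_size: tuple[int, int] = (256, 256)  # (height, width)
    class_colors: dict = field(default_factory=lambda: dict(CLASS_COLORS))
    noise_sigma: float = 8.0
    color_jitter_sigma: float = 3.0  # per-image jitter of the class mean
    illumination: tuple[float, float] = (1.05, 0.95)  # top, bottom gain
    male_fraction: float = 24.0 / 54.0  # study sex ratio
    hb_ranges: dict = field(default_factory=lambda: dict(HB_RANGES))
    mask_area_bounds: tuple[float, float] = (0.03, 0.15)
    lighting: str = "daylight"  # a preset name, or "all" for six-fold augment
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.n_per_class.values()):
            raise ConfigError("class counts must be >= 0")
        if self.lighting != "all" and self.lighting not in LIGHTING_PRESETS:
            raise ConfigError(f"unknown lighting {self.lighting!r}")


def _ellipse_mask(h, w, cy, cx, ry, rx):
    yy, xx = np.ogrid[:h, :w]
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def render_eye_image(
    class_label: str, spec: SyntheticSpec = SyntheticSpec(), seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Render one eye image and its ground-truth conjunctiva mask.

    The scene is composed of three color regions (skin, sclera, lower-lid
    conjunctiva crescent) with per-image jitter of geometry and mean color,
    i.i.d. Gaussian pixel noise, and a mild vertical illumination gradient.
    Returns ``(image_uint8, mask_bool)``; bit-identical for the same seed.
    """
    if class_label not in spec.class_colors:
        raise ConfigError(f"unknown class {class_label!r}")
    h, w = spec.image_size
    rng = np.random.default_rng(seed)

    # geometry, jittered per image
    jy, jx = rng.integers(-4, 5, size=2)
    sclera = _ellipse_mask(h, w, 0.41 * h + jy, 0.50 * w + jx, 0.215 * h, 0.37 * w)
    scale = rng.uniform(0.92, 1.08)
    cy, cx = 0.685 * h + jy, 0.50 * w + jx
    conj_ellipse = _ellipse_mask(h, w, cy, cx, 0.095 * h * scale, 0.31 * w * scale)
    yy = np.arange(h)[:, None]
    conj = conj_ellipse & np.broadcast_to(yy > cy - 0.055 * h, (h, w))  # lower crescent
    sclera = sclera & ~conj

    base = np.empty((h, w, 3), dtype=np.float64)
    base[:] = _SKIN + rng.normal(0, spec.color_jitter_sigma, 3)
    base[sclera] = _SCLERA + rng.normal(0, spec.color_jitter_sigma, 3)
    base[conj] = np.asarray(spec.class_colors[class_label]) + rng.normal(
        0, spec.color_jitter_sigma, 3
    )

    top, bottom = spec.illumination
    gain = np.linspace(top, bottom, h)[:, None, None]
    img = base * gain + rng.normal(0, spec.noise_sigma, size=(h, w, 3))
    img = np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8)

    frac = conj.sum() / (h * w)
    lo, hi = spec.mask_area_bounds
    if not (lo <= frac <= hi):
        raise ConfigError(
            f"conjunctiva mask covers {frac:.1%} of the image, outside [{lo:.0%}, {hi:.0%}]"
        )
    return img, conj


def sample_records(spec: SyntheticSpec = SyntheticSpec(), seed: int | None = None) -> pd.DataFrame:
    """Sample the dataset manifest (no pixels): one row per base image.

    Columns: subject_id, sex, hb_g_dl, label, lighting, render_seed.  Hb is
    uniform inside the class/sex grading interval, sex Bernoulli with the
    study's male fraction.  Deterministic given (spec, seed).
    """
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)
    rows = []
    i = 0
    for label in ("anemic", "moderate", "normal"):
        for _ in range(int(spec.n_per_class.get(label, 0))):
            sex = "male" if rng.random() < spec.male_fraction else "female"
            lo, hi = spec.hb_ranges[(label, sex)]
            rows.append(
                {
                    "subject_id": f"S{i:04d}",
                    "sex": sex,
                    "hb_g_dl": round(float(rng.uniform(lo, hi)), 2),
                    "label": label,
                    "lighting": "daylight" if spec.lighting == "all" else spec.lighting,
                    "render_seed": int(rng.integers(2**31)),
                }
            )
            i += 1
    return pd.DataFrame(rows)


def generate_dataset(
    spec: SyntheticSpec = SyntheticSpec(),
    out_dir: str | os.PathLike = ".",
    seed: int | None = None,
    *,
    write_masks: bool = True,
) -> pd.DataFrame:
    """Render the dataset to disk and return its manifest.

    Writes ``images/<subject>.png`` (and ``masks/<subject>.png`` ground-truth
    masks), plus ``manifest.csv``.  With ``spec.lighting == "all"`` the
    manifest is expanded six-fold over the lighting presets; augmented rows
    reference the base (daylight) image together with their ``lighting``
    value, and the white-balance gain is applied downstream when the image is
    loaded — augmented pixels are pure functions of the base render.
    """
    out_dir = str(out_dir)
    img_dir = os.path.join(out_dir, "images")
    os.makedirs(img_dir, exist_ok=True)
    if write_masks:
        os.makedirs(os.path.join(out_dir, "masks"), exist_ok=True)

    manifest = sample_records(spec, seed)
    paths = []
    for rec in manifest.itertuples():
        img, mask = render_eye_image(rec.label, spec, rec.render_seed)
        path = os.path.join(img_dir, f"{rec.subject_id}.png")
        write_image(img, path)
        if write_masks:
            Image.fromarray(mask.astype(np.uint8) * 255, mode="L").save(
                os.path.join(out_dir, "masks", f"{rec.subject_id}.png")
            )
        paths.append(path)
    manifest.insert(0, "image_path", paths)

    if spec.lighting == "all":
        from .imgio import augment_dataset

        records = augment_dataset(
            manifest.to_dict("records"), list(LIGHTING_PRESETS.values())
        )
        manifest = pd.DataFrame(records)

    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return manifest


def load_record_image(record) -> np.ndarray:
    """Load a manifest record's pixels, applying its lighting preset."""
    from .imgio import read_image

    img = read_image(record["image_path"] if isinstance(record, dict) else record.image_path)
    lighting = record["lighting"] if isinstance(record, dict) else record.lighting
    if lighting != "daylight":
        img = apply_white_balance(img, lighting)
    return img
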