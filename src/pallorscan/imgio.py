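"""Image I/O, color-space conversions, and lighting-condition augmentation.

Images are plain numpy arrays:

* ``ImageRGB``  — ``uint8`` array of shape ``(H, W, 3)``, channel order R,G,B,
  origin at the top-left, row-major (0-based ``[row, col]`` indexing).
* ``ImageLab``  — ``float64`` array of shape ``(H, W, 3)`` holding CIELAB
  (L* in [0, 100], a*/b* roughly in [-128, 128]), sRGB input, D65 white point.
* ``ImageHSI`` — ``float64`` array of shape ``(H, W, 3)`` holding hue in
  degrees [0, 360), saturation in [0, 1] and intensity in [0, 1].

The six lighting presets emulate the white-balance settings of a consumer
camera (tungsten, cloudy, daylight, flash, fluorescent, shade) as per-channel
gains; daylight is the identity.  Applying every preset to a manifest is the
data-augmentation step that grows an n-image dataset to 6n records.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from PIL import Image, UnidentifiedImageError
from skimage import color as _skcolor

from .errors import ConfigError, ImageFormatError

__all__ = [
    "LightingPreset",
    "LIGHTING_PRESETS",
    "read_image",
    "write_image",
    "rgb_to_lab",
    "rgb_to_hsi",
    "apply_white_balance",
    "augment_dataset",
]


@dataclass(frozen=True)
class LightingPreset:
    """A named white-balance setting: per-channel multiplicative gains."""

    name: str
    gains: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.gains) != 3 or any(g <= 0 for g in self.gains):
            raise ConfigError(f"preset {self.name!r}: gains must be 3 positive reals")


#: The six lighting conditions used for augmentation. Gains are plausible
#: correlated-color-temperature shifts relative to daylight (identity).
LIGHTING_PRESETS: dict[str, LightingPreset] = {
    p.name: p
    for p in (
        LightingPreset("tungsten", (1.15, 1.00, 0.80)),
        LightingPreset("cloudy", (0.95, 1.00, 1.08)),
        LightingPreset("daylight", (1.00, 1.00, 1.00)),
        LightingPreset("flash", (1.05, 1.00, 1.02)),
        LightingPreset("fluorescent", (0.95, 1.05, 1.00)),
        LightingPreset("shade", (0.90, 1.00, 1.12)),
    )
}


def _require_rgb(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ImageFormatError(f"expected (H, W, 3) RGB array, got shape {img.shape}")
    if img.shape[0] < 1 or img.shape[1] < 1:
        raise ImageFormatError("image must be at least 1x1")
    return img


def read_image(path: str | os.PathLike) -> np.ndarray:
    """Read a PNG/JPEG file into an ``(H, W, 3)`` uint8 RGB array.

    An alpha channel, if present, is dropped; grayscale images are expanded
    to three identical channels.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"image file not found: {path}")
    try:
        with Image.open(path) as im:
            arr = np.asarray(im.convert("RGB"), dtype=np.uint8)
    except UnidentifiedImageError as exc:
        raise ImageFormatError(f"not a decodable image: {path}") from exc
    return arr


def write_image(img: np.ndarray, path: str | os.PathLike) -> str:
    """Write an RGB array to a lossless 8-bit PNG; returns the path written."""
    img = _require_rgb(img)
    Image.fromarray(np.ascontiguousarray(img, dtype=np.uint8), mode="RGB").save(
        path, format="PNG"
    )
    return str(path)


def rgb_to_lab(img: np.ndarray) -> np.ndarray:
    """Convert 8-bit sRGB to CIELAB (D65 white point).

    Returns float64 ``(H, W, 3)`` with channels (L*, a*, b*).
    """
    img = _require_rgb(img)
    return _skcolor.rgb2lab(img.astype(np.float64) / 255.0)


def rgb_to_hsi(img: np.ndarray) -> np.ndarray:
    """Convert 8-bit RGB to the HSI model (arccos hue formulation).

    H is the angle in degrees in [0, 360) measured from red, computed as

        theta = arccos( ((R-G) + (R-B)) / 2 / sqrt((R-G)^2 + (R-B)(G-B)) )
        H = theta            if B <= G
        H = 360 - theta      if B >  G

    S = 1 - 3 min(R,G,B)/(R+G+B)  (0 for black), I = (R+G+B)/(3*255).
    Achromatic pixels (S = 0) have H = 0 by convention.
    """
    img = _require_rgb(img).astype(np.float64)
    r, g, b = img[..., 0], img[..., 1], img[..., 2]
    total = r + g + b
    intensity = total / (3.0 * 255.0)

    with np.errstate(invalid="ignore", divide="ignore"):
        sat = np.where(total > 0, 1.0 - 3.0 * np.minimum(np.minimum(r, g), b) / total, 0.0)
        num = 0.5 * ((r - g) + (r - b))
        den = np.sqrt((r - g) ** 2 + (r - b) * (g - b))
        cos_theta = np.where(den > 0, num / np.where(den > 0, den, 1.0), 1.0)
    theta = np.degrees(np.arccos(np.clip(cos_theta, -1.0, 1.0)))
    hue = np.where(b > g, 360.0 - theta, theta)
    # achromatic convention, and keep hue in [0, 360)
    sat = np.clip(sat, 0.0, 1.0)
    hue = np.where(sat <= 0.0, 0.0, hue)
    hue = np.where(hue >= 360.0, 0.0, hue)
    return np.stack([hue, sat, intensity], axis=-1)


def load_preset_gains(path: str | os.PathLike) -> dict[str, LightingPreset]:
    """Load a white-balance gain table from a YAML config file.

    The file maps preset names to ``[gR, gG, gB]`` gain triples, e.g.::

        tungsten: [1.20, 1.00, 0.75]
        lamp:     [1.10, 1.05, 0.90]

    Returned presets can replace or extend :data:`LIGHTING_PRESETS`; this is
    also the hook for a user-supplied global color correction (a single
    custom preset applied to every image).
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"preset config must be a mapping, got {type(raw).__name__}")
    out = {}
    for name, gains in raw.items():
        try:
            out[str(name)] = LightingPreset(str(name), tuple(float(g) for g in gains))
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"bad gains for preset {name!r}: {gains!r}") from exc
    return out


def _resolve_preset(preset: LightingPreset | str) -> LightingPreset:
    if isinstance(preset, LightingPreset):
        return preset
    try:
        return LIGHTING_PRESETS[preset]
    except KeyError:
        raise ConfigError(
            f"unknown lighting preset {preset!r}; known: {sorted(LIGHTING_PRESETS)}"
        ) from None


def apply_white_balance(img: np.ndarray, preset: LightingPreset | str) -> np.ndarray:
    """Scale each channel by the preset gain, round half-up, clip to [0, 255]."""
    img = _require_rgb(img).astype(np.float64)
    gains = np.asarray(_resolve_preset(preset).gains, dtype=np.float64)
    out = np.floor(img * gains + 0.5)  # round half-up, deterministic
    return np.clip(out, 0, 255).astype(np.uint8)


def augment_dataset(
    manifest: Sequence, presets: Sequence[LightingPreset | str] | None = None
):
    """Expand a manifest by the lighting presets: |manifest| x |presets| records.

    Each input record (any object with a ``lighting`` attribute or a mapping
    with a ``"lighting"`` key) is replicated once per preset with its
    ``lighting`` field set to the preset name; every other field (image path,
    label, Hb, ...) is inherited.  The augmented list replaces the originals;
    the daylight copy reproduces each input record.
    """
    if presets is None:
        presets = list(LIGHTING_PRESETS.values())
    if len(presets) == 0:
        raise ConfigError("augmentation requires a non-empty preset list")
    if len(manifest) == 0:
        raise ConfigError("augmentation requires a non-empty manifest")
    resolved = [_resolve_preset(p) for p in presets]
    out = []
    for rec in manifest:
        for p in resolved:
            if isinstance(rec, dict):
                new = dict(rec)
                new["lighting"] = p.name
            else:
                new = replace(rec, lighting=p.name)
            out.append(new)
    return out
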