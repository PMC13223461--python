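"""Color and statistical features of a segmented conjunctiva region.

Seven scalars summarize the masked region, chosen because conjunctival
pallor expresses itself as a loss of redness and of vascular texture:

==================  ==========================================================
mean_intensity      mean of the grayscale intensity (R+G+B)/3, in [0, 255]
mean_rg_ratio       mean(R) / mean(G), dimensionless
mean_rg_diff        mean(R) - mean(G), in [-255, 255]
std_intensity       population std-dev of grayscale intensity, in [0, 127.5]
entropy_bits        Shannon entropy of the 256-bin intensity histogram, [0, 8]
high_hue_ratio      fraction of pixels with hue >= tau_h (default 300 deg),
                    a redness proxy: red-magenta hues adjoin 360/0 degrees
red_pixel_pct       fraction of pixels classed as red: the red channel
                    dominates both others by at least delta (default 70)
==================  ==========================================================

Ratios are stored as fractions in [0, 1]; user interfaces may display them
as percentages.  All features operate on the pixel multiset returned by
:func:`pallorscan.segment.apply_mask`, so they are invariant under pixel
permutation within the mask.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from .errors import DegenerateChannelError, EmptyRegionError, RegionTooSmallError
from .imgio import rgb_to_hsi
from .segment import apply_mask

__all__ = [
    "FeatureVector",
    "FEATURE_NAMES",
    "DEFAULT_TAU_H",
    "DEFAULT_DELTA_RED",
    "MIN_REGION_SIZE",
    "mean_intensity",
    "mean_rg_ratio",
    "mean_rg_difference",
    "std_intensity",
    "intensity_entropy",
    "high_hue_ratio",
    "red_pixel_percentage",
    "extract_feature_vector",
]

#: Hue threshold (degrees) above which a pixel counts toward the high-hue
#: ratio.  Hues in [300, 360) span the magenta-red band adjoining pure red.
DEFAULT_TAU_H = 300.0

#: Red-dominance margin (8-bit counts).  A pixel is "red" when
#: R - max(G, B) >= delta; 70 demands a saturated vascular red rather than
#: the mild warm cast that skin or pale mucosa also carries.
DEFAULT_DELTA_RED = 70.0

#: Minimum region size (pixels) for a feature vector to be meaningful.
MIN_REGION_SIZE = 50


@dataclass(frozen=True)
class FeatureVector:
    mean_intensity: float
    mean_rg_ratio: float
    mean_rg_diff: float
    std_intensity: float
    entropy_bits: float
    high_hue_ratio: float
    red_pixel_pct: float
    n_pixels: int = 0

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES], dtype=np.float64)


FEATURE_NAMES = tuple(f.name for f in fields(FeatureVector))[:-1]


def _region(region: np.ndarray) -> np.ndarray:
    region = np.asarray(region)
    if region.ndim != 2 or region.shape[1] != 3:
        raise ValueError(f"region must be an (N, 3) pixel array, got {region.shape}")
    if region.shape[0] == 0:
        raise EmptyRegionError("empty region")
    return region.astype(np.float64)


def _gray(region: np.ndarray) -> np.ndarray:
    return region.mean(axis=1)  # (R+G+B)/3


def mean_intensity(region: np.ndarray) -> float:
    """Mean grayscale intensity (R+G+B)/3 over the region."""
    return float(_gray(_region(region)).mean())


def mean_rg_ratio(region: np.ndarray, *, eps: float = 1e-6) -> float:
    """mean(R) / mean(G); raises if the green mean is degenerate."""
    reg = _region(region)
    g = reg[:, 1].mean()
    if g <= eps:
        raise DegenerateChannelError("mean green channel is ~0; R/G undefined")
    return float(reg[:, 0].mean() / g)


def mean_rg_difference(region: np.ndarray) -> float:
    """mean(R) - mean(G)."""
    reg = _region(region)
    return float(reg[:, 0].mean() - reg[:, 1].mean())


def std_intensity(region: np.ndarray) -> float:
    """Population (divisor N) standard deviation of grayscale intensity."""
    return float(_gray(_region(region)).std(ddof=0))


def intensity_entropy(region: np.ndarray) -> float:
    """Shannon entropy (bits) of the 256-bin histogram of rounded intensity.

    The convention 0*log(0) = 0 applies; a constant region has 0 bits and a
    uniform histogram over all 256 levels has 8 bits.
    """
    gray = np.clip(np.floor(_gray(_region(region)) + 0.5), 0, 255).astype(np.intp)
    counts = np.bincount(gray, minlength=256)
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def high_hue_ratio(region: np.ndarray, *, tau_h: float = DEFAULT_TAU_H) -> float:
    """Fraction of region pixels whose hue is at least ``tau_h`` degrees.

    Hue is taken from the HSI transform; achromatic pixels (S = 0) never
    count.  The result is a fraction in [0, 1].
    """
    reg = _region(region).astype(np.uint8)
    hsi = rgb_to_hsi(reg.reshape(1, -1, 3)).reshape(-1, 3)
    chromatic = hsi[:, 1] > 0
    high = chromatic & (hsi[:, 0] >= tau_h)
    return float(high.sum() / reg.shape[0])


def red_pixel_percentage(region: np.ndarray, *, delta: float = DEFAULT_DELTA_RED) -> float:
    """Fraction of pixels classed as red: R > G, R > B and R - max(G,B) >= delta."""
    reg = _region(region)
    r, g, b = reg[:, 0], reg[:, 1], reg[:, 2]
    red = (r > g) & (r > b) & (r - np.maximum(g, b) >= delta)
    return float(red.mean())


def extract_feature_vector(
    img: np.ndarray,
    mask: np.ndarray,
    *,
    tau_h: float = DEFAULT_TAU_H,
    delta_red: float = DEFAULT_DELTA_RED,
    min_region: int = MIN_REGION_SIZE,
) -> FeatureVector:
    """All seven features on the masked region of ``img``.

    Raises
    ------
    RegionTooSmallError
        If the mask selects fewer than ``min_region`` pixels — flagged rather
        than silently imputed, since features on a sliver are unreliable.
    """
    region = apply_mask(img, mask)
    if region.shape[0] < min_region:
        raise RegionTooSmallError(
            f"segmented region has {region.shape[0]} px < minimum {min_region}"
        )
    return FeatureVector(
        mean_intensity=mean_intensity(region),
        mean_rg_ratio=mean_rg_ratio(region),
        mean_rg_diff=mean_rg_difference(region),
        std_intensity=std_intensity(region),
        entropy_bits=intensity_entropy(region),
        high_hue_ratio=high_hue_ratio(region, tau_h=tau_h),
        red_pixel_pct=red_pixel_percentage(region, delta=delta_red),
        n_pixels=int(region.shape[0]),
    )
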