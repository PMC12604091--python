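"""Deterministic colour mathematics for assay image analysis.

Implements the read-out side of a camera-based colorimetric assay:
white balancing against a reference region, masking of saturated
pixels, and conversion of encoded sRGB values to the CIELAB colour
space (D65 white point, 2 degree observer).  CIELAB is used because a
chemically meaningful colour change maps onto a single opponent axis:
a* (green to red) tracks the pink chromophore, b* (blue to yellow)
tracks the yellow substrate.

Conventions
-----------
* Pixels are triples of encoded (gamma-compressed) sRGB values on
  [0, 1].  Integer images are divided by full scale first
  (:func:`as_float`), so bit depth is transparent everywhere.
* Regions of interest (:class:`Rect`) are 0-based, half-open in both
  axes, row-major: ``Rect(r0, r1, c0, c1)`` covers rows ``r0..r1-1``.
* Saturation is judged on the *encoded* values, before white
  balancing: a pixel is saturated when any channel is >= the
  configured threshold (default 250/255).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "D65_WHITE",
    "Rect",
    "ColorspaceConfig",
    "ColorSample",
    "WhiteBalanceGains",
    "as_float",
    "decode_rgb",
    "encode_rgb",
    "rgb_to_xyz",
    "xyz_to_rgb",
    "rgb_to_lab",
    "saturation_mask",
    "compute_white_balance",
    "apply_gains",
    "region_color_stats",
    "delta_e",
]

# sRGB (IEC 61966-2-1) primaries -> CIE XYZ, D65 white.
_RGB_TO_XYZ = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)

#: CIE D65 reference white (2 degree observer): the XYZ of sRGB (1,1,1),
#: taken as the exact matrix row sums so the grey axis is exactly neutral.
D65_WHITE = tuple(float(v) for v in _RGB_TO_XYZ.sum(axis=1))
_XYZ_TO_RGB = np.linalg.inv(_RGB_TO_XYZ)

_DELTA = 6.0 / 29.0  # Lab cube-root kink


class SaturatedRegionError(ValueError):
    """Raised when a reference/analysis region has no usable pixels."""


@dataclass(frozen=True)
class Rect:
    """Half-open rectangle ``[row_start, row_stop) x [col_start, col_stop)``."""

    row_start: int
    row_stop: int
    col_start: int
    col_stop: int

    def __post_init__(self) -> None:
        if self.row_stop <= self.row_start or self.col_stop <= self.col_start:
            raise ValueError(f"empty rectangle: {self}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.row_stop - self.row_start, self.col_stop - self.col_start)

    def slices(self) -> tuple[slice, slice]:
        return (slice(self.row_start, self.row_stop), slice(self.col_start, self.col_stop))

    def within(self, frame_shape: tuple[int, ...]) -> bool:
        return (
            0 <= self.row_start
            and self.row_stop <= frame_shape[0]
            and 0 <= self.col_start
            and self.col_stop <= frame_shape[1]
        )

    def to_tuple(self) -> tuple[int, int, int, int]:
        return (self.row_start, self.row_stop, self.col_start, self.col_stop)


@dataclass(frozen=True)
class ColorspaceConfig:
    """Fixed colour convention: sRGB primaries, configurable white point.

    Parameters
    ----------
    white_point
        Reference tristimulus (Xn, Yn, Zn); default CIE D65.
    saturation_threshold
        Fraction of full scale at or above which an encoded channel
        counts as saturated.  Default 250/255.
    """

    white_point: tuple[float, float, float] = D65_WHITE
    saturation_threshold: float = 250.0 / 255.0

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.white_point):
            raise ValueError("white point components must be strictly positive")
        if not (0.0 < self.saturation_threshold <= 1.0):
            raise ValueError("saturation_threshold must lie in (0, 1]")


@dataclass(frozen=True)
class ColorSample:
    """Mean and intra-region dispersion of L*, a*, b* for one frame."""

    L_star: float
    a_star: float
    b_star: float
    L_sd: float = 0.0
    a_sd: float = 0.0
    b_sd: float = 0.0
    n_pixels: int = 1

    def __post_init__(self) -> None:
        if min(self.L_sd, self.a_sd, self.b_sd) < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.n_pixels < 1:
            raise ValueError("a sample needs at least one contributing pixel")

    @property
    def lab(self) -> tuple[float, float, float]:
        return (self.L_star, self.a_star, self.b_star)


@dataclass(frozen=True)
class WhiteBalanceGains:
    """Per-channel multipliers equalising the white region to its grey mean."""

    gain_r: float
    gain_g: float
    gain_b: float
    reference_grey: float

    def __post_init__(self) -> None:
        if min(self.gain_r, self.gain_g, self.gain_b) <= 0:
            raise ValueError("gains must be strictly positive")

    @property
    def as_array(self) -> np.ndarray:
        return np.array([self.gain_r, self.gain_g, self.gain_b])


def as_float(frame: np.ndarray) -> np.ndarray:
    """Return ``frame`` as float64 on [0, 1] (8/16-bit integers are scaled)."""
    arr = np.asarray(frame)
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0
    return arr.astype(np.float64)


def _check_unit_range(values: np.ndarray) -> None:
    if np.any(values < -1e-12) or np.any(values > 1 + 1e-12):
        raise ValueError("encoded channel values must lie in [0, 1]")


def decode_rgb(encoded: np.ndarray | tuple) -> np.ndarray:
    """sRGB electro-optical decoding: encoded [0,1] -> linear light [0,1]."""
    v = np.asarray(encoded, dtype=np.float64)
    _check_unit_range(v)
    return np.where(v <= 0.04045, v / 12.92, ((v + 0.055) / 1.055) ** 2.4)


def encode_rgb(linear: np.ndarray | tuple) -> np.ndarray:
    """Inverse of :func:`decode_rgb` (values clipped to [0, 1] first)."""
    v = np.clip(np.asarray(linear, dtype=np.float64), 0.0, 1.0)
    return np.where(v <= 0.0031308, v * 12.92, 1.055 * v ** (1.0 / 2.4) - 0.055)


def rgb_to_xyz(encoded: np.ndarray | tuple) -> np.ndarray:
    """Encoded sRGB -> CIE XYZ (Y of the sRGB white equals 1)."""
    lin = decode_rgb(encoded)
    return lin @ _RGB_TO_XYZ.T


def xyz_to_rgb(xyz: np.ndarray | tuple) -> np.ndarray:
    """CIE XYZ -> *linear* sRGB (no gamma encoding, no clipping)."""
    return np.asarray(xyz, dtype=np.float64) @ _XYZ_TO_RGB.T


def _lab_f(t: np.ndarray) -> np.ndarray:
    return np.where(t > _DELTA**3, np.cbrt(t), t / (3 * _DELTA**2) + 4.0 / 29.0)


def rgb_to_lab(encoded: np.ndarray | tuple, config: ColorspaceConfig | None = None) -> np.ndarray:
    """Encoded sRGB -> CIELAB.  Works on any ``(..., 3)`` array.

    Neutral inputs (equal channels) map to a* = b* = 0 exactly under
    the default white point.
    """
    config = config or ColorspaceConfig()
    xyz = rgb_to_xyz(encoded)
    wp = np.asarray(config.white_point)
    f = _lab_f(xyz / wp)
    L = 116.0 * f[..., 1] - 16.0
    a = 500.0 * (f[..., 0] - f[..., 1])
    b = 200.0 * (f[..., 1] - f[..., 2])
    return np.stack([L, a, b], axis=-1)


def saturation_mask(frame: np.ndarray, config: ColorspaceConfig | None = None) -> np.ndarray:
    """Boolean mask of saturated pixels (any encoded channel >= threshold)."""
    config = config or ColorspaceConfig()
    arr = as_float(frame)
    return np.any(arr >= config.saturation_threshold, axis=-1)


def compute_white_balance(
    white_pixels: np.ndarray, config: ColorspaceConfig | None = None
) -> WhiteBalanceGains:
    """Gains from a white reference region.

    ``gain_k = mean_grey / mean_channel_k`` where ``mean_grey`` is the
    mean over all three channels of the non-saturated pixels; applying
    the gains makes the three balanced channel means equal.
    """
    config = config or ColorspaceConfig()
    pixels = as_float(white_pixels).reshape(-1, 3)
    keep = ~np.any(pixels >= config.saturation_threshold, axis=-1)
    pixels = pixels[keep]
    if pixels.size == 0:
        raise SaturatedRegionError("white reference unusable: every pixel saturated")
    channel_means = pixels.mean(axis=0)
    if np.any(channel_means <= 0):
        raise SaturatedRegionError("white reference unusable: zero channel mean")
    grey = float(channel_means.mean())
    gains = grey / channel_means
    return WhiteBalanceGains(float(gains[0]), float(gains[1]), float(gains[2]), grey)


def apply_gains(pixels: np.ndarray, gains: WhiteBalanceGains) -> np.ndarray:
    """Apply white-balance gains to encoded pixels, clipping to [0, 1]."""
    return np.clip(as_float(pixels) * gains.as_array, 0.0, 1.0)


def region_color_stats(
    frame: np.ndarray,
    roi: Rect,
    gains: WhiteBalanceGains | None = None,
    config: ColorspaceConfig | None = None,
) -> ColorSample:
    """CIELAB mean/dispersion statistics of a region of interest.

    Order of operations: mask saturated pixels (on encoded values),
    white-balance the survivors, average the encoded channels, convert
    the *mean colour* to L*a*b*.  The dispersion is the per-channel
    standard deviation of the per-pixel L*a*b* values.
    """
    config = config or ColorspaceConfig()
    arr = as_float(frame)
    if not roi.within(arr.shape):
        raise ValueError(f"roi {roi} outside frame of shape {arr.shape[:2]}")
    patch = arr[roi.slices()].reshape(-1, 3)
    keep = ~np.any(patch >= config.saturation_threshold, axis=-1)
    patch = patch[keep]
    if patch.shape[0] == 0:
        raise SaturatedRegionError("region of interest fully saturated")
    if gains is not None:
        patch = np.clip(patch * gains.as_array, 0.0, 1.0)
    mean_rgb = patch.mean(axis=0)
    mean_lab = rgb_to_lab(mean_rgb, config)
    pixel_lab = rgb_to_lab(patch, config)
    sd = pixel_lab.std(axis=0)
    return ColorSample(
        L_star=float(mean_lab[0]),
        a_star=float(mean_lab[1]),
        b_star=float(mean_lab[2]),
        L_sd=float(sd[0]),
        a_sd=float(sd[1]),
        b_sd=float(sd[2]),
        n_pixels=int(patch.shape[0]),
    )


def delta_e(c1: ColorSample, c2: ColorSample) -> float:
    """Euclidean CIELAB colour difference (CIE76)."""
    return math.dist(c1.lab, c2.lab)
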