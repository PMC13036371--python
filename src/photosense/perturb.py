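"""Photometric perturbation engine with bit-exact, documented uint8 semantics.

A perturbed image is produced by a fixed sequential pipeline on 8-bit RGB
data — resize, then brightness, contrast, sharpness and saturation
enhancements, then a circular hue shift in 8-bit HSV space — with rounding
(half away from zero) and clipping to [0, 255] after every stage.  The
pipeline order matters: the stages do not commute on uint8 data, so it is
part of the contract.

Each enhancement interpolates the original against a "degenerate" image::

    out = round_clip((1 - factor) * degenerate + factor * original)

where the degenerate image is all-black (brightness), the uniform image at
the mean integer luma (contrast), the per-pixel grayscale luma image
(saturation), or a 3x3-smoothed copy (sharpness).  Factor 1 is therefore a
byte-exact identity for every enhancement, and the nominal perturbation
``(1, 1, 1, 1, 0)`` reproduces the resized original exactly.

The hue shift follows ``H_new = (H_old + round(dH * 255)) mod 256`` on the
8-bit hue channel, leaving S and V untouched; an integer shift is its own
inverse mod 256, so hue shifts compose additively on the H channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import convolve

from .bounds import FACTOR_NAMES, FactorBounds

__all__ = [
    "FactorSample",
    "round_half_away",
    "resize_image",
    "enhance",
    "shift_hue",
    "apply_perturbation",
    "rgb_to_hsv8",
    "hsv8_to_rgb",
]

ENHANCE_KINDS = ("brightness", "contrast", "sharpness", "saturation")

_SMOOTH_KERNEL = np.array([[1, 1, 1], [1, 5, 1], [1, 1, 1]], dtype=float) / 13.0


@dataclass(frozen=True)
class FactorSample:
    """One point in the five-dimensional photometric parameter space.

    Brightness, contrast, sharpness and saturation are dimensionless
    multiplicative factors (1.0 = no change); hue is a normalized shift of
    the 8-bit hue channel (0.0 = no change).
    """

    brightness: float = 1.0
    contrast: float = 1.0
    sharpness: float = 1.0
    saturation: float = 1.0
    hue: float = 0.0

    @classmethod
    def nominal(cls) -> "FactorSample":
        return cls()

    @classmethod
    def from_array(cls, values) -> "FactorSample":
        """Build from values ordered as :data:`~photosense.bounds.FACTOR_NAMES`."""
        values = np.asarray(values, dtype=float).ravel()
        if values.size != len(FACTOR_NAMES):
            raise ValueError(f"expected {len(FACTOR_NAMES)} values, got {values.size}")
        return cls(**dict(zip(FACTOR_NAMES, values)))

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FACTOR_NAMES])


def _check_rgb(pixels: np.ndarray) -> np.ndarray:
    pixels = np.asarray(pixels)
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise ValueError(f"expected H x W x 3 RGB array, got shape {pixels.shape}")
    if pixels.shape[0] == 0 or pixels.shape[1] == 0:
        raise ValueError("empty image")
    if pixels.dtype != np.uint8:
        raise ValueError(f"expected uint8 pixels, got dtype {pixels.dtype}")
    return pixels


def round_half_away(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer, ties away from zero (unlike numpy's banker's rounding)."""
    x = np.asarray(x, dtype=float)
    return np.where(x >= 0, np.floor(x + 0.5), np.ceil(x - 0.5))


def _round_clip(x: np.ndarray) -> np.ndarray:
    return np.clip(round_half_away(x), 0, 255).astype(np.uint8)


def _int_luma(pixels: np.ndarray) -> np.ndarray:
    """Integer luma (299 R + 587 G + 114 B) / 1000, rounded half away from zero."""
    f = pixels.astype(float)
    luma = (299.0 * f[..., 0] + 587.0 * f[..., 1] + 114.0 * f[..., 2]) / 1000.0
    return round_half_away(luma)


def resize_image(pixels: np.ndarray, side: int = 128) -> np.ndarray:
    """Point-sampled bilinear resize to ``side x side`` with half-pixel alignment.

    Output pixel centers map to source coordinates ``(i + 0.5) * scale - 0.5``
    and are bilinearly interpolated between the four surrounding source
    pixels (edges clamped).  A same-size resize is a byte-exact identity,
    and an exact 2x downscale averages each 2x2 block.
    """
    pixels = _check_rgb(pixels)
    if side < 1:
        raise ValueError(f"side must be >= 1, got {side}")
    h, w = pixels.shape[:2]
    if (h, w) == (side, side):
        return pixels.copy()

    def axis_coords(n_src: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        src = (np.arange(side) + 0.5) * (n_src / side) - 0.5
        i0 = np.floor(src).astype(int)
        frac = src - i0
        i0c = np.clip(i0, 0, n_src - 1)
        i1c = np.clip(i0 + 1, 0, n_src - 1)
        return i0c, i1c, frac

    r0, r1, fr = axis_coords(h)
    c0, c1, fc = axis_coords(w)
    f = pixels.astype(float)
    top = f[r0][:, c0] * (1 - fc)[None, :, None] + f[r0][:, c1] * fc[None, :, None]
    bot = f[r1][:, c0] * (1 - fc)[None, :, None] + f[r1][:, c1] * fc[None, :, None]
    out = top * (1 - fr)[:, None, None] + bot * fr[:, None, None]
    return _round_clip(out)


def _degenerate(pixels: np.ndarray, kind: str) -> np.ndarray:
    """The zero-factor endpoint image for an enhancement kind (float array)."""
    if kind == "brightness":
        return np.zeros_like(pixels, dtype=float)
    if kind == "contrast":
        mean = round_half_away(np.mean(_int_luma(pixels)))
        return np.full_like(pixels, float(mean), dtype=float)
    if kind == "saturation":
        return np.repeat(_int_luma(pixels)[..., None], 3, axis=2)
    if kind == "sharpness":
        f = pixels.astype(float)
        smoothed = np.stack(
            [convolve(f[..., c], _SMOOTH_KERNEL, mode="nearest") for c in range(3)],
            axis=2,
        )
        out = _round_clip(smoothed).astype(float)
        # smoothing is undefined on the border ring: copy it from the original
        out[0, :], out[-1, :] = pixels[0, :], pixels[-1, :]
        out[:, 0], out[:, -1] = pixels[:, 0], pixels[:, -1]
        return out
    raise ValueError(f"unknown enhancement kind {kind!r}; expected one of {ENHANCE_KINDS}")


def enhance(pixels: np.ndarray, kind: str, factor: float) -> np.ndarray:
    """Apply one photometric enhancement by interpolation against its degenerate image.

    ``factor = 1`` is a byte-exact identity; ``factor = 0`` yields the
    degenerate image; values beyond 1 extrapolate, with clipping to [0, 255].
    """
    pixels = _check_rgb(pixels)
    if factor < 0:
        raise ValueError(f"enhancement factor must be >= 0, got {factor}")
    if kind not in ENHANCE_KINDS:
        raise ValueError(f"unknown enhancement kind {kind!r}; expected one of {ENHANCE_KINDS}")
    if factor == 1.0:
        return pixels.copy()
    deg = _degenerate(pixels, kind)
    return _round_clip((1.0 - factor) * deg + factor * pixels.astype(float))


def rgb_to_hsv8(pixels: np.ndarray) -> np.ndarray:
    """Convert uint8 RGB to 8-bit HSV (hexcone model, all channels on [0, 255]).

    V is the channel maximum (exact); S = 255 (max - min) / max rounded;
    H is the hexcone hue on [0, 1) scaled by 255 and rounded.  Achromatic
    pixels get H = S = 0.
    """
    pixels = _check_rgb(pixels)
    f = pixels.astype(float)
    r, g, b = f[..., 0], f[..., 1], f[..., 2]
    mx = np.max(f, axis=2)
    mn = np.min(f, axis=2)
    d = mx - mn
    safe_d = np.where(d == 0, 1.0, d)
    h6 = np.where(
        mx == r,
        np.mod((g - b) / safe_d, 6.0),
        np.where(mx == g, (b - r) / safe_d + 2.0, (r - g) / safe_d + 4.0),
    )
    h6 = np.where(d == 0, 0.0, h6)
    H = round_half_away(h6 / 6.0 * 255.0)
    S = np.where(mx == 0, 0.0, round_half_away(255.0 * d / np.where(mx == 0, 1.0, mx)))
    return np.stack([H, S, mx], axis=2).astype(np.uint8)


def hsv8_to_rgb(hsv: np.ndarray) -> np.ndarray:
    """Convert 8-bit HSV back to uint8 RGB (inverse hexcone, rounded half away)."""
    hsv = np.asarray(hsv)
    if hsv.ndim != 3 or hsv.shape[2] != 3 or hsv.dtype != np.uint8:
        raise ValueError("expected H x W x 3 uint8 HSV array")
    h6 = hsv[..., 0].astype(float) * 6.0 / 255.0
    s = hsv[..., 1].astype(float) / 255.0
    v = hsv[..., 2].astype(float)
    i = np.floor(h6).astype(int) % 6
    frac = h6 - np.floor(h6)
    p = v * (1.0 - s)
    q = v * (1.0 - s * frac)
    t = v * (1.0 - s * (1.0 - frac))
    r = np.choose(i, [v, q, p, p, t, v])
    g = np.choose(i, [t, v, v, q, p, p])
    b = np.choose(i, [p, p, t, v, v, q])
    return _round_clip(np.stack([r, g, b], axis=2))


def hue_shift_amount(delta_h: float) -> int:
    """Integer shift of the 8-bit hue channel for a normalized hue shift."""
    return int(round_half_away(np.asarray(delta_h * 255.0)))


def shift_hue(pixels: np.ndarray, delta_h: float) -> np.ndarray:
    """Shift the hue channel circularly by a normalized amount ``delta_h``.

    The image is converted to 8-bit HSV, the H channel is shifted by
    ``round(delta_h * 255)`` modulo 256 (S and V untouched), and the result
    is converted back to RGB.  A zero integer shift is a byte-exact identity.
    """
    pixels = _check_rgb(pixels)
    if not (-1.0 <= delta_h <= 1.0):
        raise ValueError(f"delta_h must be in [-1, 1], got {delta_h}")
    shift = hue_shift_amount(delta_h) % 256
    if shift == 0:
        return pixels.copy()
    hsv = rgb_to_hsv8(pixels)
    hsv[..., 0] = ((hsv[..., 0].astype(int) + shift) % 256).astype(np.uint8)
    return hsv8_to_rgb(hsv)


def apply_perturbation(
    pixels: np.ndarray, sample: FactorSample, side: int = 128, resize: bool = True
) -> np.ndarray:
    """Run the full sequential perturbation pipeline.

    Order: resize -> brightness -> contrast -> sharpness -> saturation ->
    hue shift, each stage rounding and clipping internally.  With the
    nominal sample the output equals the resized original byte-for-byte.
    ``resize=False`` skips the resize stage (for callers that pre-resize
    once and sweep many samples).
    """
    out = _check_rgb(pixels)
    if resize:
        out = resize_image(out, side)
    for kind in ENHANCE_KINDS:
        out = enhance(out, kind, getattr(sample, kind))
    return shift_hue(out, sample.hue)


def check_sample_within_bounds(sample: FactorSample, bounds: list[FactorBounds]) -> None:
    """Raise if any component of ``sample`` falls outside its factor bounds."""
    by_name = {b.name: b for b in bounds}
    for name in FACTOR_NAMES:
        value = getattr(sample, name)
        b = by_name.get(name)
        if b is not None and not (b.lo <= value <= b.hi):
            raise ValueError(f"{name}={value} outside bounds [{b.lo}, {b.hi}]")
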