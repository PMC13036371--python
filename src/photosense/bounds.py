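"""Factor definitions and bounds for the photometric uncertainty model.

The acquisition-uncertainty model treats every image as subject to five
independent photometric distortions: multiplicative brightness, contrast,
sharpness and saturation rescalings, and an additive hue rotation expressed
as a normalized shift of the 8-bit hue channel.  Each factor varies inside
a fixed interval; the default intervals correspond to clinically plausible
acquisition variability for dermoscopy (±50% brightness and saturation,
±20% contrast and sharpness, ±10% hue).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = ["FactorBounds", "FACTOR_NAMES", "default_bounds", "validate_bounds"]

#: Canonical factor order used by every design, sample and report.
FACTOR_NAMES: tuple[str, ...] = (
    "brightness",
    "contrast",
    "sharpness",
    "saturation",
    "hue",
)

_DEFAULT_INTERVALS: dict[str, tuple[float, float]] = {
    "brightness": (0.5, 1.5),
    "contrast": (0.8, 1.2),
    "sharpness": (0.8, 1.2),
    "saturation": (0.5, 1.5),
    "hue": (-0.1, 0.1),
}


@dataclass(frozen=True)
class FactorBounds:
    """A named factor with its closed sampling interval ``[lo, hi]``.

    ``name`` is free-form so the sensitivity engine can be used with
    arbitrary analytic test functions; photometric configurations restrict
    names to :data:`FACTOR_NAMES`.
    """

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("factor name must be non-empty")
        if not (self.lo <= self.hi):
            raise ValueError(
                f"invalid bounds for {self.name!r}: lo={self.lo} > hi={self.hi}"
            )

    @property
    def width(self) -> float:
        return self.hi - self.lo


def default_bounds() -> list[FactorBounds]:
    """Default photometric bounds, in canonical factor order."""
    return [FactorBounds(name, *_DEFAULT_INTERVALS[name]) for name in FACTOR_NAMES]


def validate_bounds(bounds: Iterable[FactorBounds], photometric: bool = False) -> list[FactorBounds]:
    """Validate a bounds list; optionally require the five photometric factors.

    With ``photometric=True`` the list must contain exactly the five known
    factors in canonical order (reports, perturbation samples and designs all
    index by this order).
    """
    out = list(bounds)
    if not out:
        raise ValueError("bounds list is empty")
    names = [b.name for b in out]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate factor names in bounds: {names}")
    if photometric and tuple(names) != FACTOR_NAMES:
        raise ValueError(
            f"photometric bounds must name {FACTOR_NAMES} in order, got {tuple(names)}"
        )
    return out


def bounds_from_mapping(mapping: dict[str, Sequence[float]]) -> list[FactorBounds]:
    """Build photometric bounds from ``{name: [lo, hi]}``, defaulting missing factors."""
    out = []
    for name in FACTOR_NAMES:
        lo, hi = mapping.get(name, _DEFAULT_INTERVALS[name])
        out.append(FactorBounds(name, float(lo), float(hi)))
    unknown = set(mapping) - set(FACTOR_NAMES)
    if unknown:
        raise ValueError(f"unknown factor names in bounds mapping: {sorted(unknown)}")
    return out
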