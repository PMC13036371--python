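"""Black-box predictor contract and analytic probe predictors.

The audited model is treated as a fixed device: any callable mapping a
batch of uint8 RGB images to melanoma probabilities in [0, 1] can be
audited.  The contract (outputs in range, deterministic, batch order
preserved) is enforced by :func:`validate_predictor` on a canary batch.

Probe predictors are synthetic classifiers engineered so that exactly one
photometric factor drives their output: each computes a scalar image
statistic matched to its target factor and maps it through a logistic
response.  They exist to validate the whole audit chain end to end — under
the default perturbation bounds the designed factor should dominate the
total-order sensitivity ranking.
"""

from __future__ import annotations

from typing import Callable, Protocol, Sequence, runtime_checkable

import numpy as np

from .bounds import FACTOR_NAMES
from .perturb import rgb_to_hsv8, _check_rgb, _int_luma

__all__ = [
    "Predictor",
    "FunctionPredictor",
    "validate_predictor",
    "make_probe_predictor",
    "image_statistic",
]


@runtime_checkable
class Predictor(Protocol):
    """Anything with ``predict(images) -> probabilities in [0, 1]``."""

    def predict(self, images: Sequence[np.ndarray]) -> np.ndarray: ...


class FunctionPredictor:
    """Wrap a per-image scalar function as a batch :class:`Predictor`."""

    def __init__(self, fn: Callable[[np.ndarray], float], name: str = "function"):
        self._fn = fn
        self.name = name

    def predict(self, images: Sequence[np.ndarray]) -> np.ndarray:
        return np.array([float(self._fn(img)) for img in images])


class PredictorContractError(RuntimeError):
    """The wrapped model violated the probability / determinism / order contract."""


def check_probabilities(p: np.ndarray, context: str = "predictor") -> np.ndarray:
    p = np.asarray(p, dtype=float).ravel()
    if not np.all(np.isfinite(p)):
        raise PredictorContractError(f"{context} returned non-finite probabilities")
    if p.size and (p.min() < 0.0 or p.max() > 1.0):
        raise PredictorContractError(
            f"{context} returned probabilities outside [0, 1]: "
            f"min={p.min():.4g}, max={p.max():.4g}"
        )
    return p


def validate_predictor(predictor: Predictor, canary: Sequence[np.ndarray]) -> None:
    """Check the predictor contract on a canary batch.

    Verifies output range, repeat determinism, and that batch predictions
    match per-image predictions in order.
    """
    canary = list(canary)
    if not canary:
        raise ValueError("canary batch is empty")
    batch = check_probabilities(predictor.predict(canary))
    if batch.size != len(canary):
        raise PredictorContractError(
            f"predictor returned {batch.size} probabilities for {len(canary)} images"
        )
    again = check_probabilities(predictor.predict(canary))
    if not np.array_equal(batch, again):
        raise PredictorContractError("predictor is not deterministic on identical bytes")
    singles = np.concatenate([check_probabilities(predictor.predict([img])) for img in canary])
    if not np.array_equal(batch, singles):
        raise PredictorContractError("predictor does not preserve batch order")


# --- probe statistics -------------------------------------------------------
#
# Each statistic is normalized to roughly [0, 1] and chosen so that, under
# the default perturbation bounds, its target factor moves it far more than
# any other factor does:
#   brightness  mean of the HSV value channel (scales with brightness)
#   contrast    coefficient of variation of the value channel (brightness
#               rescales mean and spread together, so std/mean isolates the
#               contrast stretch)
#   saturation  mean of the HSV saturation channel
#   hue         saturation-weighted circular mean of the hue channel,
#               reported as signed circular distance from a reference hue
#   sharpness   mean absolute Laplacian of the luma channel (edge energy)


def _value_mean(img: np.ndarray) -> float:
    v = rgb_to_hsv8(img)[..., 2].astype(float)
    return float(v.mean()) / 255.0


def _value_cov(img: np.ndarray) -> float:
    v = rgb_to_hsv8(img)[..., 2].astype(float)
    mean = v.mean()
    return float(v.std() / mean) if mean > 0 else 0.0


def _saturation_mean(img: np.ndarray) -> float:
    return float(rgb_to_hsv8(img)[..., 1].mean()) / 255.0


def _hue_circular_offset(img: np.ndarray, reference: float = 0.0) -> float:
    """Signed circular distance of the saturation-weighted mean hue from ``reference``.

    Hue is meaningless for unsaturated pixels, so the circular mean is
    weighted by the saturation channel.  Result lies in [-0.5, 0.5) on the
    normalized hue circle.
    """
    hsv = rgb_to_hsv8(img)
    ang = hsv[..., 0].astype(float) / 256.0 * 2.0 * np.pi
    w = hsv[..., 1].astype(float) + 1e-9
    mean_ang = np.arctan2(np.sum(w * np.sin(ang)), np.sum(w * np.cos(ang)))
    mean_hue = (mean_ang / (2.0 * np.pi)) % 1.0
    return float((mean_hue - reference + 0.5) % 1.0 - 0.5)


def _laplacian_energy(img: np.ndarray) -> float:
    luma = _int_luma(img)
    lap = (
        luma[1:-1, :-2] + luma[1:-1, 2:] + luma[:-2, 1:-1] + luma[2:, 1:-1]
        - 4.0 * luma[1:-1, 1:-1]
    )
    return float(np.mean(np.abs(lap))) / 255.0


_STATISTICS: dict[str, Callable[[np.ndarray], float]] = {
    "brightness": _value_mean,
    "contrast": _value_cov,
    "saturation": _saturation_mean,
    "hue": _hue_circular_offset,
    "sharpness": _laplacian_energy,
}

# Logistic calibration of each probe: gain sets how steeply the statistic is
# mapped to probability; center is the statistic's typical value on an
# unperturbed synthetic lesion image, so nominal probabilities sit mid-range
# and the perturbation sweep stays on the responsive part of the logistic.
_DEFAULT_GAIN: dict[str, float] = {
    "brightness": 8.0,
    "contrast": 30.0,
    "saturation": 10.0,
    "hue": 25.0,
    "sharpness": 80.0,
}
_DEFAULT_CENTER: dict[str, float] = {
    "brightness": 0.65,
    "contrast": 0.15,
    "saturation": 0.28,
    "hue": 0.0,
    "sharpness": 0.022,
}

#: Default reference hue for the hue probe: the synthetic generator's lesion hue.
_DEFAULT_HUE_REFERENCE = 0.055


def image_statistic(img: np.ndarray, factor: str) -> float:
    """The raw probe statistic matched to ``factor`` (before the logistic map)."""
    _check_rgb(img)
    if factor not in _STATISTICS:
        raise ValueError(f"unknown factor {factor!r}; expected one of {FACTOR_NAMES}")
    return _STATISTICS[factor](img)


def make_probe_predictor(
    target_factor: str,
    gain: float | None = None,
    center: float | None = None,
    hue_reference: float | None = None,
) -> FunctionPredictor:
    """Build a probe predictor whose output is driven by one photometric factor.

    Returns ``sigmoid(gain * (statistic - center))``; for the hue probe the
    statistic is already a signed offset from ``hue_reference`` and
    ``center`` defaults to 0.  Outputs are strictly inside (0, 1).
    """
    if target_factor not in _STATISTICS:
        raise ValueError(
            f"unknown factor {target_factor!r}; expected one of {FACTOR_NAMES}"
        )
    gain = _DEFAULT_GAIN[target_factor] if gain is None else float(gain)
    center = _DEFAULT_CENTER[target_factor] if center is None else float(center)

    if target_factor == "hue":
        ref = _DEFAULT_HUE_REFERENCE if hue_reference is None else float(hue_reference)

        def stat(img: np.ndarray) -> float:
            return _hue_circular_offset(img, reference=ref)

    else:
        stat = _STATISTICS[target_factor]

    def fn(img: np.ndarray) -> float:
        z = gain * (stat(img) - center)
        return float(1.0 / (1.0 + np.exp(-z)))

    return FunctionPredictor(fn, name=f"probe:{target_factor}")


def make_constant_predictor(p: float = 0.5) -> FunctionPredictor:
    """A predictor that ignores its input (degenerate-response fixture)."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"probability must be in [0, 1], got {p}")
    return FunctionPredictor(lambda img: p, name=f"constant:{p}")
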