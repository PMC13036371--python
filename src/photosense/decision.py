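"""Decision-level instability and calibration metrics, and one-at-a-time sweeps.

The variance-based indices describe the continuous probability output;
clinical use thresholds it.  Three complementary metrics quantify what the
perturbation distribution does to the thresholded decision:

* flip rate — fraction of perturbed predictions whose label (``p >= t`` is
  positive) differs from the baseline label;
* Gini dispersion — ``2 p_hat (1 - p_hat)`` with ``p_hat`` the fraction of
  positive perturbed labels, i.e. twice the Bernoulli variance of the
  decision, in [0, 0.5];
* Brier score — mean squared difference between predicted probabilities and
  binary outcomes, a calibration measure.

One-at-a-time (OAT) sweeps vary a single factor linearly across its bounds
with every other factor held at its nominal value (1.0 for scalings, 0.0
for the hue shift), tracing the probability response curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bounds import FACTOR_NAMES, FactorBounds, default_bounds, validate_bounds
from .perturb import FactorSample, apply_perturbation, resize_image
from .predictors import Predictor, check_probabilities
from .pipeline import PerImageSensitivity

__all__ = [
    "flip_rate",
    "gini_dispersion",
    "brier",
    "oat_sweep",
    "OATSweep",
    "decision_table",
    "plot_oat_panel",
]


def _labels(p: np.ndarray, t: float) -> np.ndarray:
    return (np.asarray(p, dtype=float) >= t).astype(int)


def _check_probs(p, name: str) -> np.ndarray:
    p = np.asarray(p, dtype=float).ravel()
    if p.size == 0:
        raise ValueError(f"{name} is empty")
    if not np.all((p >= 0) & (p <= 1)):
        raise ValueError(f"{name} contains values outside [0, 1]")
    return p


def flip_rate(baseline_p: float, perturbed_p, t: float = 0.5) -> float:
    """Fraction of perturbed predictions whose thresholded label flips.

    The positive rule is ``p >= t``, so a baseline exactly at the threshold
    is labelled positive.
    """
    if not (0.0 <= baseline_p <= 1.0):
        raise ValueError(f"baseline probability {baseline_p} outside [0, 1]")
    if not (0.0 < t < 1.0):
        raise ValueError(f"threshold must be in (0, 1), got {t}")
    perturbed_p = _check_probs(perturbed_p, "perturbed probabilities")
    base_label = int(baseline_p >= t)
    return float(np.mean(_labels(perturbed_p, t) != base_label))


def gini_dispersion(perturbed_p, t: float = 0.5) -> float:
    """Gini impurity ``2 p_hat (1 - p_hat)`` of the thresholded perturbed labels.

    Equals twice the Bernoulli variance of the decision: 0 when every
    perturbation yields the same label, maximal 0.5 at an even split.
    """
    if not (0.0 < t < 1.0):
        raise ValueError(f"threshold must be in (0, 1), got {t}")
    perturbed_p = _check_probs(perturbed_p, "perturbed probabilities")
    p_hat = float(np.mean(_labels(perturbed_p, t)))
    return 2.0 * p_hat * (1.0 - p_hat)


def brier(probabilities, labels) -> float:
    """Mean squared difference between probabilities and binary outcomes."""
    p = _check_probs(probabilities, "probabilities")
    y = np.asarray(labels, dtype=float).ravel()
    if y.size != p.size:
        raise ValueError(f"length mismatch: {p.size} probabilities vs {y.size} labels")
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("labels must be binary (0/1)")
    return float(np.mean((p - y) ** 2))


@dataclass(frozen=True)
class OATSweep:
    """Probability response of one factor swept across its bounds."""

    factor: str
    grid: np.ndarray
    probabilities: np.ndarray
    nominal: FactorSample
    image_id: str

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"image_id": self.image_id, "factor": self.factor,
             "value": self.grid, "probability": self.probabilities}
        )


def oat_sweep(
    image,
    predictor: Predictor,
    factor: str,
    bounds: Sequence[FactorBounds] | None = None,
    n_steps: int = 5,
    side: int = 128,
) -> OATSweep:
    """Sweep one factor over ``n_steps`` evenly spaced values, others nominal."""
    if factor not in FACTOR_NAMES:
        raise ValueError(f"unknown factor {factor!r}; expected one of {FACTOR_NAMES}")
    if n_steps < 2:
        raise ValueError(f"n_steps must be >= 2, got {n_steps}")
    bounds = validate_bounds(bounds or default_bounds(), photometric=True)
    b = next(x for x in bounds if x.name == factor)
    grid = np.linspace(b.lo, b.hi, n_steps)
    pixels = image.image if hasattr(image, "image") else np.asarray(image)
    image_id = getattr(image, "image_id", "image")
    base = resize_image(pixels, side)
    nominal = FactorSample.nominal()
    variants = []
    for v in grid:
        values = nominal.to_array()
        values[FACTOR_NAMES.index(factor)] = v
        variants.append(
            apply_perturbation(base, FactorSample.from_array(values), side=side, resize=False)
        )
    probs = check_probabilities(predictor.predict(variants), context=f"OAT on {image_id}")
    return OATSweep(factor=factor, grid=grid, probabilities=probs,
                    nominal=nominal, image_id=str(image_id))


def plot_oat_panel(sweeps: Sequence[OATSweep], path, threshold: float = 0.5) -> None:
    """Save a panel of OAT response curves, one subplot per factor."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(sweeps), figsize=(3 * len(sweeps), 2.8), sharey=True)
    axes = np.atleast_1d(axes)
    for ax, sweep in zip(axes, sweeps):
        ax.plot(sweep.grid, sweep.probabilities, marker="o")
        ax.axhline(threshold, color="gray", ls="--", lw=0.8)
        ax.set_title(sweep.factor)
        ax.set_ylim(0, 1)
        ax.set_xlabel("factor value")
    axes[0].set_ylabel("P(positive)")
    fig.suptitle(f"One-at-a-time response, image {sweeps[0].image_id}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def decision_table(
    results: Sequence[PerImageSensitivity],
    labels: Mapping[str, int],
    t: float = 0.5,
) -> pd.DataFrame:
    """Dataset decision metrics, overall and stratified by melanoma status.

    The dataset flip rate pools every image x perturbation pair (so images
    are evaluation-weighted); the Gini column reports the mean and sample
    SD of per-image Gini dispersion; the Brier score uses the baseline
    (unperturbed) probabilities against the true labels.
    """
    results = list(results)
    if not results:
        raise ValueError("no per-image results")

    def metrics(subset: list[PerImageSensitivity]) -> dict:
        if not subset:
            return {}
        flips = np.concatenate(
            [
                _labels(r.responses, t) != int(r.baseline_p >= t)
                for r in subset
            ]
        )
        ginis = np.array([gini_dispersion(r.responses, t) for r in subset])
        base_p = np.array([r.baseline_p for r in subset])
        y = np.array([labels[r.image_id] for r in subset], dtype=float)
        return {
            "n_images": len(subset),
            "flip_rate": float(np.mean(flips)),
            "gini_mean": float(np.mean(ginis)),
            "gini_sd": float(np.std(ginis, ddof=1)) if len(subset) > 1 else 0.0,
            "brier": brier(base_p, y),
        }

    mel = [r for r in results if labels.get(r.image_id) == 1]
    non = [r for r in results if labels.get(r.image_id) == 0]
    rows = []
    for name, subset in (("melanoma", mel), ("non-melanoma", non), ("overall", results)):
        row = metrics(subset)
        if row:
            rows.append({"category": name, **row})
    return pd.DataFrame(rows)
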