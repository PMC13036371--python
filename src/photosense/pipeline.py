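"""Per-image sensitivity runs, cross-image aggregation, and stability checks.

For each image the predictor is evaluated on every row of one Saltelli
design (the same design is reused across images, so cross-image differences
in indices are attributable to the images rather than to sampling noise),
yielding per-image first-order and total-order indices plus the baseline
probability on the nominal perturbation.  Indices are then aggregated
across images by the unweighted arithmetic mean with sample standard
deviation and a normal-approximation 95% confidence half-width
(1.96 SD / sqrt(M)); images with a degenerate (flat) response are excluded
from the means and counted.  Ranking stability under dataset reduction is
assessed by stratified subsampling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import kendalltau

from .bounds import FACTOR_NAMES, FactorBounds, default_bounds, validate_bounds
from .perturb import FactorSample, apply_perturbation, resize_image
from .predictors import Predictor, check_probabilities
from .sobol import SaltelliDesign, estimate_sobol, saltelli_sample

__all__ = [
    "PerImageSensitivity",
    "AggregateReport",
    "run_image_gsa",
    "run_dataset_gsa",
    "aggregate",
    "subsample_stability",
]

logger = logging.getLogger(__name__)


@dataclass
class PerImageSensitivity:
    """Sensitivity indices and perturbation responses for one image."""

    image_id: str
    names: tuple[str, ...]
    S1: np.ndarray
    ST: np.ndarray
    degenerate: bool
    baseline_p: float
    n_eval: int
    responses: np.ndarray = field(repr=False)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "image_id": self.image_id,
                "factor": list(self.names),
                "S1": self.S1,
                "ST": self.ST,
            }
        )


@dataclass
class AggregateReport:
    """Cross-image aggregation of sensitivity indices.

    ``overall`` has one row per factor with columns mean_S1, sd_S1, ci95_S1,
    mean_ST, sd_ST, ci95_ST and interaction (mean_ST - mean_S1); ``strata``
    maps stratum labels to tables of the same shape.  ``n_used`` counts the
    images entering the means; degenerate images are excluded and counted.
    """

    overall: pd.DataFrame
    strata: dict[str, pd.DataFrame]
    n_input: int
    n_used: int
    n_degenerate: int

    def st_ranking(self) -> list[str]:
        """Factor names ordered by decreasing mean total-order index."""
        return list(self.overall.sort_values("mean_ST", ascending=False)["factor"])


def run_image_gsa(
    image,
    predictor: Predictor,
    bounds: Sequence[FactorBounds] | None = None,
    N: int = 256,
    seed: int = 2021,
    design: SaltelliDesign | None = None,
    side: int = 128,
    image_id: str | None = None,
    batch_size: int = 256,
) -> PerImageSensitivity:
    """Run one image through the perturb -> predict -> estimate chain.

    The predictor is evaluated on all ``N (D + 2)`` perturbed variants in
    the design's documented row order; the baseline probability is the
    prediction on the nominal perturbation (the resized original).  A
    pre-built ``design`` may be passed in to share one design across
    images.
    """
    pixels = image.image if hasattr(image, "image") else np.asarray(image)
    if image_id is None:
        image_id = getattr(image, "image_id", "image")
    if design is None:
        bounds = validate_bounds(bounds or default_bounds(), photometric=True)
        design = saltelli_sample(bounds, N=N, seed=seed)
    elif tuple(design.names) != FACTOR_NAMES:
        raise ValueError(f"design factors {design.names} != {FACTOR_NAMES}")

    base = resize_image(pixels, side)
    rows = design.rows
    y = np.empty(rows.shape[0])
    for start in range(0, rows.shape[0], batch_size):
        chunk = rows[start : start + batch_size]
        variants = [
            apply_perturbation(base, FactorSample.from_array(r), side=side, resize=False)
            for r in chunk
        ]
        p = check_probabilities(predictor.predict(variants), context=f"predictor on {image_id}")
        if p.size != len(variants):
            raise RuntimeError(
                f"predictor returned {p.size} probabilities for {len(variants)} images"
            )
        y[start : start + len(variants)] = p
    baseline = float(
        check_probabilities(
            predictor.predict([apply_perturbation(base, FactorSample.nominal(), side=side, resize=False)]),
            context=f"predictor on {image_id} (baseline)",
        )[0]
    )
    result = estimate_sobol(design, y)
    logger.info("image %s: %d evaluations, baseline_p=%.4f%s",
                image_id, design.n_rows, baseline,
                " [degenerate]" if result.degenerate else "")
    return PerImageSensitivity(
        image_id=str(image_id),
        names=design.names,
        S1=result.S1,
        ST=result.ST,
        degenerate=result.degenerate,
        baseline_p=baseline,
        n_eval=design.n_rows + 1,
        responses=y,
    )


def run_dataset_gsa(
    records: Sequence,
    predictor: Predictor,
    bounds: Sequence[FactorBounds] | None = None,
    N: int = 256,
    seed: int = 2021,
    side: int = 128,
) -> list[PerImageSensitivity]:
    """Run the per-image analysis over a dataset, reusing one Saltelli design."""
    bounds = validate_bounds(bounds or default_bounds(), photometric=True)
    design = saltelli_sample(bounds, N=N, seed=seed)
    results = []
    for rec in records:
        results.append(
            run_image_gsa(rec, predictor, design=design, side=side)
        )
    return results


def _index_table(rows: list[PerImageSensitivity], names: tuple[str, ...]) -> pd.DataFrame:
    M = len(rows)
    S1 = np.array([r.S1 for r in rows])
    ST = np.array([r.ST for r in rows])
    sd_S1 = S1.std(axis=0, ddof=1) if M > 1 else np.zeros(len(names))
    sd_ST = ST.std(axis=0, ddof=1) if M > 1 else np.zeros(len(names))
    mean_S1, mean_ST = S1.mean(axis=0), ST.mean(axis=0)
    return pd.DataFrame(
        {
            "factor": list(names),
            "mean_S1": mean_S1,
            "sd_S1": sd_S1,
            "ci95_S1": 1.96 * sd_S1 / np.sqrt(M),
            "mean_ST": mean_ST,
            "sd_ST": sd_ST,
            "ci95_ST": 1.96 * sd_ST / np.sqrt(M),
            "interaction": mean_ST - mean_S1,
            "n_images": M,
        }
    )


def aggregate(
    results: Sequence[PerImageSensitivity],
    strata: Mapping[str, str] | None = None,
) -> AggregateReport:
    """Aggregate per-image indices by unweighted arithmetic mean.

    ``strata`` optionally maps image_id to a group label (e.g. melanoma /
    non-melanoma, or a demographic bin); a per-group table is produced for
    every non-empty group.  Degenerate images are excluded from all means
    with a logged count; aggregating zero usable images is an error.
    """
    results = list(results)
    if not results:
        raise ValueError("no per-image results to aggregate")
    usable = [r for r in results if not r.degenerate]
    n_degenerate = len(results) - len(usable)
    if n_degenerate:
        logger.warning("excluding %d degenerate image(s) from aggregation", n_degenerate)
    if not usable:
        raise ValueError("all per-image results are degenerate; nothing to aggregate")
    names = usable[0].names
    overall = _index_table(usable, names)

    per_group: dict[str, pd.DataFrame] = {}
    if strata is not None:
        groups: dict[str, list[PerImageSensitivity]] = {}
        for r in usable:
            key = strata.get(r.image_id)
            if key is None:
                continue
            groups.setdefault(str(key), []).append(r)
        for key in sorted(groups):
            members = groups[key]
            if not members:
                logger.warning("stratum %r has no members; omitted", key)
                continue
            per_group[key] = _index_table(members, names)
    return AggregateReport(
        overall=overall,
        strata=per_group,
        n_input=len(results),
        n_used=len(usable),
        n_degenerate=n_degenerate,
    )


def subsample_stability(
    results: Sequence[PerImageSensitivity],
    fractions: Sequence[float] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8),
    n_rep: int = 20,
    seed: int = 2021,
    stratify_on: Mapping[str, object] | None = None,
) -> pd.DataFrame:
    """Stability of the total-order ranking under stratified subsampling.

    For each fraction, ``n_rep`` independent stratified subsamples (without
    replacement, proportional per stratum) are drawn and the aggregated ST
    ranking recomputed.  Returns one row per fraction with the share of
    replicates whose ranking equals the full-data ranking and the mean
    Kendall tau against it.  Replicates in which a stratum empties are
    dropped from the denominator with a warning.
    """
    results = [r for r in results if not r.degenerate]
    if not results:
        raise ValueError("no usable (non-degenerate) results")
    if n_rep < 1:
        raise ValueError(f"n_rep must be >= 1, got {n_rep}")
    for f in fractions:
        if not (0.0 < f <= 1.0):
            raise ValueError(f"fractions must lie in (0, 1], got {f}")

    rng = np.random.default_rng(seed)
    full = aggregate(results)
    full_rank = full.st_ranking()
    factor_pos = {name: i for i, name in enumerate(full_rank)}

    if stratify_on is None:
        groups = {"all": list(results)}
    else:
        groups = {}
        for r in results:
            groups.setdefault(str(stratify_on.get(r.image_id, "unknown")), []).append(r)

    rows = []
    for frac in fractions:
        agree = 0
        taus = []
        n_ok = 0
        for _ in range(n_rep):
            sample: list[PerImageSensitivity] = []
            empty = False
            for members in groups.values():
                k = int(round(frac * len(members)))
                if k == 0:
                    empty = True
                    break
                idx = rng.choice(len(members), size=k, replace=False)
                sample.extend(members[i] for i in idx)
            if empty or not sample:
                logger.warning("fraction %.2f: a stratum emptied; replicate dropped", frac)
                continue
            n_ok += 1
            sub_rank = aggregate(sample).st_ranking()
            if sub_rank == full_rank:
                agree += 1
            tau = kendalltau(
                [factor_pos[n] for n in full_rank],
                [factor_pos[n] for n in sub_rank],
            ).statistic
            taus.append(tau)
        rows.append(
            {
                "fraction": frac,
                "n_replicates": n_ok,
                "rank_agreement": agree / n_ok if n_ok else np.nan,
                "mean_kendall_tau": float(np.mean(taus)) if taus else np.nan,
            }
        )
    return pd.DataFrame(rows)
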