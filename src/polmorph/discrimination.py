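"""Psychometric colour discrimination for a free-flying honeybee observer.

The probability that a bee trained under absolute conditioning discriminates
two colours is a monotone function of their hexagon distance d. It is
modelled here as a logistic with the lower asymptote pinned at chance level:

    P(d) = 0.5 + (A - 0.5) / (1 + exp(-(d - d0)/s))

with upper asymptote A in (0.5, 1], midpoint d0 and slope scale s, both in
hexagon units. The model is calibrated by least squares on recorded
(distance, probability) pairs; a pair of colours counts as discriminable
when the predicted probability strictly exceeds the 70% threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.special import expit

__all__ = [
    "PsychometricModel",
    "ComparisonSummary",
    "fit_psychometric",
    "discrim_prob",
    "above_threshold",
    "summarize_comparisons",
    "COMPARISON_CLASSES",
]

COMPARISON_CLASSES = (
    "sepal-sepal",
    "labellum-labellum",
    "within-flower",
    "cross-flower",
)


@dataclass
class PsychometricModel:
    """Calibrated distance -> discrimination-probability curve."""

    a: float  # upper asymptote, probability
    d0: float  # midpoint distance, hexagon units
    s: float  # slope scale, hexagon units
    rmse: float | None = None
    degenerate: bool = False  # A pinned at the 0.5 chance boundary


@dataclass
class ComparisonSummary:
    """Above-threshold tally for one comparison class."""

    comparison: str
    n_pairs: int
    n_above: int

    @property
    def fraction_above(self) -> int:
        """Percentage of pairs above threshold, rounded to whole percent."""
        return round(100.0 * self.n_above / self.n_pairs)


def _logistic(d, a, d0, s):
    return 0.5 + (a - 0.5) * expit((d - d0) / s)


def fit_psychometric(pairs, n_restarts: int = 5, seed: int = 0) -> PsychometricModel:
    """Least-squares calibration of the psychometric curve.

    Parameters
    ----------
    pairs
        Sequence of (distance, probability) tuples, or a DataFrame with
        ``distance`` and ``probability`` columns. At least 4 pairs with
        non-constant distances; probabilities in [0.5, 1].
    n_restarts
        Optimizer restarts from jittered initial values; the best-RMSE fit
        is kept. Deterministic under ``seed``.
    """
    if isinstance(pairs, pd.DataFrame):
        d = pairs["distance"].to_numpy(dtype=float)
        p = pairs["probability"].to_numpy(dtype=float)
    else:
        arr = np.asarray(list(pairs), dtype=float)
        d, p = arr[:, 0], arr[:, 1]
    if d.size < 4:
        raise ValueError("need at least 4 calibration pairs")
    if np.ptp(d) == 0:
        raise ValueError("calibration distances are all equal")
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    if np.any((p < 0.5) | (p > 1.0)):
        raise ValueError("probabilities must lie in [0.5, 1]")

    rng = np.random.default_rng(seed)
    p0_base = [max(p.max(), 0.51), float(np.median(d)), float(np.ptp(d)) / 10.0]
    bounds = ([0.5, 1e-9, 1e-9], [1.0, 10.0 * d.max(), 10.0 * d.max()])
    best = None
    for k in range(n_restarts):
        p0 = list(p0_base)
        if k:
            p0[1] *= rng.uniform(0.3, 1.5)
            p0[2] *= rng.uniform(0.1, 2.0)
        try:
            popt, _ = curve_fit(_logistic, d, p, p0=p0, bounds=bounds, maxfev=20000)
        except RuntimeError:
            continue
        rmse = float(np.sqrt(np.mean((_logistic(d, *popt) - p) ** 2)))
        if best is None or rmse < best[1]:
            best = (popt, rmse)
    if best is None:
        raise RuntimeError("psychometric fit failed to converge")
    (a, d0, s), rmse = best
    # Degenerate when the asymptote collapses to chance or the fitted curve is
    # flat over the calibration range (all probabilities at chance level).
    flat = float(np.ptp(_logistic(d, a, d0, s))) < 1e-3
    return PsychometricModel(
        a=float(a), d0=float(d0), s=float(s), rmse=rmse,
        degenerate=bool(a - 0.5 < 1e-3 or flat),
    )


def discrim_prob(model: PsychometricModel, d):
    """Predicted discrimination probability at hexagon distance(s) d >= 0."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    out = _logistic(d, model.a, model.d0, model.s)
    return float(out) if out.ndim == 0 else out


def above_threshold(probability: float, theta: float = 0.70) -> bool:
    """Strict 'exceeds the threshold' rule: probability > theta."""
    if not 0.0 <= probability <= 1.0:
        raise ValueError("probability must lie in [0, 1]")
    return probability > theta


def summarize_comparisons(
    distance_matrix: pd.DataFrame,
    part_labels: dict,
    flower_ids: dict,
    model: PsychometricModel,
    theta: float = 0.70,
) -> list[ComparisonSummary]:
    """Tally above-threshold pairs in the four comparison classes.

    Classes: sepal-sepal and labellum-labellum between different flowers,
    sepal-vs-labellum within one flower, and sepal-vs-labellum across
    flowers. Each sample label must appear in ``part_labels`` (sepal or
    labellum) and ``flower_ids``.
    """
    labels = list(distance_matrix.index)
    for lab in labels:
        if lab not in part_labels or part_labels[lab] not in ("sepal", "labellum"):
            raise ValueError(f"sample {lab!r} lacks a sepal/labellum part label")
        if lab not in flower_ids:
            raise ValueError(f"sample {lab!r} lacks a flower id")
    tallies = {c: [0, 0] for c in COMPARISON_CLASSES}
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            same_flower = flower_ids[a] == flower_ids[b]
            pa, pb = part_labels[a], part_labels[b]
            if pa == pb:
                if same_flower:
                    continue  # replicate measurements of one part
                cls = "sepal-sepal" if pa == "sepal" else "labellum-labellum"
            else:
                cls = "within-flower" if same_flower else "cross-flower"
            prob = discrim_prob(model, float(distance_matrix.loc[a, b]))
            tallies[cls][0] += 1
            tallies[cls][1] += int(above_threshold(prob, theta))
    return [
        ComparisonSummary(cls, n_pairs, n_above)
        for cls, (n_pairs, n_above) in tallies.items()
        if n_pairs
    ]
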