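"""Psychological scale construction from a sorted comparison matrix.

The scale is built by JND accumulation: the rank-1 stimulus gets magnitude 0,
and each next magnitude adds the discrimination threshold between adjacent
ranks.  The threshold is half the rank-distance between the 25% and 75%
points of the logistic psychometric function governing the pair — for a
logistic with slope a that distance is 2·ln(3)/a, so the threshold is
ln(3)/a rank units, expressed on the 0–1 normalized rank axis.  Magnitudes
are finally divided by their maximum so the scale spans [0, 1].

The slope governing an adjacent pair is taken as the geometric mean of the
two stimuli's fitted slopes (a symmetric choice that avoids direction bias).

Also provided: the four-parameter hyperbolic (Naka–Rushton style) response
function R = A·C^p / (z^q + C^q) classically used to summarize contrast
response data, and a Pearson correlation helper for comparing an estimated
scale against known true values.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .ordering import FitFailure, SortedOrder

__all__ = [
    "ScaleEstimate",
    "HyperbolicFit",
    "jnd_scale",
    "fit_hyperbolic_response",
    "hyperbolic_response",
    "scale_correlation",
    "ConstantInputError",
]


class ConstantInputError(ValueError):
    """Correlation is undefined because one input vector is constant."""


@dataclass
class ScaleEstimate:
    """Normalized psychological magnitudes in [0, 1] keyed by stimulus ID.

    ``thresholds[i]`` is the JND between sorted ranks i+1 and i+2 in
    normalized rank units (before the final divide-by-maximum).
    """

    order: tuple[str, ...]
    magnitudes: dict[str, float]
    thresholds: np.ndarray

    def values_for(self, ids: Sequence[str]) -> np.ndarray:
        return np.array([self.magnitudes[s] for s in ids])

    def to_frame(self) -> pd.DataFrame:
        """Scale export: stimulus_id, rank, magnitude, threshold_to_next."""
        n = len(self.order)
        thr = list(self.thresholds) + [np.nan]
        return pd.DataFrame(
            {
                "stimulus_id": list(self.order),
                "rank": np.arange(1, n + 1),
                "magnitude": [self.magnitudes[s] for s in self.order],
                "threshold_to_next": thr,
            }
        )

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def jnd_scale(order: SortedOrder, n: int | None = None) -> ScaleEstimate:
    """Accumulate JND thresholds along the sorted order into a [0, 1] scale."""
    if order.fits is None:
        raise FitFailure("jnd_scale needs an order with psychometric fits")
    if n is None:
        n = order.n_stimuli
    slopes = order.slopes()
    if np.any(slopes <= 0):
        raise FitFailure("non-positive fitted slope")
    # geometric-mean slope per adjacent pair; ln(3)/a rank units per JND
    pair_slopes = np.sqrt(slopes[:-1] * slopes[1:])
    thresholds = np.log(3.0) / pair_slopes / max(n - 1, 1)
    magnitudes = np.concatenate([[0.0], np.cumsum(thresholds)])
    top = magnitudes[-1]
    if top > 0:
        magnitudes = magnitudes / top
    return ScaleEstimate(
        order=order.order,
        magnitudes={s: float(m) for s, m in zip(order.order, magnitudes)},
        thresholds=thresholds,
    )


# ---------------------------------------------------------------------------
# hyperbolic (Naka-Rushton style) response function
# ---------------------------------------------------------------------------

def hyperbolic_response(
    c: np.ndarray | float, amplitude: float, semi_saturation: float,
    p_exp: float, q_exp: float
) -> np.ndarray | float:
    """R = A·C^p / (z^q + C^q); accelerating at low C, saturating at high C."""
    c = np.asarray(c, dtype=float)
    return amplitude * c ** p_exp / (semi_saturation ** q_exp + c ** q_exp)


@dataclass(frozen=True)
class HyperbolicFit:
    """Fitted parameters of R = A·C^p / (z^q + C^q), all positive."""

    amplitude: float
    semi_saturation: float
    p_exp: float
    q_exp: float
    residual: float

    @property
    def params(self) -> tuple[float, float, float, float]:
        return (self.amplitude, self.semi_saturation, self.p_exp, self.q_exp)

    def predict(self, c: np.ndarray | float) -> np.ndarray | float:
        return hyperbolic_response(c, *self.params)


class HyperbolicFitError(RuntimeError):
    """Least-squares fit of the hyperbolic response did not converge."""


def fit_hyperbolic_response(
    x_values: Sequence[float], y_values: Sequence[float]
) -> HyperbolicFit:
    """Least-squares fit of the 4-parameter hyperbolic response function.

    Requires at least four strictly positive stimulus values (e.g. contrasts).
    """
    x = np.asarray(x_values, dtype=float)
    y = np.asarray(y_values, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 data points for a 4-parameter fit")
    if np.any(x <= 0):
        raise ValueError("stimulus values must be strictly positive")

    a0 = max(float(y.max()), 1e-6)
    z0 = float(np.exp(np.interp(a0 / 2.0, np.sort(y), np.log(x)[np.argsort(y)])))
    z0 = min(max(z0, x.min()), x.max())
    p0 = [a0, z0, 2.0, 2.0]
    try:
        popt, _ = optimize.curve_fit(
            hyperbolic_response, x, y, p0=p0,
            bounds=(1e-12, np.inf), maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        raise HyperbolicFitError(f"hyperbolic fit failed: {exc}") from exc
    resid = float(((hyperbolic_response(x, *popt) - y) ** 2).sum())
    return HyperbolicFit(*map(float, popt), residual=resid)


# ---------------------------------------------------------------------------
# agreement with known true values
# ---------------------------------------------------------------------------

def scale_correlation(
    estimate: ScaleEstimate | Mapping[str, float],
    truth: Mapping[str, float],
) -> float:
    """Pearson correlation between estimated and true values, matched by ID."""
    mags = estimate.magnitudes if isinstance(estimate, ScaleEstimate) else estimate
    if set(mags) != set(truth):
        raise KeyError("estimate and truth must cover the same stimulus IDs")
    ids = sorted(mags)
    if len(ids) < 3:
        raise ValueError("correlation needs at least 3 stimuli")
    a = np.array([mags[s] for s in ids])
    b = np.array([truth[s] for s in ids])
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ConstantInputError("correlation undefined for a constant vector")
    return float(stats.pearsonr(a, b).statistic)
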