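"""scikit-learn style estimators for comparison-matrix scaling.

``ComparisonScaler`` is the fit-shaped core of the package: it consumes
max-choice evidence (a :class:`~acmatrix.ComparisonTally`, an iterable of
:class:`~acmatrix.ChoiceRecord`, or a response-log DataFrame), sorts the
comparison matrix and builds the JND-based psychological scale.  It plays
by sklearn's rules (``get_params``/``set_params``, fitted attributes with a
trailing underscore, ``fit``/``transform``) so it composes with pipelines
and model selection.

``HyperbolicResponse`` wraps the four-parameter hyperbolic response
function R = A·C^p / (z^q + C^q) as a tiny regressor, handy for mapping an
estimated scale back onto a physical stimulus axis such as contrast.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import ordering, scaling
from ._logistic import DEFAULT_SLOPE_BOUNDS
from .tally import ChoiceRecord, ComparisonTally, StimulusSet

__all__ = ["ComparisonScaler", "HyperbolicResponse"]


def _coerce_tally(
    X, stimulus_ids: Sequence[str] | None
) -> ComparisonTally:
    if isinstance(X, ComparisonTally):
        return X
    if isinstance(X, pd.DataFrame):
        records = [
            ChoiceRecord(
                int(row.trial_index),
                int(row.selection_index),
                tuple(str(row.displayed_ids).split(";")),
                str(row.chosen_id),
            )
            for row in X.itertuples(index=False)
        ]
    else:
        records = list(X)
        if records and not isinstance(records[0], ChoiceRecord):
            raise TypeError(
                "X must be a ComparisonTally, a response-log DataFrame, or "
                "an iterable of ChoiceRecord"
            )
    if stimulus_ids is None:
        seen: dict[str, None] = {}
        for r in records:
            for s in r.displayed:
                seen.setdefault(s, None)
        stimulus_ids = sorted(seen)
    tally = ComparisonTally(StimulusSet(tuple(stimulus_ids)))
    for r in records:
        tally.record_choice(r)
    return tally


class ComparisonScaler(TransformerMixin, BaseEstimator):
    """Rank and scale stimuli from iterative max-choice comparison data.

    Parameters
    ----------
    stimulus_ids : sequence of str, optional
        The full stimulus set.  Inferred from the records when omitted
        (sorted union of displayed IDs) — pass it explicitly if some
        stimuli may never appear in the log.
    slope_bounds : (lo, hi), default (0.05, 50)
        Bounds on the logistic slope in inverse-rank units; the upper bound
        keeps JND thresholds finite on step-like data.
    max_iterations : int, default 40
        Cap on fit evaluations during the residual-descent sort.
    default_slope : float, default 1.0
        Substitute slope for stimuli without any observed comparison.
    random_state : int or None
        Seed for the random placement of data-free stimuli and tie breaks.

    Attributes
    ----------
    order_ : tuple of str
        Stimulus IDs sorted ascending in estimated magnitude.
    ranks_ : dict
        Stimulus ID -> rank, 1 = smallest magnitude.
    fits_ : tuple of PsychometricFit
        Per-sorted-position logistic (slope, centroid).
    rate_matrix_ : ndarray of shape (N, N)
        Estimated win rates q in sorted coordinates.
    magnitudes_ : dict
        Stimulus ID -> JND-accumulated magnitude in [0, 1].
    thresholds_ : ndarray of shape (N-1,)
        JND between adjacent ranks in normalized rank units.
    converged_ : bool, n_iter_ : int, residual_ : float
        Diagnostics of the sorting descent.
    """

    def __init__(
        self,
        stimulus_ids: Sequence[str] | None = None,
        slope_bounds: tuple[float, float] = DEFAULT_SLOPE_BOUNDS,
        max_iterations: int = ordering.DEFAULT_MAX_ITERATIONS,
        default_slope: float = ordering.DEFAULT_SLOPE,
        random_state: int | None = None,
    ) -> None:
        self.stimulus_ids = stimulus_ids
        self.slope_bounds = slope_bounds
        self.max_iterations = max_iterations
        self.default_slope = default_slope
        self.random_state = random_state

    def fit(self, X, y=None) -> "ComparisonScaler":
        """Sort the comparison matrix and build the JND scale.

        ``X`` is a ComparisonTally, an iterable of ChoiceRecord, or a
        response-log DataFrame with columns
        ``trial_index, selection_index, displayed_ids, chosen_id``.
        """
        tally = _coerce_tally(X, self.stimulus_ids)
        seed = 0 if self.random_state is None else int(self.random_state)
        order = ordering.sort_matrix(
            tally,
            rng_seed=seed,
            slope_bounds=self.slope_bounds,
            max_iterations=self.max_iterations,
            default_slope=self.default_slope,
        )
        scale = scaling.jnd_scale(order)
        self.tally_ = tally
        self.sorted_order_ = order
        self.scale_ = scale
        self.stimulus_ids_ = tally.stimuli.stimulus_ids
        self.order_ = order.order
        self.ranks_ = order.ranks()
        self.fits_ = order.fits
        self.rate_matrix_ = order.estimated_rates
        self.magnitudes_ = scale.magnitudes
        self.thresholds_ = scale.thresholds
        self.converged_ = order.converged
        self.n_iter_ = order.iterations_used
        self.residual_ = order.residual
        return self

    def transform(self, X: Sequence[str]) -> np.ndarray:
        """Map stimulus IDs to their estimated magnitudes (column vector)."""
        check_is_fitted(self, "magnitudes_")
        return np.array([[self.magnitudes_[str(s)]] for s in X])

    def fit_transform(self, X, y=None, **fit_params) -> np.ndarray:
        """Fit on the records in X and return magnitudes for the full set."""
        self.fit(X, y)
        return self.transform(self.stimulus_ids_)

    def score(self, X, y) -> float:
        """Pearson correlation between fitted magnitudes and true values.

        ``X`` is ignored (sklearn signature compatibility); ``y`` is a
        mapping from stimulus ID to true value.
        """
        check_is_fitted(self, "magnitudes_")
        return scaling.scale_correlation(self.scale_, dict(y))


class HyperbolicResponse(RegressorMixin, BaseEstimator):
    """Least-squares fit of R = A·C^p / (z^q + C^q) to scale-vs-stimulus data.

    Fitted attributes: ``amplitude_`` (A), ``semi_saturation_`` (z),
    ``p_exp_``, ``q_exp_`` and ``residual_`` (sum of squared errors).
    """

    def fit(self, X, y) -> "HyperbolicResponse":
        x = np.asarray(X, dtype=float).ravel()
        fit = scaling.fit_hyperbolic_response(x, np.asarray(y, dtype=float))
        self.amplitude_ = fit.amplitude
        self.semi_saturation_ = fit.semi_saturation
        self.p_exp_ = fit.p_exp
        self.q_exp_ = fit.q_exp
        self.residual_ = fit.residual
        self.fit_ = fit
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "fit_")
        x = np.asarray(X, dtype=float).ravel()
        return np.asarray(self.fit_.predict(x))
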