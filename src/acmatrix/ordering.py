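"""Sorting the comparison matrix by estimated psychological magnitude.

The sort iterates two steps until no re-ranking improves the fit:

1. for every sorted position, fit an increasing logistic psychometric
   function to the win rates of that stimulus against all others, by
   binomial maximum likelihood in rank coordinates;
2. build the estimated rate matrix q from the fits and propose a re-rank —
   first by the row sums of q (a stimulus with a larger total estimated win
   rate gets a higher rank), then, if that does not help, by
   maximum-likelihood placement of each stimulus against the fitted fields.
   A proposal is accepted only when the regression residual (squared
   observed-minus-estimated rates over observed cells) strictly decreases.

The initial permutation comes from raw win-rate row sums P_i = sum_j p_ij;
stimuli without any data are randomly placed (P drawn as 0 or 1) and ties
are broken randomly, both from the supplied seed.

Convention: sorted position ascends with magnitude (position N = largest).
Boundary pseudo-data pin the fits: a virtual rank-0 stimulus loses to every
stimulus and a virtual rank-(N+1) stimulus beats every stimulus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._logistic import (
    DEFAULT_SLOPE_BOUNDS,
    fit_logistic_batch,
    fit_logistic_scipy,
    logistic,
)
from .tally import ComparisonTally

__all__ = [
    "PsychometricFit",
    "SortedOrder",
    "FitFailure",
    "initial_rank",
    "fit_logistic",
    "estimate_rate_matrix",
    "sort_matrix",
]

DEFAULT_MAX_ITERATIONS = 40
DEFAULT_SLOPE = 1.0  # substitute slope (rank units) for stimuli with no data


class FitFailure(RuntimeError):
    """Raised when a psychometric fit has no data cells at all."""


@dataclass(frozen=True)
class PsychometricFit:
    """Logistic slope (inverse-rank units) and centroid (rank units)."""

    slope: float
    centroid: float

    def rate(self, rank: float | np.ndarray) -> float | np.ndarray:
        """Predicted win rate at a (possibly fractional) rank coordinate."""
        return logistic(rank, self.slope, self.centroid)


@dataclass
class SortedOrder:
    """A permutation of stimulus IDs by estimated magnitude, with fits.

    ``order[0]`` is rank 1 (smallest estimated magnitude), ``order[-1]`` is
    rank N (largest).  ``estimated_rates[i, j]`` is q for the stimuli at
    sorted positions i+1 and j+1.
    """

    order: tuple[str, ...]
    fits: tuple[PsychometricFit, ...] | None = None
    estimated_rates: np.ndarray | None = None
    converged: bool = False
    iterations_used: int = 0
    residual: float | None = None
    n_responses: dict[str, int] = field(default_factory=dict)

    @property
    def n_stimuli(self) -> int:
        return len(self.order)

    def ranks(self) -> dict[str, int]:
        """Stimulus ID -> rank (1 = smallest magnitude)."""
        return {sid: k + 1 for k, sid in enumerate(self.order)}

    def slopes(self) -> np.ndarray:
        if self.fits is None:
            raise FitFailure("order carries no psychometric fits")
        return np.array([f.slope for f in self.fits])

    def to_frame(self) -> pd.DataFrame:
        """Sorted-order export: stimulus_id, rank, slope, centroid, n_responses."""
        n = self.n_stimuli
        slopes = [f.slope for f in self.fits] if self.fits else [np.nan] * n
        cents = [f.centroid for f in self.fits] if self.fits else [np.nan] * n
        return pd.DataFrame(
            {
                "stimulus_id": list(self.order),
                "rank": np.arange(1, n + 1),
                "slope": slopes,
                "centroid": cents,
                "n_responses": [self.n_responses.get(s, 0) for s in self.order],
            }
        )

    def save_order(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def save_rates(self, path: str | Path) -> None:
        """Estimated-rate matrix export with stimulus-ID headers."""
        if self.estimated_rates is None:
            raise FitFailure("order carries no estimated rate matrix")
        ids = list(self.order)
        pd.DataFrame(self.estimated_rates, index=ids, columns=ids).to_csv(path)


# ---------------------------------------------------------------------------
# initial ranking from raw win-rate sums
# ---------------------------------------------------------------------------

def _initial_perm(tally: ComparisonTally, rng: np.random.Generator) -> np.ndarray:
    rates = tally.win_rate_matrix()
    with np.errstate(invalid="ignore"):
        p = np.nansum(rates, axis=1)
    no_data = tally.per_stimulus_responses == 0
    if no_data.any():
        p = p.astype(float)
        p[no_data] = rng.integers(0, 2, size=int(no_data.sum())).astype(float)
    # random tie-break: shuffle first, then stable-sort ascending in P
    n = tally.n_stimuli
    shuffled = rng.permutation(n)
    return shuffled[np.argsort(p[shuffled], kind="stable")]


def initial_rank(tally: ComparisonTally, rng_seed: int | np.random.Generator = 0) -> SortedOrder:
    """Rank stimuli by raw win-rate row sums (Eq-1 style); order only, no fits."""
    rng = _as_rng(rng_seed)
    perm = _initial_perm(tally, rng)
    ids = tally.stimuli.stimulus_ids
    n_resp = tally.per_stimulus_responses
    return SortedOrder(
        order=tuple(ids[k] for k in perm),
        n_responses={ids[k]: int(n_resp[k]) for k in perm},
    )


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# psychometric fitting in sorted coordinates
# ---------------------------------------------------------------------------

def fit_logistic(
    observed: Sequence[tuple[float, float, float]],
    bounds: tuple[float, float] = DEFAULT_SLOPE_BOUNDS,
) -> PsychometricFit:
    """Maximum-likelihood logistic fit to (rank, successes, totals) cells.

    The caller supplies any boundary pseudo-data as ordinary cells.  Raises
    :class:`FitFailure` when every cell is empty, in which case the caller is
    expected to substitute a default fit.
    """
    obs = np.asarray(observed, dtype=float)
    if obs.ndim != 2 or obs.shape[1] != 3:
        raise ValueError("observed must be a sequence of (rank, successes, totals)")
    if not (obs[:, 2] > 0).any():
        raise FitFailure("all cells empty; no data to fit")
    a, x = fit_logistic_scipy(obs[:, 0], obs[:, 1], obs[:, 2], slope_bounds=bounds)
    return PsychometricFit(slope=a, centroid=x)


def _fit_sorted_columns(
    wins_sorted: np.ndarray,
    slope_bounds: tuple[float, float],
    default_slope: float,
    a_init: np.ndarray | float = 0.5,
    x_init: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit one logistic per sorted position (column), vectorized.

    Returns (slopes, centroids, has_data) in sorted coordinates 1..N.
    Boundary pseudo-data are added at ranks 0 (sure loss) and N+1 (sure win),
    weight one each.  Columns without any observed outcome get the substitute
    default fit centred on their own position.  ``a_init``/``x_init`` allow
    warm starts from a previous, nearby permutation's fits.
    """
    n = wins_sorted.shape[0]
    s_obs = wins_sorted.astype(float)          # s[i, j]: i beat j count
    t_obs = s_obs + s_obs.T
    np.fill_diagonal(t_obs, 0.0)               # self cells carry no weight
    np.fill_diagonal(s_obs, 0.0)

    coords = np.arange(0, n + 2, dtype=float)  # 0 .. N+1
    s = np.zeros((n + 2, n))
    t = np.zeros((n + 2, n))
    s[1 : n + 1] = s_obs
    t[1 : n + 1] = t_obs
    s[0, :] = 0.0                              # virtual rank 0 loses to all
    t[0, :] = 1.0
    s[n + 1, :] = 1.0                          # virtual rank N+1 beats all
    t[n + 1, :] = 1.0

    positions = np.arange(1, n + 1, dtype=float)
    if x_init is None:
        x_init = positions
    slopes, centroids = fit_logistic_batch(
        s, t, coords, slope_bounds=slope_bounds,
        a_init=a_init, x_init=x_init,
    )
    has_data = t_obs.sum(axis=0) > 0
    slopes = np.where(has_data, slopes, default_slope)
    centroids = np.where(has_data, centroids, positions)
    return slopes, centroids, has_data


def estimate_rate_matrix(
    fits: Sequence[PsychometricFit] | tuple[np.ndarray, np.ndarray], n: int | None = None
) -> np.ndarray:
    """Estimated response-rate matrix q from per-position fits.

    q[i', j'] averages the column fit of j' evaluated at rank i' (probability
    that the stimulus at i' beats j') with the complement of the row fit of
    i' evaluated at j', so q[i', j'] + q[j', i'] = 1 holds exactly and the
    diagonal is 0.5.
    """
    if isinstance(fits, tuple) and len(fits) == 2 and isinstance(fits[0], np.ndarray):
        slopes, centroids = fits
    else:
        slopes = np.array([f.slope for f in fits])
        centroids = np.array([f.centroid for f in fits])
    if n is None:
        n = len(slopes)
    ranks = np.arange(1, n + 1, dtype=float)
    # up[i, j] = logistic(rank i; fit of column j)
    z = np.clip(slopes[None, :] * (ranks[:, None] - centroids[None, :]), -500, 500)
    up = 1.0 / (1.0 + np.exp(-z))
    return (up + 1.0 - up.T) / 2.0


# ---------------------------------------------------------------------------
# the full sort
# ---------------------------------------------------------------------------

def _sorted_residual(wins_sorted: np.ndarray, q: np.ndarray) -> float:
    """Sum of squared (observed - estimated) rates over observed cells."""
    w = wins_sorted.astype(float)
    tot = w + w.T
    np.fill_diagonal(tot, 0.0)
    mask = tot > 0
    obs = np.zeros_like(w)
    obs[mask] = w[mask] / tot[mask]
    return float(((obs - q)[mask] ** 2).sum())


def _placement_key(wins_sorted: np.ndarray, slopes: np.ndarray,
                   centroids: np.ndarray) -> np.ndarray:
    """Maximum-likelihood rank placement of each stimulus.

    Holding every opponent's fitted psychometric field fixed, score each
    stimulus's own observed outcomes at every candidate rank and return the
    best rank per stimulus.  Re-sorting by this key relocates badly placed
    stimuli in one jump, which the row-sum re-rank cannot do (its positional
    term anchors each stimulus near its current rank).  Stimuli without data
    keep their current position.
    """
    n = wins_sorted.shape[0]
    ranks = np.arange(1, n + 1, dtype=float)
    z = np.clip(slopes[None, :] * (ranks[:, None] - centroids[None, :]), -500, 500)
    up = np.clip(1.0 / (1.0 + np.exp(-z)), 1e-12, 1.0 - 1e-12)  # up[t, j]
    log_w, log_l = np.log(up), np.log(1.0 - up)
    w = wins_sorted.astype(float).copy()
    np.fill_diagonal(w, 0.0)
    # ll[s, t] = sum_j wins[s,j]*log P(beat j at t) + wins[j,s]*log P(lose)
    ll = w @ log_w.T + w.T @ log_l.T
    key = ll.argmax(axis=1).astype(float)
    has_data = (w + w.T).sum(axis=1) > 0
    key[~has_data] = np.arange(n)[~has_data]
    return key


def sort_matrix(
    tally: ComparisonTally,
    config: "object | None" = None,
    rng_seed: int | np.random.Generator = 0,
    *,
    slope_bounds: tuple[float, float] = DEFAULT_SLOPE_BOUNDS,
    max_iterations: int = DEFAULT_MAX_ITERATIONS,
    default_slope: float = DEFAULT_SLOPE,
    init_order: SortedOrder | None = None,
) -> SortedOrder:
    """Sort the comparison matrix by the iterated rank-then-fit procedure.

    ``config`` may be any object with ``slope_bounds`` / ``max_iterations`` /
    ``default_slope`` attributes (e.g. a :class:`~acmatrix.ComparisonScaler`);
    keyword arguments are used otherwise.  ``init_order`` warm-starts the
    descent from an existing order (e.g. the previous trial's) instead of
    the raw win-rate ranking; whichever start has the lower residual wins.
    """
    if config is not None:
        slope_bounds = getattr(config, "slope_bounds", slope_bounds)
        max_iterations = getattr(config, "max_iterations", max_iterations)
        default_slope = getattr(config, "default_slope", default_slope)
    rng = _as_rng(rng_seed)
    wins = tally.wins
    n = tally.n_stimuli
    ids = tally.stimuli.stimulus_ids
    identity = np.arange(n)

    def evaluate(perm, a_init=0.5, x_init=None):
        wins_sorted = wins[np.ix_(perm, perm)]
        slopes, centroids, _ = _fit_sorted_columns(
            wins_sorted, slope_bounds, default_slope, a_init=a_init, x_init=x_init
        )
        q = estimate_rate_matrix((slopes, centroids), n)
        return wins_sorted, slopes, centroids, q, _sorted_residual(wins_sorted, q)

    perm = _initial_perm(tally, rng)
    wins_sorted, slopes, centroids, q, residual = evaluate(perm)
    iterations = 1
    seen = {tuple(perm)}
    if init_order is not None:
        warm = np.array([tally.index[s] for s in init_order.order])
        state = evaluate(warm)
        iterations += 1
        seen.add(tuple(warm))
        if state[4] < residual:
            perm = warm
            wins_sorted, slopes, centroids, q, residual = state
    converged = False

    # Greedy residual descent over permutations.  Each step proposes a
    # re-rank — first by row sums of q (Eq-1 applied to the estimated
    # rates), then, if that does not help, by maximum-likelihood placement —
    # and accepts it when the regression residual decreases, or stays equal
    # for a permutation not visited before (an adjacent swap can leave the
    # residual untouched because the diagonal carries no data, yet the
    # re-rank keys still demand it).  The visited set prevents cycling and
    # equal-residual acceptances are rationed: with very sparse data many
    # permutations fit equally well and chasing them all buys nothing.
    ties_left = 8
    while iterations < max_iterations:
        accepted = False
        for proposal in ("row_sum", "placement"):
            if proposal == "row_sum":
                key = q.sum(axis=1)
            else:
                key = _placement_key(wins_sorted, slopes, centroids)
            reorder = np.argsort(key, kind="stable")
            if np.array_equal(reorder, identity):
                continue
            cand = perm[reorder]
            better_or_new = tuple(cand) not in seen
            seen.add(tuple(cand))
            # warm-start fits: slopes carry over, centroids shift with rank
            positions = np.arange(1, n + 1, dtype=float)
            x_warm = (centroids - positions)[reorder] + positions
            state = evaluate(cand, a_init=slopes[reorder], x_init=x_warm)
            iterations += 1
            improved = state[4] < residual - 1e-12
            tie = (
                not improved
                and better_or_new
                and ties_left > 0
                and state[4] <= residual + 1e-12
            )
            if improved or tie:
                if tie:
                    ties_left -= 1
                perm = cand
                wins_sorted, slopes, centroids, q, residual = state
                accepted = True
                break
            if iterations >= max_iterations:
                break
        if not accepted:
            converged = True
            break

    fits = tuple(PsychometricFit(float(a), float(x)) for a, x in zip(slopes, centroids))
    n_resp = tally.per_stimulus_responses
    return SortedOrder(
        order=tuple(ids[k] for k in perm),
        fits=fits,
        estimated_rates=q,
        converged=converged,
        iterations_used=iterations,
        residual=residual,
        n_responses={ids[k]: int(n_resp[k]) for k in perm},
    )
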