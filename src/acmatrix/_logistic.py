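"""Binomial maximum-likelihood fitting of increasing logistic psychometric
functions in sorted-rank coordinates.

Two entry points share one likelihood:

* :func:`fit_logistic_batch` — damped-Newton MLE for many stimuli at once
  (one column of the sorted comparison matrix per fit).  This is the hot path
  inside matrix sorting and is fully vectorized over columns.
* :func:`fit_logistic_scipy` — bounded L-BFGS-B on the same objective for a
  single fit; used by the public ``fit_logistic`` operation and as an
  internal cross-check of the batch fitter.

The model is p(win at rank r) = 1 / (1 + exp(-a * (r - x))) with slope a > 0
and centroid x, fitted to (rank, successes, totals) cells with a binomial
likelihood weighted by each cell's count.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize

DEFAULT_SLOPE_BOUNDS = (0.05, 50.0)

_STEP_SIZES = (1.0, 0.5, 0.1)


def logistic(rank: np.ndarray | float, slope: float, centroid: float) -> np.ndarray | float:
    """Increasing logistic psychometric function in rank coordinates."""
    z = np.clip(np.asarray(slope) * (np.asarray(rank) - centroid), -500.0, 500.0)
    return 1.0 / (1.0 + np.exp(-z))


def _softplus(eta: np.ndarray) -> np.ndarray:
    """log(1 + e^eta), numerically stable."""
    return np.maximum(eta, 0.0) + np.log1p(np.exp(-np.abs(eta)))


def fit_logistic_batch(
    successes: np.ndarray,
    totals: np.ndarray,
    coords: np.ndarray,
    slope_bounds: tuple[float, float] = DEFAULT_SLOPE_BOUNDS,
    a_init: np.ndarray | float = 0.5,
    x_init: np.ndarray | None = None,
    max_iter: int = 50,
    tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit one logistic per column by damped (projected) Newton iteration.

    Parameters
    ----------
    successes, totals : (P, C) arrays
        Win counts and trial counts at each of P rank coordinates for each of
        C fits; cells with ``totals == 0`` carry no weight.
    coords : (P,) array
        The shared rank coordinates.
    slope_bounds : (lo, hi)
        The slope is projected into this interval at every step, which keeps
        thresholds derived from the fit finite even for perfectly separable
        (step) data.

    Returns
    -------
    slopes, centroids : (C,) arrays

    Comparison matrices are sparse for most of a session, so the iteration
    works on the flattened list of non-empty cells and aggregates per-column
    sums with ``bincount``.
    """
    s = np.asarray(successes, dtype=float)
    t = np.asarray(totals, dtype=float)
    c = np.asarray(coords, dtype=float)
    n_fits = s.shape[1]
    lo, hi = slope_bounds
    span = c.max() - c.min()
    x_lo, x_hi = float(c.min()) - span, float(c.max()) + span

    rows, cols = np.nonzero(t > 0)
    cc = c[rows]
    sv = s[rows, cols]
    tv = t[rows, cols]

    a = np.broadcast_to(np.asarray(a_init, dtype=float), (n_fits,)).copy()
    if x_init is None:
        w = np.bincount(cols, weights=tv, minlength=n_fits)
        wc = np.bincount(cols, weights=tv * cc, minlength=n_fits)
        x = np.where(w > 0, wc / np.where(w > 0, w, 1.0), c.mean())
    else:
        x = np.asarray(x_init, dtype=float).copy()
    a = np.clip(a, lo, hi)
    x = np.clip(x, x_lo, x_hi)
    b = -a * x

    def loglik(a_vec: np.ndarray, b_vec: np.ndarray) -> np.ndarray:
        eta = np.clip(a_vec[cols] * cc + b_vec[cols], -500, 500)
        return np.bincount(
            cols, weights=sv * eta - tv * _softplus(eta), minlength=n_fits
        )

    ll = loglik(a, b)
    ridge = 1e-8

    for _ in range(max_iter):
        eta = np.clip(a[cols] * cc + b[cols], -500, 500)
        mu = 1.0 / (1.0 + np.exp(-eta))
        r = sv - tv * mu
        w = tv * mu * (1.0 - mu)
        g_a = np.bincount(cols, weights=r * cc, minlength=n_fits)
        g_b = np.bincount(cols, weights=r, minlength=n_fits)
        h_aa = np.bincount(cols, weights=w * cc * cc, minlength=n_fits) + ridge
        h_ab = np.bincount(cols, weights=w * cc, minlength=n_fits)
        h_bb = np.bincount(cols, weights=w, minlength=n_fits) + ridge
        det = h_aa * h_bb - h_ab * h_ab
        det = np.where(np.abs(det) < 1e-300, 1e-300, det)
        da = (h_bb * g_a - h_ab * g_b) / det
        db = (h_aa * g_b - h_ab * g_a) / det

        # backtracking: evaluate a few step lengths, keep the best likelihood
        best_ll = ll
        best_a, best_b = a, b
        for step in _STEP_SIZES:
            a1 = np.clip(a + step * da, lo, hi)
            b1 = b + step * db
            x1 = np.clip(-b1 / a1, x_lo, x_hi)
            b1 = -a1 * x1
            ll1 = loglik(a1, b1)
            better = ll1 > best_ll
            best_ll = np.where(better, ll1, best_ll)
            best_a = np.where(better, a1, best_a)
            best_b = np.where(better, b1, best_b)
        moved = max(np.max(np.abs(best_a - a)), np.max(np.abs(best_b - b)))
        gain = float(np.max(best_ll - ll)) if n_fits else 0.0
        a, b, ll = best_a, best_b, best_ll
        # stop when parameters settle or the likelihood is flat (the slope
        # of a separable column can drift forever at no likelihood gain)
        if moved < tol or gain < 1e-7:
            break

    return a, -b / a


def fit_logistic_scipy(
    coords: np.ndarray,
    successes: np.ndarray,
    totals: np.ndarray,
    slope_bounds: tuple[float, float] = DEFAULT_SLOPE_BOUNDS,
) -> tuple[float, float]:
    """Single bounded MLE fit via L-BFGS-B with a few restarts."""
    c = np.asarray(coords, dtype=float)
    s = np.asarray(successes, dtype=float)
    t = np.asarray(totals, dtype=float)
    mask = t > 0
    if not mask.any():
        raise ValueError("no cells with data to fit")
    c, s, t = c[mask], s[mask], t[mask]
    lo, hi = slope_bounds
    span = max(c.max() - c.min(), 1.0)
    x_bounds = (c.min() - span, c.max() + span)

    def nll(theta: np.ndarray) -> float:
        a, x = theta
        eta = np.clip(a * (c - x), -500, 500)
        return -float((s * eta - t * np.logaddexp(0.0, eta)).sum())

    x0_base = float((t * c).sum() / t.sum())
    best = None
    for a0 in (0.2, 1.0, 5.0, hi):
        res = optimize.minimize(
            nll,
            x0=np.array([np.clip(a0, lo, hi), x0_base]),
            method="L-BFGS-B",
            bounds=[slope_bounds, x_bounds],
        )
        if best is None or res.fun < best.fun:
            best = res
    return float(best.x[0]), float(best.x[1])
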