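"""Adaptive selection of the next trial's stimulus set.

Each ordered stimulus pair (i, j) carries a stress factor

    S_ij = |2·p_ij − 1| + n_j / N

where p_ij is the win rate of i over j as estimated from the fitted
psychometric matrix (0.5 before any fit exists) and n_j is the number of
pairwise outcomes already collected for j.  Low stress marks informative,
under-sampled pairs near the diagonal of the sorted matrix.  The next set of
M stimuli is found by randomized search: up to ``max_search_iterations``
random M-subsets are drawn and the one whose summed pair stress is smallest
is kept; the search stops immediately if a zero-stress subset turns up
(which is always the case at the start of a session).

The same stress total also sets how many responses to collect in the coming
trial: few when stress is low (early), up to M−1 when it is high.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .ordering import SortedOrder
from .tally import ComparisonTally

__all__ = [
    "SamplerConfig",
    "SelectedSet",
    "stress",
    "set_stress",
    "select_next_set",
    "responses_per_trial",
]

RESPONSES_RULES = ("adaptive_linear", "adaptive_squared", "fixed")
SAMPLING_MODES = ("adaptive", "random")

_CHUNK = 10000


@dataclass(frozen=True)
class SamplerConfig:
    """Protocol parameters for next-set selection and the responses rule."""

    set_size: int
    max_search_iterations: int = 50000
    responses_rule: str = "adaptive_linear"
    sampling_mode: str = "adaptive"
    s_cap: float = 5.0

    def __post_init__(self) -> None:
        if self.set_size < 2:
            raise ValueError("set_size must be at least 2")
        if self.responses_rule not in RESPONSES_RULES:
            raise ValueError(f"responses_rule must be one of {RESPONSES_RULES}")
        if self.sampling_mode not in SAMPLING_MODES:
            raise ValueError(f"sampling_mode must be one of {SAMPLING_MODES}")
        if self.max_search_iterations < 1:
            raise ValueError("max_search_iterations must be positive")
        if self.s_cap <= 0:
            raise ValueError("s_cap must be positive")


class SelectedSet(NamedTuple):
    """The chosen stimulus IDs and the stress value they attained."""

    ids: tuple[str, ...]
    stress: float


def stress(p_est: float, n_j: float, n: int) -> float:
    """Pairwise stress |2p − 1| + n_j/N for one ordered pair."""
    if not 0.0 <= p_est <= 1.0:
        raise ValueError("p_est must lie in [0, 1]")
    if n_j < 0:
        raise ValueError("n_j must be nonnegative")
    return abs(2.0 * p_est - 1.0) + n_j / n


def _pair_term_matrix(order: SortedOrder | None, tally: ComparisonTally) -> np.ndarray:
    """|2q − 1| in original stimulus indexing (symmetric, zero diagonal).

    p defaults to 0.5 (zero stress term) before any fit exists, and for any
    pair in which one member has no observed outcome at all — no
    psychometric function estimated from data governs such a pair, so its
    win rate is taken as unknown rather than from boundary-driven fits.
    """
    n = tally.n_stimuli
    if order is None or order.estimated_rates is None:
        return np.zeros((n, n))
    perm = np.array([tally.index[s] for s in order.order])
    c = np.zeros((n, n))
    c[np.ix_(perm, perm)] = np.abs(2.0 * order.estimated_rates - 1.0)
    no_data = tally.per_stimulus_responses == 0
    c[no_data, :] = 0.0
    c[:, no_data] = 0.0
    np.fill_diagonal(c, 0.0)
    return c


def set_stress(
    candidate: Sequence[str],
    order: SortedOrder | None,
    tally: ComparisonTally,
    n: int | None = None,
) -> float:
    """Total stress of a candidate set: sum over all ordered pairs in it."""
    if len(set(candidate)) != len(candidate):
        raise ValueError("candidate set contains duplicate stimuli")
    if n is None:
        n = tally.n_stimuli
    idx = np.array([tally.index[s] for s in candidate])
    pair = _pair_term_matrix(order, tally)
    n_j = tally.per_stimulus_responses
    m = len(idx)
    return float(
        pair[np.ix_(idx, idx)].sum() + (m - 1) * n_j[idx].sum() / n
    )


def _random_subsets(rng: np.random.Generator, batch: int, n: int, m: int) -> np.ndarray:
    """Uniform random M-subsets as a (batch, m) index array."""
    if m * m >= n:
        # dense case: partial shuffles via random keys
        keys = rng.random((batch, n))
        return np.argpartition(keys, m - 1, axis=1)[:, :m]
    idx = rng.integers(0, n, size=(batch, m))
    while True:
        srt = np.sort(idx, axis=1)
        bad = (np.diff(srt, axis=1) == 0).any(axis=1)
        if not bad.any():
            return idx
        idx[bad] = rng.integers(0, n, size=(int(bad.sum()), m))


def select_next_set(
    order: SortedOrder | None,
    tally: ComparisonTally,
    config: SamplerConfig,
    rng_seed: int | np.random.Generator = 0,
) -> SelectedSet:
    """Pick the next trial's M stimuli (stress-minimizing or uniform random)."""
    n = tally.n_stimuli
    m = config.set_size
    if m > n:
        raise ValueError(f"set_size {m} exceeds the number of stimuli {n}")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    ids = tally.stimuli.stimulus_ids

    pair = _pair_term_matrix(order, tally)
    n_term = tally.per_stimulus_responses / n  # each member's n counts M-1 times

    if config.sampling_mode == "random":
        idx = _random_subsets(rng, 1, n, m)[0]
        s = float(pair[np.ix_(idx, idx)].sum() + (m - 1) * n_term[idx].sum())
        return SelectedSet(tuple(ids[k] for k in idx), s)

    best_idx: np.ndarray | None = None
    best_s = np.inf
    drawn = 0
    while drawn < config.max_search_iterations:
        batch = min(_CHUNK, config.max_search_iterations - drawn)
        idx = _random_subsets(rng, batch, n, m)
        s = pair[idx[:, :, None], idx[:, None, :]].sum(axis=(1, 2))
        s += (m - 1) * n_term[idx].sum(axis=1)
        k = int(np.argmin(s))  # first occurrence of the minimum
        if s[k] < best_s:
            best_s = float(s[k])
            best_idx = idx[k]
        if best_s <= 0.0:
            break  # a zero-stress set cannot be improved on
        drawn += batch
    return SelectedSet(tuple(ids[k] for k in best_idx), best_s)


def responses_per_trial(total_stress: float, config: SamplerConfig) -> int:
    """How many selections to collect next trial, in [1, M−1].

    The adaptive rules scale the ratio (or squared ratio) of the set's total
    stress to M onto the 1..M−1 span, normalized by ``s_cap``; the fixed rule
    always runs the full elimination sequence.
    """
    if total_stress < 0:
        raise ValueError("total_stress must be nonnegative")
    m = config.set_size
    if config.responses_rule == "fixed":
        return m - 1
    ratio = total_stress / m
    if config.responses_rule == "adaptive_squared":
        ratio = ratio ** 2
    k = round(ratio * (m - 1) / config.s_cap)
    return int(min(max(k, 1), m - 1))
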