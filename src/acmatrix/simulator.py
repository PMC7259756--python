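"""Model-observer simulation and efficiency benchmark harness.

The model observer holds one true psychological value per stimulus on a
[0, 1] continuum (equally spaced for the linear shape; optionally warped by
a power or hyperbolic value function) and, when shown a set of stimuli,
reports the one whose value-plus-Gaussian-noise is largest.  Noise is drawn
fresh at every selection step.  True values are randomly paired with
stimulus IDs so that nothing in the protocol can exploit the labelling.

``run_experiment`` drives the full adaptive loop — select a set, collect the
trial's elimination responses, re-sort the matrix, rebuild the JND scale —
until the Pearson correlation between estimated and true values reaches the
criterion (default 0.95) or a response cap is hit.  ``run_benchmark``
repeats that over seeded replicates and conditions and aggregates the
number of responses needed.

Seeding: every replicate derives its generators from
``numpy.random.SeedSequence([master_seed, replicate_index])`` and spawns one
child stream each for value assignment, observer noise, the sampler and the
sorter, so any single replicate can be re-run in isolation and matched
seeds across conditions share the same observer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import ordering, sampler, scaling
from .tally import ChoiceRecord, ComparisonTally, StimulusSet

__all__ = [
    "ObserverModel",
    "ExperimentTrace",
    "BenchmarkRow",
    "generate_true_values",
    "make_observer",
    "observe_choice",
    "run_experiment",
    "run_benchmark",
]

VALUE_SHAPES = ("linear", "power", "hyperbolic")
DEFAULT_NOISE_SD = 0.05  # 1/20 of the normalized response range
DEFAULT_CRITERION = 0.95


def value_function(x: np.ndarray, shape: str) -> np.ndarray:
    """Map equally spaced [0, 1] positions onto psychological values."""
    x = np.asarray(x, dtype=float)
    if shape == "linear":
        y = x
    elif shape == "power":
        y = x ** 2
    elif shape == "hyperbolic":
        y = x ** 2 / (0.5 ** 2 + x ** 2)
    else:
        raise ValueError(f"unknown value shape {shape!r}; use one of {VALUE_SHAPES}")
    top = y.max()
    return y / top if top > 0 else y


def generate_true_values(
    n: int, value_shape: str = "linear",
    rng_seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Equally spaced base grid warped by the value shape, randomly permuted.

    The returned array is indexed by stimulus number; the random permutation
    decouples stimulus labels from psychological values.
    """
    if n < 2:
        raise ValueError("need at least 2 stimuli")
    rng = _as_rng(rng_seed)
    grid = np.arange(n, dtype=float) / (n - 1)
    return rng.permutation(value_function(grid, value_shape))


@dataclass(frozen=True)
class ObserverModel:
    """True psychological values plus Gaussian internal noise."""

    stimulus_ids: tuple[str, ...]
    true_values: tuple[float, ...]
    noise_sd: float = DEFAULT_NOISE_SD
    value_shape: str = "linear"

    def __post_init__(self) -> None:
        if len(self.stimulus_ids) != len(self.true_values):
            raise ValueError("one true value per stimulus is required")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if len(set(self.true_values)) != len(self.true_values):
            raise ValueError("true values must be distinct")

    @property
    def truth(self) -> dict[str, float]:
        return dict(zip(self.stimulus_ids, self.true_values))

    def value_array(self, ids: Sequence[str]) -> np.ndarray:
        lookup = self.truth
        return np.array([lookup[s] for s in ids])


def make_observer(
    stimuli: StimulusSet | Sequence[str] | int,
    value_shape: str = "linear",
    noise_sd: float = DEFAULT_NOISE_SD,
    rng_seed: int | np.random.Generator = 0,
) -> ObserverModel:
    """Build a model observer with randomly paired true values."""
    if isinstance(stimuli, int):
        stimuli = StimulusSet.from_count(stimuli)
    elif not isinstance(stimuli, StimulusSet):
        stimuli = StimulusSet(tuple(stimuli))
    values = generate_true_values(stimuli.n_stimuli, value_shape, rng_seed)
    return ObserverModel(
        stimulus_ids=stimuli.stimulus_ids,
        true_values=tuple(float(v) for v in values),
        noise_sd=noise_sd,
        value_shape=value_shape,
    )


def observe_choice(
    model: ObserverModel,
    presented: Sequence[str],
    rng: np.random.Generator,
) -> str:
    """The model observer's pick: argmax of true value + fresh Gaussian noise."""
    if len(presented) < 2:
        raise ValueError("a choice needs at least 2 presented stimuli")
    values = model.value_array(presented)
    if model.noise_sd > 0:
        values = values + rng.normal(0.0, model.noise_sd, size=len(presented))
    return presented[int(np.argmax(values))]


# ---------------------------------------------------------------------------
# the full experiment loop
# ---------------------------------------------------------------------------

@dataclass
class ExperimentTrace:
    """Outcome of one simulated session."""

    responses_used: int
    correlation_history: list[tuple[int, float]]
    terminated_by: str  # "criterion" or "response_cap"
    final_scale: scaling.ScaleEstimate | None
    final_order: ordering.SortedOrder | None
    observer: ObserverModel
    n_trials: int
    tally: ComparisonTally | None = None

    @property
    def final_correlation(self) -> float:
        return self.correlation_history[-1][1] if self.correlation_history else float("nan")


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _replicate_streams(seed: int, replicate: int | None = None):
    """Four independent generators (values, noise, sampler, sorter)."""
    entropy = [int(seed)] if replicate is None else [int(seed), int(replicate)]
    children = np.random.SeedSequence(entropy).spawn(4)
    return tuple(np.random.default_rng(ss) for ss in children)


def _estimate_correlation(
    order: ordering.SortedOrder, model: ObserverModel
) -> tuple[float, scaling.ScaleEstimate]:
    scale = scaling.jnd_scale(order)
    n = order.n_stimuli
    if n >= 3:
        r = scaling.scale_correlation(scale, model.truth)
    else:
        # N = 2: correlation is degenerate; score exact order agreement
        truth_order = tuple(
            s for _, s in sorted(zip(model.true_values, model.stimulus_ids))
        )
        r = 1.0 if order.order == truth_order else -1.0
    return r, scale


def run_experiment(
    n_stimuli: int,
    set_size: int,
    observer: ObserverModel | None = None,
    *,
    noise_sd: float = DEFAULT_NOISE_SD,
    value_shape: str = "linear",
    sampling_mode: str = "adaptive",
    responses_rule: str = "adaptive_linear",
    s_cap: float = 5.0,
    max_search_iterations: int = 50000,
    criterion: float = DEFAULT_CRITERION,
    response_cap: int | None = None,
    slope_bounds: tuple[float, float] = ordering.DEFAULT_SLOPE_BOUNDS,
    max_sort_iterations: int = ordering.DEFAULT_MAX_ITERATIONS,
    rng_seed: int = 0,
    replicate: int | None = None,
    record_history: bool = True,
) -> ExperimentTrace:
    """Run one full simulated session until criterion or response cap."""
    rng_values, rng_noise, rng_sampler, rng_sorter = _replicate_streams(rng_seed, replicate)
    stimuli = StimulusSet.from_count(n_stimuli)
    if observer is None:
        observer = ObserverModel(
            stimulus_ids=stimuli.stimulus_ids,
            true_values=tuple(
                float(v) for v in generate_true_values(n_stimuli, value_shape, rng_values)
            ),
            noise_sd=noise_sd,
            value_shape=value_shape,
        )
    else:
        stimuli = StimulusSet(observer.stimulus_ids)
        n_stimuli = stimuli.n_stimuli
    if response_cap is None:
        response_cap = 50 * n_stimuli
    config = sampler.SamplerConfig(
        set_size=set_size,
        max_search_iterations=max_search_iterations,
        responses_rule=responses_rule,
        sampling_mode=sampling_mode,
        s_cap=s_cap,
    )

    tally = ComparisonTally(stimuli)
    order: ordering.SortedOrder | None = None
    history: list[tuple[int, float]] = []
    responses = 0
    trial = 0
    terminated_by = "response_cap"
    scale = None

    while responses < response_cap:
        selected = sampler.select_next_set(order, tally, config, rng_sampler)
        k_target = sampler.responses_per_trial(selected.stress, config)
        k_target = min(k_target, response_cap - responses)
        displayed = list(selected.ids)
        for step in range(k_target):
            if len(displayed) < 2:
                break
            chosen = observe_choice(observer, displayed, rng_noise)
            tally.record_choice(ChoiceRecord(trial, step, tuple(displayed), chosen))
            displayed.remove(chosen)
            responses += 1
        trial += 1
        order = ordering.sort_matrix(
            tally, rng_seed=rng_sorter,
            slope_bounds=slope_bounds, max_iterations=max_sort_iterations,
            init_order=order,  # warm-start from the previous trial's order
        )
        r, scale = _estimate_correlation(order, observer)
        if record_history:
            history.append((responses, r))
        if r >= criterion:
            terminated_by = "criterion"
            break

    if not record_history and scale is not None:
        history.append((responses, r))
    return ExperimentTrace(
        responses_used=responses,
        correlation_history=history,
        terminated_by=terminated_by,
        final_scale=scale,
        final_order=order,
        observer=observer,
        n_trials=trial,
        tally=tally,
    )


# ---------------------------------------------------------------------------
# benchmark harness
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BenchmarkRow:
    """Aggregate responses-to-criterion for one simulated condition."""

    n_stimuli: int
    set_size: int
    noise_sd: float
    value_shape: str
    sampling_mode: str
    responses_rule: str
    replicates: int
    mean_responses: float
    sd_responses: float
    mean_correlation: float
    n_capped: int


_CONDITION_KEYS = (
    "n_stimuli", "set_size", "noise_sd", "value_shape",
    "sampling_mode", "responses_rule",
)


def run_benchmark(
    conditions: Iterable[Mapping],
    replicates: int = 20,
    rng_seed: int = 0,
    **experiment_kwargs,
) -> pd.DataFrame:
    """Run ``replicates`` seeded sessions per condition and aggregate.

    Replicate seeds derive from (rng_seed, replicate index) only, so two
    conditions in the same benchmark share matched observers replicate by
    replicate.
    """
    rows = []
    for cond in conditions:
        cond = dict(cond)
        unknown = set(cond) - set(_CONDITION_KEYS)
        if unknown:
            raise ValueError(f"unknown condition keys: {sorted(unknown)}")
        used, corrs, capped = [], [], 0
        for rep in range(replicates):
            trace = run_experiment(
                n_stimuli=int(cond.get("n_stimuli", 100)),
                set_size=int(cond.get("set_size", 8)),
                noise_sd=float(cond.get("noise_sd", DEFAULT_NOISE_SD)),
                value_shape=str(cond.get("value_shape", "linear")),
                sampling_mode=str(cond.get("sampling_mode", "adaptive")),
                responses_rule=str(cond.get("responses_rule", "adaptive_linear")),
                rng_seed=rng_seed,
                replicate=rep,
                record_history=False,
                **experiment_kwargs,
            )
            used.append(trace.responses_used)
            corrs.append(trace.final_correlation)
            capped += trace.terminated_by == "response_cap"
        rows.append(
            BenchmarkRow(
                n_stimuli=int(cond.get("n_stimuli", 100)),
                set_size=int(cond.get("set_size", 8)),
                noise_sd=float(cond.get("noise_sd", DEFAULT_NOISE_SD)),
                value_shape=str(cond.get("value_shape", "linear")),
                sampling_mode=str(cond.get("sampling_mode", "adaptive")),
                responses_rule=str(cond.get("responses_rule", "adaptive_linear")),
                replicates=replicates,
                mean_responses=float(np.mean(used)),
                sd_responses=float(np.std(used, ddof=1)) if len(used) > 1 else 0.0,
                mean_correlation=float(np.mean(corrs)),
                n_capped=capped,
            )
        )
    frame = pd.DataFrame([r.__dict__ for r in rows])
    return frame.rename(columns={"n_stimuli": "N", "set_size": "M"})
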