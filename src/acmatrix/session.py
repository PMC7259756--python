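"""File-backed experiment sessions for human observers.

A session drives the collect -> sort -> sample loop across process
restarts: every completed response updates a single JSON state document
(tally, audit log of all choices, current sorted order, pending trial and
generator state), so a crashed or paused session continues exactly where it
left off, and replaying the audit log from scratch reconstructs the same
state.  The number of responses to collect in a trial is fixed when the
trial opens, from the stress of the selected set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from . import ordering, sampler, scaling
from .tally import ChoiceRecord, ComparisonTally, StimulusSet

__all__ = ["SessionState", "session_init", "session_respond", "session_export"]


class ConfigError(ValueError):
    """The session configuration is invalid; the message names the key."""


class EmptyExportError(RuntimeError):
    """Export requested before any response was recorded."""


_CONFIG_DEFAULTS = {
    "set_size": None,            # required
    "n_stimuli": None,           # or stimulus_ids
    "stimulus_ids": None,
    "seed": 0,
    "max_search_iterations": 50000,
    "responses_rule": "adaptive_linear",
    "sampling_mode": "adaptive",
    "s_cap": 5.0,
    "slope_bounds": list(ordering.DEFAULT_SLOPE_BOUNDS),
    "max_sort_iterations": ordering.DEFAULT_MAX_ITERATIONS,
}


def _check_config(config: dict) -> dict:
    cfg = dict(_CONFIG_DEFAULTS)
    unknown = set(config) - set(cfg)
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    cfg.update(config)
    if cfg["stimulus_ids"] is None:
        if not cfg["n_stimuli"] or int(cfg["n_stimuli"]) < 2:
            raise ConfigError("config key 'n_stimuli' must be an integer >= 2")
        cfg["stimulus_ids"] = list(
            StimulusSet.from_count(int(cfg["n_stimuli"])).stimulus_ids
        )
    cfg["n_stimuli"] = len(cfg["stimulus_ids"])
    if not cfg["set_size"] or not 2 <= int(cfg["set_size"]) <= cfg["n_stimuli"]:
        raise ConfigError("config key 'set_size' must satisfy 2 <= M <= N")
    try:
        sampler.SamplerConfig(
            set_size=int(cfg["set_size"]),
            max_search_iterations=int(cfg["max_search_iterations"]),
            responses_rule=cfg["responses_rule"],
            sampling_mode=cfg["sampling_mode"],
            s_cap=float(cfg["s_cap"]),
        )
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc
    return cfg


@dataclass
class SessionState:
    """The complete, serializable state of a running session."""

    config: dict
    tally: ComparisonTally
    order: ordering.SortedOrder | None
    displayed: list[str]        # remaining stimuli of the pending trial
    trial_set: list[str]        # the pending trial's full displayed set
    k_target: int
    k_done: int
    trial_index: int
    rng_state: dict

    # -- helpers -----------------------------------------------------------

    def sampler_config(self) -> sampler.SamplerConfig:
        c = self.config
        return sampler.SamplerConfig(
            set_size=int(c["set_size"]),
            max_search_iterations=int(c["max_search_iterations"]),
            responses_rule=c["responses_rule"],
            sampling_mode=c["sampling_mode"],
            s_cap=float(c["s_cap"]),
        )

    def rng(self) -> np.random.Generator:
        gen = np.random.default_rng(0)
        gen.bit_generator.state = self.rng_state
        return gen

    # -- serialization -----------------------------------------------------

    def to_json(self) -> str:
        order_state = None
        if self.order is not None:
            order_state = {
                "order": list(self.order.order),
                "slopes": [f.slope for f in self.order.fits] if self.order.fits else None,
                "centroids": [f.centroid for f in self.order.fits] if self.order.fits else None,
                "converged": self.order.converged,
                "iterations_used": self.order.iterations_used,
                "residual": self.order.residual,
            }
        doc = {
            "config": self.config,
            "tally": self.tally.to_state(),
            "order": order_state,
            "displayed": self.displayed,
            "trial_set": self.trial_set,
            "k_target": self.k_target,
            "k_done": self.k_done,
            "trial_index": self.trial_index,
            "rng_state": self.rng_state,
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SessionState":
        doc = json.loads(text)
        tally = ComparisonTally.from_state(doc["tally"])
        order = None
        if doc["order"] is not None:
            o = doc["order"]
            fits = None
            if o["slopes"] is not None:
                fits = tuple(
                    ordering.PsychometricFit(a, x)
                    for a, x in zip(o["slopes"], o["centroids"])
                )
            rates = None
            if fits is not None:
                rates = ordering.estimate_rate_matrix(fits, len(o["order"]))
            order = ordering.SortedOrder(
                order=tuple(o["order"]),
                fits=fits,
                estimated_rates=rates,
                converged=o["converged"],
                iterations_used=o["iterations_used"],
                residual=o["residual"],
                n_responses={
                    s: int(n)
                    for s, n in zip(
                        tally.stimuli.stimulus_ids, tally.per_stimulus_responses
                    )
                },
            )
        state = cls(
            config=doc["config"],
            tally=tally,
            order=order,
            displayed=list(doc["displayed"]),
            trial_set=list(doc["trial_set"]),
            k_target=int(doc["k_target"]),
            k_done=int(doc["k_done"]),
            trial_index=int(doc["trial_index"]),
            rng_state=doc["rng_state"],
        )
        return state

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "SessionState":
        return cls.from_json(Path(path).read_text())


def _open_trial(state: SessionState) -> None:
    """Select the next stimulus set and fix the trial's response target."""
    rng = state.rng()
    selected = sampler.select_next_set(
        state.order, state.tally, state.sampler_config(), rng
    )
    state.rng_state = rng.bit_generator.state
    state.trial_set = list(selected.ids)
    state.displayed = list(selected.ids)
    state.k_target = sampler.responses_per_trial(selected.stress, state.sampler_config())
    state.k_done = 0


def session_init(config: dict) -> SessionState:
    """Start a session: empty tally, first trial selected, state ready to save."""
    cfg = _check_config(config)
    tally = ComparisonTally(StimulusSet(tuple(cfg["stimulus_ids"])))
    rng = np.random.default_rng(int(cfg["seed"]))
    state = SessionState(
        config=cfg,
        tally=tally,
        order=None,
        displayed=[],
        trial_set=[],
        k_target=1,
        k_done=0,
        trial_index=0,
        rng_state=rng.bit_generator.state,
    )
    _open_trial(state)
    return state


def session_respond(state: SessionState, chosen: str) -> SessionState:
    """Record one choice; closes the trial and opens the next when due."""
    chosen = str(chosen)
    if chosen not in state.displayed:
        raise ValueError(
            f"stimulus {chosen!r} is not on display; valid options: "
            f"{sorted(state.displayed)}"
        )
    record = ChoiceRecord(
        trial_index=state.trial_index,
        selection_index=state.k_done,
        displayed=tuple(state.displayed),
        chosen=chosen,
    )
    state.tally.record_choice(record)
    state.displayed.remove(chosen)
    state.k_done += 1
    if state.k_done >= state.k_target or len(state.displayed) < 2:
        rng = state.rng()
        state.order = ordering.sort_matrix(
            state.tally,
            rng_seed=rng,
            slope_bounds=tuple(state.config["slope_bounds"]),
            max_iterations=int(state.config["max_sort_iterations"]),
            init_order=state.order,
        )
        state.rng_state = rng.bit_generator.state
        state.trial_index += 1
        _open_trial(state)
    return state


def session_export(state: SessionState, out_dir: str | Path) -> dict[str, Path]:
    """Write scale, response-log and sorted-order CSVs; returns the paths."""
    if state.tally.total_responses() < 1:
        raise EmptyExportError("no responses recorded yet; nothing to export")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    order = state.order
    if order is None:  # a trial is open but none completed: sort what we have
        order = ordering.sort_matrix(state.tally, rng_seed=state.rng())
    scale = scaling.jnd_scale(order)
    paths = {
        "scale": out / "scale.csv",
        "responses": out / "responses.csv",
        "sorted_order": out / "sorted_order.csv",
        "estimated_rates": out / "estimated_rates.csv",
    }
    scale.save(paths["scale"])
    state.tally.save_response_log(paths["responses"])
    order.save_order(paths["sorted_order"])
    order.save_rates(paths["estimated_rates"])
    return paths
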