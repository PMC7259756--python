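"""Win-count bookkeeping for iterative-elimination max-choice responses.

Each trial shows M stimuli; the observer repeatedly picks the one with the
largest subjective value and the pick is removed from the display.  A single
pick among m stimuli implies m-1 pairwise "wins" (the chosen stimulus beat
every other displayed stimulus), so one trial of k picks fills many cells of
the N x N comparison matrix at once.

Counts are stored as an ordered integer matrix ``wins[i, j]`` = number of
outcomes where stimulus i beat stimulus j; win *rates* are always derived on
demand, never stored, so the evidence stays exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StimulusSet",
    "ChoiceRecord",
    "ComparisonTally",
    "record_choice",
    "win_rate",
    "total_responses",
]

MISSING = None  # sentinel returned by win_rate when a pair has no data


class InvalidRecordError(ValueError):
    """The choice record is inconsistent (chosen not displayed, duplicates...)."""


class MembershipError(KeyError):
    """A stimulus ID does not belong to the stimulus set."""


@dataclass(frozen=True)
class StimulusSet:
    """An ordered collection of N >= 2 distinct opaque stimulus labels."""

    stimulus_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        ids = tuple(str(s) for s in self.stimulus_ids)
        object.__setattr__(self, "stimulus_ids", ids)
        if len(ids) < 2:
            raise ValueError("a stimulus set needs at least 2 stimuli")
        if len(set(ids)) != len(ids):
            raise ValueError("stimulus IDs must be distinct")

    @property
    def n_stimuli(self) -> int:
        return len(self.stimulus_ids)

    @classmethod
    def from_count(cls, n: int, prefix: str = "s") -> "StimulusSet":
        """Build a set of n stimuli labelled ``{prefix}001 .. {prefix}NNN``."""
        width = max(3, len(str(n)))
        return cls(tuple(f"{prefix}{i + 1:0{width}d}" for i in range(n)))


@dataclass(frozen=True)
class ChoiceRecord:
    """One selection step: which stimuli were on display and which was chosen.

    ``selection_index`` counts the elimination steps within a trial, so within
    one trial the display at step k+1 is the display at step k minus its
    chosen element.
    """

    trial_index: int
    selection_index: int
    displayed: tuple[str, ...]
    chosen: str

    def __post_init__(self) -> None:
        displayed = tuple(str(s) for s in self.displayed)
        object.__setattr__(self, "displayed", displayed)
        object.__setattr__(self, "chosen", str(self.chosen))
        if self.trial_index < 0 or self.selection_index < 0:
            raise InvalidRecordError("trial_index and selection_index must be >= 0")
        if len(displayed) < 2:
            raise InvalidRecordError("a choice needs at least 2 displayed stimuli")
        if len(set(displayed)) != len(displayed):
            raise InvalidRecordError("displayed stimuli must be distinct")
        if self.chosen not in displayed:
            raise InvalidRecordError(
                f"chosen stimulus {self.chosen!r} is not among the displayed set"
            )


class ComparisonTally:
    """N x N ordered win-count matrix plus per-stimulus outcome totals.

    ``per_stimulus_responses[j]`` is the number of pairwise outcomes involving
    stimulus j (the n_j that feeds the sampler's stress factor), while
    ``total_responses()`` counts individual selections made by the observer.
    """

    def __init__(self, stimuli: StimulusSet | Sequence[str]) -> None:
        if not isinstance(stimuli, StimulusSet):
            stimuli = StimulusSet(tuple(stimuli))
        self.stimuli = stimuli
        self.index = {sid: k for k, sid in enumerate(stimuli.stimulus_ids)}
        n = stimuli.n_stimuli
        self.wins = np.zeros((n, n), dtype=np.int64)
        self._n_selections = 0
        self.records: list[ChoiceRecord] = []

    # -- core updates ------------------------------------------------------

    @property
    def n_stimuli(self) -> int:
        return self.stimuli.n_stimuli

    @property
    def per_stimulus_responses(self) -> np.ndarray:
        """n_j: pairwise outcomes involving each stimulus (wins + losses)."""
        return self.wins.sum(axis=0) + self.wins.sum(axis=1)

    def record_choice(self, record: ChoiceRecord) -> "ComparisonTally":
        """Credit the chosen stimulus with a win over every other displayed one."""
        try:
            c = self.index[record.chosen]
            losers = [self.index[s] for s in record.displayed if s != record.chosen]
        except KeyError as exc:
            raise MembershipError(f"unknown stimulus ID {exc.args[0]!r}") from exc
        self.wins[c, losers] += 1
        self._n_selections += 1
        self.records.append(record)
        return self

    def record_trial(self, trial_index: int, displayed: Sequence[str],
                     choices: Sequence[str]) -> "ComparisonTally":
        """Record a full or partial elimination sequence for one trial."""
        remaining = list(displayed)
        for k, chosen in enumerate(choices):
            self.record_choice(ChoiceRecord(trial_index, k, tuple(remaining), chosen))
            remaining.remove(chosen)
        return self

    # -- derived quantities ------------------------------------------------

    def win_rate(self, i: str, j: str) -> float | None:
        """Empirical P(i judged larger than j), or MISSING with no data."""
        if i == j:
            raise ValueError("win rate is undefined for a stimulus against itself")
        a, b = self.index[i], self.index[j]
        w, l = self.wins[a, b], self.wins[b, a]
        total = w + l
        if total == 0:
            return MISSING
        return float(w) / float(total)

    def win_rate_matrix(self) -> np.ndarray:
        """N x N matrix of empirical win rates; NaN where a pair has no data."""
        w = self.wins.astype(float)
        tot = w + w.T
        with np.errstate(invalid="ignore", divide="ignore"):
            rates = np.where(tot > 0, w / np.where(tot > 0, tot, 1.0), np.nan)
        np.fill_diagonal(rates, np.nan)
        return rates

    def total_responses(self) -> int:
        """Number of recorded choice selections (not pairwise outcomes)."""
        return self._n_selections

    def total_outcomes(self) -> int:
        """Number of implied pairwise outcomes, sum over records of m_r - 1."""
        return int(self.wins.sum())

    # -- serialization -----------------------------------------------------

    def response_log_frame(self) -> pd.DataFrame:
        """Response log as a DataFrame, one row per selection."""
        return pd.DataFrame(
            {
                "trial_index": [r.trial_index for r in self.records],
                "selection_index": [r.selection_index for r in self.records],
                "displayed_ids": [";".join(r.displayed) for r in self.records],
                "chosen_id": [r.chosen for r in self.records],
            }
        )

    def save_response_log(self, path: str | Path) -> None:
        self.response_log_frame().to_csv(path, index=False)

    @classmethod
    def from_response_log(
        cls, path: str | Path, stimuli: StimulusSet | Sequence[str]
    ) -> "ComparisonTally":
        """Rebuild a tally by replaying a response-log CSV."""
        frame = pd.read_csv(path, dtype={"displayed_ids": str, "chosen_id": str})
        tally = cls(stimuli)
        for row in frame.itertuples(index=False):
            tally.record_choice(
                ChoiceRecord(
                    int(row.trial_index),
                    int(row.selection_index),
                    tuple(row.displayed_ids.split(";")),
                    row.chosen_id,
                )
            )
        return tally

    def save_snapshot(self, csv_path: str | Path, meta_path: str | Path | None = None) -> None:
        """Write the win-count matrix as CSV plus a JSON sidecar with the ID map."""
        csv_path = Path(csv_path)
        ids = list(self.stimuli.stimulus_ids)
        pd.DataFrame(self.wins, index=ids, columns=ids).to_csv(csv_path)
        meta = {
            "stimulus_ids": ids,
            "id_to_index": self.index,
            "n_selections": self._n_selections,
        }
        if meta_path is None:
            meta_path = csv_path.with_suffix(".json")
        Path(meta_path).write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_snapshot(cls, csv_path: str | Path, meta_path: str | Path | None = None) -> "ComparisonTally":
        csv_path = Path(csv_path)
        if meta_path is None:
            meta_path = csv_path.with_suffix(".json")
        meta = json.loads(Path(meta_path).read_text())
        tally = cls(StimulusSet(tuple(meta["stimulus_ids"])))
        frame = pd.read_csv(csv_path, index_col=0)
        if list(frame.index) != meta["stimulus_ids"]:
            raise ValueError("snapshot CSV and sidecar disagree on stimulus IDs")
        tally.wins = frame.to_numpy(dtype=np.int64)
        tally._n_selections = int(meta["n_selections"])
        return tally

    # -- state dict (used by the session module) ---------------------------

    def to_state(self) -> dict:
        return {
            "stimulus_ids": list(self.stimuli.stimulus_ids),
            "wins": self.wins.tolist(),
            "n_selections": self._n_selections,
            "records": [
                [r.trial_index, r.selection_index, list(r.displayed), r.chosen]
                for r in self.records
            ],
        }

    @classmethod
    def from_state(cls, state: dict) -> "ComparisonTally":
        tally = cls(StimulusSet(tuple(state["stimulus_ids"])))
        tally.wins = np.asarray(state["wins"], dtype=np.int64)
        tally._n_selections = int(state["n_selections"])
        tally.records = [
            ChoiceRecord(t, s, tuple(d), c) for t, s, d, c in state["records"]
        ]
        return tally


# -- module-level operation wrappers --------------------------------------

def record_choice(tally: ComparisonTally, record: ChoiceRecord) -> ComparisonTally:
    """Incorporate one max-choice selection into the tally (in place)."""
    return tally.record_choice(record)


def win_rate(tally: ComparisonTally, i: str, j: str) -> float | None:
    """Empirical win rate of i over j, or MISSING (None) with no data."""
    return tally.win_rate(i, j)


def total_responses(tally: ComparisonTally) -> int:
    """Number of individual selections recorded so far."""
    return tally.total_responses()


def choices_from_log(records: Iterable[ChoiceRecord],
                     stimuli: StimulusSet | Sequence[str]) -> ComparisonTally:
    """Build a tally from an iterable of ChoiceRecords."""
    tally = ComparisonTally(stimuli)
    for record in records:
        tally.record_choice(record)
    return tally
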