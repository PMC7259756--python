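import numpy as np
import pytest

from acmatrix.tally import ChoiceRecord, ComparisonTally, StimulusSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def four_ids():
    return ("A", "B", "C", "D")


def make_random_tally(n, n_trials, m, seed, noise_sd=0.1):
    """Tally from a crude simulated observer on random sets (test helper).

    True magnitude of stimulus k is k/(n-1); each trial ranks a random
    m-subset by value + Gaussian noise and records the full elimination.
    """
    rng = np.random.default_rng(seed)
    ids = tuple(f"s{k:02d}" for k in range(n))
    values = np.arange(n) / (n - 1)
    tally = ComparisonTally(StimulusSet(ids))
    for t in range(n_trials):
        subset = rng.choice(n, size=m, replace=False)
        noisy = values[subset] + rng.normal(0, noise_sd, m)
        ranked = subset[np.argsort(-noisy)]
        remaining = [ids[k] for k in ranked]
        for sel in range(len(remaining) - 1):
            tally.record_choice(
                ChoiceRecord(t, sel, tuple(remaining), remaining[0])
            )
            remaining = remaining[1:]
    return tally, {ids[k]: values[k] for k in range(n)}


@pytest.fixture
def random_tally():
    tally, truth = make_random_tally(n=8, n_trials=30, m=3, seed=7)
    return tally, truth
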