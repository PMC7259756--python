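"""Model observer, experiment loop and benchmark harness."""

import numpy as np
import pytest
from scipy import stats

from acmatrix.simulator import (
    ObserverModel,
    generate_true_values,
    make_observer,
    observe_choice,
    run_benchmark,
    run_experiment,
    value_function,
)


class TestTrueValues:
    def test_linear_three_stimuli(self):
        vals = generate_true_values(3, "linear", rng_seed=0)
        assert sorted(vals) == [0.0, 0.5, 1.0]

    def test_linear_five_stimuli(self):
        vals = generate_true_values(5, "linear", rng_seed=1)
        assert sorted(vals) == [0.0, 0.25, 0.5, 0.75, 1.0]

    def test_hyperbolic_midpoint_before_rescale(self):
        # x^2 / (0.5^2 + x^2) at x = 0.5 is 0.25 / 0.5 = 0.5; the rescale
        # divides by the value at x = 1 (= 0.8)
        y = value_function(np.array([0.5, 1.0]), "hyperbolic")
        assert y[0] == pytest.approx(0.5 / 0.8)
        assert y[1] == pytest.approx(1.0)

    def test_power_shape(self):
        y = value_function(np.array([0.0, 0.5, 1.0]), "power")
        np.testing.assert_allclose(y, [0.0, 0.25, 1.0])

    def test_values_randomly_paired_with_ids(self):
        a = generate_true_values(30, "linear", rng_seed=0)
        b = generate_true_values(30, "linear", rng_seed=1)
        assert sorted(a) == sorted(b)
        assert not np.array_equal(a, b)

    def test_unknown_shape_rejected(self):
        with pytest.raises(ValueError):
            generate_true_values(5, "cubic", rng_seed=0)


class TestObserveChoice:
    def test_noiseless_observer_is_argmax(self):
        model = make_observer(10, noise_sd=0.0, rng_seed=0)
        ids = list(model.stimulus_ids)
        best = max(ids, key=lambda s: model.truth[s])
        rng = np.random.default_rng(0)
        for _ in range(5):
            assert observe_choice(model, ids, rng) == best

    def test_two_stimulus_accuracy_matches_gaussian_difference(self):
        # P(correct) = Phi(delta / (sigma * sqrt(2)))
        delta, sigma, n = 0.1, 0.08, 100_000
        model = ObserverModel(("lo", "hi"), (0.4, 0.4 + delta), noise_sd=sigma)
        rng = np.random.default_rng(7)
        correct = sum(
            observe_choice(model, ("lo", "hi"), rng) == "hi" for _ in range(n)
        )
        p_theory = stats.norm.cdf(delta / (sigma * np.sqrt(2)))
        se = np.sqrt(p_theory * (1 - p_theory) / n)
        assert abs(correct / n - p_theory) < 3 * se

    def test_three_stimulus_frequencies_match_monte_carlo_oracle(self):
        values = np.array([0.30, 0.36, 0.40])
        sigma, n = 0.05, 60_000
        ids = ("a", "b", "c")
        model = ObserverModel(ids, tuple(values), noise_sd=sigma)
        rng = np.random.default_rng(11)
        counts = {s: 0 for s in ids}
        for _ in range(n):
            counts[observe_choice(model, ids, rng)] += 1
        # independent vectorized simulation as the oracle
        oracle_rng = np.random.default_rng(400)
        draws = values + oracle_rng.normal(0, sigma, size=(n, 3))
        oracle = np.bincount(np.argmax(draws, axis=1), minlength=3) / n
        for k, s in enumerate(ids):
            se = np.sqrt(oracle[k] * (1 - oracle[k]) / n)
            assert abs(counts[s] / n - oracle[k]) < 4 * np.sqrt(2) * se

    def test_singleton_presentation_rejected(self):
        model = make_observer(4, rng_seed=0)
        with pytest.raises(ValueError):
            observe_choice(model, model.stimulus_ids[:1], np.random.default_rng(0))


class TestRunExperiment:
    def test_noiseless_run_recovers_exact_order(self):
        # deterministic argmax + transitive data: driving the criterion to 1
        # must recover the generating permutation exactly, with r ~ 1.0
        trace = run_experiment(10, 4, noise_sd=0.0, rng_seed=3, criterion=0.999)
        assert trace.terminated_by == "criterion"
        truth = trace.observer.truth
        est = trace.final_order.order
        assert list(est) == sorted(truth, key=truth.get)
        mags = trace.final_scale.magnitudes
        ids = sorted(truth)
        r = stats.pearsonr([mags[s] for s in ids], [truth[s] for s in ids]).statistic
        assert r == pytest.approx(1.0, abs=5e-3)

    def test_noiseless_run_meets_default_criterion_quickly(self):
        trace = run_experiment(10, 4, noise_sd=0.0, rng_seed=3)
        assert trace.terminated_by == "criterion"
        assert trace.final_correlation >= 0.95

    def test_identical_seeds_give_identical_traces(self):
        a = run_experiment(12, 4, rng_seed=5, replicate=2)
        b = run_experiment(12, 4, rng_seed=5, replicate=2)
        assert a.responses_used == b.responses_used
        assert a.correlation_history == b.correlation_history
        assert a.final_order.order == b.final_order.order
        assert a.final_scale.magnitudes == b.final_scale.magnitudes

    def test_two_stimulus_degenerate_case(self):
        trace = run_experiment(2, 2, noise_sd=0.01, rng_seed=0)
        assert trace.terminated_by == "criterion"
        assert trace.responses_used <= 10

    def test_response_cap_terminates_gracefully(self):
        trace = run_experiment(20, 4, noise_sd=0.3, rng_seed=0, response_cap=12)
        assert trace.terminated_by == "response_cap"
        assert trace.responses_used <= 12

    def test_history_counts_strictly_increase(self):
        trace = run_experiment(15, 5, rng_seed=1)
        counts = [n for n, _ in trace.correlation_history]
        assert all(b > a for a, b in zip(counts, counts[1:]))

    def test_selection_concentrates_near_diagonal(self, monkeypatch):
        # the hallmark of the adaptive search: as outcomes accumulate the
        # chosen pairs move toward the diagonal of the (true) order
        import acmatrix.sampler as sampler_mod

        picked = []
        original = sampler_mod.select_next_set

        def spy(order, tally, config, rng_seed=0):
            out = original(order, tally, config, rng_seed)
            picked.append(out.ids)
            return out

        monkeypatch.setattr(sampler_mod, "select_next_set", spy)
        trace = run_experiment(
            20, 2, noise_sd=0.05, rng_seed=0, response_cap=150, criterion=2.0
        )
        truth = trace.observer.truth
        rank = {s: r for r, s in enumerate(sorted(truth, key=truth.get))}
        dists = [abs(rank[a] - rank[b]) for a, b in picked]
        third = len(dists) // 3
        assert np.mean(dists[-third:]) < np.mean(dists[:third])


class TestRunBenchmark:
    def test_single_replicate_row_matches_run_experiment(self):
        cond = dict(n_stimuli=10, set_size=3, noise_sd=0.05, value_shape="linear")
        frame = run_benchmark([cond], replicates=1, rng_seed=9)
        trace = run_experiment(10, 3, noise_sd=0.05, rng_seed=9, replicate=0)
        assert frame.loc[0, "mean_responses"] == trace.responses_used
        assert frame.loc[0, "sd_responses"] == 0.0

    def test_matched_seeds_across_conditions(self):
        conds = [
            dict(n_stimuli=8, set_size=3, sampling_mode="adaptive"),
            dict(n_stimuli=8, set_size=3, sampling_mode="random"),
        ]
        frame = run_benchmark(conds, replicates=2, rng_seed=4)
        assert list(frame["sampling_mode"]) == ["adaptive", "random"]
        assert set(frame.columns) >= {
            "N", "M", "noise_sd", "value_shape", "sampling_mode",
            "responses_rule", "replicates", "mean_responses", "sd_responses",
        }

    def test_unknown_condition_key_rejected(self):
        with pytest.raises(ValueError):
            run_benchmark([{"n_stimuli": 8, "shoe_size": 42}], replicates=1)


class TestObserverModelValidation:
    def test_duplicate_values_rejected(self):
        with pytest.raises(ValueError):
            ObserverModel(("a", "b"), (0.5, 0.5))

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            ObserverModel(("a", "b"), (0.1, 0.9), noise_sd=-1.0)
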