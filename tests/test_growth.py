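"""Growth-rate extraction, carrying capacity, and dominance prediction."""

import numpy as np
import pytest
from scipy import stats

from evoassembly.errors import UndefinedResultError
from evoassembly.growth import (
    GrowthCurve,
    GrowthParams,
    aggregate_growth_params,
    carrying_capacity,
    dominance_prediction_accuracy,
    growth_rate_time_to_threshold,
    predict_dominant_from_growth,
    smooth_moving_mean,
)
from evoassembly.simulate import lagged_logistic_od, simulate_growth_curves


def exponential_curve(doubling_h=1.0, lag_h=0.0, dt_min=10.0, t_max=24.0, od0=1e-4):
    t = np.arange(0.0, t_max, dt_min / 60.0)
    od = od0 * np.power(2.0, np.maximum(0.0, t - lag_h) / doubling_h)
    return GrowthCurve("w1", "sp", "e1", "t1", t, np.minimum(od, 1.0))


class TestGrowthRate:
    def test_pure_exponential_recovers_unit_rate(self):
        r = growth_rate_time_to_threshold(exponential_curve())
        # t* = log2(800) h exactly, so r = 1 up to interpolation error
        assert r == pytest.approx(1.0, abs=0.01)

    def test_lag_reduces_the_rate(self):
        r = growth_rate_time_to_threshold(exponential_curve(lag_h=2.0))
        assert r == pytest.approx(np.log2(800) / (np.log2(800) + 2.0), abs=0.01)

    def test_plateau_below_threshold_is_undefined(self):
        t = np.arange(0.0, 48.0, 1 / 6)
        od = 0.05 * (1 - np.exp(-t))
        assert growth_rate_time_to_threshold(GrowthCurve("w", "s", "e", "t", t, od)) is None

    def test_interpolation_converges_with_sampling_interval(self):
        errors = []
        for dt in (30.0, 10.0, 2.0):
            r = growth_rate_time_to_threshold(exponential_curve(dt_min=dt))
            errors.append(abs(r - 1.0))
        assert errors[0] >= errors[1] >= errors[2]
        assert errors[2] < 1e-3

    def test_faster_doubling_gives_larger_rate(self, rng):
        for _ in range(20):
            d1, d2 = sorted(rng.uniform(0.5, 4.0, size=2))
            if d2 - d1 < 1e-3:
                continue
            lag = rng.uniform(0.0, 3.0)
            r_fast = growth_rate_time_to_threshold(exponential_curve(d1, lag, t_max=96))
            r_slow = growth_rate_time_to_threshold(exponential_curve(d2, lag, t_max=96))
            assert r_fast > r_slow

    def test_curve_starting_above_threshold_rejected(self):
        t = np.arange(0.0, 5.0, 1 / 6)
        with pytest.raises(ValueError):
            growth_rate_time_to_threshold(GrowthCurve("w", "s", "e", "t", t, np.full(t.size, 0.5)))


class TestSmoothing:
    def test_constant_series_unchanged(self):
        np.testing.assert_allclose(smooth_moving_mean([0.4] * 10), 0.4)

    def test_three_point_window(self):
        out = smooth_moving_mean([0.5, 0.52, 0.48])
        assert out[1] == pytest.approx(0.5)

    def test_truncated_endpoints(self):
        np.testing.assert_allclose(smooth_moving_mean([0.0, 1.0, 0.0]), [0.5, 1 / 3, 0.5])

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            smooth_moving_mean([1.0, 2.0], window=2)


class TestCarryingCapacity:
    def test_constant_replicates(self):
        assert carrying_capacity({"r1": [0.5] * 10, "r2": [0.5] * 10}) == pytest.approx(0.5)

    def test_mean_across_replicates(self):
        assert carrying_capacity({"r1": [0.4], "r2": [0.6]}) == pytest.approx(0.5)

    def test_noisy_recovery_within_sampling_error(self, rng):
        true_k, noise_sd, n_rep, n_cycles = 0.55, 0.02, 4, 38
        trajs = {
            f"r{k}": true_k + rng.normal(0, noise_sd, size=n_cycles) for k in range(n_rep)
        }
        est = carrying_capacity(trajs)
        se = noise_sd / np.sqrt(n_rep * n_cycles)
        assert abs(est - true_k) < 4 * se

    def test_empty_input_undefined(self):
        with pytest.raises(UndefinedResultError):
            carrying_capacity({})


class TestAggregation:
    def test_two_level_mean_differs_from_flat_mean(self):
        curves = []
        for evo, doublings in (("e1", (1.0, 1 / 1.2)), ("e2", (1 / 0.8,))):
            for k, d in enumerate(doublings):
                curves.append(exponential_curve(doubling_h=d))
                curves[-1].species = "sp"
                curves[-1].evo_replicate = evo
                curves[-1].tech_replicate = f"t{k}"
        params = aggregate_growth_params(curves)
        # within-evo means ~ (1.1, 0.8) -> species mean 0.95, not flat 1.0
        assert params["sp"].r == pytest.approx(0.95, abs=0.01)
        flat = np.mean([growth_rate_time_to_threshold(c) for c in curves])
        assert abs(params["sp"].r - flat) > 0.02

    def test_single_curve_returns_its_own_rate(self):
        c = exponential_curve()
        params = aggregate_growth_params([c])
        assert params["sp"].r == pytest.approx(growth_rate_time_to_threshold(c))

    def test_species_never_reaching_threshold_has_undefined_rate(self):
        t = np.arange(0.0, 48.0, 1 / 6)
        c = GrowthCurve("w", "slow", "e1", "t1", t, np.full(t.size, 0.01))
        params = aggregate_growth_params([c])
        assert params["slow"].r is None


class TestDominance:
    params = {
        "A": GrowthParams("A", r=0.95, K=0.6),
        "B": GrowthParams("B", r=0.95, K=0.4),
        "C": GrowthParams("C", r=None, K=None),
    }

    def test_higher_k_wins(self):
        pred = predict_dominant_from_growth(("A", "B"), self.params, "K")
        assert pred.species == "A" and not pred.tie_flagged

    def test_exact_tie_flagged(self):
        pred = predict_dominant_from_growth(("A", "B"), self.params, "r")
        assert pred.tie_flagged

    def test_undefined_criterion_excludes_pair(self):
        pred = predict_dominant_from_growth(("A", "C"), self.params, "r")
        assert pred.species is None
        assert "undefined" in pred.excluded_reason

    def test_blank_subtraction_shifts_crossing(self):
        c = exponential_curve()
        r_blanked = growth_rate_time_to_threshold(c, blank=0.01)
        assert r_blanked < growth_rate_time_to_threshold(c)


class TestObservedDominant:
    def test_mean_fraction_and_majority_modes(self):
        from evoassembly.growth import observed_dominant
        from conftest import build_series

        # mean fraction favours A (0.55), but B dominates 2 of 3 replicates
        ts = build_series(
            "A-B", ("A", "B"),
            {("r1", 7): (0.95, 0.05), ("r2", 7): (0.4, 0.6), ("r3", 7): (0.3, 0.7)},
        )
        assert observed_dominant(ts, 70) == "A"
        assert observed_dominant(ts, 70, mode="majority") == "B"

    def test_exact_tie_is_undetermined(self):
        from evoassembly.growth import observed_dominant
        from conftest import build_series

        ts = build_series("A-B", ("A", "B"), {("r1", 7): (0.5, 0.5)})
        assert observed_dominant(ts, 70) is None


class TestDominanceAccuracy:
    def test_perfect_prediction_closed_form(self):
        observed = {(f"a{i}", f"b{i}"): f"a{i}" for i in range(42)}
        acc, p, n = dominance_prediction_accuracy(observed, observed)
        assert acc == 1.0 and n == 42
        assert p == pytest.approx(0.5**42)

    @pytest.mark.parametrize(
        "correct, expected_p",
        [(21, 0.5611928356238423), (30, 0.003957948667448363)],
    )
    def test_exact_binomial_tail(self, correct, expected_p):
        observed = {(f"a{i}", f"b{i}"): f"a{i}" for i in range(42)}
        predicted = {
            pair: (pair[0] if i < correct else pair[1])
            for i, pair in enumerate(sorted(observed))
        }
        acc, p, n = dominance_prediction_accuracy(observed, predicted)
        assert acc == pytest.approx(correct / 42)
        assert p == pytest.approx(expected_p)
        assert p == pytest.approx(stats.binom.sf(correct - 1, 42, 0.5))

    def test_excluded_pairs_do_not_count(self):
        observed = {("a", "b"): "a", ("c", "d"): "c"}
        predicted = {("a", "b"): "a", ("c", "d"): None}
        acc, _, n = dominance_prediction_accuracy(observed, predicted)
        assert (acc, n) == (1.0, 1)

    def test_no_evaluable_pairs(self):
        with pytest.raises(UndefinedResultError):
            dominance_prediction_accuracy({("a", "b"): "a"}, {("a", "b"): None})


class TestSimulatedCurveRecovery:
    def test_noiseless_logistic_with_unit_doubling(self):
        t = np.arange(0.0, 48.0, 1 / 6)
        od = lagged_logistic_od(t, lag_h=0.0, doubling_h=1.0, K=0.7)
        r = growth_rate_time_to_threshold(GrowthCurve("w", "s", "e", "t", t, od))
        # logistic slowdown near threshold biases r down by < 2%
        assert r == pytest.approx(1.0, rel=0.02)

    def test_saturation_below_threshold_gives_undefined_rate(self):
        curves = simulate_growth_curves(
            {"s": {"lag": 1.0, "doubling": 1.0, "K": 0.05}}, noise_sd=0.0, seed=0
        )
        assert all(growth_rate_time_to_threshold(c) is None for c in curves)

    def test_noisy_recovery_within_five_percent(self):
        truth = {"lag": 1.5, "doubling": 1.3, "K": 0.6}
        curves = simulate_growth_curves(
            {"s": truth}, n_evo_replicates=1, n_tech_replicates=4,
            noise_sd=0.003, evo_jitter=0.0, seed=14,
        )
        t = np.arange(0.0, 48.0, 1 / 6)
        clean = lagged_logistic_od(t, truth["lag"], truth["doubling"], truth["K"])
        r_true = growth_rate_time_to_threshold(GrowthCurve("w", "s", "e", "t", t, clean))
        params = aggregate_growth_params(curves)
        assert params["s"].r == pytest.approx(r_true, rel=0.05)
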