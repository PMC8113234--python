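"""The pairwise-to-trio assembly rule, its accuracy, and winner predictions."""

import numpy as np
import pytest
from scipy import stats

from evoassembly.assembly import (
    PairOutcome,
    max_increaser_prediction_accuracy,
    pair_outcome,
    predict_trio_from_pairs,
    predict_trio_max_increaser,
    prediction_accuracy,
    uninformed_guess,
)
from evoassembly.errors import UndefinedResultError
from evoassembly.simulate import make_consistent_trio
from conftest import build_series


def outcomes(fa_ab, fb_bc, fc_ac, generation=70.0):
    """Three PairOutcome for trio A/B/C from the first-named species' fractions."""
    return [
        PairOutcome(("A", "B"), generation, {"A": fa_ab, "B": 1 - fa_ab}),
        PairOutcome(("B", "C"), generation, {"B": fb_bc, "C": 1 - fb_bc}),
        PairOutcome(("A", "C"), generation, {"C": fc_ac, "A": 1 - fc_ac}),
    ]


class TestPredictTrioFromPairs:
    def test_symmetric_pairs_predict_barycenter(self):
        pred = predict_trio_from_pairs(outcomes(0.5, 0.5, 0.5))
        np.testing.assert_allclose(pred.predicted, [1 / 3] * 3, atol=1e-12)

    def test_hand_computed_geometric_means(self):
        # f_A|AB=0.8, f_A|AC=0.2, f_B|BC=0.6, f_C|AC=0.8, f_C|BC=0.4
        pred = predict_trio_from_pairs(outcomes(0.8, 0.6, 0.8))
        g = np.array([np.sqrt(0.8 * 0.2), np.sqrt(0.2 * 0.6), np.sqrt(0.8 * 0.4)])
        np.testing.assert_allclose(pred.predicted, g / g.sum(), atol=1e-12)
        np.testing.assert_allclose(
            pred.predicted, [0.30486, 0.26401, 0.43113], atol=1e-5
        )

    def test_excluded_species_floors_to_small_fraction(self):
        pred = predict_trio_from_pairs(outcomes(0.0, 0.5, 1.0), floor=1e-3)
        assert pred.predicted[0] < 0.01  # species A lost both its pairs

    def test_permutation_equivariance(self, rng):
        f = rng.uniform(0.1, 0.9, size=3)
        pred = predict_trio_from_pairs(outcomes(*f)).predicted
        relabeled = [
            PairOutcome(("X", "Y"), 70.0, {"X": f[0], "Y": 1 - f[0]}),
            PairOutcome(("Y", "Z"), 70.0, {"Y": f[1], "Z": 1 - f[1]}),
            PairOutcome(("X", "Z"), 70.0, {"Z": f[2], "X": 1 - f[2]}),
        ]
        np.testing.assert_allclose(
            predict_trio_from_pairs(relabeled).predicted, pred, atol=1e-12
        )

    def test_inconsistent_generations_rejected(self):
        pairs = outcomes(0.5, 0.5, 0.5)
        pairs[2] = PairOutcome(("A", "C"), 400.0, {"A": 0.5, "C": 0.5})
        with pytest.raises(ValueError):
            predict_trio_from_pairs(pairs)

    def test_missing_pair_rejected(self):
        with pytest.raises(ValueError):
            predict_trio_from_pairs(outcomes(0.5, 0.5, 0.5)[:2])


class TestUninformedGuess:
    def test_values_and_sum(self):
        np.testing.assert_allclose(uninformed_guess(3), [1 / 3] * 3)
        np.testing.assert_allclose(uninformed_guess(2), [0.5, 0.5])
        assert uninformed_guess(7).sum() == pytest.approx(1.0)

    def test_rejects_singletons(self):
        with pytest.raises(ValueError):
            uninformed_guess(1)


class TestPredictionAccuracy:
    def test_perfect_prediction_scores_one(self, rng):
        x = rng.dirichlet(np.ones(3))
        assert prediction_accuracy(x, x) == pytest.approx(1.0)

    def test_barycenter_vs_vertex(self):
        acc = prediction_accuracy([1 / 3] * 3, [1, 0, 0])
        assert acc == pytest.approx(1 - np.sqrt(2) / 3, abs=1e-9)

    def test_opposite_pair_vertices_score_zero(self):
        assert prediction_accuracy([1, 0], [0, 1]) == pytest.approx(0.0)

    def test_lower_bound_for_trios(self, rng):
        # sqrt(n) normalization: trio accuracy can never fall below 1 - sqrt(2/3)
        for _ in range(50):
            a, b = rng.dirichlet(np.ones(3)), rng.dirichlet(np.ones(3))
            assert prediction_accuracy(a, b) >= 1 - np.sqrt(2 / 3) - 1e-12

    def test_monotone_decrease_along_a_ray(self):
        pred = np.array([1 / 3, 1 / 3, 1 / 3])
        target = np.array([0.8, 0.1, 0.1])
        accs = [
            prediction_accuracy(pred, pred + t * (target - pred))
            for t in np.linspace(0, 1, 11)
        ]
        assert all(a > b for a, b in zip(accs, accs[1:]))


class TestConsistentTrioFixedPoint:
    def test_constructed_observation_scores_exactly_one(self, rng):
        for _ in range(20):
            pairs = outcomes(*rng.uniform(0.05, 0.95, size=3))
            obs = make_consistent_trio(pairs)
            pred = predict_trio_from_pairs(pairs)
            assert prediction_accuracy(pred.predicted, obs) == pytest.approx(1.0, abs=1e-12)

    def test_accuracy_improves_as_noise_shrinks(self, rng):
        pairs = outcomes(0.7, 0.4, 0.6)
        obs = make_consistent_trio(pairs)
        pred = predict_trio_from_pairs(pairs).predicted
        mean_acc = []
        for scale in (10.0, 100.0, 1000.0):
            noisy = rng.dirichlet(obs * scale, size=200)
            mean_acc.append(np.mean([prediction_accuracy(pred, o) for o in noisy]))
        assert mean_acc[0] < mean_acc[1] < mean_acc[2]


class TestPairOutcome:
    def test_mean_over_replicates(self, pair_series):
        out = pair_outcome(pair_series, 400)
        assert out.fraction_of["A"] == pytest.approx(0.45)  # mean of 0.1 and 0.8
        assert out.n_replicates == 2

    def test_rejects_trios(self):
        ts = build_series("t", ("A", "B", "C"), {("r1", 7): (0.2, 0.3, 0.5)})
        with pytest.raises(ValueError):
            pair_outcome(ts, 70)


class TestAccuracySweep:
    @staticmethod
    def _dataset():
        pair_map = {
            "A-B": build_series("A-B", ("A", "B"), {("r1", 7): (0.7, 0.3)}),
            "B-C": build_series("B-C", ("B", "C"), {("r1", 7): (0.4, 0.6)}),
            "A-C": build_series("A-C", ("A", "C"), {("r1", 7): (0.5, 0.5)}),
        }
        trio_map = {
            "A-B-C": build_series(
                "A-B-C", ("A", "B", "C"),
                {("r1", 7): (0.5, 0.2, 0.3), ("r2", 7): (0.2, 0.5, 0.3)},
            )
        }
        return trio_map, pair_map

    def test_mean_observation_scores_at_least_per_replicate(self):
        """Distance to the replicate mean is bounded by the mean distance (convexity)."""
        from evoassembly.assembly import accuracy_sweep

        trio_map, pair_map = self._dataset()
        kwargs = dict(generations=[70.0], methods=["pairs_same_generation", "uninformed"])
        mean_acc, _ = accuracy_sweep(trio_map, pair_map, **kwargs)
        rep_acc, _ = accuracy_sweep(trio_map, pair_map, observation="per_replicate", **kwargs)
        merged = mean_acc.merge(rep_acc, on=["trio", "generation", "method"])
        assert (merged["accuracy_x"] >= merged["accuracy_y"] - 1e-12).all()

    def test_trio_with_missing_pair_excluded(self):
        from evoassembly.assembly import accuracy_sweep

        trio_map, pair_map = self._dataset()
        del pair_map["B-C"]
        frame, excluded = accuracy_sweep(trio_map, pair_map, generations=[70.0])
        assert frame.empty
        assert excluded and excluded[0][0] == "A-B-C"


class TestTrioMaxIncreaserPrediction:
    def test_consistent_double_winner(self):
        pred = predict_trio_max_increaser(
            {("A", "B"): "A", ("A", "C"): "A", ("B", "C"): "B"}
        )
        assert pred.species == "A"
        assert not pred.transient_topology

    def test_transient_topology_falls_back_to_mean_increase(self):
        pred = predict_trio_max_increaser(
            {("A", "B"): "A", ("B", "C"): "B", ("A", "C"): "C"},
            mean_increases={"A": 1.2, "B": 2.5, "C": 1.1},
        )
        assert pred.species == "B"
        assert pred.transient_topology

    def test_transient_topology_detected(self):
        pred = predict_trio_max_increaser(
            {("A", "B"): "A", ("A", "C"): "C", ("B", "C"): "B"},
            mean_increases={"A": 1.0, "B": 1.0, "C": 2.0},
        )
        assert pred.transient_topology

    def test_tie_flags_propagate(self):
        pred = predict_trio_max_increaser(
            {("A", "B"): "A", ("A", "C"): "A", ("B", "C"): "C"},
            tie_flags={("A", "B"): True},
        )
        assert pred.tie_flagged


class TestWinnerPredictionAccuracy:
    def test_all_correct_closed_form(self):
        observed = {f"t{i}": "A" for i in range(10)}
        acc, p, n = max_increaser_prediction_accuracy(observed, observed)
        assert acc == 1.0 and n == 10
        assert p == pytest.approx((1 / 3) ** 10)

    def test_eighteen_of_twentytwo(self):
        observed = {f"t{i}": "A" for i in range(22)}
        predicted = {f"t{i}": ("A" if i < 18 else "B") for i in range(22)}
        acc, p, n = max_increaser_prediction_accuracy(observed, predicted)
        assert acc == pytest.approx(18 / 22)
        assert p == pytest.approx(stats.binom.sf(17, 22, 1 / 3))
        assert p == pytest.approx(4e-6, rel=0.1)

    def test_chance_level_predictions_center_on_third(self, rng):
        rates = []
        for _ in range(300):
            observed = {f"t{i}": rng.choice(list("ABC")) for i in range(20)}
            predicted = {f"t{i}": rng.choice(list("ABC")) for i in range(20)}
            acc, _, _ = max_increaser_prediction_accuracy(observed, predicted)
            rates.append(acc)
        assert np.mean(rates) == pytest.approx(1 / 3, abs=0.02)

    def test_no_evaluable_trios(self):
        with pytest.raises(UndefinedResultError):
            max_increaser_prediction_accuracy({"a": "A"}, {"b": "B"})
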