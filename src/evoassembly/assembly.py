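"""Bottom-up prediction of trio compositions from pairwise outcomes.

The assembly rule predicts the fraction of species *i* in a three-species
community as proportional to the weighted geometric mean of its fractions in
the two pairwise cocultures it takes part in:

    g_i = prod_{j != i} f_{i|ij} ** w_ij,   f_i = g_i / sum_k g_k

with equal weights ``w_ij = 1/2`` by default.  Prediction accuracy against an
observed composition is ``1 - ||prediction - observation|| / sqrt(n)``.

A coarser, qualitative prediction identifies the trio's maximally increasing
member from the pairs': a species that is the max-increaser in both of its
pairs is predicted for the trio; when every pair has a different winner (a
"transient topology"), the species with the highest mean increase is used.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UndefinedResultError
from .io_composition import CompositionTimeSeries, GenerationMap, composition_at_generation
from .repeatability import DEFAULT_FRACTION_FLOOR

__all__ = [
    "PairOutcome",
    "TrioPrediction",
    "pair_outcome",
    "predict_trio_from_pairs",
    "uninformed_guess",
    "prediction_accuracy",
    "accuracy_sweep",
    "TrioWinnerPrediction",
    "predict_trio_max_increaser",
    "max_increaser_prediction_accuracy",
    "PREDICTION_METHODS",
]

PREDICTION_METHODS = (
    "pairs_same_generation",
    "pairs_ecological",
    "carrying_capacity",
    "uninformed",
)


@dataclass(frozen=True)
class PairOutcome:
    """Replicate-averaged pairwise fractions at one resolved generation."""

    pair: tuple[str, str]
    generation: float
    fraction_of: dict[str, float]
    n_replicates: int = 0

    def __post_init__(self) -> None:
        if len(self.pair) != 2 or self.pair[0] == self.pair[1]:
            raise ValueError("pair must be two distinct species")
        object.__setattr__(self, "pair", tuple(sorted(self.pair)))
        total = sum(self.fraction_of.get(s, 0.0) for s in self.pair)
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"pairwise fractions of {self.pair} sum to {total:.6g}, not 1")


@dataclass
class TrioPrediction:
    """Predicted composition of a three-species community."""

    trio: tuple[str, str, str]
    source_generation: float
    predicted: np.ndarray
    method: str = "pairs_same_generation"

    def __post_init__(self) -> None:
        self.trio = tuple(self.trio)
        self.predicted = np.asarray(self.predicted, dtype=float)
        if self.predicted.size != 3 or np.any(self.predicted < 0):
            raise ValueError("prediction must be three non-negative fractions")
        if abs(self.predicted.sum() - 1.0) > 1e-9:
            raise ValueError("prediction must sum to 1")


def pair_outcome(
    series: CompositionTimeSeries,
    generation: float,
    gmap: GenerationMap | None = None,
) -> PairOutcome:
    """Mean pairwise fractions across the replicates present at the nearest transfer."""
    if series.n_species != 2:
        raise ValueError(f"community {series.community!r} is not a pair")
    resolved = composition_at_generation(series, generation, gmap)
    if not resolved.fractions:
        raise UndefinedResultError(
            f"pair {series.community!r} has no replicates at transfer {resolved.transfer}"
        )
    mean = np.mean([v for v in resolved.fractions.values()], axis=0)
    mean = mean / mean.sum()
    return PairOutcome(
        pair=tuple(series.species),
        generation=resolved.generation,
        fraction_of={sp: float(f) for sp, f in zip(series.species, mean)},
        n_replicates=len(resolved.fractions),
    )


def predict_trio_from_pairs(
    pairs: Sequence[PairOutcome],
    weights: Mapping[tuple[str, str], float] | None = None,
    floor: float = DEFAULT_FRACTION_FLOOR,
    generation_tol: float = 1e-6,
) -> TrioPrediction:
    """Weighted-geometric-mean assembly rule.

    ``pairs`` must be the three pairwise outcomes covering one trio, all at
    the same generation.  ``weights`` optionally maps each (sorted) pair to
    the exponent applied to that pair's fraction; by default both exponents
    are 1/2 (plain geometric mean).  Zero pairwise fractions are floored by
    ``floor`` before the product so an excluded species yields a small but
    finite predicted fraction.
    """
    if len(pairs) != 3:
        raise ValueError("exactly three pairwise outcomes are required")
    species = sorted({s for p in pairs for s in p.pair})
    if len(species) != 3:
        raise ValueError(f"pairs do not cover a trio: {species}")
    seen = {p.pair for p in pairs}
    if len(seen) != 3:
        raise ValueError("duplicate pair outcomes")
    gens = [p.generation for p in pairs]
    if max(gens) - min(gens) > generation_tol:
        raise ValueError(f"pair outcomes are at inconsistent generations: {gens}")

    geo = []
    for sp in species:
        prod = 1.0
        for p in pairs:
            if sp not in p.pair:
                continue
            w = 0.5 if weights is None else float(weights[p.pair])
            f = max(p.fraction_of[sp], floor)
            prod *= f**w
        geo.append(prod)
    geo = np.asarray(geo)
    return TrioPrediction(
        trio=tuple(species),
        source_generation=float(np.mean(gens)),
        predicted=geo / geo.sum(),
        method="pairs_same_generation",
    )


def uninformed_guess(n: int) -> np.ndarray:
    """Barycentric prediction: every species at 1/n."""
    if n < 2:
        raise ValueError("n must be >= 2")
    return np.full(n, 1.0 / n)


def prediction_accuracy(prediction, observation, normalization: str = "sqrt_n") -> float:
    """1 - ||prediction - observation||_2 / sqrt(n).

    Equals 1 for a perfect prediction; can reach 0 only for two-species
    compositions under the sqrt(n) scaling (the simplex diameter is sqrt(2)
    for any n, so for n = 3 the score is bounded below by 1 - sqrt(2/3)).
    """
    prediction = np.asarray(prediction, dtype=float)
    observation = np.asarray(observation, dtype=float)
    if prediction.shape != observation.shape:
        raise ValueError(f"shape mismatch: {prediction.shape} vs {observation.shape}")
    n = prediction.size
    factor = np.sqrt(n) if normalization == "sqrt_n" else np.sqrt(2.0)
    return float(1.0 - np.linalg.norm(prediction - observation) / factor)


def accuracy_sweep(
    trio_series: Mapping[str, CompositionTimeSeries],
    pair_series: Mapping[str, CompositionTimeSeries],
    gmap: GenerationMap | None = None,
    generations: Sequence[float] | None = None,
    methods: Sequence[str] = PREDICTION_METHODS,
    g_ecological: float = 70.0,
    carrying_capacities: Mapping[str, float] | None = None,
    floor: float = DEFAULT_FRACTION_FLOOR,
    observation: str = "mean",
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Per-trio prediction accuracies across generations and methods.

    Methods: ``pairs_same_generation`` (assembly rule from pairs at the
    evaluated generation), ``pairs_ecological`` (pairs frozen at
    ``g_ecological``), ``carrying_capacity`` (species' mean monoculture
    carrying capacities normalized to sum 1; requires ``carrying_capacities``),
    and ``uninformed`` (1/3 each).  Observation is the mean composition of the
    trio's replicates at the evaluated generation (``observation="per_replicate"``
    instead averages per-replicate accuracies, for diagnostics).  Trios whose
    three constituent pairs are not all present are excluded and reported.

    Returns a long frame ``trio, generation, method, accuracy`` plus the
    exclusion list.
    """
    if observation not in ("mean", "per_replicate"):
        raise ValueError(f"unknown observation mode {observation!r}")
    gmap = gmap or GenerationMap()
    if generations is None:
        generations = [gmap.generation(t) for t in gmap.sampled_transfers]
    pair_index: dict[tuple[str, str], CompositionTimeSeries] = {}
    for ts in pair_series.values():
        if ts.n_species == 2:
            pair_index[tuple(sorted(ts.species))] = ts

    rows = []
    excluded: list[tuple[str, str]] = []
    for name in sorted(trio_series):
        trio_ts = trio_series[name]
        if trio_ts.n_species != 3:
            excluded.append((name, "not a trio"))
            continue
        sp = sorted(trio_ts.species)
        needed = [(sp[0], sp[1]), (sp[0], sp[2]), (sp[1], sp[2])]
        missing = [p for p in needed if p not in pair_index]
        if missing:
            excluded.append((name, f"missing constituent pairs {missing}"))
            continue
        for g in generations:
            resolved = composition_at_generation(trio_ts, g, gmap)
            if not resolved.fractions:
                continue
            # realign observations to sorted species order
            order = [trio_ts.species.index(s) for s in sp]
            if observation == "mean":
                mean = np.mean([v for v in resolved.fractions.values()], axis=0)
                obs_list = [(mean / mean.sum())[order]]
            else:
                obs_list = [v[order] for _, v in sorted(resolved.fractions.items())]
            for method in methods:
                try:
                    if method == "pairs_same_generation":
                        outs = [pair_outcome(pair_index[p], g, gmap) for p in needed]
                        pred = predict_trio_from_pairs(outs, floor=floor).predicted
                    elif method == "pairs_ecological":
                        outs = [pair_outcome(pair_index[p], g_ecological, gmap) for p in needed]
                        pred = predict_trio_from_pairs(outs, floor=floor).predicted
                    elif method == "carrying_capacity":
                        if carrying_capacities is None:
                            continue
                        ks = np.array([carrying_capacities[s] for s in sp], dtype=float)
                        pred = ks / ks.sum()
                    elif method == "uninformed":
                        pred = uninformed_guess(3)
                    else:
                        raise ValueError(f"unknown method {method!r}")
                except UndefinedResultError:
                    continue
                rows.append(
                    {
                        "trio": name,
                        "generation": float(g),
                        "method": method,
                        "accuracy": float(
                            np.mean([prediction_accuracy(pred, o) for o in obs_list])
                        ),
                    }
                )
    frame = pd.DataFrame(rows, columns=["trio", "generation", "method", "accuracy"])
    return frame, excluded


@dataclass
class TrioWinnerPrediction:
    """Predicted maximally increasing member of a trio, from its pairs."""

    trio: tuple[str, str, str]
    species: str
    transient_topology: bool = False
    tie_flagged: bool = False


def predict_trio_max_increaser(
    pair_winners: Mapping[tuple[str, str], str],
    mean_increases: Mapping[str, float] | None = None,
    tie_flags: Mapping[tuple[str, str], bool] | None = None,
) -> TrioWinnerPrediction:
    """Predict a trio's max-increaser from its three pairs' max-increasers.

    If one species is the max-increaser in both pairs it belongs to, that
    species is predicted.  Otherwise every pair has a distinct winner
    (transient topology) and the species with the highest mean increase is
    predicted; ``mean_increases`` is required in that case.
    """
    winners = {tuple(sorted(p)): w for p, w in pair_winners.items()}
    if len(winners) != 3:
        raise ValueError("winners for exactly three pairs are required")
    species = sorted({s for p in winners for s in p})
    if len(species) != 3:
        raise ValueError(f"pairs do not cover a trio: {species}")
    tie_flagged = bool(tie_flags and any(tie_flags.get(p, False) for p in winners))

    win_counts = {s: 0 for s in species}
    for p, w in winners.items():
        if w not in p:
            raise ValueError(f"winner {w!r} is not a member of pair {p}")
        win_counts[w] += 1
    double = [s for s in species if win_counts[s] == 2]
    if double:
        return TrioWinnerPrediction(
            trio=tuple(species), species=double[0], tie_flagged=tie_flagged
        )
    if mean_increases is None:
        raise ValueError("transient topology: mean_increases required to break the cycle")
    best = max(species, key=lambda s: (mean_increases[s], ))
    # label-order tie-break on exact ties
    top = [s for s in species if mean_increases[s] == mean_increases[best]]
    return TrioWinnerPrediction(
        trio=tuple(species),
        species=sorted(top)[0],
        transient_topology=True,
        tie_flagged=tie_flagged or len(top) > 1,
    )


def max_increaser_prediction_accuracy(
    observed: Mapping[str, str], predicted: Mapping[str, str]
) -> tuple[float, float, int]:
    """Fraction of trios whose max-increaser was predicted correctly.

    Chance level for a trio is 1/3; significance is the exact one-sided
    binomial tail P(X >= k | n, 1/3).  Returns (accuracy, p_value, n).
    """
    trios = sorted(set(observed) & set(predicted))
    n = len(trios)
    if n == 0:
        raise UndefinedResultError("no trios with both observed and predicted winner")
    k = sum(observed[t] == predicted[t] for t in trios)
    p = float(stats.binom.sf(k - 1, n, 1.0 / 3.0))
    return k / n, p, n
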