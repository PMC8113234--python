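"""Evolutionary repeatability: the maximally increasing member and its null model.

For every replicate the *maximally increasing member* is the species whose
relative abundance grew by the largest factor between an ecological reference
generation (~70) and the end of the experiment (~400).  A community's
repeatability score is the frequency of replicates sharing the same
max-increaser; it ranges from ``1/n`` (every species equally often) to 1
(perfectly repeatable).

The null model shuffles the pooled fold changes of all (community, replicate,
species) slots of one size class (pairs or trios separately), recomputes every
community's score, and takes the across-community mean; the p-value is the raw
frequency of shuffled means at least as high as the observed mean over 2000
iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import UndefinedResultError
from .io_composition import CompositionTimeSeries, GenerationMap, composition_at_generation

__all__ = [
    "FoldChangeTable",
    "fold_changes",
    "max_increaser",
    "repeatability_score",
    "ShuffleNullResult",
    "shuffle_null",
    "observed_vs_null_report",
    "significance_tier",
    "MIN_REPLICATES",
    "DEFAULT_ITERATIONS",
    "DEFAULT_FRACTION_FLOOR",
]

#: Communities need at least this many replicates present at both generations.
MIN_REPLICATES = 3

#: Shuffle-null iterations used throughout.
DEFAULT_ITERATIONS = 2000

#: Pseudo-fraction replacing zeros when colony totals are unavailable.
DEFAULT_FRACTION_FLOOR = 1e-3


@dataclass
class FoldChangeTable:
    """Relative-abundance fold changes of one size class (fixed species count).

    ``table`` is long format with columns ``community, replicate, species,
    fold``; every (community, replicate) present carries exactly ``n_species``
    rows.  ``excluded`` lists (community, reason) pairs dropped on the way.
    """

    n_species: int
    table: pd.DataFrame
    g1: float = 70.0
    g2: float = 400.0
    excluded: list[tuple[str, str]] = field(default_factory=list)

    def communities(self) -> tuple[str, ...]:
        return tuple(sorted(self.table["community"].unique()))

    def community_matrix(self, community: str) -> tuple[list[str], list[str], np.ndarray]:
        """(replicates, species, folds[replicate, species]) for one community."""
        sub = self.table[self.table["community"] == community]
        pivot = sub.pivot(index="replicate", columns="species", values="fold").sort_index()
        pivot = pivot.loc[:, sorted(pivot.columns)]
        return list(pivot.index), list(pivot.columns), pivot.to_numpy(dtype=float)


def _floored_fraction(frac: float, total_count: int | None, floor: float) -> float:
    if frac > 0:
        return frac
    if total_count is not None:
        return 1.0 / (total_count + 1.0)
    return floor


def fold_changes(
    series_map: Mapping[str, CompositionTimeSeries],
    g1: float = 70.0,
    g2: float = 400.0,
    gmap: GenerationMap | None = None,
    floor: float = DEFAULT_FRACTION_FLOOR,
    min_replicates: int = MIN_REPLICATES,
) -> dict[int, FoldChangeTable]:
    """Fold change of every species' relative abundance between two generations.

    Zero fractions are floored before division: by ``1/(total colonies + 1)``
    when colony counts are available (the plating detection limit), otherwise
    by ``floor``.  Replicates missing either generation are dropped;
    communities left with fewer than ``min_replicates`` replicates are
    excluded with a reason.  Results are split by species count (pairs and
    trios are analysed separately).
    """
    gmap = gmap or GenerationMap()
    tables: dict[int, list[dict]] = {}
    excluded: dict[int, list[tuple[str, str]]] = {}
    for community in sorted(series_map):
        ts = series_map[community]
        at1 = composition_at_generation(ts, g1, gmap)
        at2 = composition_at_generation(ts, g2, gmap)
        reps = sorted(set(at1.fractions) & set(at2.fractions))
        n = ts.n_species
        if len(reps) < min_replicates:
            excluded.setdefault(n, []).append(
                (community, f"only {len(reps)} replicates present at both generations (< {min_replicates})")
            )
            continue
        for rep in reps:
            f1 = at1.fractions[rep]
            f2 = at2.fractions[rep]
            tot1 = ts.sample_total_count(rep, at1.transfer)
            tot2 = ts.sample_total_count(rep, at2.transfer)
            for i, sp in enumerate(ts.species):
                a = _floored_fraction(float(f1[i]), tot1, floor)
                b = _floored_fraction(float(f2[i]), tot2, floor)
                tables.setdefault(n, []).append(
                    {"community": community, "replicate": rep, "species": sp, "fold": b / a}
                )
    out: dict[int, FoldChangeTable] = {}
    for n in sorted(set(tables) | set(excluded)):
        frame = pd.DataFrame(
            tables.get(n, []), columns=["community", "replicate", "species", "fold"]
        )
        out[n] = FoldChangeTable(
            n_species=n, table=frame, g1=g1, g2=g2, excluded=excluded.get(n, [])
        )
    return out


def max_increaser(folds: Sequence[float], species: Sequence[str]) -> tuple[str, bool]:
    """Species with the largest fold change in one replicate.

    Exact ties break toward the earliest species in label order; the returned
    flag is True when a tie occurred.
    """
    folds = np.asarray(folds, dtype=float)
    if folds.size < 2:
        raise ValueError("need >= 2 species")
    if not np.isfinite(folds).all():
        raise ValueError("fold changes must be finite (floor zero fractions first)")
    order = np.argsort(np.asarray(species, dtype=object), kind="stable")
    sorted_species = [species[i] for i in order]
    sorted_folds = folds[order]
    best = int(np.argmax(sorted_folds))
    tie = bool(np.sum(sorted_folds == sorted_folds[best]) > 1)
    return sorted_species[best], tie


def repeatability_score(winners: Sequence[str]) -> float:
    """Frequency of the modal max-increaser across replicates (in [1/n, 1])."""
    if len(winners) == 0:
        raise UndefinedResultError("no replicates")
    values, counts = np.unique(np.asarray(winners, dtype=object), return_counts=True)
    return float(counts.max() / len(winners))


def _winner_indices(folds: np.ndarray) -> np.ndarray:
    """argmax over the trailing species axis; first index wins ties (label order)."""
    return np.argmax(folds, axis=-1)


def _scores_from_winners(winners: np.ndarray, mask: np.ndarray, n_species: int) -> np.ndarray:
    """Modal winner frequency per community.

    winners: (..., C, k_max) integer species indices; mask: (C, k_max) valid
    replicates.  Returns scores of shape (..., C).
    """
    k = mask.sum(axis=-1)  # (C,)
    counts = np.stack(
        [np.sum((winners == s) & mask, axis=-1) for s in range(n_species)], axis=-1
    )
    return counts.max(axis=-1) / k


@dataclass
class ShuffleNullResult:
    """Observed repeatability of one size class against its shuffle null."""

    n_species: int
    n_communities: int
    iterations: int
    per_community_score: dict[str, float]
    observed_mean: float
    null_means: np.ndarray
    p_value: float
    seed: int | None = None

    def summary(self) -> dict:
        q1, med, q3 = np.percentile(self.null_means, [25, 50, 75])
        return {
            "n_species": self.n_species,
            "n_communities": self.n_communities,
            "iterations": self.iterations,
            "observed_mean": self.observed_mean,
            "null_mean": float(np.mean(self.null_means)),
            "null_quartiles": [float(q1), float(med), float(q3)],
            "p_value": self.p_value,
            "seed": self.seed,
        }


def shuffle_null(
    fold_table: FoldChangeTable,
    iterations: int = DEFAULT_ITERATIONS,
    seed: int | np.random.Generator | None = None,
    min_communities: int = 2,
    granularity: str = "values",
    conservative_p: bool = False,
) -> ShuffleNullResult:
    """Permutation null for the mean repeatability score of one size class.

    Every iteration pools all (community, replicate, species) fold changes of
    the class, permutes the pool uniformly without replacement, reassigns the
    values to the original slots, and recomputes each community's score and
    the across-community mean.  The p-value is the raw frequency of
    iterations whose null mean is at least the observed mean;
    ``conservative_p=True`` switches to the (b+1)/(m+1) estimator, which can
    never report zero.

    ``granularity="replicates"`` permutes intact per-replicate fold-change
    vectors across slots instead of individual scalar values.
    """
    if granularity not in ("values", "replicates"):
        raise ValueError(f"unknown granularity {granularity!r}")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    communities = fold_table.communities()
    if len(communities) < min_communities:
        raise UndefinedResultError(
            f"shuffle null needs >= {min_communities} communities, got {len(communities)}"
        )
    n = fold_table.n_species
    mats = []
    per_community_score: dict[str, float] = {}
    for community in communities:
        reps, species, folds = fold_table.community_matrix(community)
        if folds.shape[1] != n:
            raise ValueError(
                f"community {community!r} has {folds.shape[1]} species, expected {n}"
            )
        mats.append(folds)
        winners = _winner_indices(folds)
        per_community_score[community] = float(
            _scores_from_winners(winners[None, :], np.ones(folds.shape[0], bool)[None, :], n)[0]
        )

    k_max = max(m.shape[0] for m in mats)
    C = len(mats)
    values = np.full((C, k_max, n), -np.inf)
    mask = np.zeros((C, k_max), dtype=bool)
    for c, m in enumerate(mats):
        values[c, : m.shape[0], :] = m
        mask[c, : m.shape[0]] = True
    observed_mean = float(np.mean(list(per_community_score.values())))

    if granularity == "values":
        pool = values[mask].ravel()  # M*n scalars, fixed slot order
    else:
        pool = values[mask]  # M intact replicate vectors
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    null_means = np.empty(iterations)
    # batch permutations via argsort of iid uniforms; chunked to bound memory
    chunk = max(1, int(2e7 // max(pool.size, 1)))
    slot_values = np.full((C, k_max, n), -np.inf)
    for start in range(0, iterations, chunk):
        stop = min(start + chunk, iterations)
        b = stop - start
        keys = rng.random((b, pool.shape[0]))
        idx = np.argsort(keys, axis=1, kind="stable")
        permuted = pool[idx]  # (b, M*n) scalars or (b, M, n) vectors
        batch = np.broadcast_to(slot_values, (b, C, k_max, n)).copy()
        batch[:, mask, :] = permuted.reshape(b, -1, n)
        winners = _winner_indices(batch)  # (b, C, k_max)
        scores = _scores_from_winners(winners, mask, n)  # (b, C)
        null_means[start:stop] = scores.mean(axis=1)

    exceed = int(np.sum(null_means >= observed_mean))
    if conservative_p:
        p_value = (exceed + 1) / (iterations + 1)
    else:
        p_value = exceed / iterations
    return ShuffleNullResult(
        n_species=n,
        n_communities=C,
        iterations=iterations,
        per_community_score=per_community_score,
        observed_mean=observed_mean,
        null_means=null_means,
        p_value=p_value,
        seed=seed if isinstance(seed, int) else None,
    )


def significance_tier(p_value: float) -> str:
    """Figure-style annotation: '**' below 0.005, '*' at or below 0.05, else ''."""
    if p_value < 0.005:
        return "**"
    if p_value <= 0.05:
        return "*"
    return ""


def observed_vs_null_report(results: Mapping[int, ShuffleNullResult]) -> dict:
    """Combine the pair and trio shuffle-null results into one summary record."""
    report = {}
    for n in sorted(results):
        res = results[n]
        entry = res.summary()
        entry["significance"] = significance_tier(res.p_value)
        report[{2: "pairs", 3: "trios"}.get(n, f"{n}_species")] = entry
    return report
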