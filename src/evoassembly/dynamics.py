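"""Compositional-change and replicate-variability metrics.

Distances between community compositions are Euclidean distances between
fraction vectors, normalized by ``sqrt(n)`` for an ``n``-species community
(the convention used throughout the study; the true maximal distance between
two points of the simplex, ``sqrt(2)``, is available via
``normalization="true_max"``).

Two change profiles are computed per replicate: the step-to-step change
``Delta(t, t-1)`` between consecutive plated transfers, and the divergence
``Delta(g, g_ref)`` from the replicate's own composition at a reference
generation (by default ~70, the end of the ecological transient).

Between-replicate variability of a community at one generation is the mean
distance of the replicates from their medoid replicate; its null model
replaces real fractions by draws from a flat Dirichlet and the two
distributions are compared with a one-sided Mann-Whitney U test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist

from .errors import UndefinedResultError
from .io_composition import CompositionTimeSeries, GenerationMap, composition_at_generation

__all__ = [
    "normalized_distance",
    "stepwise_change",
    "change_from_reference",
    "medoid_replicate",
    "replicate_variability",
    "VariabilityResult",
    "community_variability",
    "dirichlet_null_variability",
    "variability_vs_null_test",
]


def _norm_factor(n: int, normalization: str) -> float:
    if normalization == "sqrt_n":
        return float(np.sqrt(n))
    if normalization == "true_max":
        return float(np.sqrt(2.0))
    raise ValueError(f"unknown normalization {normalization!r}")


def normalized_distance(x, y, normalization: str = "sqrt_n") -> float:
    """Euclidean distance between two fraction vectors, scaled to [0, 1].

    The default scaling divides by ``sqrt(n)`` where ``n = len(x)``;
    ``normalization="true_max"`` divides by ``sqrt(2)``, the actual diameter
    of the simplex for any ``n >= 2``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    return float(np.linalg.norm(x - y) / _norm_factor(x.size, normalization))


def stepwise_change(
    series: CompositionTimeSeries,
    gmap: GenerationMap | None = None,
    normalization: str = "sqrt_n",
) -> pd.DataFrame:
    """Delta(t, t-1): change between consecutive plated transfers, per replicate.

    Returns a long frame with columns ``community, replicate, transfer,
    generation, delta`` where ``transfer``/``generation`` refer to the later
    of the two timepoints.  Replicates with fewer than two samples contribute
    no rows.
    """
    gmap = gmap or GenerationMap()
    rows = []
    for rep in series.replicates:
        transfers = series.replicate_transfers(rep)
        for prev_t, t in zip(transfers[:-1], transfers[1:]):
            delta = normalized_distance(
                series.sample(rep, t), series.sample(rep, prev_t), normalization
            )
            rows.append(
                {
                    "community": series.community,
                    "replicate": rep,
                    "transfer": t,
                    "generation": gmap.generation(t),
                    "delta": delta,
                }
            )
    return pd.DataFrame(rows, columns=["community", "replicate", "transfer", "generation", "delta"])


def change_from_reference(
    series: CompositionTimeSeries,
    g_ref: float = 70.0,
    gmap: GenerationMap | None = None,
    normalization: str = "sqrt_n",
) -> pd.DataFrame:
    """Delta(g, g_ref): divergence of each replicate from its own reference composition.

    The reference is the replicate's composition at the transfer nearest
    ``g_ref``; rows cover every sampled transfer at or after the reference.
    Replicates missing the reference sample are skipped.
    """
    gmap = gmap or GenerationMap()
    ref_transfer = gmap.nearest_transfer(g_ref)
    rows = []
    for rep in series.replicates:
        if not series.has_sample(rep, ref_transfer):
            continue
        ref = series.sample(rep, ref_transfer)
        for t in series.replicate_transfers(rep):
            if t < ref_transfer:
                continue
            delta = normalized_distance(series.sample(rep, t), ref, normalization)
            rows.append(
                {
                    "community": series.community,
                    "replicate": rep,
                    "transfer": t,
                    "generation": gmap.generation(t),
                    "delta": delta,
                }
            )
    return pd.DataFrame(rows, columns=["community", "replicate", "transfer", "generation", "delta"])


def _ordered(compositions: Mapping[str, np.ndarray]) -> tuple[list[str], np.ndarray]:
    keys = sorted(compositions)
    mat = np.asarray([compositions[k] for k in keys], dtype=float)
    return keys, mat


def medoid_replicate(compositions: Mapping[str, np.ndarray]) -> str:
    """Replicate minimizing the summed Euclidean distance to all other replicates.

    Ties break toward the lexicographically smallest replicate id.
    """
    if not compositions:
        raise ValueError("no replicates given")
    keys, mat = _ordered(compositions)
    dists = cdist(mat, mat)
    return keys[int(np.argmin(dists.sum(axis=1)))]


def replicate_variability(
    compositions: Mapping[str, np.ndarray],
    normalization: str = "sqrt_n",
    include_medoid: bool = True,
) -> float:
    """Mean normalized distance of the replicates from their medoid replicate.

    With ``include_medoid=True`` (default) the medoid's zero distance to
    itself enters the mean; the alternative averages over the non-medoid
    replicates only.  Undefined for fewer than two replicates.
    """
    if len(compositions) < 2:
        raise UndefinedResultError("replicate variability needs >= 2 replicates")
    keys, mat = _ordered(compositions)
    medoid = medoid_replicate(compositions)
    ref = np.asarray(compositions[medoid], dtype=float)
    d = np.linalg.norm(mat - ref, axis=1) / _norm_factor(mat.shape[1], normalization)
    if include_medoid:
        return float(d.mean())
    mask = np.array([k != medoid for k in keys])
    return float(d[mask].mean())


@dataclass
class VariabilityResult:
    """Between-replicate variability of one community at one generation."""

    community: str
    generation: float
    transfer: int
    n_replicates: int
    medoid_replicate: str
    mean_distance_from_medoid: float


def community_variability(
    series: CompositionTimeSeries,
    generation: float,
    gmap: GenerationMap | None = None,
    normalization: str = "sqrt_n",
    include_medoid: bool = True,
) -> VariabilityResult:
    """Variability of a community's replicates at the transfer nearest ``generation``."""
    resolved = composition_at_generation(series, generation, gmap)
    if len(resolved.fractions) < 2:
        raise UndefinedResultError(
            f"community {series.community!r}: fewer than 2 replicates at transfer {resolved.transfer}"
        )
    return VariabilityResult(
        community=series.community,
        generation=resolved.generation,
        transfer=resolved.transfer,
        n_replicates=len(resolved.fractions),
        medoid_replicate=medoid_replicate(resolved.fractions),
        mean_distance_from_medoid=replicate_variability(
            resolved.fractions, normalization, include_medoid
        ),
    )


def dirichlet_null_variability(
    n_species: int,
    n_replicates: int,
    n_draws: int,
    seed: int | np.random.Generator | None = None,
    normalization: str = "sqrt_n",
    include_medoid: bool = True,
) -> np.ndarray:
    """Null distribution of replicate variability for random communities.

    Each draw replaces the real replicate compositions by ``n_replicates``
    iid vectors from a flat Dirichlet (alpha = 1) on the ``n_species``
    simplex and computes the medoid-based variability.  Fully vectorized;
    deterministic under a fixed seed.
    """
    if n_replicates < 2:
        raise UndefinedResultError("replicate variability needs >= 2 replicates")
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = rng.dirichlet(np.ones(n_species), size=(n_draws, n_replicates))
    # pairwise distances within each draw: (draws, k, k)
    diff = draws[:, :, None, :] - draws[:, None, :, :]
    dmat = np.linalg.norm(diff, axis=-1)
    medoid_idx = np.argmin(dmat.sum(axis=2), axis=1)  # first index wins ties = label order
    d_to_medoid = np.take_along_axis(dmat, medoid_idx[:, None, None], axis=1)[:, 0, :]
    d_to_medoid = d_to_medoid / _norm_factor(n_species, normalization)
    if include_medoid:
        return d_to_medoid.mean(axis=1)
    total = d_to_medoid.sum(axis=1)  # medoid's own term is exactly 0
    return total / (n_replicates - 1)


def variability_vs_null_test(
    observed: Sequence[float], null: Sequence[float]
) -> tuple[float, float]:
    """One-sided Mann-Whitney U test of observed variabilities against a null sample.

    The alternative is that observed communities are *less* variable than the
    random-community null.  Midranks handle ties; the degenerate case where
    every value is tied returns p = 0.5.
    """
    observed = np.asarray(observed, dtype=float)
    null = np.asarray(null, dtype=float)
    if observed.size == 0 or null.size == 0:
        raise ValueError("both samples must be non-empty")
    if np.ptp(np.concatenate([observed, null])) == 0:
        return float(observed.size * null.size / 2.0), 0.5
    res = stats.mannwhitneyu(observed, null, alternative="less", method="auto")
    return float(res.statistic), float(res.pvalue)
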