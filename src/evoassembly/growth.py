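"""Growth-curve parameter extraction and growth-based dominance prediction.

The growth rate of a strain is the number of divisions needed to grow from the
inoculation density (OD 1e-4) to a fixed threshold (OD 0.08), i.e.
``log2(0.08 / 1e-4)``, divided by the time the strain took to reach that
threshold.  The measure deliberately folds the lag phase into the rate.  The
carrying capacity is the OD a monoculture reaches by the end of a growth
cycle, smoothed per well with a 3-point moving mean and averaged across
replicates.

The dominance prediction asks whether the species with the higher r (or K)
is the more abundant one in a pairwise coculture, scored with an exact
one-sided binomial test at chance 1/2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FormatError, UndefinedResultError
from .io_composition import CompositionTimeSeries, GenerationMap, composition_at_generation

__all__ = [
    "GrowthCurve",
    "GrowthParams",
    "read_growth_curves",
    "write_growth_curves",
    "read_endpoint_ods",
    "write_endpoint_ods",
    "growth_rate_time_to_threshold",
    "smooth_moving_mean",
    "carrying_capacity",
    "aggregate_growth_params",
    "DominancePrediction",
    "predict_dominant_from_growth",
    "observed_dominant",
    "dominance_prediction_accuracy",
    "DEFAULT_OD0",
    "DEFAULT_OD_THRESHOLD",
]

DEFAULT_OD0 = 1e-4
DEFAULT_OD_THRESHOLD = 0.08

GROWTH_COLUMNS = ("well", "species", "evo_replicate", "tech_replicate", "time_min", "od")


@dataclass
class GrowthCurve:
    """One well's OD-versus-time trace."""

    well: str
    species: str
    evo_replicate: str
    tech_replicate: str
    time_h: np.ndarray
    od: np.ndarray

    def __post_init__(self) -> None:
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.time_h.size != self.od.size or self.time_h.size == 0:
            raise ValueError("time and OD must be equal-length, non-empty")
        if np.any(np.diff(self.time_h) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(self.od < 0):
            raise ValueError("OD values must be >= 0")


@dataclass
class GrowthParams:
    """Per-species growth parameters aggregated over replicates."""

    species: str
    r: float | None
    K: float | None
    provenance: str = "mono_evolved"
    n_evolutionary: int = 0


def read_growth_curves(path, sep: str = ",") -> list[GrowthCurve]:
    """Read long-format growth curves (`well,species,evo_replicate,tech_replicate,time_min,od`)."""
    table = pd.read_csv(path, sep=sep)
    missing = [c for c in GROWTH_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"growth-curve table is missing columns: {missing}")
    curves = []
    for (well, sp, evo, tech), sub in table.groupby(
        ["well", "species", "evo_replicate", "tech_replicate"], sort=True
    ):
        sub = sub.sort_values("time_min", kind="stable")
        curves.append(
            GrowthCurve(
                well=str(well),
                species=str(sp),
                evo_replicate=str(evo),
                tech_replicate=str(tech),
                time_h=sub["time_min"].to_numpy(dtype=float) / 60.0,
                od=sub["od"].to_numpy(dtype=float),
            )
        )
    return curves


def write_growth_curves(curves: Sequence[GrowthCurve], path, sep: str = ",") -> None:
    rows = []
    for c in sorted(curves, key=lambda c: (c.species, c.evo_replicate, c.tech_replicate, c.well)):
        for t, od in zip(c.time_h, c.od):
            rows.append(
                {
                    "well": c.well,
                    "species": c.species,
                    "evo_replicate": c.evo_replicate,
                    "tech_replicate": c.tech_replicate,
                    "time_min": t * 60.0,
                    "od": od,
                }
            )
    pd.DataFrame(rows, columns=list(GROWTH_COLUMNS)).to_csv(path, sep=sep, index=False)


def growth_rate_time_to_threshold(
    curve: GrowthCurve,
    od0: float = DEFAULT_OD0,
    threshold: float = DEFAULT_OD_THRESHOLD,
    blank: float = 0.0,
) -> float | None:
    """Divisions from ``od0`` to ``threshold`` divided by the time to reach it.

    The crossing time is found by linear interpolation between the bracketing
    samples, which removes most of the 10-min quantization.  Returns ``None``
    when the curve never reaches the threshold (e.g. the strain plateaus
    below it).  Curves are assumed blank-corrected; a per-plate ``blank`` can
    be subtracted here instead (off by default).
    """
    if threshold <= od0:
        raise ValueError("threshold must exceed the initial OD")
    od = curve.od - blank if blank else curve.od
    t = curve.time_h
    if od[0] >= threshold:
        raise ValueError("curve must start below the threshold")
    above = np.nonzero(od >= threshold)[0]
    if above.size == 0:
        return None
    j = int(above[0])
    t_star = t[j - 1] + (threshold - od[j - 1]) / (od[j] - od[j - 1]) * (t[j] - t[j - 1])
    if t_star <= 0:
        return None
    return float(np.log2(threshold / od0) / t_star)


def smooth_moving_mean(series, window: int = 3) -> np.ndarray:
    """Centered moving mean; endpoints average over the truncated window."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd positive integer")
    values = np.asarray(series, dtype=float)
    if values.size == 0:
        raise ValueError("series must be non-empty")
    return (
        pd.Series(values).rolling(window, center=True, min_periods=1).mean().to_numpy()
    )


def carrying_capacity(
    end_of_cycle_od: Mapping[str, Sequence[float]] | pd.DataFrame,
    window: int = 3,
    cycles: slice | Sequence[int] | None = None,
) -> float:
    """Carrying capacity from monoculture end-of-cycle ODs.

    ``end_of_cycle_od`` maps replicate -> OD trajectory over cycles (or a
    DataFrame with replicates as columns).  Each trajectory is smoothed with
    a centered ``window``-point moving mean, then all smoothed values over
    the requested cycles (default: all) are averaged across replicates.
    """
    if isinstance(end_of_cycle_od, pd.DataFrame):
        trajs = {str(c): end_of_cycle_od[c].dropna().to_numpy() for c in end_of_cycle_od.columns}
    else:
        trajs = {k: np.asarray(v, dtype=float) for k, v in end_of_cycle_od.items()}
    values = []
    for rep in sorted(trajs):
        traj = trajs[rep]
        if traj.size == 0:
            continue
        smoothed = smooth_moving_mean(traj, window)
        if cycles is not None:
            smoothed = smoothed[cycles]
        values.append(np.asarray(smoothed, dtype=float))
    if not values:
        raise UndefinedResultError("no end-of-cycle OD values available")
    return float(np.mean([v.mean() for v in values]))


def aggregate_growth_params(
    curves: Sequence[GrowthCurve],
    od0: float = DEFAULT_OD0,
    threshold: float = DEFAULT_OD_THRESHOLD,
    end_of_cycle_od: Mapping[str, Mapping[str, Sequence[float]]] | None = None,
    provenance: str = "mono_evolved",
) -> dict[str, GrowthParams]:
    """Two-level averaging of growth rates: technical -> evolutionary -> species.

    Technical replicates are averaged within each evolutionary replicate
    first, then evolutionary-replicate values are averaged — on an unbalanced
    design this differs from the flat mean over wells.  Curves that never
    reach the threshold contribute no rate.  ``end_of_cycle_od`` optionally
    maps species -> replicate -> end-of-cycle OD trajectory, from which K is
    estimated via :func:`carrying_capacity`.
    """
    by_species: dict[str, dict[str, list[float]]] = {}
    seen = set()
    for c in curves:
        seen.add(c.species)
        r = growth_rate_time_to_threshold(c, od0, threshold)
        if r is not None:
            by_species.setdefault(c.species, {}).setdefault(c.evo_replicate, []).append(r)
    species_names = sorted(seen | (set(end_of_cycle_od) if end_of_cycle_od else set()))
    out: dict[str, GrowthParams] = {}
    for sp in species_names:
        evo_means = [
            float(np.mean(vals)) for _, vals in sorted(by_species.get(sp, {}).items())
        ]
        r = float(np.mean(evo_means)) if evo_means else None
        K = None
        if end_of_cycle_od and sp in end_of_cycle_od:
            K = carrying_capacity(end_of_cycle_od[sp])
        out[sp] = GrowthParams(
            species=sp, r=r, K=K, provenance=provenance, n_evolutionary=len(evo_means)
        )
    return out


def read_endpoint_ods(path, sep: str = ",") -> dict[str, dict[str, np.ndarray]]:
    """Read monoculture end-of-cycle ODs (`species,replicate,cycle,od`) into nested mappings."""
    table = pd.read_csv(path, sep=sep)
    missing = [c for c in ("species", "replicate", "cycle", "od") if c not in table.columns]
    if missing:
        raise FormatError(f"endpoint-OD table is missing columns: {missing}")
    out: dict[str, dict[str, np.ndarray]] = {}
    for (sp, rep), sub in table.groupby(["species", "replicate"], sort=True):
        sub = sub.sort_values("cycle", kind="stable")
        out.setdefault(str(sp), {})[str(rep)] = sub["od"].to_numpy(dtype=float)
    return out


def write_endpoint_ods(
    endpoint_ods: Mapping[str, Mapping[str, Sequence[float]]], path, sep: str = ","
) -> None:
    rows = []
    for sp in sorted(endpoint_ods):
        for rep in sorted(endpoint_ods[sp]):
            for cycle, od in enumerate(np.asarray(endpoint_ods[sp][rep], dtype=float), start=1):
                rows.append({"species": sp, "replicate": rep, "cycle": cycle, "od": od})
    pd.DataFrame(rows, columns=["species", "replicate", "cycle", "od"]).to_csv(
        path, sep=sep, index=False
    )


@dataclass
class DominancePrediction:
    """Predicted dominant species of a pair from a growth criterion."""

    pair: tuple[str, str]
    criterion: str
    species: str | None
    tie_flagged: bool = False
    excluded_reason: str | None = None


def predict_dominant_from_growth(
    pair: tuple[str, str],
    params: Mapping[str, GrowthParams],
    criterion: str = "r",
) -> DominancePrediction:
    """Predict the more abundant species of a pair as the one with the larger r or K.

    Pairs for which the criterion is undefined for either species are marked
    excluded rather than guessed at.
    """
    if criterion not in ("r", "K"):
        raise ValueError("criterion must be 'r' or 'K'")
    a, b = sorted(pair)
    vals = {}
    for sp in (a, b):
        gp = params.get(sp)
        v = None if gp is None else getattr(gp, criterion)
        if v is None:
            return DominancePrediction(
                pair=(a, b),
                criterion=criterion,
                species=None,
                excluded_reason=f"{criterion} undefined for species {sp!r}",
            )
        vals[sp] = v
    if vals[a] == vals[b]:
        return DominancePrediction(pair=(a, b), criterion=criterion, species=a, tie_flagged=True)
    winner = a if vals[a] > vals[b] else b
    return DominancePrediction(pair=(a, b), criterion=criterion, species=winner)


def observed_dominant(
    series: CompositionTimeSeries,
    generation: float,
    gmap: GenerationMap | None = None,
    mode: str = "mean_fraction",
) -> str | None:
    """Observed dominant species of a pair at the resolved transfer.

    ``mode="mean_fraction"`` (default): species with mean fraction > 0.5
    across replicates; ``mode="majority"``: species dominating the most
    replicates.  Returns ``None`` when no replicate has the sample or the
    criterion is exactly tied.
    """
    if series.n_species != 2:
        raise ValueError("dominance is defined for pairs")
    if mode not in ("mean_fraction", "majority"):
        raise ValueError(f"unknown dominance mode {mode!r}")
    resolved = composition_at_generation(series, generation, gmap)
    if not resolved.fractions:
        return None
    if mode == "mean_fraction":
        score = np.mean([v for v in resolved.fractions.values()], axis=0)
    else:
        score = np.sum([v > 0.5 for v in resolved.fractions.values()], axis=0)
    if score[0] == score[1]:
        return None
    return series.species[int(np.argmax(score))]


def dominance_prediction_accuracy(
    observed: Mapping[tuple[str, str], str],
    predictions: Mapping[tuple[str, str], DominancePrediction | str | None],
) -> tuple[float, float, int]:
    """Accuracy of growth-based dominance predictions over evaluable pairs.

    A pair is evaluable when it has both an observed dominant and a
    non-excluded prediction.  Significance is the exact one-sided binomial
    tail P(X >= k | n, 1/2).  Returns (accuracy, p_value, n).
    """
    k = 0
    n = 0
    for pair in sorted(observed):
        pred = predictions.get(pair)
        if isinstance(pred, DominancePrediction):
            pred = pred.species
        if pred is None or observed[pair] is None:
            continue
        n += 1
        k += int(pred == observed[pair])
    if n == 0:
        raise UndefinedResultError("no evaluable pairs")
    p = float(stats.binom.sf(k - 1, n, 0.5))
    return k / n, p, n
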