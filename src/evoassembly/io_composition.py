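"""Reading, validation and transformation of community-composition data.

Composition data are long-format delimited tables with one row per
(community, replicate, transfer, species), carrying a colony count and/or a
relative fraction.  The in-memory container is :class:`CompositionTimeSeries`,
one per community, holding a fraction vector per (replicate, transfer) sample
in a fixed species order.

Generations are accounted for through :class:`GenerationMap`: one 48-h
growth–dilution cycle at a 1500-fold dilution corresponds to
``log2(1500) ~ 10.55`` generations, so 38 cycles span roughly 400 generations.
Plating happens only at a discrete set of transfers; queries for a target
generation resolve to the nearest sampled transfer.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import DataError, FormatError

__all__ = [
    "DEFAULT_SAMPLED_TRANSFERS",
    "FRACTION_SUM_TOL",
    "LOW_COUNT_THRESHOLD",
    "GenerationMap",
    "CompositionTimeSeries",
    "ValidationReport",
    "CompositionAtGeneration",
    "CoexistenceExclusion",
    "read_composition_table",
    "write_composition_table",
    "fraction_posterior_sd",
    "composition_at_generation",
    "filter_coexisting",
]

#: Transfers at which community composition was plated in the evolution experiment.
DEFAULT_SAMPLED_TRANSFERS: tuple[int, ...] = (0, 2, 5, 7, 10, 14, 19, 30, 38)

#: Tolerance on the sum of species fractions within one sample.
FRACTION_SUM_TOL = 1e-6

#: Colony totals at or below this trigger a validation warning (plating noise floor).
LOW_COUNT_THRESHOLD = 15

REQUIRED_COLUMNS = ("community", "replicate", "transfer", "species")


@dataclass(frozen=True)
class GenerationMap:
    """Mapping between transfer (cycle) index and bacterial generations.

    Parameters
    ----------
    dilution_factor
        Fold-dilution applied between growth cycles; must exceed 1.  The
        number of doublings needed to regrow the diluted culture is
        ``log2(dilution_factor)``, which is the generations per cycle.
    sampled_transfers
        Transfers at which composition was actually measured.
    """

    dilution_factor: float = 1500.0
    sampled_transfers: tuple[int, ...] = DEFAULT_SAMPLED_TRANSFERS

    def __post_init__(self) -> None:
        if self.dilution_factor <= 1:
            raise ValueError("dilution_factor must be > 1")
        if not self.sampled_transfers or any(t < 0 for t in self.sampled_transfers):
            raise ValueError("sampled_transfers must be non-empty and non-negative")
        object.__setattr__(self, "sampled_transfers", tuple(sorted(self.sampled_transfers)))

    @property
    def generations_per_cycle(self) -> float:
        return math.log2(self.dilution_factor)

    def generation(self, transfer: float) -> float:
        """Cumulative generations elapsed by the given transfer."""
        return transfer * self.generations_per_cycle

    def nearest_transfer(self, generation: float) -> int:
        """Sampled transfer whose generation is closest to ``generation``.

        Ties are broken toward the earlier transfer.
        """
        if generation < 0:
            raise ValueError("generation must be >= 0")
        best_t = self.sampled_transfers[0]
        best_d = abs(self.generation(best_t) - generation)
        for t in self.sampled_transfers[1:]:
            d = abs(self.generation(t) - generation)
            if d < best_d:  # strict: earlier transfer wins ties
                best_t, best_d = t, d
        return best_t


@dataclass
class ValidationReport:
    """Warnings and errors collected while reading a composition table."""

    warnings: list[str] = field(default_factory=list)
    errors: list[str] = field(default_factory=list)
    n_rows: int = 0
    n_samples: int = 0
    n_communities: int = 0

    def warn(self, message: str) -> None:
        self.warnings.append(message)

    def summary(self) -> dict:
        return {
            "n_rows": self.n_rows,
            "n_samples": self.n_samples,
            "n_communities": self.n_communities,
            "n_warnings": len(self.warnings),
            "n_errors": len(self.errors),
            "warnings": list(self.warnings),
            "errors": list(self.errors),
        }

    def to_json(self) -> str:
        return json.dumps(self.summary(), indent=2, sort_keys=True)


class CompositionTimeSeries:
    """Species fractions of one community, per replicate and transfer.

    Parameters
    ----------
    community
        Community identifier.
    species
        Fixed species order used by every fraction vector.
    fractions
        DataFrame indexed by a (replicate, transfer) MultiIndex with one
        column per species; each row sums to 1 within ``FRACTION_SUM_TOL``.
    counts
        Optional colony counts with the same index/columns.
    """

    def __init__(
        self,
        community: str,
        species: Iterable[str],
        fractions: pd.DataFrame,
        counts: pd.DataFrame | None = None,
    ) -> None:
        self.community = str(community)
        self.species = tuple(str(s) for s in species)
        if len(set(self.species)) != len(self.species) or not self.species:
            raise ValueError("species labels must be non-empty and unique")
        fractions = fractions.loc[:, list(self.species)].sort_index()
        sums = fractions.sum(axis=1).to_numpy()
        bad = np.abs(sums - 1.0) > FRACTION_SUM_TOL
        if bad.any():
            idx = fractions.index[bad][0]
            raise DataError(
                f"community {self.community!r}: fractions at sample {idx} sum to "
                f"{sums[bad][0]:.6g}, not 1"
            )
        self.fractions = fractions
        self.counts = counts.loc[:, list(self.species)].sort_index() if counts is not None else None

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def replicates(self) -> tuple[str, ...]:
        return tuple(sorted(self.fractions.index.get_level_values(0).unique()))

    @property
    def transfers(self) -> tuple[int, ...]:
        return tuple(sorted(self.fractions.index.get_level_values(1).unique()))

    def has_sample(self, replicate: str, transfer: int) -> bool:
        return (replicate, transfer) in self.fractions.index

    def sample(self, replicate: str, transfer: int) -> np.ndarray:
        """Fraction vector (species order ``self.species``) of one sample."""
        return self.fractions.loc[(replicate, transfer)].to_numpy(dtype=float)

    def sample_total_count(self, replicate: str, transfer: int) -> int | None:
        if self.counts is None or (replicate, transfer) not in self.counts.index:
            return None
        return int(self.counts.loc[(replicate, transfer)].sum())

    def replicate_transfers(self, replicate: str) -> tuple[int, ...]:
        sub = self.fractions.xs(replicate, level=0, drop_level=True)
        return tuple(sorted(sub.index))

    def __len__(self) -> int:
        return len(self.fractions)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"CompositionTimeSeries({self.community!r}, species={self.species}, "
            f"{len(self.replicates)} replicates, {len(self)} samples)"
        )


def _to_long_frame(series_map: Mapping[str, CompositionTimeSeries]) -> pd.DataFrame:
    rows = []
    for community in sorted(series_map):
        ts = series_map[community]
        for (replicate, transfer) in ts.fractions.index:
            for sp in ts.species:
                count = (
                    ts.counts.loc[(replicate, transfer), sp]
                    if ts.counts is not None and (replicate, transfer) in ts.counts.index
                    else None
                )
                rows.append(
                    {
                        "community": community,
                        "replicate": replicate,
                        "transfer": transfer,
                        "species": sp,
                        "count": count,
                        "fraction": ts.fractions.loc[(replicate, transfer), sp],
                    }
                )
    frame = pd.DataFrame(rows, columns=["community", "replicate", "transfer", "species", "count", "fraction"])
    return frame.sort_values(["community", "replicate", "transfer", "species"], kind="stable").reset_index(drop=True)


def write_composition_table(
    series_map: Mapping[str, CompositionTimeSeries], path, sep: str = ","
) -> None:
    """Write communities back to the long delimited format (deterministic row order)."""
    _to_long_frame(series_map).to_csv(path, sep=sep, index=False)


def read_composition_table(
    path, sep: str = ","
) -> tuple[dict[str, CompositionTimeSeries], ValidationReport]:
    """Read a long-format composition table.

    The table must carry the columns ``community, replicate, transfer, species``
    and at least one of ``count`` / ``fraction``.  Fractions are recomputed from
    counts whenever counts are present (counts win on conflict, with a warning);
    samples with a colony total at or below ``LOW_COUNT_THRESHOLD`` are flagged.

    Returns
    -------
    (series_map, report)
        One :class:`CompositionTimeSeries` per community, plus the validation
        report of warnings accumulated along the way.
    """
    report = ValidationReport()
    try:
        table = pd.read_csv(path, sep=sep)
    except (OSError, pd.errors.ParserError) as exc:
        raise FormatError(f"cannot read composition table {path}: {exc}") from exc

    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"composition table is missing required columns: {missing}")
    has_count = "count" in table.columns and table["count"].notna().any()
    has_fraction = "fraction" in table.columns and table["fraction"].notna().any()
    if not has_count and not has_fraction:
        raise FormatError("composition table needs a 'count' or 'fraction' column with data")

    report.n_rows = len(table)
    table = table.copy()
    table["community"] = table["community"].astype(str)
    table["replicate"] = table["replicate"].astype(str)
    table["species"] = table["species"].astype(str)
    table["transfer"] = table["transfer"].astype(int)
    if (table["transfer"] < 0).any():
        raise DataError("transfer indices must be >= 0")
    if "count" in table.columns and (table["count"].dropna() < 0).any():
        raise DataError("colony counts must be non-negative")

    series_map: dict[str, CompositionTimeSeries] = {}
    for community, sub in table.groupby("community", sort=True):
        species = tuple(sorted(sub["species"].unique()))
        frac_rows: dict[tuple[str, int], np.ndarray] = {}
        count_rows: dict[tuple[str, int], np.ndarray] = {}
        for (replicate, transfer), sample in sub.groupby(["replicate", "transfer"], sort=True):
            sample = sample.set_index("species").reindex(list(species))
            counts = sample["count"].to_numpy(dtype=float) if "count" in sample.columns else np.full(len(species), np.nan)
            fracs = sample["fraction"].to_numpy(dtype=float) if "fraction" in sample.columns else np.full(len(species), np.nan)
            key = (str(replicate), int(transfer))
            if np.isfinite(counts).all():
                total = counts.sum()
                if total <= 0:
                    report.warn(f"{community}/{replicate}@t{transfer}: zero total colony count; sample skipped")
                    continue
                derived = counts / total
                if np.isfinite(fracs).all() and np.max(np.abs(derived - fracs)) > FRACTION_SUM_TOL:
                    report.warn(
                        f"{community}/{replicate}@t{transfer}: fraction column inconsistent with "
                        "counts; counts used"
                    )
                if total <= LOW_COUNT_THRESHOLD:
                    report.warn(
                        f"{community}/{replicate}@t{transfer}: only {int(total)} colonies counted "
                        f"(<= {LOW_COUNT_THRESHOLD})"
                    )
                frac_rows[key] = derived
                count_rows[key] = counts
            else:
                if not np.isfinite(fracs).all():
                    report.warn(f"{community}/{replicate}@t{transfer}: incomplete counts and fractions; sample skipped")
                    continue
                if abs(fracs.sum() - 1.0) > FRACTION_SUM_TOL:
                    raise DataError(
                        f"{community}/{replicate}@t{transfer}: fractions sum to {fracs.sum():.6g}, not 1"
                    )
                frac_rows[key] = fracs

        if not frac_rows:
            report.warn(f"{community}: no valid samples; community skipped")
            continue
        index = pd.MultiIndex.from_tuples(sorted(frac_rows), names=["replicate", "transfer"])
        fractions = pd.DataFrame(
            [frac_rows[k] for k in index], index=index, columns=list(species)
        )
        counts_df = None
        if count_rows and set(count_rows) == set(frac_rows):
            counts_df = pd.DataFrame(
                [count_rows[k] for k in index], index=index, columns=list(species)
            )
        series_map[community] = CompositionTimeSeries(community, species, fractions, counts_df)

    report.n_communities = len(series_map)
    report.n_samples = sum(len(ts) for ts in series_map.values())
    return series_map, report


def fraction_posterior_sd(p, n):
    """Standard deviation of the beta posterior of a plated species fraction.

    With ``p`` the observed fraction and ``n`` the total number of colonies
    counted in the sample, the posterior spread is ``sqrt(p * (1 - p)) / (n + 1)``.
    Vectorised over ``p`` and ``n``.
    """
    p = np.asarray(p, dtype=float)
    n = np.asarray(n)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("fractions must lie in [0, 1]")
    if np.any(np.asarray(n, dtype=float) < 1):
        raise ValueError("total colony count must be >= 1")
    out = np.sqrt(p * (1.0 - p)) / (np.asarray(n, dtype=float) + 1.0)
    return float(out) if out.ndim == 0 else out


@dataclass
class CompositionAtGeneration:
    """Per-replicate compositions resolved at the transfer nearest a target generation."""

    community: str
    target_generation: float
    transfer: int
    generation: float
    fractions: dict[str, np.ndarray]
    missing_replicates: tuple[str, ...] = ()


def composition_at_generation(
    series: CompositionTimeSeries,
    generation: float,
    gmap: GenerationMap | None = None,
) -> CompositionAtGeneration:
    """Resolve a target generation to the nearest plated transfer and collect samples.

    Replicates lacking that transfer are excluded and listed in
    ``missing_replicates``.
    """
    gmap = gmap or GenerationMap()
    transfer = gmap.nearest_transfer(generation)
    fractions: dict[str, np.ndarray] = {}
    missing: list[str] = []
    for rep in series.replicates:
        if series.has_sample(rep, transfer):
            fractions[rep] = series.sample(rep, transfer)
        else:
            missing.append(rep)
    return CompositionAtGeneration(
        community=series.community,
        target_generation=float(generation),
        transfer=transfer,
        generation=gmap.generation(transfer),
        fractions=fractions,
        missing_replicates=tuple(missing),
    )


@dataclass(frozen=True)
class CoexistenceExclusion:
    community: str
    species: str
    transfer: int
    reason: str


def filter_coexisting(
    series_map: Mapping[str, CompositionTimeSeries],
    g_threshold: float = 70.0,
    min_fraction: float | None = None,
    gmap: GenerationMap | None = None,
) -> tuple[dict[str, CompositionTimeSeries], list[CoexistenceExclusion]]:
    """Drop communities in which some species went extinct in every replicate.

    A species counts as extinct in a replicate at the transfer nearest
    ``g_threshold`` when its colony count is 0 (counts available) or its
    fraction falls below the detection floor ``min_fraction`` (fractions only;
    default ``1e-6``).  A community is removed only when a species is extinct
    in *all* replicates that have the sample.
    """
    gmap = gmap or GenerationMap()
    floor = 1e-6 if min_fraction is None else float(min_fraction)
    kept: dict[str, CompositionTimeSeries] = {}
    excluded: list[CoexistenceExclusion] = []
    for community in sorted(series_map):
        ts = series_map[community]
        transfer = gmap.nearest_transfer(g_threshold)
        reps = [r for r in ts.replicates if ts.has_sample(r, transfer)]
        if not reps:
            kept[community] = ts  # cannot assess; retain
            continue
        lost_species = None
        for i, sp in enumerate(ts.species):
            extinct = []
            for rep in reps:
                if ts.counts is not None:
                    extinct.append(ts.counts.loc[(rep, transfer), sp] == 0)
                else:
                    extinct.append(ts.sample(rep, transfer)[i] < floor)
            if all(extinct):
                lost_species = sp
                break
        if lost_species is None:
            kept[community] = ts
        else:
            excluded.append(
                CoexistenceExclusion(
                    community=community,
                    species=lost_species,
                    transfer=transfer,
                    reason=f"species {lost_species!r} extinct in all {len(reps)} replicates at transfer {transfer}",
                )
            )
    return kept, excluded
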