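"""Synthetic serial-dilution communities with the statistical structure the analyses assume.

The latent model is generalized Lotka–Volterra competition integrated within
each 48-h growth cycle,

    dx_i/dt = x_i * r_i * (1 - sum_j a_ij * x_j / K_i),

followed by a 1500-fold dilution.  This produces the two-timescale structure
of the experiment: compositions converge to the ecological cycle-to-cycle
fixed point within the first handful of transfers, after which slow
"evolutionary" drift is modelled phenomenologically — growth rates and
interaction coefficients take small per-cycle steps relaxing toward
community-level attractor values, with replicate-specific deviations whose
scale is controlled by a concentration parameter kappa (large kappa means
replicates drift together, i.e. repeatable evolution).

Observed compositions are multinomial colony counts (default depth uniform on
20–100, honouring the > 15-colony floor of the plating protocol) drawn from
the latent fractions at the sampled transfers.

Two shortcut generators bypass the ODE for fast statistical tests:
:func:`plant_repeatability` synthesizes generation-70/400 fraction pairs with
an exactly known modal-winner probability, and :func:`make_consistent_trio`
builds a trio observation satisfying the assembly rule exactly.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .assembly import PairOutcome, predict_trio_from_pairs
from .errors import ConfigError
from .io_composition import (
    DEFAULT_SAMPLED_TRANSFERS,
    CompositionTimeSeries,
    GenerationMap,
)
from .growth import GrowthCurve

__all__ = [
    "DriftConfig",
    "CommunitySpec",
    "SimulationConfig",
    "GroundTruth",
    "default_config",
    "simulate_serial_dilution",
    "plant_repeatability",
    "make_consistent_trio",
    "simulate_growth_curves",
    "simulate_endpoint_ods",
]

EXTINCTION_FLOOR = 1e-12


@dataclass(frozen=True)
class DriftConfig:
    """Phenomenological evolution acting on gLV parameters.

    onset_transfer
        First transfer after which parameters start drifting (default 7,
        ~74 generations — the end of the ecological transient).
    attractor_scale
        SD of the community-level log-space displacement each parameter
        relaxes toward over the course of the experiment.
    attractor_bias
        Mean of the log displacement of growth rates (positive: most strains
        get faster, as adaptation to the medium would produce).
    community_scale
        SD of the community-level deviation from the species-level
        displacement.  Adaptation is drawn once per species (growth rates)
        and once per ordered species pair (interactions) and shared by every
        community containing them, so compositional changes in pairs and
        trios are mechanistically coupled; this parameter controls how much
        each community departs from that shared course.
    kappa
        Replicate-attractor concentration; replicate-specific attractor
        offsets have SD ``attractor_scale / kappa``.  Large kappa makes
        evolution repeatable across replicates.
    relaxation
        Per-cycle fractional relaxation toward the attractor.
    step_sd
        SD of the additional unbiased per-cycle log-space noise step.
    """

    onset_transfer: int = 7
    attractor_scale: float = 0.4
    attractor_bias: float = 0.25
    community_scale: float = 0.1
    kappa: float = 4.0
    relaxation: float = 0.1
    step_sd: float = 0.03
    enabled: bool = True


@dataclass(frozen=True)
class CommunitySpec:
    name: str
    species: tuple[str, ...]
    n_replicates: int


@dataclass
class SimulationConfig:
    """Full description of one synthetic evolution experiment."""

    species_pool: tuple[str, ...]
    communities: list[CommunitySpec]
    r: dict[str, float]
    K: dict[str, float]
    interactions: dict[tuple[str, str], float]
    cycles: int = 38
    hours_per_cycle: float = 48.0
    dilution_factor: float = 1500.0
    sampled_transfers: tuple[int, ...] = DEFAULT_SAMPLED_TRANSFERS
    drift: DriftConfig = field(default_factory=DriftConfig)
    sampling_depth: tuple[int, int] | None = (20, 100)
    initial_od: float = 1e-4
    rtol: float = 1e-8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dilution_factor <= 1:
            raise ConfigError("dilution_factor must be > 1")
        if any(v <= 0 for v in self.r.values()) or any(v <= 0 for v in self.K.values()):
            raise ConfigError("growth rates and carrying capacities must be positive")
        for spec in self.communities:
            if spec.n_replicates < 3:
                raise ConfigError(f"community {spec.name!r}: replicate counts must be >= 3")
            if not set(spec.species) <= set(self.species_pool):
                raise ConfigError(f"community {spec.name!r}: species outside the pool")
        if self.sampling_depth is not None:
            lo, hi = self.sampling_depth
            if lo <= 15 or hi < lo:
                raise ConfigError("sampling depth minimum must exceed 15 colonies")
        if max(self.sampled_transfers) > self.cycles:
            raise ConfigError("sampled transfers exceed the number of cycles")

    @property
    def generation_map(self) -> GenerationMap:
        return GenerationMap(self.dilution_factor, self.sampled_transfers)


@dataclass
class GroundTruth:
    """Noise-free truth underlying a simulated dataset."""

    latent_fractions: dict[str, dict[str, dict[int, np.ndarray]]]
    planted_winner: dict[str, str]
    winner_probability: dict[str, float]
    true_r: dict[str, float]
    true_K: dict[str, float]


def default_config(
    seed: int = 0,
    n_pairs: int = 44,
    n_trios: int = 43,
    pair_replicates: int = 6,
    trio_replicates: int = 4,
    cycles: int = 38,
    kappa: float = 4.0,
    sampling_depth: tuple[int, int] | None = (20, 100),
) -> SimulationConfig:
    """Default study design: a 16-species pool assembled into pairs and trios.

    Communities are drawn from a 10-species clique so that every trio's three
    constituent pairs are themselves part of the design, mirroring the
    experiment's construction of trios from coexisting, measured pairs.
    Ancestral interaction coefficients are drawn to guarantee stable pairwise
    coexistence (a_ij K_j / K_i < 1 both ways).
    """
    rng = np.random.default_rng(seed)
    sampled = tuple(t for t in DEFAULT_SAMPLED_TRANSFERS if t <= cycles)
    pool = tuple(f"sp{i + 1:02d}" for i in range(16))
    r = {sp: float(rng.uniform(0.25, 0.5)) for sp in pool}
    K = {sp: float(rng.uniform(0.3, 0.9)) for sp in pool}

    clique = pool[:10]
    all_pairs = list(itertools.combinations(clique, 2))  # 45
    dropped_pair = all_pairs[-1]
    pairs = [p for p in all_pairs if p != dropped_pair][:n_pairs]
    pair_set = set(pairs)
    trio_candidates = [
        t
        for t in itertools.combinations(clique, 3)
        if all(p in pair_set for p in itertools.combinations(t, 2))
    ]
    trio_idx = rng.choice(len(trio_candidates), size=min(n_trios, len(trio_candidates)), replace=False)
    trios = [trio_candidates[i] for i in sorted(trio_idx)]

    interactions: dict[tuple[str, str], float] = {}
    for i, j in itertools.permutations(pool, 2):
        # scaled competition coefficient < 1 ensures ancestral pair coexistence
        c = rng.uniform(0.25, 0.9)
        interactions[(i, j)] = float(c * K[i] / K[j])

    communities = [
        CommunitySpec(name="-".join(p), species=p, n_replicates=pair_replicates) for p in pairs
    ] + [CommunitySpec(name="-".join(t), species=t, n_replicates=trio_replicates) for t in trios]
    return SimulationConfig(
        species_pool=pool,
        communities=communities,
        r=r,
        K=K,
        interactions=interactions,
        cycles=cycles,
        sampled_transfers=sampled,
        drift=DriftConfig(kappa=kappa),
        sampling_depth=sampling_depth,
        seed=seed,
    )


def _grow_cycle(
    x: np.ndarray,
    r: np.ndarray,
    K: np.ndarray,
    A: np.ndarray,
    hours: float,
    rtol: float,
) -> np.ndarray:
    """Integrate gLV for all replicates of one community over one growth cycle.

    ``x, r, K`` have shape (R, n); ``A`` has shape (R, n, n).
    """
    R, n = x.shape

    def rhs(_t, y):
        X = y.reshape(R, n)
        comp = np.einsum("rij,rj->ri", A, X)
        return (X * r * (1.0 - comp / K)).ravel()

    sol = solve_ivp(
        rhs, (0.0, hours), x.ravel(), method="RK45", rtol=rtol, atol=1e-12
    )
    if not sol.success:  # pragma: no cover - defensive
        raise RuntimeError(f"gLV integration failed: {sol.message}")
    out = sol.y[:, -1].reshape(R, n)
    out[out < EXTINCTION_FLOOR] = 0.0
    return out


def simulate_serial_dilution(
    config: SimulationConfig,
) -> tuple[dict[str, CompositionTimeSeries], GroundTruth]:
    """Run the growth–dilution experiment for every community in the config.

    Returns the observed composition time series (multinomial colony counts at
    the sampled transfers, or the latent fractions themselves when
    ``config.sampling_depth`` is None) together with the ground truth.
    """
    master = np.random.SeedSequence(config.seed)
    streams = master.spawn(len(config.communities))
    sampled = set(config.sampled_transfers)
    drift = config.drift

    # species- and pair-level adaptation shared across communities: the same
    # strain drifts the same way wherever it evolves, so pair changes inform
    # trio changes
    adapt_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    pool = tuple(config.species_pool)
    species_dr = {sp: adapt_rng.normal(drift.attractor_bias, drift.attractor_scale) for sp in pool}
    pair_dA = {
        (i, j): adapt_rng.normal(0.0, drift.attractor_scale)
        for i in pool
        for j in pool
        if i != j
    }

    series_map: dict[str, CompositionTimeSeries] = {}
    latent_all: dict[str, dict[str, dict[int, np.ndarray]]] = {}
    planted_winner: dict[str, str] = {}
    winner_prob: dict[str, float] = {}

    for spec, stream in zip(config.communities, streams):
        rng = np.random.default_rng(stream)
        species = tuple(spec.species)
        n = len(species)
        R = spec.n_replicates
        reps = [f"r{k + 1:02d}" for k in range(R)]

        log_r = np.log(np.array([[config.r[s] for s in species]] * R))
        K = np.array([[config.K[s] for s in species]] * R)
        # log-space parameters; a zero interaction maps to -inf and stays zero
        log_A = np.zeros((R, n, n))
        for a in range(n):
            for b in range(n):
                if a != b:
                    value = config.interactions[(species[a], species[b])]
                    log_A[:, a, b] = math.log(value) if value > 0 else -math.inf

        # community-level attractors (shared adaptation + community deviation)
        # with replicate-specific offsets
        if drift.enabled:
            comm_dr = np.array([species_dr[s] for s in species]) + rng.normal(
                0.0, drift.community_scale, size=n
            )
            comm_dA = np.array(
                [
                    [0.0 if a == b else pair_dA[(species[a], species[b])] for b in range(n)]
                    for a in range(n)
                ]
            ) + rng.normal(0.0, drift.community_scale, size=(n, n))
            np.fill_diagonal(comm_dA, 0.0)
            rep_dr = comm_dr + rng.normal(0.0, drift.attractor_scale / drift.kappa, size=(R, n))
            rep_dA = comm_dA + rng.normal(
                0.0, drift.attractor_scale / drift.kappa, size=(R, n, n)
            )
            for k in range(R):
                np.fill_diagonal(rep_dA[k], 0.0)
            target_log_r = log_r + rep_dr
            target_log_A = log_A + rep_dA
            planted_winner[spec.name] = species[int(np.argmax(comm_dr))]
            winner_prob[spec.name] = float("nan")

        x = np.full((R, n), config.initial_od / n)
        latent: dict[str, dict[int, np.ndarray]] = {rep: {} for rep in reps}

        def record(transfer: int, x_now: np.ndarray) -> None:
            for k, rep in enumerate(reps):
                total = x_now[k].sum()
                frac = x_now[k] / total if total > 0 else np.full(n, 1.0 / n)
                latent[rep][transfer] = frac

        if 0 in sampled:
            record(0, x)
        for cycle in range(1, config.cycles + 1):
            x = _grow_cycle(
                x, np.exp(log_r), K, np.exp(log_A), config.hours_per_cycle, config.rtol
            )
            if cycle in sampled:
                record(cycle, x)
            x = x / config.dilution_factor
            x[x < EXTINCTION_FLOOR] = 0.0
            if drift.enabled and cycle >= drift.onset_transfer:
                log_r += drift.relaxation * (target_log_r - log_r) + rng.normal(
                    0.0, drift.step_sd, size=log_r.shape
                )
                step_A = drift.relaxation * (target_log_A - log_A) + rng.normal(
                    0.0, drift.step_sd, size=log_A.shape
                )
                drifting = np.isfinite(log_A) & ~np.eye(n, dtype=bool)
                log_A[drifting] += step_A[drifting]

        # observation: multinomial colony counts at the sampled transfers
        frac_rows: dict[tuple[str, int], np.ndarray] = {}
        count_rows: dict[tuple[str, int], np.ndarray] = {}
        for rep in reps:
            for transfer, frac in latent[rep].items():
                if config.sampling_depth is None:
                    frac_rows[(rep, transfer)] = frac
                else:
                    lo, hi = config.sampling_depth
                    depth = int(rng.integers(lo, hi + 1))
                    counts = rng.multinomial(depth, frac / frac.sum())
                    count_rows[(rep, transfer)] = counts.astype(float)
                    frac_rows[(rep, transfer)] = counts / depth

        index = pd.MultiIndex.from_tuples(sorted(frac_rows), names=["replicate", "transfer"])
        fractions = pd.DataFrame([frac_rows[k] for k in index], index=index, columns=list(species))
        counts_df = (
            pd.DataFrame([count_rows[k] for k in index], index=index, columns=list(species))
            if count_rows
            else None
        )
        series_map[spec.name] = CompositionTimeSeries(spec.name, species, fractions, counts_df)
        latent_all[spec.name] = latent

    truth = GroundTruth(
        latent_fractions=latent_all,
        planted_winner=planted_winner,
        winner_probability=winner_prob,
        true_r=dict(config.r),
        true_K=dict(config.K),
    )
    return series_map, truth


def plant_repeatability(
    n_communities: int,
    n_species: int,
    n_replicates: int,
    q: float,
    seed: int | np.random.Generator | None = None,
    transfers: tuple[int, int] = (7, 38),
    prefix: str = "planted",
) -> tuple[dict[str, CompositionTimeSeries], GroundTruth]:
    """Synthesize generation-70/400 composition pairs with known modal structure.

    For each community one species is planted as the modal winner; every
    replicate's maximally increasing member is the planted species with
    probability exactly ``q`` and any other species with probability
    ``(1 - q) / (n - 1)``.  Fractions at the first transfer are flat-Dirichlet;
    fold factors with disjoint log-ranges then guarantee the drawn winner is
    the strict max-increaser.  The ODE model is bypassed entirely.
    """
    if not (1.0 / n_species <= q <= 1.0):
        raise ValueError(f"q must lie in [1/{n_species}, 1]")
    if n_replicates < 1 or n_communities < 1:
        raise ValueError("need at least one community and replicate")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t1, t2 = transfers

    series_map: dict[str, CompositionTimeSeries] = {}
    latent_all: dict[str, dict[str, dict[int, np.ndarray]]] = {}
    planted: dict[str, str] = {}
    species = tuple(chr(ord("A") + i) for i in range(n_species))
    probs_template = np.full(n_species, 0.0)
    for c in range(n_communities):
        name = f"{prefix}{c + 1:03d}"
        w = int(rng.integers(n_species))
        planted[name] = species[w]
        probs = probs_template.copy()
        probs[:] = (1.0 - q) / (n_species - 1) if n_species > 1 else 0.0
        probs[w] = q
        frac_rows: dict[tuple[str, int], np.ndarray] = {}
        latent: dict[str, dict[int, np.ndarray]] = {}
        for k in range(n_replicates):
            rep = f"r{k + 1:02d}"
            winner = int(rng.choice(n_species, p=probs))
            f1 = rng.dirichlet(np.ones(n_species))
            lam = np.exp(rng.uniform(-1.2, -0.6, size=n_species))
            lam[winner] = math.exp(rng.uniform(0.6, 1.2))
            f2 = f1 * lam
            f2 = f2 / f2.sum()
            frac_rows[(rep, t1)] = f1
            frac_rows[(rep, t2)] = f2
            latent[rep] = {t1: f1, t2: f2}
        index = pd.MultiIndex.from_tuples(sorted(frac_rows), names=["replicate", "transfer"])
        fractions = pd.DataFrame([frac_rows[k] for k in index], index=index, columns=list(species))
        series_map[name] = CompositionTimeSeries(name, species, fractions)
        latent_all[name] = latent

    truth = GroundTruth(
        latent_fractions=latent_all,
        planted_winner=planted,
        winner_probability={name: q for name in planted},
        true_r={},
        true_K={},
    )
    return series_map, truth


def make_consistent_trio(pairs: Sequence[PairOutcome], floor: float = 1e-3) -> np.ndarray:
    """Trio observation that satisfies the assembly rule exactly.

    Returns the geometric-mean prediction of the three pairwise outcomes
    verbatim, so ``prediction_accuracy(prediction, observation)`` is 1.
    """
    return predict_trio_from_pairs(pairs, floor=floor).predicted.copy()


def lagged_logistic_od(
    t_h: np.ndarray,
    lag_h: float,
    doubling_h: float,
    K: float,
    od0: float = 1e-4,
) -> np.ndarray:
    """Noise-free lagged logistic growth curve.

    Flat at ``od0`` until ``lag_h``, then logistic growth with the given
    doubling time saturating at ``K``.
    """
    t_eff = np.maximum(0.0, np.asarray(t_h, dtype=float) - lag_h)
    return K / (1.0 + (K / od0 - 1.0) * np.power(2.0, -t_eff / doubling_h))


def simulate_growth_curves(
    species_params: Mapping[str, Mapping[str, float]],
    n_evo_replicates: int = 2,
    n_tech_replicates: int = 4,
    noise_sd: float = 0.003,
    dt_min: float = 10.0,
    t_max_h: float = 48.0,
    od0: float = 1e-4,
    evo_jitter: float = 0.05,
    seed: int | np.random.Generator | None = None,
) -> list[GrowthCurve]:
    """Plate-reader growth curves from lagged-logistic ground truth.

    ``species_params`` maps species -> ``{"lag": h, "doubling": h, "K": OD}``.
    Each evolutionary replicate gets small multiplicative parameter jitter;
    each technical replicate adds iid Gaussian OD noise truncated at 0,
    sampled every ``dt_min`` minutes.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = np.arange(0.0, t_max_h + 1e-9, dt_min / 60.0)
    curves: list[GrowthCurve] = []
    for sp in sorted(species_params):
        p = species_params[sp]
        if p["K"] <= od0:
            raise ConfigError(f"species {sp!r}: K must exceed the initial OD")
        for e in range(n_evo_replicates):
            lag = p["lag"] * math.exp(rng.normal(0.0, evo_jitter))
            doubling = p["doubling"] * math.exp(rng.normal(0.0, evo_jitter))
            K = p["K"] * math.exp(rng.normal(0.0, evo_jitter))
            clean = lagged_logistic_od(t, lag, doubling, K, od0)
            for tech in range(n_tech_replicates):
                od = clean + rng.normal(0.0, noise_sd, size=t.size)
                np.maximum(od, 0.0, out=od)
                curves.append(
                    GrowthCurve(
                        well=f"{sp}-e{e + 1}-t{tech + 1}",
                        species=sp,
                        evo_replicate=f"e{e + 1}",
                        tech_replicate=f"t{tech + 1}",
                        time_h=t,
                        od=od,
                    )
                )
    return curves


def simulate_endpoint_ods(
    species_K: Mapping[str, float],
    n_replicates: int = 3,
    cycles: int = 38,
    noise_sd: float = 0.02,
    seed: int | np.random.Generator | None = None,
) -> dict[str, dict[str, np.ndarray]]:
    """Monoculture end-of-cycle OD trajectories around each species' true K."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out: dict[str, dict[str, np.ndarray]] = {}
    for sp in sorted(species_K):
        K = species_K[sp]
        out[sp] = {
            f"r{k + 1:02d}": np.maximum(
                0.0, K + rng.normal(0.0, noise_sd, size=cycles)
            )
            for k in range(n_replicates)
        }
    return out
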