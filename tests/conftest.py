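"""Shared fixtures: small hand-built composition series and tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from evoassembly.io_composition import CompositionTimeSeries

settings.register_profile("default", deadline=None, derandomize=True)
settings.load_profile("default")


def build_series(
    community: str,
    species: tuple[str, ...],
    samples: dict[tuple[str, int], tuple[float, ...]],
    counts: dict[tuple[str, int], tuple[float, ...]] | None = None,
) -> CompositionTimeSeries:
    """Construct a CompositionTimeSeries from explicit (replicate, transfer) -> fractions."""
    index = pd.MultiIndex.from_tuples(sorted(samples), names=["replicate", "transfer"])
    fractions = pd.DataFrame([samples[k] for k in index], index=index, columns=list(species))
    counts_df = None
    if counts is not None:
        counts_df = pd.DataFrame([counts[k] for k in index], index=index, columns=list(species))
    return CompositionTimeSeries(community, species, fractions, counts_df)


@pytest.fixture
def pair_series() -> CompositionTimeSeries:
    """One pair, two replicates, three transfers, drifting apart late."""
    return build_series(
        "A-B",
        ("A", "B"),
        {
            ("r1", 0): (0.5, 0.5),
            ("r1", 7): (0.6, 0.4),
            ("r1", 38): (0.1, 0.9),
            ("r2", 0): (0.5, 0.5),
            ("r2", 7): (0.6, 0.4),
            ("r2", 38): (0.8, 0.2),
        },
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)
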