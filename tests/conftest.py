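"""Shared fixtures: tiny genomes, origin layouts and fragment factories.

All fixture data is generated programmatically; no files are shipped.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from replifork import CRICK, WATSON, Genome, Origin
from replifork.simulate import SPhaseModel


@pytest.fixture
def genome() -> Genome:
    return Genome({"chrI": 100_000, "chrII": 200_000})


@pytest.fixture
def single_origin_genome() -> Genome:
    return Genome({"chrI": 100_000})


@pytest.fixture
def single_origin() -> Origin:
    return Origin("chrI", 49_900, 50_100, "ori1")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


def make_fragments(rng: np.random.Generator, genome: Genome, n: int,
                   length: int = 165) -> pd.DataFrame:
    """Uniform random fragments with random strands across the genome."""
    chroms = rng.choice(genome.names, n)
    lengths = np.array([genome[c] for c in chroms])
    starts = (rng.random(n) * (lengths - length)).astype(np.int64)
    strands = np.where(rng.random(n) < 0.5, WATSON, CRICK)
    return pd.DataFrame(
        {"chrom": chroms, "start": starts, "end": starts + length, "strand": strands}
    )


@pytest.fixture
def random_fragments(rng, genome) -> pd.DataFrame:
    return make_fragments(rng, genome, 1000)


def simple_model(n_origins: int = 1, **overrides) -> SPhaseModel:
    """Deterministic always-firing model; override freely."""
    params = dict(
        competence=np.ones(n_origins),
        firing_mean=np.zeros(n_origins),
        firing_sd=np.zeros(n_origins),
        fork_speed=1000.0,
    )
    params.update(overrides)
    return SPhaseModel(**params)
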