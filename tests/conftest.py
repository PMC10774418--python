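from __future__ import annotations

import numpy as np
import pytest

from polyescan import ProteomeSpec, composition, fixed_sampler, gen_proteome


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240109)


@pytest.fixture
def small_proteome():
    """50 background-only sequences (E at 7%), deterministic."""
    spec = ProteomeSpec(
        n_sequences=50,
        length_sampler=fixed_sampler(200),
        composition=composition({"E": 0.07}),
        seed=1234,
    )
    records, truth = gen_proteome(spec)
    return records, truth


@pytest.fixture
def planted_proteome():
    """100 sequences, 5 carrying a planted 9-E run, zero background E."""
    spec = ProteomeSpec(
        n_sequences=100,
        length_sampler=fixed_sampler(120),
        composition=composition({"E": 0.0}),
        planted_runs=[("E", 9, 5)],
        seed=77,
    )
    records, truth = gen_proteome(spec)
    return records, truth
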