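"""Shared fixtures: small simulated protocols and hand-built count tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from aptaselex import (CycleLibrary, FrequencyMatrix, CycleSpec, SimConfig,
                       frequencies, recovery_config, run_protocol)


@pytest.fixture(scope="session")
def small_sim():
    """A scaled-down toggle protocol with planted families (fast, seeded)."""
    cfg = recovery_config(seed=11, n_background=3000, depth=30_000,
                          pool_size=3_000_000)
    libs, truth = run_protocol(cfg)
    return cfg, libs, truth


@pytest.fixture(scope="session")
def small_matrix(small_sim) -> FrequencyMatrix:
    _, libs, _ = small_sim
    return frequencies(libs)


def make_matrix(table: dict[str, dict[str, int]],
                extracted: dict[str, int] | None = None) -> FrequencyMatrix:
    """Build a FrequencyMatrix from {cycle: {sequence: count}} by hand."""
    libs = []
    for cycle, counts in table.items():
        total = extracted[cycle] if extracted else sum(counts.values())
        libs.append(CycleLibrary(cycle_id=cycle, counts=dict(counts),
                                 total_reads=total,
                                 extracted_reads=sum(counts.values())))
    return frequencies(libs)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
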