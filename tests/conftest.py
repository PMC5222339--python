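"""Shared fixtures: tiny hand-built tables and seeded simulated datasets."""

from __future__ import annotations

import numpy as np
import pytest

from clonestruct import (GenotypeTable, LocusDef, SampleUnit,
                         SimulationConfig, simulate_dataset)


@pytest.fixture
def two_locus_panel() -> list[LocusDef]:
    return [LocusDef("LocA", motif_length=2), LocusDef("LocB", motif_length=3)]


@pytest.fixture
def small_table(two_locus_panel) -> GenotypeTable:
    """Five samples at two loci; two samples carry a missing call."""
    rows = [
        ("s1", "P1", ((100, 102), (200, 200))),
        ("s2", "P1", ((100, 102), (200, 200))),
        ("s3", "P1", (None, (200, 203))),
        ("s4", "P2", ((100, 100), (200, 206))),
        ("s5", "P2", ((102, 104), None)),
    ]
    return GenotypeTable(
        loci=two_locus_panel,
        samples=[SampleUnit(id=i, site=p, genotype=g) for i, p, g in rows],
    )


@pytest.fixture(scope="session")
def default_sim():
    """One default simulated dataset (fixed seed) shared across tests."""
    cfg = SimulationConfig(seed=20_240_901)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def clean_sim():
    """Default simulation without somatic mutation or missing data."""
    cfg = SimulationConfig(seed=20_240_902, somatic_mu=0.0,
                           missing_rate=0.0)
    return simulate_dataset(cfg)


def make_population(freqs, n, f_is, seed, loci, site="P1", prefix="x"):
    """Small helper: a single-site table of sexual genotypes."""
    from clonestruct import simulate_genets

    rng = np.random.default_rng(seed)
    genotypes = simulate_genets(freqs, n, f_is, rng, loci)
    return GenotypeTable(
        loci=loci,
        samples=[SampleUnit(id=f"{prefix}{i}", site=site, genotype=g)
                 for i, g in enumerate(genotypes)],
    )
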