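"""Shared fixtures: small synthetic studies reused across test modules."""
from __future__ import annotations

import pytest

from pangenefam import SimConfig, generate_all
from pangenefam.synthetic import SyntheticPangenome


@pytest.fixture(scope="session")
def small_sim() -> SyntheticPangenome:
    """A 6-genome study small enough for every downstream stage."""
    cfg = SimConfig(
        n_genomes=6,
        genes_per_genome=60,
        class_mix={"core": 0.4, "softcore": 0.0, "dispensable": 0.35, "private": 0.25},
        tandem_rate=0.05,
        truncation_rate=0.25,
        n_variants=400,
        seed=42,
    )
    return generate_all(cfg)


@pytest.fixture(scope="session")
def softcore_sim() -> SyntheticPangenome:
    """A 12-genome study where every occupancy class is feasible."""
    cfg = SimConfig(n_genomes=12, genes_per_genome=120, seed=7)
    return generate_all(cfg)
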