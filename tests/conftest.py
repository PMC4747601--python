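"""Shared fixtures: a small ground-truthed community reused across tests."""

from __future__ import annotations

import numpy as np
import pytest

from panrecruit import GeneSequence, SimulationConfig, build_pangenomes, mutate_strain
from panrecruit.simulate import (
    simulate_host_genome,
    simulate_reads,
    simulate_reference_genes,
    species_ids,
)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        n_species=3,
        genes_per_species=6,
        strain_divergence=(0.04, 0.08, 0.12),
        n_read_pairs=2000,
        host_genome_length=30_000,
        seed=101,
    )


@pytest.fixture(scope="session")
def small_community(small_config):
    """(config, refs, strains, host, reads, truth) for a 3-species run."""
    cfg = small_config
    refs = simulate_reference_genes(cfg)
    strains = {
        sp: mutate_strain(refs[sp], cfg.divergences[i], seed=[cfg.seed, 21, i])
        for i, sp in enumerate(species_ids(cfg.n_species))
    }
    host = simulate_host_genome(cfg.host_genome_length, seed=[cfg.seed, 2])
    reads, truth = simulate_reads(cfg, strains, host)
    return cfg, refs, strains, host, reads, truth


@pytest.fixture(scope="session")
def small_pangenomes(small_community):
    """Pan-genomes built from the reference plus a 5%-diverged second strain."""
    cfg, refs, _, _, _, _ = small_community
    genes = []
    for i, sp in enumerate(species_ids(cfg.n_species)):
        for gid, seq in sorted(refs[sp].items()):
            genes.append(GeneSequence(gid, sp, "ref", seq))
        db = mutate_strain(refs[sp], 0.05, seed=[cfg.seed, 20, i])
        for gid, seq in sorted(db.items()):
            genes.append(GeneSequence(f"{gid}_b1", sp, "db1", seq))
    return build_pangenomes(genes)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
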