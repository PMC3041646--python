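"""Shared fixtures: small handcrafted gene models and simulated datasets."""

from __future__ import annotations

import numpy as np
import pytest

from ticfinder.genome_model import GeneModel, Transcript
from ticfinder.simulate import SimulationConfig, generate_dataset, generate_genome


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def two_plus_genes(gap: int = 5_000, seed: int = 7):
    """Two plus-strand 3-exon genes separated by ``gap`` bp of intergenic
    sequence, on one chromosome."""
    rng = np.random.default_rng(seed)

    def gene(gene_id, acc, offset):
        exons = []
        pos = offset
        for elen, ilen in ((120, 300), (100, 250), (110, 0)):
            exons.append((pos, pos + elen))
            pos += elen + ilen
        return Transcript(acc, gene_id, "chr1", "+", exons, coding_flag=True), pos

    tA, endA = gene("GA", "NM_A", 100)
    tB, endB = gene("GB", "NM_B", endA + gap)
    genome = {"chr1": random_seq(rng, endB + 200)}
    return GeneModel([tA, tB], genome)


@pytest.fixture(scope="session")
def toy_model():
    return two_plus_genes()


@pytest.fixture(scope="session")
def sim_small():
    """A small seeded dataset with planted readthroughs and a decoy pair."""
    cfg = SimulationConfig(
        seed=11,
        n_genes=24,
        n_tic=3,
        n_decoy_pairs=1,
        total_reads=30_000,
        expression_sigma=0.8,
    )
    sim = generate_genome(cfg)
    return sim


@pytest.fixture(scope="session")
def sim_reads_small():
    cfg = SimulationConfig(
        seed=11,
        n_genes=24,
        n_tic=3,
        n_decoy_pairs=1,
        total_reads=30_000,
        expression_sigma=0.8,
    )
    return generate_dataset(cfg)
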