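from __future__ import annotations

import pandas as pd
import pytest

from hetscape.genome_io import (
    GeneAnnotation,
    GenomeModel,
    GenomicInterval,
    IntervalSet,
)
from hetscape.synthetic import SimulationConfig, simulate


def random_intervals(rng, genome, n, max_len=2000, chrom=None):
    ivals = []
    for _ in range(n):
        c = chrom or genome.chrom_names[rng.integers(len(genome.chrom_names))]
        clen = genome.length(c)
        length = int(rng.integers(1, max_len))
        start = int(rng.integers(0, max(1, clen - length)))
        ivals.append(GenomicInterval(c, start, start + length))
    return IntervalSet(ivals, genome)


def random_annotation(rng, genome, n_genes, promoter_window=(2000, 500)):
    rows = []
    for i in range(n_genes):
        c = genome.chrom_names[rng.integers(len(genome.chrom_names))]
        clen = genome.length(c)
        length = int(rng.integers(500, 5000))
        start = int(rng.integers(0, max(1, clen - length)))
        strand = "+" if rng.random() < 0.5 else "-"
        rows.append((f"G{i:04d}", c, strand, start, start + length))
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "start", "end"])
    return GeneAnnotation(df, promoter_window, genome)


@pytest.fixture
def small_genome():
    return GenomeModel([("chrA", 100_000), ("chrB", 60_000)])


def small_sim_config(seed=0, **overrides) -> SimulationConfig:
    """A scaled-down landscape for fast module tests."""
    defaults = dict(
        seed=seed,
        n_planted_locks=5,
        lock_chrom_length=5_000_000,
        lock_genes_per_domain=5,
        background_genes=50,
        filler_genes=500,
        filler_chrom_length=2_000_000,
        site_genes=300,
        site_chrom_length=6_000_000,
        n_sites={"day0": 200, "day1": 200, "day2": 600},
        enhancer_state_design={"active": 50, "primed": 50, "intermediate": 50, "poised": 50},
        enhancer_chrom_length=6_200_000,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def default_truth():
    """One full-size landscape shared across tests (read-only)."""
    return simulate(SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def small_truth():
    return simulate(small_sim_config(seed=7))
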