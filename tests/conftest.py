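from __future__ import annotations

import numpy as np
import pytest

from gametephase.datatypes import GT_MISSING, GenotypeMatrix, SnpPanel
from gametephase.simulate import SimConfig, simulate_all


def make_panel(n_loci: int, chrom: str = "chr1", spacing: int = 100,
               start: int = 50) -> SnpPanel:
    pos = start + spacing * np.arange(n_loci)
    ref = np.full(n_loci, "A")
    alt = np.full(n_loci, "C")
    return SnpPanel([chrom], np.zeros(n_loci, np.int32), pos, ref, alt)


def make_matrix(rows, panel: SnpPanel | None = None, spacing: int = 100,
                ) -> GenotypeMatrix:
    """Build a GenotypeMatrix from a list of genotype rows (0/1/-1)."""
    data = np.asarray(rows, dtype=np.int8)
    if panel is None:
        panel = make_panel(data.shape[1], spacing=spacing)
    n = data.shape[0]
    called = (data != GT_MISSING).sum(axis=1)
    return GenotypeMatrix([f"cell{i:03d}" for i in range(n)], panel, data,
                          called, np.zeros(n, np.int64), np.zeros(n, np.int64))


@pytest.fixture(scope="session")
def tiny_sim():
    """Small error-free simulation shared by several tests."""
    cfg = SimConfig(n_chromosomes=1, chrom_length=100_000, snp_rate=0.002,
                    n_cells=6, crossover_lambda=1.0, genotype_error=0.0,
                    missing_rate_target=0.0, mean_depth=3.0, seed=11)
    truth, matrix, reads = simulate_all(cfg)
    return cfg, truth, matrix, reads


@pytest.fixture(scope="session")
def default_sim():
    """Noisy default-parameter simulation, genotypes only (shared: expensive)."""
    from gametephase.simulate import (simulate_cell_observations,
                                      simulate_diploid_genome, simulate_meiosis)
    cfg = SimConfig(n_chromosomes=2, chrom_length=1_000_000, snp_rate=0.002,
                    n_cells=30, crossover_lambda=2.0, genotype_error=0.01,
                    missing_rate_target=0.40, seed=7)
    truth = simulate_meiosis(simulate_diploid_genome(cfg))
    matrix = simulate_cell_observations(truth)
    return cfg, truth, matrix


@pytest.fixture(scope="session")
def reads_sim():
    """Noisy simulation with reads, scaled to 300 kb chromosomes so the
    read-level stages stay fast."""
    cfg = SimConfig(n_chromosomes=2, chrom_length=300_000, snp_rate=0.002,
                    n_cells=30, crossover_lambda=2.0, genotype_error=0.01,
                    missing_rate_target=0.40, mean_depth=2.0, seed=7)
    truth, matrix, reads = simulate_all(cfg)
    return cfg, truth, matrix, reads
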