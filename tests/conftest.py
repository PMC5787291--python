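import numpy as np
import pytest

from nucdyn.synthetic_data import (SimulationConfig, simulate_genome,
                                   simulate_tracks, simulate_counts)


@pytest.fixture(scope="session")
def small_study():
    """Zero-noise study with planted shifts: genome, genes, tracks, manifest."""
    cfg = SimulationConfig(n_genes=60, seed=101, n_shift=20, poisson=False)
    genome, genes, manifest = simulate_genome(cfg)
    control, treated, manifest = simulate_tracks(genes, cfg, manifest)
    return cfg, genome, genes, control, treated, manifest


@pytest.fixture(scope="session")
def typeII_study():
    """Zero-noise cohort of type II genes only (full -1 nucleosomes)."""
    cfg = SimulationConfig(n_genes=100, seed=102, frac_typeI=0.0, poisson=False)
    genome, genes, manifest = simulate_genome(cfg)
    control, treated, manifest = simulate_tracks(genes, cfg, manifest)
    return cfg, genome, genes, control, treated, manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(20240101)
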