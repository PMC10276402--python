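import numpy as np
import pytest

from burstkit.distributions import BurstParams, ConversionRates, UracilDistribution
from burstkit.likelihoods import CellObservation, GeneObservations
from burstkit.simulator import SeqNoiseConfig, simulate_gene_dataset


@pytest.fixture(scope="session")
def fig9_params() -> BurstParams:
    """a=2, b=25, delta=0.001 — the schematic's technical parameter point."""
    return BurstParams.from_burst(b=25.0, kappa=0.002, delta=0.001)


@pytest.fixture(scope="session")
def sim_params() -> BurstParams:
    """a=0.5, b=50, delta=0.001 — the printed bursty-expression constants."""
    return BurstParams.from_burst(b=50.0, kappa=0.0005, delta=0.001)


@pytest.fixture(scope="session")
def rates1000() -> ConversionRates:
    return ConversionRates(lambda_s=0.01, lambda_n=0.075, t=1000.0)


@pytest.fixture(scope="session")
def udist60() -> UracilDistribution:
    return UracilDistribution.from_poisson(60.0)


@pytest.fixture(scope="session")
def small_gene(sim_params) -> GeneObservations:
    """120 simulated cells at the printed constants (shortened burn-in)."""
    noise = SeqNoiseConfig(n_cells=120, t0=30000.0)
    gene, _ = simulate_gene_dataset(sim_params, noise, np.random.default_rng(42))
    return gene


@pytest.fixture()
def toy_gene(udist60) -> GeneObservations:
    """Three hand-built cells with known UMI counts and histograms."""
    cells = [
        CellObservation("c0", l=2, alpha=0.1, y={0: 6, 1: 2, 4: 1}),
        CellObservation("c1", l=0, alpha=0.2, y={}),
        CellObservation("c2", l=5, alpha=0.15, y={0: 10, 2: 3}),
    ]
    return GeneObservations("toy", cells, lambda_s=0.01, udist=udist60)
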