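import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles importable

from balancerscan import BalancerConfig
from balancerscan import simulate as sim


@pytest.fixture(scope="session")
def reference():
    """Small two-chromosome genome with 40 genes, half in the balanced region."""
    return sim.simulate_reference(1, n_chromosomes=2, chrom_length=100_000,
                                  n_genes=40)


@pytest.fixture(scope="session")
def zones(reference):
    genome, genes = reference
    return sim.make_zones(genome, genes, n_zones=10)


@pytest.fixture(scope="session")
def dup_config():
    return BalancerConfig.duplication()


@pytest.fixture(scope="session")
def dup_cohort(reference, zones, dup_config):
    """20-strain duplication-balanced cohort with truth labels and MMP db."""
    genome, genes = reference
    return sim.simulate_cohort(
        genome, genes, zones, dup_config, n_strains=20, n_background=12, seed=7
    )
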