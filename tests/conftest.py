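import numpy as np
import pytest

from lobeqtl.config import Chromosome, CoverageModel, CrossDesign, GenomeConfig


@pytest.fixture(scope="session")
def small_genome() -> GenomeConfig:
    """Three-chromosome desk-scale genome: an X, one autosome, and a tiny
    non-recombining chromosome 4."""
    return GenomeConfig(
        chromosomes=[
            Chromosome("X", 8_000_000, 16.0, is_x=True),
            Chromosome("2L", 8_000_000, 20.0),
            Chromosome("4", 800_000, 0.0, recombining=False),
        ],
        snp_density=2e-4,
    )


@pytest.fixture(scope="session")
def small_design() -> CrossDesign:
    return CrossDesign(generations=6, population_size=50, n_males=40)


@pytest.fixture(scope="session")
def small_cohort(small_genome, small_design):
    from lobeqtl.simulate import simulate_ail_cohort

    return simulate_ail_cohort(small_genome, small_design, seed=123)


@pytest.fixture(scope="session")
def deep_reads(small_cohort, small_genome):
    """Error-free, high-depth read counts for the small cohort."""
    from lobeqtl.simulate import simulate_snp_reads, snp_panel

    panel = snp_panel(small_genome, seed=7)
    model = CoverageModel(mean_depth=30.0, parent_depth=30.0, error_rate=0.0)
    return simulate_snp_reads(small_cohort, panel, model, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
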