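import numpy as np
import pandas as pd
import pytest

from nlr_methylome.methylome import REPORT_COLUMNS
from nlr_methylome.simulate import SimulationConfig, simulate_study


def make_records(rows):
    """Build a cytosine-record frame from (chrom, pos, strand, meth, unmeth, context) tuples."""
    return pd.DataFrame(
        [(c, p, s, m, u, ctx, "NNN") for c, p, s, m, u, ctx in rows],
        columns=REPORT_COLUMNS,
    )


def small_config(**overrides) -> SimulationConfig:
    """A fast cohort: 6 genes of ~1 kb on one 30-kb chromosome."""
    defaults = dict(
        seed=11,
        n_chromosomes=1,
        chrom_length_bp=30_000,
        n_genes=6,
        gene_length_range=(800, 1_200),
        coverage_lambda=20.0,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_study():
    return simulate_study(small_config())


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
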