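import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from gbmscan.simulate import SimulationConfig, simulate_methylome

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: master seed of the reference mixture used across the suite
MIXTURE_SEED = 7


@pytest.fixture(scope="session")
def default_mixture():
    """Reference synthetic mixture: 1000 genes, 70% unmethylated / 20% gbM /
    10% TE-like, 20× coverage, 0.5% non-conversion."""
    cfg = SimulationConfig(seed=MIXTURE_SEED)
    genes, records, truth = simulate_methylome(cfg)
    return cfg, genes, records, truth


@pytest.fixture(scope="session")
def small_methylome():
    """Fast fixture for I/O, metrics and pipeline tests."""
    cfg = SimulationConfig(n_genes=60, seed=11)
    genes, records, truth = simulate_methylome(cfg)
    return cfg, genes, records, truth


def make_records(rows):
    """Build a cytosine record frame from (chrom,pos,strand,context,mc,cov)."""
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "context", "mc", "cov"])


def make_genes(rows):
    """Build a gene-model frame from (gene_id,chrom,strand,start,end)."""
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "start", "end"])
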