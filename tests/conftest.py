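import numpy as np
import pandas as pd
import pytest

from spliceqtl import synthetic_data as sd
from spliceqtl.io_core import FeatureRecord


@pytest.fixture(scope="session")
def small_config():
    """Four-tissue study layout at desk scale with planted geQTL and sQTL genes."""
    return sd.SimConfig(n_genes=6, seed=11, breed_fst=0.1)


@pytest.fixture(scope="session")
def genotypes(small_config):
    return sd.simulate_genotypes(small_config)


@pytest.fixture(scope="session")
def annotation(small_config):
    return sd.simulate_annotation(small_config)


@pytest.fixture(scope="session")
def counts_truth(small_config, genotypes):
    return sd.simulate_counts(small_config, genotypes)


@pytest.fixture(scope="session")
def single_tissue_300():
    """One cohort of 300 individuals with a single 100-SNP cis window,
    shared by the genetic-correlation tests."""
    cfg = sd.SimConfig(
        n_genes=1,
        n_snps_per_window=100,
        seed=3,
        tissues=[sd.TissueSpec("t1", "c", 300)],
    )
    gm = sd.simulate_genotypes(cfg)
    gene = FeatureRecord("gene000", "gene", "1", 2_000_000, 2_002_199, "+", "gene000")
    return cfg, gm, gene


def series(values, samples):
    return pd.Series(np.asarray(values, dtype=float), index=list(samples))
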