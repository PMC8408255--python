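import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from homoevol.simdata import SimConfig, simulate_dataset, simulate_counts


@pytest.fixture(scope="session")
def small_config():
    """A compact study design shared by the integration-style tests."""
    return SimConfig(n_chrom_pairs=2, genes_per_chrom=80, chrom_length=500_000,
                     ltr_class_counts=(6, 10, 4), seed=3)


@pytest.fixture(scope="session")
def small_truth(small_config):
    _, truth = simulate_dataset(small_config, None)
    return truth


@pytest.fixture(scope="session")
def small_counts(small_config, small_truth):
    return simulate_counts(small_truth, small_config)


@pytest.fixture(scope="session")
def small_bundle(small_config, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("bundle")
    bundle, truth = simulate_dataset(small_config, str(outdir))
    return bundle, truth


def make_count_matrix(truth, counts, config):
    """CountMatrix wrapper used across bias/dynamics tests."""
    from homoevol.bias import CountMatrix

    lengths = pd.Series({g: i["cds_len"] for g, i in truth.gene_info.items()})
    return CountMatrix(counts=counts, design=config.sample_table(),
                       gene_lengths=lengths)
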