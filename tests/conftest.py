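import numpy as np
import pytest

from tcrbind import (BindingRecord, ModelConfig, SyntheticConfig,
                     generate_benchmark)


@pytest.fixture
def toy_positives():
    """Five epitopes x two distinct receptors each, positives only."""
    epitopes = ["GILGFVFTL", "NLVPMVATV", "ELAGIGILTV", "KLGGALQAK", "AVFDRKSDAK"]
    suffixes = ["NEQFF", "YGYTF"]
    return [BindingRecord(e, f"CASS{e[:4]}{suf}", 1)
            for e in epitopes for suf in suffixes]


@pytest.fixture(scope="session")
def tiny_benchmark():
    """Small motif-planted benchmark: 6 epitopes x 12 positives, no noise."""
    cfg = SyntheticConfig(n_epitopes=6, tcrs_per_epitope=12, label_noise=0.0,
                          rng_seed=7)
    return generate_benchmark(cfg)


@pytest.fixture(scope="session")
def tiny_config():
    """A very small network configuration for fast structural tests."""
    return ModelConfig.reduced(tcr_len=14, epitope_len=10, filters=4,
                               attention_dim=4, dense_sizes=(12, 6),
                               kernel_sizes_tcr=(3, None),
                               kernel_sizes_epitope=(3, None))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
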