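import numpy as np
import pytest

from orthomarker.synthetic import SimConfig


@pytest.fixture
def small_config() -> SimConfig:
    """A desk-scale cohort: quick to generate, still exercises every stage."""
    return SimConfig(
        seed=7,
        n_loci_uce=15,
        n_loci_usco=4,
        n_species=8,
        tips_per_species=3,
        n_monophyly_violations=2,
        exon_bp=5_000,
        n_clusters=3,
        cluster_size=8,
        n_snps=200,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
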