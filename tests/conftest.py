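import numpy as np
import pytest

from hotspotdrive import branches, synth


@pytest.fixture(scope="session")
def clean_sim():
    """Small quartet with no heterozygotes (exact truth recovery)."""
    cfg = synth.SimConfig(seed=11, L_HM=600, L_CM=600, het_rate=0.0)
    return synth.simulate_quartet_alignment(cfg)


@pytest.fixture(scope="session")
def het_sim():
    """Small quartet with Denisovan heterozygosity."""
    cfg = synth.SimConfig(seed=12, L_HM=600, L_CM=600, het_rate=2e-3)
    return synth.simulate_quartet_alignment(cfg)


@pytest.fixture(scope="session")
def clean_cols(clean_sim):
    return branches.QuartetColumns.from_simulation(clean_sim)


@pytest.fixture(scope="session")
def het_cols(het_sim):
    return branches.QuartetColumns.from_simulation(het_sim)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
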