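import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from nucpos import Config
from nucpos.preprocess import make_candidate_regions
from nucpos.simulate import sample_reads, sample_truth

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def sonicated_cfg() -> Config:
    return Config.preset("sonicated")


@pytest.fixture(scope="session")
def mnase_cfg() -> Config:
    return Config.preset("mnase")


@pytest.fixture(scope="session")
def three_nuc_region(sonicated_cfg):
    """One candidate region simulated from a 3-nucleosome truth array."""
    rng = np.random.default_rng(42)
    truth = sample_truth(3, 1000.0, sonicated_cfg, rng)
    reads = sample_reads(truth, rng)
    regions = make_candidate_regions(reads, sonicated_cfg)
    assert len(regions) == 1
    return regions[0], truth
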