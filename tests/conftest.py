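import warnings

import numpy as np
import pytest

from mddnet import synth

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def small_truth():
    """Tiny ground truth with a 5-connection disorder effect."""
    cfg = synth.GroundTruthConfig(n_fc=30, n_sites=3, n_travelers=4,
                                  disorder_support=5, n_negative=3, noise_sd=0.1)
    return synth.generate_ground_truth(cfg, seed=101)


@pytest.fixture(scope="session")
def small_study(small_truth):
    return synth.generate_multisite_dataset(
        small_truth, synth.default_site_configs(3, n_hc_per_site=20, n_mdd_per_site=12),
        seed=102)


@pytest.fixture(scope="session")
def small_travelers(small_truth):
    return synth.generate_traveling_dataset(small_truth, scans_per_site=2, seed=103)


@pytest.fixture(scope="session")
def noisefree_truth():
    cfg = synth.GroundTruthConfig(n_fc=12, n_sites=3, n_travelers=4,
                                  disorder_support=4, n_negative=2, noise_sd=0.0)
    return synth.generate_ground_truth(cfg, seed=7)


@pytest.fixture(scope="session")
def noisefree_study(noisefree_truth):
    return synth.generate_multisite_dataset(
        noisefree_truth, synth.default_site_configs(3, n_hc_per_site=4, n_mdd_per_site=3),
        seed=8)


@pytest.fixture(scope="session")
def noisefree_travelers(noisefree_truth):
    return synth.generate_traveling_dataset(noisefree_truth, scans_per_site=2, seed=9)


@pytest.fixture(scope="session")
def signal_dataset():
    """Two-site cohort with a clean 10-connection disorder signal."""
    cfg = synth.GroundTruthConfig(n_fc=60, n_sites=2, disorder_support=10, n_negative=7,
                                  disorder_sd=0.12, noise_sd=0.1,
                                  sampling_sd=0.0, measurement_sd=0.0)
    gt = synth.generate_ground_truth(cfg, seed=201)
    data = synth.generate_multisite_dataset(
        gt, synth.default_site_configs(2, n_hc_per_site=60, n_mdd_per_site=40), seed=202)
    return gt, data
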