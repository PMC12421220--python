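import numpy as np
import pytest

import ricianfit as rf

STUDY_SEED = 1


@pytest.fixture(scope="session")
def protocol():
    return rf.AcquisitionProtocol.default()


@pytest.fixture(scope="session")
def snr10_study():
    """Reduced-scale loss-comparison study at SNR 10 (shared across tests)."""
    return rf.reduced_bias_study(snr=10.0, seed=STUDY_SEED)


@pytest.fixture(scope="session")
def snr30_study():
    """Reduced-scale loss-comparison study at SNR 30 (shared across tests)."""
    return rf.reduced_bias_study(snr=30.0, seed=STUDY_SEED)


@pytest.fixture(scope="session")
def small_noisy_batch(protocol):
    """A modest SNR-10 batch with ground truth, for fitting/metrics tests."""
    grid = rf.make_parameter_grid(n_levels=3)
    batch, _ = rf.build_dataset(grid, protocol, sigma=0.1, reps_per_combo=4,
                                seed=77, n_validation=0)
    return batch
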