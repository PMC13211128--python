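import numpy as np
import pytest

from mfsleepnet.model import ModelConfig
from mfsleepnet.profiles import get_profile
from mfsleepnet.synth_psg import SubjectParams, generate_cohort


@pytest.fixture(scope="session")
def fast_profile():
    """32 Hz single-channel profile: the lowest rate whose Nyquist clears
    the 12-14 Hz spindle band; keeps training-heavy tests affordable."""
    return get_profile("custom", eeg_channels=1, eog_channels=1,
                       fs_eeg=32.0, fs_eog=32.0)


@pytest.fixture(scope="session")
def tiny_config(fast_profile):
    return ModelConfig.from_profile(fast_profile, width_multiplier=1 / 16)


@pytest.fixture(scope="session")
def clean_subject():
    return SubjectParams(noise_sd=0.3, drift_wave=(8.0, 300.0),
                         drift_slope=0.01)


@pytest.fixture(scope="session")
def small_cohort(fast_profile, clean_subject):
    """200 strongly separable preprocessed epochs, 5 subjects, uniform mix."""
    return generate_cohort(5, 40, fast_profile, imbalance=np.ones(5) / 5,
                           master_seed=3, preprocess=True,
                           subject_params=clean_subject)


@pytest.fixture(scope="session")
def mild_cohort(fast_profile):
    """300 epochs with moderate noise: hard enough that the ablation
    methods separate, easy enough to learn at desk scale."""
    mild = SubjectParams(noise_sd=0.5, drift_wave=(10.0, 300.0),
                         drift_slope=0.01)
    return generate_cohort(6, 50, fast_profile, imbalance=np.ones(5) / 5,
                           master_seed=5, preprocess=True,
                           subject_params=mild)


@pytest.fixture(scope="session")
def trained_base(tiny_config, small_cohort):
    """Tiny full model trained to high accuracy on the separable cohort.

    Shared by the learning-sanity and adaptation acceptance tests."""
    from mfsleepnet.model import MFSleepNet
    from mfsleepnet.training import TrainConfig, predict, train_model

    model = MFSleepNet(tiny_config, seed=0)
    train_model(model, small_cohort, small_cohort,
                TrainConfig(epochs=30, lr=1e-3, seed=0, batch_size=32))
    train_acc = float((predict(model, small_cohort) == small_cohort.labels).mean())
    return model, train_acc


@pytest.fixture(scope="session")
def raw_cohort(fast_profile):
    """Small raw (unnormalized) cohort with heterogeneous subjects."""
    return generate_cohort(3, 20, fast_profile, master_seed=11,
                           preprocess=False)
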