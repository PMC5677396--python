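import dataclasses

import numpy as np
import pytest

from soilhsi import ExperimentConfig, SPAConfig, SVMConfig, SyntheticConfig
from soilhsi.synthetic_data import _default_class_params


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def small_synthetic_config(**overrides) -> SyntheticConfig:
    """A scaled-down cohort for fast pipeline tests."""
    defaults = dict(n_per_class=(9, 9, 9), n_bands=60, roi_size=16, seed=0)
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


def small_experiment_config(seed=0, **synth_overrides) -> ExperimentConfig:
    return ExperimentConfig(
        synthetic=small_synthetic_config(**synth_overrides),
        seed=seed,
        spa=SPAConfig(max_vars=6),
        svm=SVMConfig(log2c=(-3, 9, 4), log2g=(-9, 3, 4), cv_folds=3),
        plsr_max_components=8,
    )


def noiseless_synthetic_config(**overrides) -> SyntheticConfig:
    """Default cohort with every random spectral perturbation switched off."""
    class_params = {
        soil: dataclasses.replace(
            p, baseline_jitter_sd=0.0, slope_jitter_sd=0.0, trough_jitter_sd=0.0
        )
        for soil, p in _default_class_params().items()
    }
    defaults = dict(spectral_noise_sd=0.0, smooth_noise_sd=0.0, class_params=class_params)
    defaults.update(overrides)
    return SyntheticConfig(**defaults)
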