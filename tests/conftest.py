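import numpy as np
import pandas as pd
import pytest

from equigait import SimConfig, generate_trial
from equigait.simulate import generate_cohort


def noise_free(config: SimConfig) -> SimConfig:
    """Copy of a config with all stochastic components switched off."""
    import dataclasses

    return dataclasses.replace(
        config,
        kin_noise_sd_mm=0.0,
        kin_stride_jitter_mm=0.0,
        emg_stride_cv=0.0,
        drift_mm=0.0,
    )


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(n_horses=2, strides_per_trial=8, seed=42)


@pytest.fixture(scope="session")
def baseline_trial(small_config):
    return generate_trial(small_config, 0, "baseline1")


@pytest.fixture(scope="session")
def induced_trial(small_config):
    return generate_trial(small_config, 0, "iHL")


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


def make_arv_frame(values, horse="H01", muscle="biceps", side="left",
                   condition="baseline1", reference="ipsilateral") -> pd.DataFrame:
    return pd.DataFrame(
        {
            "horse_id": horse,
            "muscle": muscle,
            "side": side,
            "condition": condition,
            "stride": np.arange(len(values)),
            "reference": reference,
            "arv_raw": np.asarray(values, float),
        }
    )
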