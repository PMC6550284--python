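import numpy as np
import pandas as pd
import pytest

from actibiomark import (ActigraphySeries, ModelConfig, SynthConfig,
                         build_matrix, generate_cohort)


@pytest.fixture
def small_config():
    """A small, fast cohort with a strong group effect."""
    return SynthConfig(n_patients=6, n_controls=6, n_minutes=1440, seed=7,
                       patient_mean_ratio=0.5)


@pytest.fixture
def small_matrix(small_config):
    return build_matrix(generate_cohort(small_config))


@pytest.fixture
def fast_model():
    return ModelConfig(task="classify", rounds=50, seed=7)


def make_series(values, subject_id="s1", start="2003-05-07 12:00:00"):
    return ActigraphySeries(subject_id=subject_id,
                            start_time=pd.Timestamp(start),
                            values=np.asarray(values, dtype=float))
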