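import numpy as np
import pandas as pd
import pytest

from phenoscreen import SimulationConfig, StimulusProtocol, simulate_feature_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A small two-strain screen with known injected effects."""
    config = SimulationConfig(
        n_strains=2,
        wells_per_strain_per_day=5,
        n_days=3,
        n_features_per_window=60,
        affected_fraction=0.2,
        effect_size_dist={"name": "fixed", "value": 2.0},
        sigma_day=0.3,
        sigma_well=1.0,
        nan_rate=0.02,
        rng_seed=11,
    )
    tables, metadata, truth = simulate_feature_dataset(config)
    return config, tables, metadata, truth


@pytest.fixture(scope="session")
def short_protocol():
    """A compressed recording protocol to keep timeseries tests fast."""
    return StimulusProtocol(
        segment_durations=(30.0, 60.0, 30.0),
        pulse_starts=(20.0,),
        pulse_duration=10.0,
        fps=25.0,
    )
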