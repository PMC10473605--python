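import logging

import numpy as np
import pandas as pd
import pytest

from swmkit import behavior, brainbehavior, synthdata

logging.getLogger("swmkit").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_config() -> synthdata.GeneratorConfig:
    """Two studies, few participants — fast end-to-end fixture."""
    return synthdata.GeneratorConfig(
        n_studies=2,
        participants_per_study=(8, 9),
        target_amplitude=(6.0, 7.0),
        trials_per_participant=48,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return synthdata.generate_dataset(small_config)


@pytest.fixture(scope="session")
def default_dataset():
    """Full-size six-study dataset on generator defaults."""
    cfg = synthdata.GeneratorConfig(seed=7)
    return cfg, synthdata.generate_dataset(cfg)


@pytest.fixture(scope="session")
def default_analysis(default_dataset):
    _, (trials, truths) = default_dataset
    return behavior.analyze(trials), truths


@pytest.fixture(scope="session")
def standardized_activity(default_analysis):
    """Joined, within-study standardized activity + behavior table."""
    result, truths = default_analysis
    activity, _ = synthdata.simulate_network_activity(truths, seed=7)
    return brainbehavior.standardize_activity(activity, result.summaries)


def make_trials(
    target_angle,
    response_angle,
    target_amp=6.0,
    response_amp=None,
    participant_id="P1",
    study_id="S1",
) -> pd.DataFrame:
    """Hand-built trial table for unit tests."""
    target_angle = np.atleast_1d(np.asarray(target_angle, dtype=float))
    response_angle = np.atleast_1d(np.asarray(response_angle, dtype=float))
    if response_amp is None:
        response_amp = np.full_like(target_angle, target_amp)
    return pd.DataFrame(
        {
            "study_id": study_id,
            "participant_id": participant_id,
            "trial": np.arange(target_angle.size),
            "target_angle_deg": target_angle,
            "target_amp_dva": target_amp,
            "response_angle_deg": np.mod(response_angle, 360.0),
            "response_amp_dva": np.atleast_1d(np.asarray(response_amp, float)),
        }
    )
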