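import numpy as np
import pandas as pd
import pytest

from tfspm import synthetic_data as synth
from tfspm.pipeline import RunConfig, analyze_dataset
from tfspm.preprocess import EpochSet


@pytest.fixture(scope="session")
def paper_mimic_dataset():
    """One full-size paper_mimic dataset shared across expensive tests."""
    return synth.simulate_dataset(synth.paper_mimic_config(seed=42))


@pytest.fixture(scope="session")
def paper_mimic_result(paper_mimic_dataset):
    """Full presentation-1 analysis of the shared paper_mimic dataset."""
    return analyze_dataset(
        paper_mimic_dataset, RunConfig(preset="paper_mimic", seed=42)
    )


@pytest.fixture(scope="session")
def small_run_config():
    """Cut-down paper_mimic layout for fast end-to-end pipeline tests."""
    return dict(identities=4, repetitions=2, n_targets=2, n_subjects=2)


def make_epochset(
    data: np.ndarray,
    sample_rate_hz: float = 200.0,
    subjects=None,
    channels=None,
    stimulus_types=None,
    directions=None,
    trial_index=None,
    t0_ms: float = -500.0,
) -> EpochSet:
    """Assemble an EpochSet around a raw (n_epochs, n_samples) array."""
    n = len(data)
    step = 1000.0 / sample_rate_hz
    labels = pd.DataFrame(
        dict(
            subject=subjects if subjects is not None else np.zeros(n, dtype=int),
            channel=channels if channels is not None else ["amy_L"] * n,
            stimulus_type=(
                stimulus_types if stimulus_types is not None else ["eyes"] * n
            ),
            direction=directions if directions is not None else ["averted"] * n,
            presentation=1,
            trial_index=(
                trial_index if trial_index is not None else np.arange(n)
            ),
        )
    )
    return EpochSet(
        data=np.asarray(data, dtype=float),
        times_ms=t0_ms + step * np.arange(data.shape[1]),
        sample_rate_hz=sample_rate_hz,
        labels=labels,
    )
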