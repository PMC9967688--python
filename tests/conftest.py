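import numpy as np
import pandas as pd
import pytest

from emodecode import (
    ObservationSet,
    StudyDesign,
    build_observation_set,
    default_spec,
    generate_cohort,
)

RATE = 500.0
WLEN = 1500
N_WIN = 8
N_ROI = 10


@pytest.fixture(scope="session")
def tiny_design():
    return StudyDesign(n_participants=1, n_sessions=1, trials_per_session=5)


@pytest.fixture(scope="session")
def small_cohort_obs():
    """20-trial cohort (4 per condition) with the shipped preset, preprocessed."""
    design = StudyDesign(n_participants=2, n_sessions=1, trials_per_session=10)
    trials = generate_cohort(design, default_spec(), seed=11)
    return build_observation_set(trials)


def synthetic_observation_set(
    tensors: dict[str, np.ndarray],
    conditions=None,
    rate: float = RATE,
    baseline: dict[str, np.ndarray] | None = None,
) -> ObservationSet:
    """Wrap raw window tensors in an ObservationSet, bypassing filtering.

    Used to feed analytically-known signals (tones, white noise, lagged
    couplings) straight into the feature extractors.
    """
    n_obs = next(iter(tensors.values())).shape[0]
    if conditions is None:
        conditions = ["neutral"] * n_obs
    meta = pd.DataFrame(
        {
            "participant": np.ones(n_obs, dtype=int),
            "session": np.ones(n_obs, dtype=int),
            "trial": np.arange(1, n_obs + 1),
            "condition": conditions,
        }
    )
    if baseline is None:
        baseline = {k: v.copy() for k, v in tensors.items()}
    return ObservationSet(
        emotional=tensors, baseline=baseline, metadata=meta, sampling_rate=rate
    )


def windowed_noise(rng, n_obs=1, n_roi=N_ROI, n_win=N_WIN, wlen=WLEN):
    return rng.standard_normal((n_obs, n_roi, n_win, wlen))
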