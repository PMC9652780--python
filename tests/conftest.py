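import numpy as np
import pandas as pd
import pytest

from vwmlab.config import EEGSimConfig, GenConfig, MixtureTruth
from vwmlab.synth import gen_likert_trials
from vwmlab.tcc import SimilarityFunction, estimate_similarity


@pytest.fixture(scope="session")
def orientation_sim() -> SimilarityFunction:
    """Similarity function estimated from a synthetic Likert block."""
    cfg = GenConfig(seed=42, n_subjects=5)
    return estimate_similarity(gen_likert_trials(cfg, "orientation"))


@pytest.fixture(scope="session")
def exponential_sim() -> SimilarityFunction:
    """Noise-free exponential similarity on the orientation offset grid."""
    offsets = np.array([0, 2.5, 5, 10, 15, 20, 25, 30, 35, 40, 45, 60, 75, 90.0])
    return SimilarityFunction(
        domain="orientation", offsets=offsets, f=np.exp(-offsets / 20.0)
    )


def quiet_eeg(**kw) -> EEGSimConfig:
    """EEG config with artifacts and variability off unless overridden."""
    base = dict(
        noise_sd=0.0, saccade_rate=0.0, blink_rate=0.0, subject_amp_sd=0.0,
        heog_noise_sd=0.0,
    )
    base.update(kw)
    return EEGSimConfig(**base)


def mixture_trials(truth: MixtureTruth, n: int, seed: int,
                   trial_type: str = "3O") -> pd.DataFrame:
    """One-subject recall table with a given generative mixture truth."""
    from vwmlab.synth import gen_recall_trials

    cfg = GenConfig(
        seed=seed, n_subjects=1,
        mixture_truth=truth if trial_type == "3O" else MixtureTruth(),
        mixture_truth_by_type={trial_type: truth},
    )
    return gen_recall_trials(cfg, trial_types=[trial_type], trials_per_type=n)
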