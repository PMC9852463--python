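import numpy as np
import pytest

from skillseq.sequences import SequenceDataset, TrialSequence
from skillseq.synthetic import GeneratorConfig, generate_dataset


def make_trial(coords, trial_id="t1", subject_id="s1", fps=30.0, missing=None,
               label=None, score=None):
    coords = np.asarray(coords, dtype=float)
    if missing is None:
        missing = np.any(np.isnan(coords), axis=1)
    return TrialSequence(trial_id=trial_id, subject_id=subject_id, fps=fps,
                         coords=coords, missing_mask=np.asarray(missing, bool),
                         label=label, score=score)


@pytest.fixture(scope="session")
def small_dataset():
    """60-trial synthetic cohort (6 subjects x 10 trials), fast to rebuild."""
    cfg = GeneratorConfig(n_subjects=6, trials_per_subject=10, seed=7)
    ds, truth = generate_dataset(cfg)
    return ds, truth, cfg


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
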