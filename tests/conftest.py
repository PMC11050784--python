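import numpy as np
import pytest

from jolreact import (EpochsSet, Montage, TimeAxis, condition_evoked,
                      combine_evoked, standard_montage_40)

CONDS = ("JOL", "no-JOL")


@pytest.fixture(scope="session")
def montage40():
    return standard_montage_40()


@pytest.fixture
def small_montage():
    # 4 electrodes on a line, 30 mm apart: chain adjacency under the 45 mm rule
    labels = ("A", "B", "C", "D")
    pos = np.array([[0, 0, 0], [30, 0, 0], [60, 0, 0], [90, 0, 0]], float)
    return Montage(labels, pos)


def make_epochs(data, montage, subject="S01", sfreq=500.0, t_start=-100.0,
                conditions=None):
    data = np.asarray(data, float)
    n_trials = data.shape[0]
    if conditions is None:
        conditions = np.array([CONDS[i % 2] for i in range(n_trials)], object)
    time = TimeAxis(sfreq, t_start, data.shape[2])
    return EpochsSet(subject, data, conditions, time, montage)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def toy_evoked_group(diffs, montage, sfreq=500.0, t_start=0.0):
    """Build a group EvokedSet whose JOL-minus-no-JOL equals ``diffs``.

    ``diffs``: (n_subjects, n_channels, n_samples).
    """
    from jolreact import EvokedSet

    diffs = np.asarray(diffs, float)
    n_subj = diffs.shape[0]
    data = np.zeros((n_subj, 2) + diffs.shape[1:])
    data[:, 0] = diffs  # JOL; no-JOL stays zero
    time = TimeAxis(sfreq, t_start, diffs.shape[2])
    return EvokedSet([f"S{i:02d}" for i in range(n_subj)], data, time, montage)
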