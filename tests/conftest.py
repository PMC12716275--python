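import numpy as np
import pytest

import sleepwarp as sw
from sleepwarp.core import Hypnogram, QCError


@pytest.fixture(scope="session")
def profile():
    return sw.make_profile(5, cluster=1)


@pytest.fixture(scope="session")
def night(profile):
    """One synthetic night (hypnogram + band powers), no raw EEG."""
    return sw.generate_night(profile, seed=11)


@pytest.fixture(scope="session")
def deep_hypnogram():
    """A 3.2-h N2/N3-heavy scored night for raw-EEG event tests."""
    labels = (
        ["W"] * 4
        + ["N2"] * 160 + ["N3"] * 100 + ["N2"] * 60 + ["REM"] * 24
        + ["N2"] * 140 + ["N3"] * 60 + ["REM"] * 20
        + ["W"] * 4
    )
    return Hypnogram(np.array(labels, dtype=object))


@pytest.fixture(scope="session")
def raw_night(profile, deep_hypnogram):
    """Raw EEG with planted spindle/slow-wave ground truth."""
    rec, events, truth = sw.simulate_raw_eeg(deep_hypnogram, profile, seed=9)
    return rec, events, truth


@pytest.fixture(scope="session")
def cohort_small():
    """5 subjects x 4 nights (band powers only) for forecast tests."""
    return sw.generate_cohort(5, 4, seed=3)


@pytest.fixture(scope="session")
def cohort_features():
    """The full study-scale cohort (8 subjects x 10 nights) with night
    features at 60-s resolution, shared by the warping-level tests."""
    profiles, nights = sw.generate_cohort(8, 10, seed=1)
    feats = []
    for n in nights:
        try:
            feats.append(
                sw.build_night_features(
                    n.bandpower,
                    n.hypnogram,
                    resolution_s=60.0,
                    night_id=f"{n.subject_id}-{n.night_index:02d}",
                    subject_id=n.subject_id,
                    night_index=n.night_index,
                )
            )
        except QCError:
            pass
    return profiles, feats


def random_features(rng, length, n_bands=5):
    """A random z-scored feature matrix for DTW property tests."""
    m = rng.normal(size=(n_bands, length))
    return (m - m.mean(axis=1, keepdims=True)) / m.std(axis=1, keepdims=True)
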