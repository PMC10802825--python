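import numpy as np
import pytest

from vtcycle.episodes import Cohort, Episode

# The worked example from the measurement-convention figure: CL1 is the
# PVC-coupled interval (373 ms), then device-measured CLs 375, 360, 373.
FIG1_WINDOW = [373.0, 375.0, 360.0, 373.0]


@pytest.fixture
def fig1_window():
    return list(FIG1_WINDOW)


def make_episode(cl, episode_id="E01", patient_id="P01", label="terminating"):
    return Episode(episode_id=episode_id, patient_id=patient_id, label=label,
                   cl_ms=np.asarray(cl, dtype=float))


@pytest.fixture
def eleven_beat_episode():
    """A fixed 11-beat analysis-eligible episode (synthetic values)."""
    cl = [360, 348, 332, 341, 326, 330, 318, 324, 315, 321, 319]
    return make_episode(cl, episode_id="F11")


@pytest.fixture
def two_episode_cohort():
    rng = np.random.default_rng(42)
    eps = [
        make_episode(320 + rng.normal(0, 15, 14), "A1", "P01", "terminating"),
        make_episode(330 + rng.normal(0, 8, 20), "A2", "P02", "sustained"),
    ]
    return Cohort(episodes=eps, provenance="conftest")


def random_windows(n_windows, rng, min_len=4, max_len=12, loc=340.0, scale=25.0):
    """Random CL-like windows of varying length for oracle-equivalence checks."""
    out = []
    for _ in range(n_windows):
        n = int(rng.integers(min_len, max_len + 1))
        out.append(loc + scale * rng.standard_normal(n))
    return out
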