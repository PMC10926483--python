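import numpy as np
import pytest

from optomotor.fictrac import Trajectory
from optomotor.pipeline import analyze_cohort
from optomotor.simulate import default_design, simulate_cohort
from optomotor.stimuli import StimulusSpec, build_schedule


def make_trajectory(
    heading: np.ndarray,
    frame_rate: float = 50.0,
    ball_diameter: float = 5.0,
    increments: np.ndarray | None = None,
) -> Trajectory:
    """Trajectory with a prescribed heading channel and zero side/forward motion."""
    n = len(heading)
    if increments is None:
        dh = np.diff(heading, prepend=heading[0])
        increments = np.column_stack([np.zeros(n), np.zeros(n), dh])
    return Trajectory(
        frame_index=np.arange(n),
        time=np.arange(n) / frame_rate,
        integrated_heading=np.asarray(heading, dtype=float),
        rotation_increment=increments,
        movement_speed=np.linalg.norm(increments, axis=1),
        ball_diameter=ball_diameter,
        frame_rate=frame_rate,
    )


@pytest.fixture
def single_stimulus_schedule():
    """One grating, 4 repeats of 10 s left + 10 s right (the default protocol)."""
    return build_schedule([StimulusSpec(0.0625, 16.0)], epoch_duration=10.0, repeats=4, isi=180.0, order_seed=0)


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic cohort (24 animals x 12 stimuli, seeded)."""
    return simulate_cohort(default_design(seed=1))


@pytest.fixture(scope="session")
def cohort_analysis(default_cohort):
    """Full feature extraction + Monte-Carlo k selection + assignment on the
    default cohort at the scaled-down consensus settings (reps=200, B=25)."""
    return analyze_cohort(default_cohort, reps=200, n_reference=25, seed=1)
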