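import numpy as np
import pytest

from mgtraj import GridSpec, SynthConfig, UniformTrajectory, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 20-patient synthetic cohort with ground truth (seed fixed)."""
    return generate_cohort(SynthConfig(n_patients=20, seed=7))


@pytest.fixture
def grid12():
    return GridSpec(0.0, 11.0, 1.0)


def make_traj(pid, values, grid=None):
    values = np.asarray(values, dtype=float)
    if grid is None:
        grid = GridSpec(0.0, float(len(values) - 1), 1.0)
    return UniformTrajectory(pid, "x", grid, values,
                             np.zeros(len(values), dtype=bool))
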