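import numpy as np
import pytest

from gaitstrat.core_data import CHANNELS, GaitCycle
from gaitstrat.synthetic_data import CohortConfig, generate_cohort


def make_cycle(
    seed=0, T=30, toe_off=None, subject_id="S01", side="left",
    cycle_index=1, group="iSCI", scale=10.0,
):
    """Random but valid 9-channel gait cycle for structural tests."""
    rng = np.random.default_rng(seed)
    angles = scale * rng.standard_normal((len(CHANNELS), T))
    return GaitCycle(
        subject_id=subject_id, side=side, cycle_index=cycle_index,
        angles=angles, toe_off_index=toe_off if toe_off is not None else T // 2,
        group=group,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Compact synthetic cohort (6 impaired + 2 control subjects)."""
    return generate_cohort(CohortConfig(n_subjects=6, n_controls=2, seed=7))


@pytest.fixture(scope="session")
def default_cohort():
    """Full-scale default cohort: 28 impaired subjects, 21 controls."""
    return generate_cohort(CohortConfig(seed=11))
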