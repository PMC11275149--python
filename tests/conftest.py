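import numpy as np
import pytest

import fdgquant as fq
from fdgquant.synthetic_data import _fine_grid_min, feng_plasma_input, frame_average


@pytest.fixture(scope="session")
def schedule() -> fq.FrameSchedule:
    return fq.mouse_dynamic_schedule()


@pytest.fixture(scope="session")
def input_params() -> fq.InputModelParams:
    return fq.InputModelParams()


@pytest.fixture(scope="session")
def frame_input_function(schedule, input_params) -> fq.InputFunction:
    """Noise-free frame-averaged plasma input on the acquisition grid."""
    fine = _fine_grid_min(schedule, 1.0)
    plasma = frame_average(fine, feng_plasma_input(input_params, fine), schedule)
    return fq.InputFunction(schedule.mid_times_min, plasma)


@pytest.fixture(scope="session")
def clean_phantom() -> fq.PhantomSession:
    """Default-geometry phantom with noise disabled (analytic voxel values)."""
    return fq.build_phantom_session(fq.PhantomConfig(noise_level=0.0), seed=7)


def make_tac(schedule, values, organ="tumor", n_voxels=1, units="kBq/mL"):
    return fq.TimeActivityCurve(
        mid_times_min=schedule.mid_times_min,
        values=np.asarray(values, float),
        organ=organ,
        n_voxels=n_voxels,
        units=units,
    )
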