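import numpy as np
import pytest

from hammersim import analysis as an
from hammersim import protocols as pr
from hammersim import subject as sj
from hammersim.dynamics import HandImpedance, ToolSpec, make_velocity_profile


@pytest.fixture(scope="session")
def profile_ccw():
    return make_velocity_profile(40.0, 0.7, 1000.0)


@pytest.fixture(scope="session")
def profile_cw():
    return make_velocity_profile(-40.0, 0.7, 1000.0)


@pytest.fixture(scope="session")
def tool():
    return ToolSpec(head_mass=0.7, rod_length=0.3)


@pytest.fixture(scope="session")
def impedance():
    return HandImpedance()


@pytest.fixture(scope="session")
def exp3_noisefree_table():
    """One noise-free subject through the full Experiment-3 schedule."""
    params = sj.exp3_cohort_params(
        motor_noise_sd=0.0,
        direction_noise_sd=0.0,
        kernel_sd_sd=0.0,
        deadapt_kernel_sd_sd=0.0,
    )
    cohort = sj.make_cohort(params, 1, seed=11)
    sched = pr.build_experiment(3, seed=5)
    return pr.run_experiment(sched, cohort, seed=12)
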