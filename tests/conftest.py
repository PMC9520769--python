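import dataclasses

import pytest

from npmicroenv import BufferModel, SolverOptions, named_scenario


@pytest.fixture(scope="session")
def coarse_options():
    """Fast solver settings for behavioural (non-convergence) tests."""
    return SolverOptions(
        resolution=16, dt_init_h=0.02, dt_max_h=0.2, ramp_h=1.0, sample_every_h=12.0
    )


@pytest.fixture(scope="session")
def quick_options():
    """Very coarse settings for sweep-style tests."""
    return SolverOptions(
        resolution=10, dt_init_h=0.05, dt_max_h=0.25, ramp_h=0.5, sample_every_h=24.0
    )


@pytest.fixture(scope="session")
def bead_4m():
    return named_scenario("bead_24w_LG_NX_4M")


def with_buffer_slope(scenario, slope):
    return dataclasses.replace(scenario, buffer=BufferModel(slope_ph_per_mm=slope))
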