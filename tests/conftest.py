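import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import fbdry

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def short_inputs() -> fbdry.LineInputs:
    """Reduced 45-min identification-style scenario (three setpoint steps)."""
    return fbdry.build_inputs(fbdry.IDENT_RUN_SHORT_STEPS)


@pytest.fixture(scope="session")
def short_trajectory(short_inputs) -> fbdry.Trajectory:
    """One shared high-accuracy simulation of the reduced scenario."""
    return fbdry.simulate_line(
        short_inputs, solver=fbdry.SolverOptions(rtol=1e-8, atol=1e-10, dt_out=5.0))


@pytest.fixture(scope="session")
def one_cycle_inputs() -> fbdry.LineInputs:
    """Single-setpoint scenario long enough for cell 1 to fill, dry, and empty."""
    steps = (fbdry.ExperimentStep(0.0, 1100.0, 20, 40, 45, 300, 580),)
    return fbdry.build_inputs(steps)
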