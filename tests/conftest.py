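import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")

from scartherm import GridSpec, SolverSpec  # noqa: E402

# Coarse-but-adequate resolution for property tests: 40 x 60 cells with a
# 10 um surface cell, and a shortened fine-step count through the pulse.
COARSE_GRID = GridSpec(dr_mm=0.25, nz=60, dz0_mm=0.01)
FAST_SOLVER = SolverSpec(pulse_steps=120)


@pytest.fixture(scope="session")
def coarse_grid():
    return COARSE_GRID


@pytest.fixture(scope="session")
def fast_solver():
    return FAST_SOLVER
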