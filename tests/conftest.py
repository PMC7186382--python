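"""Shared fixtures.

The two ``study_*`` fixtures run the full calibrate-perturb-evaluate
pipeline once per session on the default configuration; the acceptance
tests all read from them.  Everything else uses the fast configuration
(reduced optimization budgets) or constructed inputs.
"""

import numpy as np
import pytest

from elbowsim import default_config, fast_config
from elbowsim.simulate import ModelContext
from elbowsim.study import run_full_study

#: single seed used for the session-scoped pipeline runs
STUDY_SEED = 1


@pytest.fixture(scope="session")
def default_cfg():
    return default_config()


@pytest.fixture(scope="session")
def ctx(default_cfg):
    return ModelContext(default_cfg)


@pytest.fixture(scope="session")
def fast_cfg():
    return fast_config()


@pytest.fixture(scope="session")
def fast_ctx(fast_cfg):
    return ModelContext(fast_cfg)


@pytest.fixture(scope="session")
def study_25(default_cfg):
    """Full study (calibration + all protocols + torque model), 25 ms delay."""
    return run_full_study(default_cfg, delay=0.025, seed=STUDY_SEED)


@pytest.fixture(scope="session")
def study_50(default_cfg):
    """Perturbation runs with gains recalibrated for the 50 ms delay."""
    return run_full_study(default_cfg, delay=0.050, seed=STUDY_SEED,
                          include_torque_model=False)


def make_sim_result(t, phi, omega, u_open, u_closed):
    """Minimal SimResult for metric arithmetic tests (forces zeroed)."""
    from elbowsim.simulate import SimResult
    from elbowsim.controller import total_u

    t = np.asarray(t, dtype=float)
    u_open = np.asarray(u_open, dtype=float)
    u_closed = np.asarray(u_closed, dtype=float)
    n, m = u_open.shape
    zeros = np.zeros((n, m))
    return SimResult(
        t=t, phi=np.asarray(phi, dtype=float),
        omega=np.asarray(omega, dtype=float),
        u_open=u_open, u_closed=u_closed,
        u_total=total_u(u_open, u_closed),
        activity=zeros.copy(), l_ce=zeros.copy(), v_ce=zeros.copy(),
        force=zeros.copy(), contact_first=zeros.copy(),
        constraint_force=np.zeros((n, 2)), active_torque=np.zeros(n),
    )
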