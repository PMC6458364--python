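import numpy as np
import pytest

from btslip import GaitModel, WalkerParams


@pytest.fixture(scope="session")
def params():
    return WalkerParams()


@pytest.fixture(scope="session")
def fmch_results():
    return GaitModel("fmch").fit()


@pytest.fixture(scope="session")
def nmf_results():
    return GaitModel("nmf").fit()


@pytest.fixture(scope="session")
def preflex_results():
    return GaitModel("preflex").fit()


@pytest.fixture(scope="session")
def adaptive_results():
    return GaitModel("adaptive_nmf").fit()


@pytest.fixture(scope="session")
def nmf_cycle(nmf_results):
    """Trajectory window of one converged nmF stride."""
    cyc = nmf_results.cycle
    st = cyc.strides.iloc[len(cyc.strides) // 2]
    traj = cyc.trajectory
    return traj[(traj["t"] >= st["t_start"]) & (traj["t"] <= st["t_end"])]


def walker_state(x=0.0, y=1.08, vx=1.0, vy=0.0, phi=np.pi / 2, phidot=0.0,
                 activations=None, foot_x=(0.0, 0.0), contact=(1, 0),
                 stance_leg=0):
    from btslip.engine import WalkerState
    return WalkerState(
        x=x, y=y, vx=vx, vy=vy, phi=phi, phidot=phidot,
        activations=np.zeros(4) if activations is None else np.asarray(activations, float),
        foot_x=np.asarray(foot_x, float),
        contact=np.asarray(contact, dtype=np.int64),
        stance_leg=stance_leg)
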