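import numpy as np
import pytest

from nonrad.trajectory import Trajectory


def make_toy_trajectory(gaps_ev, crossing=None, values=None, dt_fs=0.5):
    """Model-space trajectory with a prescribed gap series (eV), an
    optional crossing frame, and an optional 1-DoF coordinate series."""
    from nonrad import units

    gaps_ev = np.asarray(gaps_ev, dtype=float)
    n = len(gaps_ev)
    active = np.ones(n, dtype=int)
    hops = []
    if crossing is not None:
        active[crossing:] = 0
        hops = [(crossing, 1, 0)]
    if values is None:
        values = np.zeros(n)
    energies = np.zeros((n, 2))
    energies[:, 1] = gaps_ev * units.EV_TO_HARTREE
    return Trajectory(
        positions=np.asarray(values, dtype=float)[:, None],
        energies=energies,
        active=active,
        hops=hops,
        dt=dt_fs * units.FS_TO_AU_TIME,
    )


@pytest.fixture(scope="session")
def carbonyl_model():
    from nonrad import models

    return models.build_carbonyl_lock_model()


@pytest.fixture(scope="session")
def tully_model():
    from nonrad import models

    return models.build_tully_single_crossing()
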