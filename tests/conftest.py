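import numpy as np
import pytest

from dpdmem import EpsilonSpec, RunParams, SimulationBox, SystemState


@pytest.fixture
def neutral_table():
    return EpsilonSpec().make_table()


@pytest.fixture
def params():
    return RunParams(seed=7)


@pytest.fixture
def small_box():
    return SimulationBox((5.0, 5.0, 5.0))


def two_bead_state(box, r, types=(0, 0), vel=None):
    """Two beads separated by r along x, centered in the box."""
    L = np.asarray(box.lengths)
    pos = np.array(
        [
            [L[0] / 2 - r / 2, L[1] / 2, L[2] / 2],
            [L[0] / 2 + r / 2, L[1] / 2, L[2] / 2],
        ]
    )
    state = SystemState(box, pos, types=np.array(types, dtype=np.int64))
    if vel is not None:
        state.vel = np.asarray(vel, dtype=np.float64)
    return state


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_state(rng, n, box_lengths=(6.0, 6.0, 6.0)):
    box = SimulationBox(box_lengths)
    pos = rng.uniform(0, 1, (n, 3)) * np.asarray(box_lengths)
    return SystemState(box, pos)


def brute_force_pairs(pos, box, cutoff):
    """O(N^2) minimum-image pair enumeration (oracle)."""
    L = np.asarray(box)
    n = len(pos)
    out = []
    for i in range(n):
        d = pos[i] - pos[i + 1 :]
        d -= L * np.rint(d / L)
        r2 = (d**2).sum(axis=1)
        for k in np.flatnonzero(r2 < cutoff * cutoff):
            out.append((i, i + 1 + k))
    return sorted(out)
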