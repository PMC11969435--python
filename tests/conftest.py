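import numpy as np
import pytest

from pegshell.core import AtomRecord, Frame, Topology, Trajectory


def make_point_topology(n, charges=None, groups=None, bonds=(), **atom_kwargs):
    """n featureless point atoms, optionally charged/grouped/bonded."""
    charges = charges if charges is not None else [0.0] * n
    atoms = [AtomRecord("X", charge=q, mass=1.0, **atom_kwargs) for q in charges]
    return Topology(atoms, bonds=bonds, groups=groups or {"ALL": list(range(n))})


def make_frame(positions, box=100.0, time=0.0):
    positions = np.asarray(positions, dtype=float)
    return Frame(positions, time=time, box=np.array([box] * 3, dtype=float))


def make_traj(list_of_positions, box=100.0, dt=1.0):
    return Trajectory(
        [make_frame(p, box=box, time=k * dt) for k, p in enumerate(list_of_positions)]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
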