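import numpy as np
import pytest

from retspec.structure_io import AtomRecord, Frame, Trajectory


def make_atom(serial, name, element, xyz, charge=None, resname="MOL", resid=1, chain="A"):
    return AtomRecord(
        serial=serial, name=name, resname=resname, resid=resid,
        chain=chain, element=element, xyz=np.asarray(xyz, dtype=float),
        charge=charge,
    )


@pytest.fixture
def pocket_frame():
    """Tiny pocket: retinal-like pair plus two waters and a tyrosine O."""
    atoms = [
        make_atom(1, "N15", "N", (0, 0, 0), resname="RET"),
        make_atom(2, "H15", "H", (1.01, 0, 0), resname="RET"),
        make_atom(3, "C15", "C", (-1.4, 0, 0), resname="RET"),
        make_atom(4, "OH", "O", (0, 3.0, 0), resname="TYR", resid=126),
        make_atom(5, "O", "O", (3.0, 0, 0), resname="HOH", resid=401),
        make_atom(6, "H1", "H", (3.6, 0.7, 0), resname="HOH", resid=401),
        make_atom(7, "H2", "H", (3.6, -0.7, 0), resname="HOH", resid=401),
        make_atom(8, "O", "O", (0, -4.0, 2.0), resname="HOH", resid=402),
    ]
    return Frame(atoms=atoms)


def static_trajectory(frame: Frame, n_frames: int, stride: float = 10.0) -> Trajectory:
    """Repeat one frame n times (fresh atom copies, correct times)."""
    import copy

    frames = []
    for k in range(n_frames):
        fr = copy.deepcopy(frame)
        fr.time = k * stride
        frames.append(fr)
    return Trajectory(frames=frames, stride=stride)
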