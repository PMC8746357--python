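import numpy as np
import pytest

from retspec.errors import SelectionError, ValidationError
from retspec.geometry import (
    HBondCriteria,
    hbond_occupancy,
    integrated_rdf,
    pair_distance_stats,
)
from retspec.structure_io import Frame, Selection, Trajectory

from conftest import make_atom, static_trajectory

N15 = Selection(resnames={"RET"}, atom_names={"N15"})
H15 = Selection(resnames={"RET"}, atom_names={"H15"})
Y126 = Selection(resnames={"TYR"}, atom_names={"OH"})
WATER_O = Selection(resnames={"HOH"}, atom_names={"O"})
RET = Selection(resnames={"RET"})


def random_pocket_trajectory(n_frames=20, n_waters=5, seed=0):
    rng = np.random.default_rng(seed)
    frames = []
    for k in range(n_frames):
        atoms = [
            make_atom(1, "N15", "N", rng.normal(0, 0.1, 3), resname="RET"),
            make_atom(2, "H15", "H", (1.01, 0, 0) + rng.normal(0, 0.05, 3), resname="RET"),
            make_atom(3, "C15", "C", (-1.4, 0, 0) + rng.normal(0, 0.1, 3), resname="RET"),
            make_atom(4, "OH", "O", (0, 3.0, 0) + rng.normal(0, 0.3, 3),
                      resname="TYR", resid=126),
        ]
        for w in range(n_waters):
            atoms.append(
                make_atom(5 + w, "O", "O", rng.uniform(-6, 6, 3),
                          resname="HOH", resid=401 + w)
            )
        frames.append(Frame(atoms=atoms, time=k * 10.0))
    return Trajectory(frames=frames, stride=10.0)


def rigid_transform(traj, seed=1):
    rng = np.random.default_rng(seed)
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    shift = rng.uniform(-20, 20, 3)
    frames = []
    for fr in traj.frames:
        atoms = [
            make_atom(a.serial, a.name, a.element, q @ a.xyz + shift,
                      resname=a.resname, resid=a.resid)
            for a in fr.atoms
        ]
        frames.append(Frame(atoms=atoms, time=fr.time))
    return Trajectory(frames=frames, stride=traj.stride)


class TestPairDistance:
    def test_static_pair(self, pocket_frame):
        traj = static_trajectory(pocket_frame, 10)
        mean, sd, series = pair_distance_stats(traj, N15, Y126)
        assert mean == pytest.approx(3.0, abs=1e-12)
        assert sd == 0.0
        assert len(series) == 10

    def test_matches_brute_force_oracle(self):
        traj = random_pocket_trajectory()
        mean, sd, series = pair_distance_stats(traj, N15, Y126)
        manual = []
        for fr in traj.frames:
            a = next(x for x in fr.atoms if x.name == "N15")
            b = next(x for x in fr.atoms if x.name == "OH")
            manual.append(float(np.sqrt(np.sum((a.xyz - b.xyz) ** 2))))
        manual = np.array(manual)
        np.testing.assert_array_equal(series, manual)
        assert mean == manual.mean()
        assert sd == pytest.approx(manual.std(ddof=1), rel=1e-12)

    def test_rigid_motion_invariance(self):
        traj = random_pocket_trajectory()
        moved = rigid_transform(traj)
        m1, s1, _ = pair_distance_stats(traj, N15, Y126)
        m2, s2, _ = pair_distance_stats(moved, N15, Y126)
        assert m1 == pytest.approx(m2, abs=1e-9)
        assert s1 == pytest.approx(s2, abs=1e-9)

    def test_ambiguous_selection_rejected(self):
        traj = random_pocket_trajectory()
        with pytest.raises(SelectionError):
            pair_distance_stats(traj, N15, WATER_O)  # >1 atom
        with pytest.raises(SelectionError):
            pair_distance_stats(traj, N15, Selection(resnames={"GLU"}))  # 0 atoms


class TestIntegratedRdf:
    def test_single_water_is_step_function(self):
        atoms = [
            make_atom(1, "N15", "N", (0, 0, 0), resname="RET"),
            make_atom(2, "O", "O", (3.0, 0, 0), resname="HOH", resid=401),
        ]
        traj = static_trajectory(Frame(atoms=atoms), 5)
        rdf = integrated_rdf(traj, RET, WATER_O, r_max=6.0, dr=0.5)
        assert np.all(rdf.counts[rdf.radii < 3.0] == 0.0)
        assert np.all(rdf.counts[rdf.radii >= 3.0] == 1.0)

    def test_counts_non_decreasing(self):
        rdf = integrated_rdf(
            random_pocket_trajectory(seed=7), RET, WATER_O, r_max=12.0, dr=0.25
        )
        assert np.all(np.diff(rdf.counts) >= 0)

    def test_matches_brute_force_oracle(self):
        traj = random_pocket_trajectory(n_frames=8, n_waters=6, seed=3)
        r_max, dr = 10.0, 0.5
        rdf = integrated_rdf(traj, RET, WATER_O, r_max=r_max, dr=dr)
        radii = dr * np.arange(1, int(r_max / dr) + 1)
        expected = np.zeros_like(radii)
        for fr in traj.frames:
            heavy = [a.xyz for a in fr.atoms if a.resname == "RET" and a.element != "H"]
            for w in fr.atoms:
                if w.resname == "HOH" and w.name == "O":
                    dmin = min(np.linalg.norm(w.xyz - h) for h in heavy)
                    expected += dmin <= radii
        expected /= len(traj)
        np.testing.assert_array_equal(rdf.counts, expected)

    def test_hydrogens_excluded_from_reference(self, pocket_frame):
        traj = static_trajectory(pocket_frame, 2)
        # water 401 oxygen sits 3.0 Å from N15 but 1.99 Å from RET H15;
        # with heavy-only reference its min distance is 3.0
        rdf = integrated_rdf(traj, RET, WATER_O, r_max=4.0, dr=0.1)
        first_nonzero = rdf.radii[np.argmax(rdf.counts > 0)]
        assert first_nonzero == pytest.approx(3.0, abs=0.1001)

    def test_empty_chromophore_rejected(self):
        traj = random_pocket_trajectory()
        with pytest.raises(SelectionError):
            integrated_rdf(traj, Selection(resnames={"XXX"}), WATER_O)


def hbond_traj(distance, collinear=True):
    """Donor at origin, H on +x, acceptor at given N···A distance."""
    direction = np.array([1.0, 0, 0]) if collinear else np.array([0, 1.0, 0])
    atoms = [
        make_atom(1, "N15", "N", (0, 0, 0), resname="RET"),
        make_atom(2, "H15", "H", (1.01, 0, 0), resname="RET"),
        make_atom(3, "OH", "O", distance * direction, resname="TYR", resid=126),
    ]
    return static_trajectory(Frame(atoms=atoms), 10)


class TestHBondOccupancy:
    def test_permanent_linear_contact(self):
        assert hbond_occupancy(hbond_traj(2.9), N15, H15, Y126) == 100.0

    def test_permanently_distant(self):
        assert hbond_occupancy(hbond_traj(10.0), N15, H15, Y126) == 0.0

    def test_angle_criterion_rejects_perpendicular_acceptor(self):
        # D···A = 2.9 Å but D-H···A angle ≈ 69° < 120°
        assert hbond_occupancy(hbond_traj(2.9, collinear=False), N15, H15, Y126) == 0.0

    def test_monotone_under_relaxed_criteria(self):
        traj = random_pocket_trajectory(n_frames=50, seed=11)
        strict = HBondCriteria(max_da_distance=3.0, min_dha_angle=150.0)
        loose = HBondCriteria(max_da_distance=4.0, min_dha_angle=100.0)
        occ_strict = hbond_occupancy(traj, N15, H15, Y126, strict)
        occ_loose = hbond_occupancy(traj, N15, H15, Y126, loose)
        assert 0.0 <= occ_strict <= occ_loose <= 100.0

    def test_missing_hydrogen_rejected(self):
        traj = hbond_traj(2.9)
        with pytest.raises(SelectionError):
            hbond_occupancy(
                traj, N15, Selection(resnames={"RET"}, atom_names={"H99"}), Y126
            )

    def test_criteria_validation(self):
        with pytest.raises(ValidationError):
            HBondCriteria(max_da_distance=-1.0)
        with pytest.raises(ValidationError):
            HBondCriteria(min_dha_angle=270.0)
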