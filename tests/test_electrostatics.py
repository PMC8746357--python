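import numpy as np
import pytest

from retspec.constants import COULOMB_K, vdw_radius
from retspec.electrostatics import (
    ChargedEnvironment,
    coulomb_potential,
    fibonacci_sphere,
    project_potential,
    select_environment,
    tuning_descriptor,
    vdw_surface,
)
from retspec.errors import SelectionError, SingularityError, ValidationError
from retspec.structure_io import Frame, Selection

from conftest import make_atom


def env_of(*charges):
    pos = np.array([c[0] for c in charges], dtype=float)
    q = np.array([c[1] for c in charges], dtype=float)
    return ChargedEnvironment(positions=pos, charges=q)


class TestCoulomb:
    def test_unit_charge_at_2A(self):
        phi = coulomb_potential((0, 0, 0), env_of(((2.0, 0, 0), 1.0)))
        assert round(phi, 2) == 166.03

    def test_superposition(self):
        e1 = env_of(((2.0, 0, 0), 1.0))
        e2 = env_of(((0, 3.0, 0), -0.5))
        both = env_of(((2.0, 0, 0), 1.0), ((0, 3.0, 0), -0.5))
        p = (0.1, 0.2, 0.3)
        assert coulomb_potential(p, both) == pytest.approx(
            coulomb_potential(p, e1) + coulomb_potential(p, e2), rel=1e-12
        )

    def test_zero_charges(self):
        assert coulomb_potential((0, 0, 0), env_of(((1, 1, 1), 0.0))) == 0.0

    def test_coincident_point_rejected(self):
        with pytest.raises(SingularityError):
            coulomb_potential((2.0, 0, 0), env_of(((2.0, 0, 0), 1.0)))

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(0)
        pos = rng.uniform(-5, 5, (4, 3))
        q = rng.uniform(-1, 1, 4)
        point = np.array([1.0, -2.0, 0.5])
        m = rng.normal(size=(3, 3))
        rot, r = np.linalg.qr(m)
        rot *= np.sign(np.diag(r))
        shift = np.array([10.0, -3.0, 7.0])
        before = coulomb_potential(point, ChargedEnvironment(pos, q))
        after = coulomb_potential(
            rot @ point + shift, ChargedEnvironment(pos @ rot.T + shift, q)
        )
        assert before == pytest.approx(after, rel=1e-12)


def charged_pocket():
    atoms = [
        make_atom(1, "N15", "N", (0, 0, 0), charge=0.56, resname="RET"),
        make_atom(2, "C15", "C", (-1.4, 0, 0), charge=0.44, resname="RET"),
        make_atom(3, "OE1", "O", (0, 6.0, 0), charge=-1.0, resname="GLU", resid=194),
        make_atom(4, "CD", "C", (0, 7.2, 0), charge=0.5, resname="GLU", resid=194),
        make_atom(5, "O", "O", (4.0, 0, 0), charge=-0.834, resname="HOH", resid=401),
        make_atom(6, "O", "O", (20.0, 0, 0), charge=-0.834, resname="HOH", resid=402),
    ]
    return Frame(atoms=atoms)


class TestSelectEnvironment:
    def test_large_cutoff_includes_all_non_center(self):
        env = select_environment(charged_pocket(), Selection(resnames={"RET"}), 100.0)
        assert len(env) == 4
        assert "RET1" not in env.labels

    def test_tiny_cutoff_empty(self):
        env = select_environment(charged_pocket(), Selection(resnames={"RET"}), 1e-9)
        assert len(env) == 0

    def test_whole_residue_rule(self):
        # GLU 194: OE1 at 6.0 Å is inside a 6.5-Å cutoff, CD at 7.2 Å is not;
        # both atoms must enter together
        env = select_environment(charged_pocket(), Selection(resnames={"RET"}), 6.5)
        assert sorted(env.labels) == ["GLU194", "GLU194", "HOH401"]

    def test_membership_monotone_in_cutoff(self):
        frame = charged_pocket()
        sizes = [
            len(select_environment(frame, Selection(resnames={"RET"}), c))
            for c in (2.0, 5.0, 8.0, 25.0, 100.0)
        ]
        assert sizes == sorted(sizes)

    def test_missing_charges_rejected(self):
        frame = charged_pocket()
        frame.atoms[3].charge = None
        with pytest.raises(ValidationError):
            select_environment(frame, Selection(resnames={"RET"}), 10.0)


class TestVdwSurface:
    def test_single_carbon_keeps_all_points(self):
        frame = Frame([make_atom(1, "C", "C", (0, 0, 0))])
        pts, owners = vdw_surface(frame, 200)
        assert len(pts) == 200
        np.testing.assert_allclose(
            np.linalg.norm(pts, axis=1), vdw_radius("C"), atol=1e-9
        )
        assert set(owners) == {0}

    def test_overlapping_spheres_lose_points(self):
        frame = Frame(
            [
                make_atom(1, "C", "C", (0, 0, 0)),
                make_atom(2, "C", "C", (1.0, 0, 0)),
            ]
        )
        pts, owners = vdw_surface(frame, 200)
        assert len(pts) < 400
        assert {0, 1} == set(owners)

    def test_exhaustive_containment_oracle(self):
        rng = np.random.default_rng(5)
        atoms = [
            make_atom(i + 1, "C", "CNOS"[i % 4], rng.uniform(-2, 2, 3))
            for i in range(6)
        ]
        frame = Frame(atoms)
        pts, owners = vdw_surface(frame, 64)
        centers = frame.coords
        radii = np.array([vdw_radius(a.element) for a in frame.atoms])
        for p, o in zip(pts, owners):
            assert abs(np.linalg.norm(p - centers[o]) - radii[o]) < 1e-6
            for j in range(len(atoms)):
                if j != o:
                    assert np.linalg.norm(p - centers[j]) >= radii[j] - 1e-9

    def test_unknown_element_rejected(self):
        frame = Frame([make_atom(1, "X", "Xx", (0, 0, 0))])
        with pytest.raises(ValidationError):
            vdw_surface(frame, 10)

    def test_fibonacci_sphere_is_unit_and_spread(self):
        pts = fibonacci_sphere(500)
        np.testing.assert_allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)
        assert np.linalg.norm(pts.mean(axis=0)) < 0.01


class TestProjection:
    def test_negative_charge_localises_negative_lobe(self):
        frame = Frame(
            [
                make_atom(1, "C1", "C", (0, 0, 0)),
                make_atom(2, "C2", "C", (8.0, 0, 0)),
            ]
        )
        pts, owners = vdw_surface(frame, 100)
        env = env_of(((10.5, 0, 0), -1.0))
        smap = project_potential(pts, owners, env)
        assert smap.owner_atom[int(np.argmin(smap.potential))] == 1
        assert smap.potential.min() < 0

    def test_linearity_in_charges(self):
        frame = Frame([make_atom(1, "C", "C", (0, 0, 0))])
        pts, owners = vdw_surface(frame, 50)
        e1 = env_of(((4.0, 1.0, 0), -0.5), ((0, -5.0, 1.0), 0.3))
        e2 = ChargedEnvironment(e1.positions, 2.0 * e1.charges)
        m1 = project_potential(pts, owners, e1)
        m2 = project_potential(pts, owners, e2)
        np.testing.assert_allclose(m2.potential, 2.0 * m1.potential, rtol=1e-12)

    def test_mirror_symmetry_on_linear_molecule(self):
        # three collinear atoms symmetric about the origin; mirroring the
        # environment through the center mirrors the potential map
        frame = Frame(
            [
                make_atom(1, "C1", "C", (-3.0, 0, 0)),
                make_atom(2, "C2", "C", (0, 0, 0)),
                make_atom(3, "C3", "C", (3.0, 0, 0)),
            ]
        )
        pts, owners = vdw_surface(frame, 80)
        env = env_of(((6.0, 2.0, 1.0), -1.0))
        mirrored_env = env_of(((-6.0, 2.0, 1.0), -1.0))
        phi = project_potential(pts, owners, env).potential
        mirror = np.array([-1.0, 1.0, 1.0])
        phi_mirror_pts = np.array(
            [coulomb_potential(p * mirror, mirrored_env) for p in pts]
        )
        np.testing.assert_allclose(phi, phi_mirror_pts, rtol=1e-10)

    def test_empty_environment_rejected(self):
        frame = Frame([make_atom(1, "C", "C", (0, 0, 0))])
        pts, owners = vdw_surface(frame, 10)
        with pytest.raises(ValidationError):
            project_potential(pts, owners, ChargedEnvironment(np.empty((0, 3)), np.empty(0)))


def toy_chromophore():
    return Frame(
        [
            make_atom(1, "N15", "N", (0, 0, 0), resname="RET"),
            make_atom(2, "C15", "C", (-1.4, 0, 0), resname="RET"),
            make_atom(3, "H15", "H", (1.0, 0, 0), resname="RET"),
            make_atom(4, "C1", "C", (-11.0, 0, 0), resname="RET"),
            make_atom(5, "C2", "C", (-12.4, 0, 0), resname="RET"),
        ]
    )


SB = Selection(atom_names={"N15", "C15", "H15"})
RING = Selection(atom_names={"C1", "C2"})


class TestTuningDescriptor:
    def test_anion_near_schiff_base_predicts_blue_shift(self):
        env = env_of(((0, 3.0, 0), -1.0))
        td = tuning_descriptor(toy_chromophore(), env, SB, RING)
        assert td.delta < 0
        assert td.predicts_blue_shift

    def test_symmetric_charge_gives_zero_delta(self):
        frame = Frame(
            [
                make_atom(1, "N15", "N", (2.0, 0, 0), resname="RET"),
                make_atom(2, "C1", "C", (-2.0, 0, 0), resname="RET"),
            ]
        )
        env = env_of(((0, 4.0, 0), -1.0))
        td = tuning_descriptor(
            frame, env, Selection(atom_names={"N15"}), Selection(atom_names={"C1"})
        )
        assert td.delta == pytest.approx(0.0, abs=1e-12)

    def test_delta_monotone_as_charge_slides_toward_schiff_base(self):
        frame = toy_chromophore()
        deltas = []
        for x in np.linspace(-12.0, 0.0, 13):
            env = env_of(((x, 3.5, 0), -1.0))
            deltas.append(tuning_descriptor(frame, env, SB, RING).delta)
        assert all(b < a for a, b in zip(deltas, deltas[1:]))

    def test_empty_region_rejected(self):
        env = env_of(((0, 3.0, 0), -1.0))
        with pytest.raises(SelectionError):
            tuning_descriptor(
                toy_chromophore(), env, Selection(atom_names={"ZZ"}), RING
            )

    def test_9cis_ensemble_has_most_negative_schiff_base_potential(self):
        # ensemble-mean phi_sb over the three packaged isomer pockets:
        # the 9-cis model (closest tyrosine, most waters) stabilises the
        # protonated Schiff base the most
        from retspec.synthetic_data import Seed, generate_trajectory, load_fixture

        means = {}
        for isomer in ("9-cis", "11-cis", "all-trans"):
            traj = generate_trajectory(load_fixture(isomer), 200, Seed(21))
            phis = []
            for fr in traj.frames:
                env = select_environment(fr, Selection(resnames={"RET"}), 50.0)
                phis.append(tuning_descriptor(fr, env).phi_sb)
            means[isomer] = np.mean(phis)
        assert means["9-cis"] < means["11-cis"] < means["all-trans"]
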