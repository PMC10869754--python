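"""Structural collective variables: alignment, translocation/rotation,
displacement charge, salt bridges, hydrogen bonds."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from vsdga import features as ft


def _rotmat(axis, deg):
    axis = np.asarray(axis) / np.linalg.norm(axis)
    a = np.radians(deg)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * K @ K


def _frame(coords, **kw):
    n = len(coords)
    return ft.StructureFrame(coords=coords,
                             atom_names=kw.pop("names", [f"C{i}" for i in range(n)]),
                             residue_ids=kw.pop("resids", np.arange(n)), **kw)


@pytest.fixture
def helix_frame():
    """Idealized helix: 3.6 residues/turn, 1.5 A rise, radius 2.3 A."""
    t = np.arange(18) * (2 * np.pi / 3.6)
    coords = np.column_stack([2.3 * np.cos(t), 2.3 * np.sin(t), 1.5 * np.arange(18)])
    return _frame(coords)


class TestKabschAlign:
    def test_identity_when_equal(self, helix_frame):
        aligned, R, rmsd = ft.kabsch_align(helix_frame, helix_frame,
                                           np.arange(18))
        np.testing.assert_allclose(R, np.eye(3), atol=1e-10)
        assert rmsd < 1e-10

    def test_inverts_known_rotation(self, helix_frame):
        R30 = _rotmat([0, 0, 1], 30.0)
        moved = _frame(helix_frame.coords @ R30.T + [1.0, -2.0, 0.5])
        aligned, R, rmsd = ft.kabsch_align(moved, helix_frame, np.arange(18))
        assert rmsd < 1e-10
        np.testing.assert_allclose(aligned.coords, helix_frame.coords, atol=1e-9)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-10)

    def test_beats_rotation_grid_search(self, helix_frame):
        """Kabsch RMSD is below a brute-force scan over rotations about
        random axes (global optimality check on noisy data)."""
        rng = np.random.default_rng(0)
        noisy = _frame(helix_frame.coords @ _rotmat([1, 1, 0], 40.0).T
                       + 0.3 * rng.standard_normal((18, 3)))
        _, _, rmsd = ft.kabsch_align(noisy, helix_frame, np.arange(18))
        ref = helix_frame.coords - helix_frame.coords.mean(0)
        mob = noisy.coords - noisy.coords.mean(0)
        best = np.inf
        for _ in range(600):
            ax = rng.standard_normal(3)
            ang = rng.uniform(0, 360)
            trial = mob @ _rotmat(ax, ang).T
            best = min(best, np.sqrt(np.mean(np.sum((trial - ref) ** 2, -1))))
        assert rmsd <= best + 1e-9

    def test_collinear_selection_rejected(self):
        coords = np.column_stack([np.zeros(5), np.zeros(5), np.arange(5.0)])
        frame = _frame(coords)
        with pytest.raises(ValueError, match="collinear"):
            ft.kabsch_align(frame, frame, np.arange(5))


class TestDistanceZ:
    def test_identity_zero(self, helix_frame):
        assert ft.distance_z(helix_frame, helix_frame, np.arange(18)) == pytest.approx(0.0, abs=1e-12)

    def test_translation_along_axis(self, helix_frame):
        ax = ft.principal_axis(helix_frame, np.arange(18))
        moved = _frame(helix_frame.coords + 2.0 * ax)
        d = ft.distance_z(moved, helix_frame, np.arange(18), axis=ax)
        assert d == pytest.approx(2.0, abs=1e-9)

    def test_rotation_about_axis_invariant(self, helix_frame):
        ax = ft.principal_axis(helix_frame, np.arange(18))
        com = helix_frame.com(np.arange(18))
        moved = _frame((helix_frame.coords - com) @ _rotmat(ax, 25).T + com)
        d = ft.distance_z(moved, helix_frame, np.arange(18), axis=ax)
        assert abs(d) < 1e-9

    def test_empty_selection_rejected(self, helix_frame):
        with pytest.raises(ValueError, match="empty"):
            ft.distance_z(helix_frame, helix_frame, np.array([], dtype=int))


class TestSpinAngle:
    def test_identity_zero(self, helix_frame):
        assert ft.spin_angle(helix_frame, helix_frame, np.arange(18)) == pytest.approx(0.0, abs=1e-10)

    def test_constructed_rotation_recovered(self, helix_frame):
        sel = np.arange(18)
        ax = ft.principal_axis(helix_frame, sel)
        com = helix_frame.com(sel)
        rot = _frame((helix_frame.coords - com) @ _rotmat(ax, -60).T + com)
        theta = ft.spin_angle(rot, helix_frame, sel, axis=ax)
        assert theta == pytest.approx(-60.0, abs=1e-8)

    def test_antisymmetry_small_rotations(self, helix_frame):
        sel = np.arange(18)
        ax = ft.principal_axis(helix_frame, sel)
        com = helix_frame.com(sel)
        rot = _frame((helix_frame.coords - com) @ _rotmat(ax, 7.5).T + com)
        fwd = ft.spin_angle(rot, helix_frame, sel, axis=ax)
        bwd = ft.spin_angle(helix_frame, rot, sel, axis=ax)
        assert fwd == pytest.approx(-bwd, abs=1e-8)

    def test_matches_grid_scan(self, helix_frame):
        """Closed-form angle equals the argmin of a fine brute-force RMSD
        scan over rotations about the axis."""
        rng = np.random.default_rng(1)
        sel = np.arange(18)
        ax = ft.principal_axis(helix_frame, sel)
        com = helix_frame.com(sel)
        target = _frame((helix_frame.coords - com) @ _rotmat(ax, 23.4).T + com
                        + 0.05 * rng.standard_normal((18, 3)))
        theta = ft.spin_angle(target, helix_frame, sel, axis=ax)
        grid = np.arange(-180.0, 180.0, 0.01)
        ref = target.coords[sel] - target.com(sel)
        base = helix_frame.coords[sel] - com
        m = helix_frame.masses[sel][:, None]
        best, best_t = np.inf, None
        for t in grid[np.abs(grid - theta) < 1.0]:  # scan near the answer
            trial = base @ _rotmat(ax, t).T
            r = np.sum(m * (trial - ref) ** 2)
            if r < best:
                best, best_t = r, t
        assert theta == pytest.approx(best_t, abs=0.01)

    def test_atoms_on_axis_rejected(self):
        coords = np.column_stack([np.zeros(4), np.zeros(4), np.arange(4.0)])
        frame = _frame(coords)
        with pytest.raises(ValueError, match="axis"):
            ft.spin_angle(frame, frame, np.arange(4), axis=np.array([0, 0, 1.0]))


class TestDisplacementCharge:
    def _frame(self, z, q, Lz=80.0):
        z = np.asarray(z, dtype=float)
        n = len(z)
        coords = np.column_stack([np.zeros(n), np.zeros(n), z])
        return ft.StructureFrame(coords=coords, atom_names=["X"] * n,
                                 residue_ids=np.arange(n),
                                 charges=np.asarray(q, dtype=float),
                                 box_length_z=Lz, unwrapped_z=z)

    def test_midpoint_charge(self):
        assert ft.displacement_charge(self._frame([0.0], [1.0])) == pytest.approx(0.5)

    def test_full_translocation_transfers_unit_charge(self):
        lo = ft.displacement_charge(self._frame([-40.0], [1.0]))
        hi = ft.displacement_charge(self._frame([40.0], [1.0]))
        assert hi - lo == pytest.approx(1.0, abs=1e-12)

    @given(hst.floats(min_value=-30, max_value=30))
    @settings(deadline=None, max_examples=30, derandomize=True)
    def test_neutral_system_shift_invariant(self, dz):
        z = np.array([-5.0, 3.0, 10.0])
        q = np.array([1.0, -0.5, -0.5])
        a = ft.displacement_charge(self._frame(z, q))
        b = ft.displacement_charge(self._frame(z + dz, q))
        assert a == pytest.approx(b, abs=1e-9)

    def test_charged_system_shift_is_linear(self):
        z = np.array([0.0, 5.0])
        q = np.array([1.0, 0.5])
        Lz = 80.0
        a = ft.displacement_charge(self._frame(z, q, Lz))
        b = ft.displacement_charge(self._frame(z + 4.0, q, Lz))
        assert b - a == pytest.approx(q.sum() * 4.0 / Lz, abs=1e-12)

    def test_wrapped_coordinates_forbidden(self):
        f = self._frame([0.0], [1.0])
        f.unwrapped_z = None
        with pytest.raises(ValueError, match="unwrapped"):
            ft.displacement_charge(f)


class TestSaltBridges:
    def test_three_four_five(self):
        coords = np.array([[0, 0, 0], [3, 4, 0]], dtype=float)
        frame = _frame(coords, names=["CZ", "CG"], resids=np.array([1, 2]))
        d = ft.salt_bridge_distances(frame, [((1, "CZ"), (2, "CG"))])
        assert d[0] == pytest.approx(5.0)

    def test_group_center_of_mass_target(self):
        coords = np.array([[0, 0, 0], [0, 0, 0.5], [0, 0, 1.5]], dtype=float)
        frame = _frame(coords, names=["CZ", "O1", "O1"],
                       resids=np.array([1, 2, 3]))
        d = ft.salt_bridge_distances(
            frame, [((1, "CZ"), [(2, "O1"), (3, "O1")])])
        assert d[0] == pytest.approx(1.0)

    def test_printed_residue_groups_give_60_distances(self):
        """The two printed residue groups (5 sensing arginines x 6 acidic
        partners) define (5 x 6) + (5 x 6) = 60 distance features."""
        pairs = ft.committor_distance_pairs()
        assert len(pairs) == 60
        # build a synthetic structure carrying exactly the needed atoms
        rng = np.random.default_rng(2)
        names, resids, coords = [], [], []
        for r in ft.SENSING_ARGININES:
            for nm in ("CA", "CZ"):
                names.append(nm); resids.append(r); coords.append(rng.normal(size=3))
        for resid, resname in ft.ACIDIC_PARTNERS:
            carbon = "CG" if resname == "ASP" else "CD"
            for nm in ("CA", carbon):
                names.append(nm); resids.append(resid); coords.append(rng.normal(size=3))
        frame = ft.StructureFrame(coords=np.array(coords), atom_names=names,
                                  residue_ids=np.array(resids))
        d = ft.salt_bridge_distances(frame, pairs)
        assert d.shape == (60,) and np.all(d > 0)

    def test_unresolvable_atom_lists_candidates(self):
        frame = _frame(np.zeros((1, 3)), names=["CA"], resids=np.array([7]))
        with pytest.raises(KeyError, match="CA"):
            frame.select(7, "CZ")


class TestHydrogenBonds:
    def _dha(self, d_to_a, angle_deg):
        """Donor at origin, H 1 A along x; acceptor placed in-plane so the
        D-H-A angle equals ``angle_deg`` and |D-A| = ``d_to_a``."""
        D = np.array([0.0, 0.0, 0.0])
        H = np.array([1.0, 0.0, 0.0])
        theta = np.radians(angle_deg)
        # law of cosines in triangle D-H-A with |DH| = 1:
        # |DA|^2 = 1 + |HA|^2 - 2 |HA| cos(theta)
        ha = np.cos(theta) + np.sqrt(np.cos(theta) ** 2 - 1.0 + d_to_a**2)
        direction = np.array([-np.cos(theta), np.sin(theta), 0.0])  # from H
        A = H + ha * direction
        coords = np.vstack([D, H, A])
        return _frame(coords, names=["N", "H", "O"], resids=np.array([1, 1, 2]))

    def test_collinear_bond_accepted(self):
        frame = self._dha(2.9, 180.0)
        bonds = ft.hydrogen_bonds(frame, [(0, 1)], [2])
        assert bonds == [(0, 1, 2)]

    def test_distance_cutoff(self):
        frame = self._dha(3.6, 180.0)
        assert ft.hydrogen_bonds(frame, [(0, 1)], [2]) == []

    def test_angle_cutoff(self):
        frame = self._dha(2.9, 90.0)
        assert ft.hydrogen_bonds(frame, [(0, 1)], [2]) == []

    def test_monotone_under_tightening(self):
        rng = np.random.default_rng(3)
        coords = rng.uniform(0, 8, size=(30, 3))
        frame = _frame(coords)
        donors = [(i, i + 1) for i in range(0, 10, 2)]
        acceptors = np.arange(15, 30)
        loose = ft.HBondCriteria(max_heavy_distance=5.0, min_angle=90.0)
        tight = ft.HBondCriteria(max_heavy_distance=3.5, min_angle=120.0)
        got_loose = set(ft.hydrogen_bonds(frame, donors, acceptors, loose))
        got_tight = set(ft.hydrogen_bonds(frame, donors, acceptors, tight))
        assert got_tight <= got_loose

    def test_criteria_validation(self):
        with pytest.raises(ValueError):
            ft.HBondCriteria(max_heavy_distance=-1.0)
        with pytest.raises(ValueError):
            ft.HBondCriteria(min_angle=0.0)
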