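import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ligdyn.geometry import (GeometryError, RotamerState, classify_rotamer,
                             dihedral_from_coords, dihedral_series,
                             distance_series, kabsch_fit, rmsd_series, rmsf)
from ligdyn.structio import SelectionSpec

from _oracles import (brute_rmsd_series_nm, dihedral_acos, horn_quaternion_fit,
                      postfit_rmsd)
from conftest import make_point_traj


def _rot_z(deg):
    a = np.radians(deg)
    return np.array([[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0], [0, 0, 1]])


class TestKabsch:
    def test_identity_on_self(self):
        pts = np.random.default_rng(0).normal(0, 5, (10, 3))
        tr = kabsch_fit(pts, pts)
        assert np.allclose(tr.rotation, np.eye(3), atol=1e-10)
        assert np.allclose(tr.apply(pts), pts, atol=1e-10)

    def test_recovers_exact_rigid_motion(self):
        pts = np.random.default_rng(1).normal(0, 5, (12, 3))
        R, t = _rot_z(90), np.array([1.0, 2.0, 3.0])
        ref = pts @ R.T + t
        tr = kabsch_fit(pts, ref)
        assert np.allclose(tr.apply(pts), ref, atol=1e-8)
        assert np.allclose(tr.rotation, R, atol=1e-8)

    def test_matches_quaternion_oracle_on_random_clouds(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            mob = rng.normal(0, 3, (10, 3))
            ref = rng.normal(0, 3, (10, 3))
            tr = kabsch_fit(mob, ref)
            ours = np.sqrt(np.mean(np.sum((tr.apply(mob) - ref) ** 2, axis=1)))
            assert abs(ours - postfit_rmsd(mob, ref)) < 1e-8

    def test_proper_rotation_even_for_reflected_target(self):
        pts = np.random.default_rng(2).normal(0, 3, (8, 3))
        mirrored = pts * np.array([1, 1, -1])
        tr = kabsch_fit(pts, mirrored)
        assert np.linalg.det(tr.rotation) == pytest.approx(1.0, abs=1e-10)

    def test_weighted_fit_prioritizes_heavy_points(self):
        # two points agree under identity, one outlier: weighting the pair
        # heavily must keep the fit near identity for them
        mob = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [5, 5, 0.0]])
        ref = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [9, 9, 0.0]])
        w = np.array([1e6, 1e6, 1e6, 1.0])
        tr = kabsch_fit(mob, ref, weights=w)
        assert np.allclose(tr.apply(mob)[:3], ref[:3], atol=1e-3)

    def test_too_few_atoms(self):
        with pytest.raises(GeometryError, match="at least 3"):
            kabsch_fit(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_rejected(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0.0]])
        with pytest.raises(GeometryError, match="collinear"):
            kabsch_fit(pts, pts + 1.0)


class TestRmsdSeries:
    def _sel_all(self):
        return SelectionSpec.make(res_name="UNK")

    def test_identical_frames_all_zero(self):
        base = np.random.default_rng(3).normal(0, 4, (6, 3))
        traj = make_point_traj(np.stack([base] * 5))
        s = rmsd_series(traj, fit_sel=self._sel_all(), measure_sel=self._sel_all())
        assert np.allclose(s.values, 0.0, atol=1e-9)
        assert s.values[0] == 0.0
        assert s.units == "nm"

    def test_uniform_displacement_of_measured_atoms(self):
        # fit atoms unchanged, measured atoms displaced by 1 A = 0.1 nm
        rng = np.random.default_rng(4)
        fit = rng.normal(0, 4, (5, 3))
        meas = rng.normal(0, 4, (4, 3))
        f0 = np.vstack([fit, meas])
        f1 = np.vstack([fit, meas + np.array([1.0, 0, 0])])
        names = [f"F{i}" for i in range(5)] + [f"M{i}" for i in range(4)]
        traj = make_point_traj(np.stack([f0, f1]), names=names)
        s = rmsd_series(traj,
                        fit_sel=SelectionSpec.make(atom_name=[f"F{i}" for i in range(5)]),
                        measure_sel=SelectionSpec.make(atom_name=[f"M{i}" for i in range(4)]))
        assert s.values[1] == pytest.approx(0.1, abs=1e-12)

    def test_matches_per_frame_oracle(self, small_traj):
        from ligdyn.structio import resolve_selection
        fit_sel = SelectionSpec.make(atom_name=("N", "CA", "C"), is_ligand=False)
        meas_sel = SelectionSpec.make(is_ligand=True)
        s = rmsd_series(small_traj, fit_sel=fit_sel, measure_sel=meas_sel)
        fit_idx = resolve_selection(small_traj, fit_sel)
        meas_idx = resolve_selection(small_traj, meas_sel)
        oracle = brute_rmsd_series_nm(small_traj, fit_idx, meas_idx, 0)
        assert np.max(np.abs(s.values[1:] - oracle[1:])) < 1e-10

    def test_invariant_under_global_rigid_motion(self, small_traj):
        from ligdyn.structio import TrajectoryFrames
        s0 = rmsd_series(small_traj)
        R, t = _rot_z(37.0), np.array([5.0, -3.0, 11.0])
        moved = TrajectoryFrames(small_traj.atoms, small_traj.coords @ R.T + t,
                                 small_traj.times_ns)
        s1 = rmsd_series(moved)
        assert np.allclose(s0.values, s1.values, atol=1e-9)


class TestRmsf:
    def test_static_trajectory_zero(self):
        base = np.random.default_rng(5).normal(0, 4, (6, 3))
        traj = make_point_traj(np.stack([base] * 4))
        sel = SelectionSpec.make(res_name="UNK")
        r = rmsf(traj, fit_sel=sel, measure_sel=sel)
        assert np.allclose(r.values, 0.0, atol=1e-9)

    def test_alternating_displacement_closed_form(self):
        # one atom oscillates +/- d about its mean along x; fit atoms static
        rng = np.random.default_rng(6)
        fit = rng.normal(0, 5, (4, 3))
        d = 0.7  # A
        frames = []
        for f in range(10):
            probe = np.array([[0.0, 10.0, 0.0]]) + np.array([[d if f % 2 else -d, 0, 0]])
            frames.append(np.vstack([fit, probe]))
        names = ["F0", "F1", "F2", "F3", "P"]
        traj = make_point_traj(np.stack(frames), names=names)
        r = rmsf(traj, fit_sel=SelectionSpec.make(atom_name=("F0", "F1", "F2", "F3")),
                 measure_sel=SelectionSpec.make(atom_name="P"))
        assert r.values[0] == pytest.approx(d / 10.0, abs=1e-12)  # nm

    def test_matches_definition_oracle(self, small_traj):
        from ligdyn.structio import resolve_selection
        fit_sel = SelectionSpec.make(atom_name=("N", "CA", "C"), is_ligand=False)
        meas_sel = SelectionSpec.make(atom_name="CA", is_ligand=False)
        r = rmsf(small_traj, fit_sel=fit_sel, measure_sel=meas_sel)
        fit_idx = resolve_selection(small_traj, fit_sel)
        meas_idx = resolve_selection(small_traj, meas_sel)
        fitted = []
        ref = small_traj.coords[0][fit_idx]
        for f in range(small_traj.n_frames):
            R, t = horn_quaternion_fit(small_traj.coords[f][fit_idx], ref)
            fitted.append(small_traj.coords[f][meas_idx] @ R.T + t)
        fitted = np.stack(fitted)
        mean = fitted.mean(axis=0)
        oracle = np.sqrt(np.mean(np.sum((fitted - mean) ** 2, axis=2), axis=0)) / 10.0
        assert np.max(np.abs(r.values - oracle)) < 1e-10

    def test_invariant_under_frame_reordering(self, small_traj):
        from ligdyn.structio import TrajectoryFrames
        perm = np.random.default_rng(8).permutation(small_traj.n_frames)
        shuffled = TrajectoryFrames(small_traj.atoms, small_traj.coords[perm],
                                    small_traj.times_ns)
        a = rmsf(small_traj, reference_frame=0)
        # same reference geometry: use the frame that moved to position 0
        b = rmsf(shuffled, reference_frame=int(np.where(perm == 0)[0][0]))
        assert np.allclose(np.sort(a.values), np.sort(b.values), atol=1e-9)

    def test_single_frame_rejected(self):
        traj = make_point_traj(np.zeros((1, 4, 3)))
        sel = SelectionSpec.make(res_name="UNK")
        with pytest.raises(GeometryError, match="2 frames"):
            rmsf(traj, fit_sel=sel, measure_sel=sel)


class TestDistances:
    def test_three_four_five(self):
        traj = make_point_traj(np.array([[[0, 0, 0], [3, 4, 0.0]]]), names=["A1", "B1"])
        s = distance_series(traj, SelectionSpec.make(atom_name="A1"),
                            SelectionSpec.make(atom_name="B1"))
        assert s.values[0] == pytest.approx(5.0)
        assert s.units == "A"

    def test_same_atom_zero(self):
        traj = make_point_traj(np.random.default_rng(9).normal(0, 3, (4, 2, 3)),
                               names=["A1", "B1"])
        s = distance_series(traj, SelectionSpec.make(atom_name="A1"),
                            SelectionSpec.make(atom_name="A1"))
        assert np.all(s.values == 0.0)

    def test_multi_atom_selection_rejected(self, small_traj):
        with pytest.raises(GeometryError, match="exactly 1"):
            distance_series(small_traj, SelectionSpec.make(atom_name="CA"),
                            SelectionSpec.make(atom_name="CB"))

    def test_matches_norm_oracle(self, small_traj):
        a = SelectionSpec.make(res_seq=176, atom_name="CA")
        b = SelectionSpec.make(res_seq=188, atom_name="CA")
        s = distance_series(small_traj, a, b)
        from ligdyn.structio import resolve_selection
        ia = resolve_selection(small_traj, a)[0]
        ib = resolve_selection(small_traj, b)[0]
        oracle = [np.linalg.norm(small_traj.coords[f, ia] - small_traj.coords[f, ib])
                  for f in range(small_traj.n_frames)]
        assert np.array_equal(s.values, np.array(oracle))


class TestDihedrals:
    def test_anti_periplanar_is_180(self):
        pts = np.array([[0, 1, 0], [0, 0, 0], [1, 0, 0], [1, -1, 0.0]])
        assert dihedral_from_coords(pts[None])[0] == pytest.approx(180.0)

    def test_mirror_image_negates(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            pts = rng.normal(0, 2, (4, 3))
            a = dihedral_from_coords(pts[None])[0]
            m = dihedral_from_coords((pts * np.array([1, 1, -1]))[None])[0]
            if abs(a) < 179.0:  # at the branch point +180/-180 are identified
                assert m == pytest.approx(-a, abs=1e-9)

    def test_constructed_plus_60_gauche(self):
        # start anti (180), rotate the terminal atom by -120 deg about the
        # central bond to land at +60
        axis = np.array([1.0, 0, 0])
        p0 = np.array([0.0, 1, 0])
        p1 = np.array([0.0, 0, 0])
        p2 = np.array([1.0, 0, 0])
        a = np.radians(-120.0)
        R = np.array([[1, 0, 0],
                      [0, np.cos(a), -np.sin(a)],
                      [0, np.sin(a), np.cos(a)]])
        p3 = p2 + R @ np.array([0.0, -1.0, 0.0])
        val = dihedral_from_coords(np.array([p0, p1, p2, p3])[None])[0]
        assert val == pytest.approx(60.0, abs=1e-6)

    def test_matches_acos_oracle_on_random_geometries(self):
        rng = np.random.default_rng(11)
        pts = rng.normal(0, 3, (1000, 4, 3))
        ours = dihedral_from_coords(pts)
        oracle = np.array([dihedral_acos(p) for p in pts])
        assert np.max(np.abs(ours - oracle)) < 1e-9

    def test_matches_mdanalysis_convention(self):
        MDA = pytest.importorskip("MDAnalysis.lib.distances")
        rng = np.random.default_rng(12)
        pts = rng.normal(0, 3, (50, 4, 3))
        ours = dihedral_from_coords(pts)
        ref = np.degrees(MDA.calc_dihedrals(pts[:, 0], pts[:, 1], pts[:, 2], pts[:, 3]))
        assert np.max(np.abs(ours - ref)) < 1e-3  # float32 reference

    def test_collinear_flagged_nan(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0.0]])
        assert np.isnan(dihedral_from_coords(pts[None])[0])

    def test_series_requires_distinct_atoms(self, small_traj):
        ca9 = SelectionSpec.make(res_seq=9, atom_name="CA")
        n9 = SelectionSpec.make(res_seq=9, atom_name="N")
        c9 = SelectionSpec.make(res_seq=9, atom_name="C")
        with pytest.raises(GeometryError, match="distinct"):
            dihedral_series(small_traj, ca9, n9, c9, ca9)


class TestRotamers:
    @pytest.mark.parametrize("angle,state", [
        (180.0, RotamerState.TRANS),
        (60.0, RotamerState.GAUCHE_PLUS),
        (-60.0, RotamerState.GAUCHE_MINUS),
        (-170.0, RotamerState.TRANS),
        (120.0, RotamerState.GAUCHE_PLUS),   # boundary to upper interval
        (0.0, RotamerState.GAUCHE_MINUS),
        (-120.0, RotamerState.TRANS),
        (150.0, RotamerState.TRANS),
        (-179.9, RotamerState.TRANS),
    ])
    def test_classification(self, angle, state):
        assert classify_rotamer(angle) is state

    @given(st.floats(min_value=-180.0, max_value=180.0,
                     exclude_min=True, allow_nan=False))
    @settings(max_examples=300, deadline=None)
    def test_partition_no_gaps(self, angle):
        assert classify_rotamer(angle) in (RotamerState.GAUCHE_PLUS,
                                           RotamerState.TRANS,
                                           RotamerState.GAUCHE_MINUS)

    def test_out_of_range_rejected(self):
        with pytest.raises(GeometryError):
            classify_rotamer(-180.0)
        with pytest.raises(GeometryError):
            classify_rotamer(200.0)
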