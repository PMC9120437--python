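"""Trajectory reading, site selection, superposition and residue reduction."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from dynawass import trajio
from dynawass.errors import (
    DegenerateGeometryError,
    FormatError,
    NoBindingSiteError,
    PreconditionError,
)
from dynawass.trajio import (
    BindingSite,
    ResidueActivity,
    compute_activity_ratio,
    kabsch,
    load_trajectory,
    residue_centers_of_mass,
    rmsf_per_residue,
    select_binding_site,
    superpose_frames,
)

from conftest import make_ptraj, make_system

PDB_ATOM = (
    "ATOM  {serial:5d} {name:<4s} {res:<3s} A{resid:4d}    "
    "{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {elem:>2s}\n"
)


def write_pdb(path, frames_nm, names, resids, elements, resname="ALA"):
    """Minimal multi-frame PDB writer (coordinates given in nm)."""
    with open(path, "w") as fh:
        for m, frame in enumerate(frames_nm, start=1):
            fh.write(f"MODEL     {m:4d}\n")
            for i, (xyz, name, rid, el) in enumerate(zip(frame, names, resids, elements)):
                x, y, z = (np.asarray(xyz) * 10.0).tolist()  # nm -> Angstrom
                fh.write(
                    PDB_ATOM.format(
                        serial=i + 1, name=name, res=resname, resid=rid, x=x, y=y, z=z, elem=el
                    )
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


class TestLoadTrajectory:
    def test_pdb_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        frames = rng.uniform(0.1, 2.0, size=(3, 5, 3))
        path = tmp_path / "fix.pdb"
        write_pdb(path, frames, ["N", "CA", "C", "O", "CB"], [1] * 5, ["N", "C", "C", "O", "C"])
        traj = load_trajectory(path, frame_interval_ps=2.0)
        assert len(traj.runs) == 1
        # PDB stores 3 decimals in Angstrom -> 1e-4 nm precision
        np.testing.assert_allclose(traj.runs[0], frames, atol=6e-5)
        assert traj.frame_interval_ps == 2.0
        assert [a.element for a in traj.atoms] == ["N", "C", "C", "O", "C"]
        assert traj.atoms[1].is_backbone and traj.atoms[4].is_heavy

    def test_atom_count_mismatch_names_file(self, tmp_path):
        frames5 = np.zeros((1, 5, 3)) + 0.5
        frames6 = np.zeros((2, 6, 3)) + 0.5
        top = tmp_path / "top.pdb"
        bad = tmp_path / "bad.pdb"
        write_pdb(top, frames5, ["CA"] * 5, [1] * 5, ["C"] * 5)
        write_pdb(bad, frames6, ["CA"] * 6, [1] * 6, ["C"] * 6)
        with pytest.raises(FormatError, match="bad.pdb"):
            load_trajectory(top, [top, bad], frame_interval_ps=1.0)

    def test_missing_frame_interval(self, tmp_path):
        path = tmp_path / "x.pdb"
        write_pdb(path, np.full((2, 3, 3), 0.4), ["CA"] * 3, [1, 2, 3], ["C"] * 3)
        with pytest.raises(Exception, match="frame_interval"):
            load_trajectory(path)


def _two_particle_system(distances_nm, dt=2.0):
    """Residue 1 (one C at origin) + ligand residue 9 at given x-distances."""
    frames = np.zeros((len(distances_nm), 2, 3))
    frames[:, 1, 0] = distances_nm
    return make_system(
        [frames], elements=["C", "C"], resids=[1, 9], ligand=(1,), dt=dt, sid="holo"
    )


class TestActivityRatio:
    @pytest.mark.parametrize(
        "dists,expected",
        [
            ([0.3] * 10, 1.0),
            ([0.6] * 10, 0.0),
            ([0.3, 0.3, 0.3, 0.6, 0.6], 0.6),
        ],
    )
    def test_contact_fraction(self, dists, expected):
        traj = _two_particle_system(dists)
        acts = compute_activity_ratio(traj, [1], cutoff_nm=0.5, analysis_window_ps=1e9)
        assert acts[0][1].ratio == pytest.approx(expected)

    def test_apo_system_rejected(self):
        traj = make_system(
            [np.zeros((3, 2, 3)) + 0.1], elements=["C", "C"], resids=[1, 2], sid="apo"
        )
        with pytest.raises(PreconditionError):
            compute_activity_ratio(traj, [1])

    def test_rigid_transform_invariance(self):
        rng = np.random.default_rng(3)
        frames = rng.uniform(0, 1, size=(6, 2, 3))
        base = make_system([frames], elements=["C", "C"], resids=[1, 9], ligand=(1,))
        rot = Rotation.from_rotvec([0.3, -1.0, 0.7]).as_matrix()
        moved = make_system(
            [frames @ rot.T + np.array([5.0, -2.0, 1.0])],
            elements=["C", "C"],
            resids=[1, 9],
            ligand=(1,),
        )
        a = compute_activity_ratio(base, [1], cutoff_nm=0.7, analysis_window_ps=1e9)
        b = compute_activity_ratio(moved, [1], cutoff_nm=0.7, analysis_window_ps=1e9)
        assert a[0][1].ratio == b[0][1].ratio


class TestSelectBindingSite:
    @staticmethod
    def _acts(ratios):
        return {
            rid: ResidueActivity(residue_id=rid, n_contact_frames=int(r * 10), n_total_frames=10)
            for rid, r in ratios.items()
        }

    def test_strict_threshold(self):
        acts = [[self._acts({1: 0.6, 2: 0.5, 3: 0.4})]]
        assert select_binding_site(acts, 0.5).residue_ids == (1,)

    def test_union_over_runs(self):
        acts = [[self._acts({1: 0.9, 2: 0.1}), self._acts({1: 0.1, 2: 0.9})]]
        assert select_binding_site(acts, 0.5).residue_ids == (1, 2)

    def test_order_invariant_and_sorted(self):
        a = [[self._acts({5: 0.9})], [self._acts({2: 0.9})]]
        assert select_binding_site(a, 0.5).residue_ids == (2, 5)
        assert select_binding_site(a[::-1], 0.5).residue_ids == (2, 5)

    def test_no_site_detected(self):
        with pytest.raises(NoBindingSiteError, match="no residue"):
            select_binding_site([[self._acts({1: 0.0, 2: 0.0})]], 0.5)


class TestSuperposition:
    @staticmethod
    def _system(frames):
        n = frames.shape[1]
        return make_system([frames], elements=["C"] * n, resids=list(range(n)), sid="s")

    def test_identity_and_translation(self):
        rng = np.random.default_rng(1)
        ref = rng.normal(size=(5, 3))
        frames = np.stack([ref, ref + np.array([1.0, 0, 0])])
        traj = self._system(frames)
        fitted = superpose_frames(traj, ref, range(5))
        np.testing.assert_allclose(fitted.runs[0][0], ref, atol=1e-10)
        np.testing.assert_allclose(fitted.runs[0][1], ref, atol=1e-10)

    def test_rotation_recovered_vs_quaternion_oracle(self):
        rng = np.random.default_rng(2)
        ref = rng.normal(size=(6, 3))
        rot90 = Rotation.from_euler("z", 90, degrees=True)
        frame = ref @ rot90.as_matrix().T
        traj = self._system(np.stack([frame, frame]))
        fitted = superpose_frames(traj, ref, range(6))
        assert np.sqrt(((fitted.runs[0][0] - ref) ** 2).sum(1).mean()) < 1e-8
        # independent oracle: scipy's quaternion-based alignment
        r_oracle, _ = Rotation.align_vectors(ref - ref.mean(0), frame - frame.mean(0))
        r_ours, _ = kabsch(frame, ref)
        np.testing.assert_allclose(r_ours, r_oracle.as_matrix(), atol=1e-8)

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        frames = rng.normal(size=(4, 5, 3))
        ref = rng.normal(size=(5, 3))
        traj = self._system(frames)
        once = superpose_frames(traj, ref, range(5))
        twice = superpose_frames(once, ref, range(5))
        np.testing.assert_allclose(twice.runs[0], once.runs[0], atol=1e-9)

    def test_collinear_reference_rejected(self):
        ref = np.zeros((4, 3))
        ref[:, 0] = np.arange(4)
        traj = self._system(np.random.default_rng(0).normal(size=(2, 4, 3)))
        with pytest.raises(DegenerateGeometryError):
            superpose_frames(traj, ref, range(4))


class TestCentersOfMass:
    def test_weighted_mean_and_heavy_filter(self):
        # residue 1: C at x=0 and O at x=1 -> COM x = 15.999/28.01
        # residue 2: methane-like, heavy_only -> carbon position
        frames = np.zeros((2, 7, 3))
        frames[:, 1, 0] = 1.0
        frames[:, 2, :] = 0.7  # the methane carbon
        frames[:, 3:, :] = 5.0  # hydrogens far away
        traj = make_system(
            [frames],
            elements=["C", "O", "C", "H", "H", "H", "H"],
            resids=[1, 1, 2, 2, 2, 2, 2],
        )
        pt = residue_centers_of_mass(traj, BindingSite(residue_ids=(1, 2)), heavy_only=True)
        assert pt.runs[0][0, 0, 0] == pytest.approx(15.999 / (12.011 + 15.999))
        np.testing.assert_allclose(pt.runs[0][:, 1, :], 0.7)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(5)
        frames = rng.normal(size=(3, 4, 3))
        v = np.array([0.3, -1.2, 2.0])
        sysa = make_system([frames], elements=["C", "O", "N", "S"], resids=[1, 1, 2, 2])
        sysb = make_system([frames + v], elements=["C", "O", "N", "S"], resids=[1, 1, 2, 2])
        site = BindingSite(residue_ids=(1, 2))
        pa = residue_centers_of_mass(sysa, site)
        pb = residue_centers_of_mass(sysb, site)
        np.testing.assert_allclose(pb.runs[0], pa.runs[0] + v, atol=1e-12)

    def test_missing_residue_is_named(self):
        traj = make_system([np.zeros((2, 1, 3)) + 0.2], elements=["C"], resids=[1])
        with pytest.raises(PreconditionError, match="7"):
            residue_centers_of_mass(traj, BindingSite(residue_ids=(7,)))


class TestRMSF:
    def test_static_and_alternating(self):
        static = make_ptraj([np.full((10, 1, 3), 0.3)])
        np.testing.assert_allclose(rmsf_per_residue(static), 0.0, atol=1e-14)
        frames = np.zeros((10, 1, 3))
        frames[::2, 0, 0] = 0.2
        frames[1::2, 0, 0] = -0.2
        assert rmsf_per_residue(make_ptraj([frames]))[0] == pytest.approx(0.2)

    def test_isotropic_gaussian_scaling(self):
        rng = np.random.default_rng(6)
        s = 0.05
        frames = rng.normal(scale=s, size=(200_000, 2, 3))
        rmsf = rmsf_per_residue(make_ptraj([frames]))
        np.testing.assert_allclose(rmsf, s * np.sqrt(3), rtol=0.02)

    def test_burn_in_exhausts_frames(self):
        pt = make_ptraj([np.zeros((5, 1, 3))], dt=1.0)
        with pytest.raises(PreconditionError):
            rmsf_per_residue(pt, burn_in_ps=10.0)


def test_particle_trajectory_hdf5_round_trip(tmp_path):
    rng = np.random.default_rng(7)
    pt = make_ptraj([rng.normal(size=(5, 3, 3)), rng.normal(size=(4, 3, 3))], dt=2.0, sid="rt")
    pt.to_hdf5(tmp_path / "p.h5")
    back = pt.from_hdf5(tmp_path / "p.h5")
    assert back.system_id == "rt" and back.frame_interval_ps == 2.0
    for a, b in zip(pt.runs, back.runs):
        np.testing.assert_array_equal(a, b)
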