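import numpy as np
import pytest

from gafdyn.datamodel import FormatError
from gafdyn.synthetic import gen_rocking_trajectory, gen_water_paths, _write_xyz
from gafdyn.trajectory import (
    HBondCriteria,
    TrajectorySeries,
    count_permeations,
    dcc_matrix,
    hb_occupancy,
    helix_angle_series,
    read_trajectory,
)


def _random_walk_traj(n_frames=200, n_atoms=10, seed=0, dt_ns=0.1):
    rng = np.random.default_rng(seed)
    coords = rng.normal(0, 1.0, (n_frames, n_atoms, 3)).cumsum(axis=0) * 0.01
    coords += rng.uniform(-5, 5, (1, n_atoms, 3))
    return TrajectorySeries(coords, dt_ns, ["CA"] * n_atoms, np.arange(n_atoms))


class TestReadTrajectory:
    def test_multiframe_pdb_roundtrip(self, tmp_path, helix20):
        from gafdyn.structure import write_pdb

        p = tmp_path / "traj.pdb"
        frames = []
        base = np.concatenate([
            [helix20.residues[i][a] for a in ("N", "CA", "C")]
            for i in helix20.residue_numbers()])
        with open(p, "w") as fh:
            for f in range(5):
                fh.write(f"MODEL     {f + 1}\n")
                serial = 1
                for i in helix20.residue_numbers():
                    for a in ("N", "CA", "C"):
                        x, y, z = helix20.residues[i][a] + f * 0.1
                        fh.write(f"ATOM  {serial:5d}  {a:<3s}ALA A{i:4d}    "
                                 f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           "
                                 f"{a[0]}\n")
                        serial += 1
                fh.write("ENDMDL\n")
        t = read_trajectory(p, dt_ns=0.5)
        assert t.n_frames == 5 and t.n_atoms == 60
        np.testing.assert_allclose(t.coordinates[3], base + 0.3, atol=2e-3)

    def test_shuffled_models_canonicalized(self, tmp_path):
        p = tmp_path / "shuf.pdb"
        atoms = [("N", 1.0), ("CA", 2.0), ("C", 3.0)]
        with open(p, "w") as fh:
            for f, order in enumerate([atoms, atoms[::-1]]):
                fh.write(f"MODEL     {f + 1}\n")
                for s, (name, x) in enumerate(order, 1):
                    fh.write(f"ATOM  {s:5d}  {name:<3s}ALA A   1    "
                             f"{x + f:8.3f}{0.0:8.3f}{0.0:8.3f}  1.00  0.00"
                             f"           {name[0]}\n")
                fh.write("ENDMDL\n")
        t = read_trajectory(p)
        assert t.atom_names == ["N", "CA", "C"]
        # frame 2 reordered back to frame-1 atom identity order
        np.testing.assert_allclose(t.coordinates[1, :, 0], [2.0, 3.0, 4.0])

    def test_xyz_frame_count(self, tmp_path):
        series, _ = gen_rocking_trajectory(n_res=8, n_frames=100, seed=0)
        p = tmp_path / "t.xyz"
        _write_xyz(series, p)
        back = read_trajectory(p)
        assert back.n_frames == 100
        assert back.n_atoms == 8

    def test_empty_selection_rejected(self, tmp_path):
        t = _random_walk_traj()
        with pytest.raises(ValueError, match="0 atoms"):
            t.select(names=["ZZ"])

    def test_inconsistent_atom_count_rejected(self, tmp_path):
        p = tmp_path / "bad.pdb"
        with open(p, "w") as fh:
            fh.write("MODEL     1\n")
            fh.write("ATOM      1  CA AALA A   1       1.000   0.000   0.000"
                     "  1.00  0.00           C\n")
            fh.write("ATOM      2  C  AALA A   1       2.000   0.000   0.000"
                     "  1.00  0.00           C\nENDMDL\nMODEL     2\n")
            fh.write("ATOM      1  CA AALA A   1       1.000   0.000   0.000"
                     "  1.00  0.00           C\nENDMDL\n")
        with pytest.raises(FormatError):
            read_trajectory(p)

    def test_wrapped_trajectory_guard(self, tmp_path):
        coords = np.zeros((3, 2, 3))
        coords[1, :, 0] = 40.0  # jump beyond half the declared box
        t = TrajectorySeries(coords, 0.1, ["C", "C"], np.array([1, 2]))
        p = tmp_path / "wrap.xyz"
        _write_xyz(t, p)
        with pytest.raises(ValueError, match="wrapped"):
            read_trajectory(p, box=20.0)


class TestDCC:
    def test_unit_diagonal(self):
        d = dcc_matrix(_random_walk_traj(), window_ns=2.0)
        assert np.allclose(np.diag(d.matrix), 1.0)

    def test_rigid_translation_perfectly_correlated(self):
        n_frames, n_atoms = 400, 8
        rng = np.random.default_rng(1)
        drift = rng.normal(0, 1, (n_frames, 1, 3)).cumsum(axis=0)
        base = rng.uniform(-5, 5, (1, n_atoms, 3))
        t = TrajectorySeries(base + drift, 0.1, ["CA"] * n_atoms, np.arange(n_atoms))
        d = dcc_matrix(t, window_ns=4.0)
        assert np.allclose(d.matrix, 1.0, atol=1e-10)

    def test_independent_noise_decorrelated(self):
        rng = np.random.default_rng(2)
        coords = rng.normal(0, 1, (4000, 12, 3))
        t = TrajectorySeries(coords, 0.1, ["CA"] * 12, np.arange(12))
        d = dcc_matrix(t, window_ns=400.0)
        off = d.matrix[~np.eye(12, dtype=bool)]
        assert np.abs(off).mean() < 0.05

    def test_rotation_translation_invariance(self):
        t = _random_walk_traj(seed=3)
        from gafdyn.synthetic import _rodrigues

        R = _rodrigues(np.array([1.0, 2.0, 0.5]), 0.8)
        moved = TrajectorySeries(t.coordinates @ R.T + np.array([3.0, -1.0, 7.0]),
                                 t.dt_ns, t.atom_names, t.residue_numbers)
        a = dcc_matrix(t, 2.0).matrix
        b = dcc_matrix(moved, 2.0).matrix
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_zero_variance_atom_flagged_not_nan(self):
        coords = np.random.default_rng(0).normal(0, 1, (100, 3, 3))
        coords[:, 2] = 5.0  # frozen atom
        t = TrajectorySeries(coords, 0.1, ["CA"] * 3, np.arange(3))
        d = dcc_matrix(t, 10.0)
        assert d.undefined[2, 0] and d.undefined[2, 2]
        assert np.isfinite(d.matrix[:2, :2]).all()


class TestHelixAngles:
    def test_first_frame_is_zero(self):
        series, _ = gen_rocking_trajectory(n_res=12, n_frames=150, seed=0)
        angles = helix_angle_series(series)
        assert angles[0] == 0.0

    def test_constructed_rigid_rotation_recovered(self, helix20):
        from gafdyn.synthetic import _rodrigues
        from gafdyn.structure import helix_axis

        nums = helix20.residue_numbers()
        ca = np.array([helix20.residues[i]["CA"] for i in nums])
        axis = helix_axis(helix20)
        perp = np.cross(axis, [1.0, 0, 0])
        perp /= np.linalg.norm(perp)
        R = _rodrigues(perp, np.deg2rad(10.0))
        c = ca - ca.mean(axis=0)
        t = TrajectorySeries(np.stack([c, c @ R.T]), 0.1, ["CA"] * len(nums),
                             np.array(nums))
        angles = helix_angle_series(t)
        assert angles[1] == pytest.approx(10.0, abs=0.1)

    def test_rocking_sd_recovered(self):
        from gafdyn.trajectory import rocking_sd_estimate

        for seed in (0, 1, 2):
            series, truth = gen_rocking_trajectory(
                n_res=16, rock_sd_deg=10.0, corr_time_ns=5.0, dt_ns=1.0,
                n_frames=10_000, seed=seed)
            assert rocking_sd_estimate(series) == pytest.approx(10.0, rel=0.15)

    def test_rocking_series_stationary(self):
        series, _ = gen_rocking_trajectory(
            n_res=16, rock_sd_deg=10.0, corr_time_ns=5.0, dt_ns=1.0,
            n_frames=10_000, seed=1)
        angles = np.deg2rad(helix_angle_series(series))
        half = len(angles) // 2
        sd1, sd2 = angles[:half].std(), angles[half:].std()
        assert abs(sd1 - sd2) / sd1 < 0.2

    def test_collinear_coordinates_rejected(self):
        coords = np.zeros((3, 5, 3))
        coords[:, :, 2] = np.arange(5)
        t = TrajectorySeries(coords, 0.1, ["CA"] * 5, np.arange(5))
        with pytest.raises(ValueError, match="degenerate"):
            helix_angle_series(t)


class TestPermeation:
    def test_single_monotone_crossing(self):
        z = np.linspace(-20, 20, 100)
        rec = count_permeations(z, -15, 15, dt_ns=0.1)
        assert rec.events == 1
        assert rec.directions == ["+z"]

    def test_same_side_oscillation_scores_nothing(self):
        t = np.linspace(0, 50 * 2 * np.pi, 5000)
        z = -20 + 10 * (1 + np.sin(t)) / 1.0  # enters slab, re-exits below
        rec = count_permeations(z, -15, 15, dt_ns=0.1)
        assert rec.events == 0

    def test_scheduled_crossings_counted_exactly(self):
        sched = [
            [{"kind": "cross", "start": 0, "end": 50, "direction": +1},
             {"kind": "bounce", "start": 100, "end": 150, "direction": +1},
             {"kind": "cross", "start": 200, "end": 260, "direction": -1},
             {"kind": "cross", "start": 300, "end": 360, "direction": +1}],
            [{"kind": "cross", "start": 10, "end": 80, "direction": -1},
             {"kind": "cross", "start": 120, "end": 180, "direction": +1}],
            [{"kind": "cross", "start": 40, "end": 90, "direction": +1},
             {"kind": "bounce", "start": 120, "end": 170, "direction": -1},
             {"kind": "cross", "start": 200, "end": 300, "direction": -1}],
        ]
        z, truth = gen_water_paths(sched, n_frames=400, dt_ns=0.1)
        rec = count_permeations(z, -15.0, 15.0, dt_ns=0.1)
        assert rec.events == truth["n_crossings"] == 7
        assert sorted(rec.directions) == sorted(
            e["direction"] for e in truth["events"])

    def test_time_reversal_flips_directions(self):
        sched = [[{"kind": "cross", "start": 5, "end": 60, "direction": +1},
                  {"kind": "cross", "start": 80, "end": 140, "direction": -1}]]
        z, _ = gen_water_paths(sched, n_frames=200)
        fwd = count_permeations(z, -15, 15)
        rev = count_permeations(z[:, ::-1], -15, 15)
        assert fwd.events == rev.events
        flip = {"+z": "-z", "-z": "+z"}
        assert sorted(rev.directions) == sorted(flip[d] for d in fwd.directions)

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            count_permeations(np.zeros(10), 5.0, -5.0)


class TestHBonds:
    def test_always_bound(self):
        n = 50
        donor = np.zeros((n, 3))
        hydrogen = np.tile([1.0, 0, 0], (n, 1))
        acc = np.tile([2.8, 0, 0], (n, 1))  # linear D-H...A, d(DA)=2.8
        rep = hb_occupancy(donor, hydrogen, {"w1": acc})
        assert rep.occupancy == 1.0
        assert rep.n_partners == 1

    def test_never_bound(self):
        n = 50
        donor = np.zeros((n, 3))
        hydrogen = np.tile([1.0, 0, 0], (n, 1))
        acc = np.tile([9.0, 0, 0], (n, 1))
        rep = hb_occupancy(donor, hydrogen, {"w1": acc})
        assert rep.occupancy == 0.0 and rep.n_partners == 0

    def test_three_partners_disjoint_windows(self):
        n = 90
        donor = np.zeros((n, 3))
        hydrogen = np.tile([1.0, 0, 0], (n, 1))
        far = np.array([9.0, 0, 0])
        near = np.array([2.8, 0, 0])
        accs = {}
        for k, (lo, hi) in enumerate([(0, 30), (30, 60), (60, 80)]):
            a = np.tile(far, (n, 1))
            a[lo:hi] = near
            accs[f"w{k}"] = a
        rep = hb_occupancy(donor, hydrogen, accs, dt_ns=0.1)
        assert rep.n_partners == 3
        assert rep.occupancy == pytest.approx(80 / 90)
        assert rep.partner_occupancy["w0"] == pytest.approx(30 / 90)

    def test_angle_criterion_enforced(self):
        n = 10
        donor = np.zeros((n, 3))
        hydrogen = np.tile([1.0, 0, 0], (n, 1))
        acc = np.tile([1.0, 1.8, 0.0], (n, 1))  # ~90 deg D-H-A, close enough
        rep = hb_occupancy(donor, hydrogen, {"w": acc},
                           HBondCriteria(max_da_distance=3.5, min_dha_angle_deg=150))
        assert rep.occupancy == 0.0
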