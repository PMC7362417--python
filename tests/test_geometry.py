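"""Geometry metrics: closed-form values and rigid-motion invariance."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from nucleowrap.errors import GeometryError, SelectionError, TopologyError
from nucleowrap.geometry import (
    SeriesStat,
    angle,
    end_to_end_series,
    radius_of_gyration,
    rmsd_series,
    rmsf_per_residue,
    superpose,
)
from nucleowrap.model import ChainInfo, NucleoAssembly, Selection, Trajectory
from nucleowrap.synth import BreathingSpec, SuperhelixSpec, make_breathing_trajectory, make_wrapped_ncp


def _point_cloud_assembly(coords):
    n = len(coords)
    return NucleoAssembly(
        chains=[ChainInfo("A", "histone")],
        chain_id=np.array(["A"] * n),
        res_id=np.arange(1, n + 1),
        res_name=np.array(["ALA"] * n),
        atom_name=np.array(["CA"] * n),
        element=np.array(["C"] * n),
        coord=np.asarray(coords, dtype=float),
    )


class TestRmsd:
    def test_reference_against_itself_is_zero(self):
        rng = np.random.default_rng(0)
        a = _point_cloud_assembly(rng.normal(size=(10, 3)) * 5)
        traj = Trajectory(a, a.coord[None])
        assert rmsd_series(traj).values[0] == pytest.approx(0.0, abs=1e-9)

    def test_invariant_under_rigid_motion(self):
        rng = np.random.default_rng(1)
        coords = rng.normal(size=(20, 3)) * 8
        rot = Rotation.from_euler("z", 90, degrees=True)
        moved = rot.apply(coords) + np.array([10.0, 0.0, 0.0])
        a = _point_cloud_assembly(coords)
        traj = Trajectory(a, np.stack([coords, moved]))
        out = rmsd_series(traj, ref=0)
        assert out.values[1] == pytest.approx(0.0, abs=1e-6)

    def test_hand_computed_single_displacement_no_fit(self):
        coords = np.zeros((10, 3))
        coords[:, 0] = np.arange(10) * 10.0
        moved = coords.copy()
        moved[3, 1] += 5.0
        a = _point_cloud_assembly(coords)
        traj = Trajectory(a, np.stack([coords, moved]))
        out = rmsd_series(traj, ref=0, superpose_fit=False)
        assert out.values[1] == pytest.approx(math.sqrt(25 / 10), abs=1e-9)

    def test_underdetermined_fit_rejected(self):
        a = _point_cloud_assembly([[0, 0, 0], [1, 0, 0]])
        traj = Trajectory(a, a.coord[None])
        with pytest.raises(SelectionError):
            rmsd_series(traj)


class TestEndToEnd:
    def test_known_distance(self):
        spec = SuperhelixSpec(n_bp=2, atoms_per_bp=1)
        ncp = make_wrapped_ncp(spec)
        coords = ncp.coord.copy()
        coords[ncp.entry_p_index] = [0.0, 0.0, 0.0]
        coords[ncp.exit_p_index] = [72.0, 0.0, 0.0]
        traj = Trajectory(ncp, coords[None])
        assert end_to_end_series(traj).values[0] == pytest.approx(72.0)

    def test_coincident_ends_are_zero(self):
        ncp = make_wrapped_ncp(SuperhelixSpec(n_bp=2, atoms_per_bp=1))
        coords = ncp.coord.copy()
        coords[ncp.exit_p_index] = coords[ncp.entry_p_index]
        assert end_to_end_series(Trajectory(ncp, coords[None])).values[0] == 0.0

    def test_wrapped_superhelix_matches_analytic_chord(self, full_ncp):
        spec = SuperhelixSpec()
        traj = Trajectory(full_ncp, full_ncp.coord[None])
        dtheta = 2 * math.pi * spec.turns
        chord = math.sqrt(2 * spec.superhelix_radius ** 2 * (1 - math.cos(dtheta))
                          + (spec.pitch * spec.turns) ** 2)
        assert end_to_end_series(traj).values[0] == pytest.approx(chord, abs=1e-6)


class TestRg:
    def test_ring_of_points_equals_radius(self):
        r = 7.3
        theta = np.linspace(0, 2 * math.pi, 36, endpoint=False)
        coords = np.column_stack([r * np.cos(theta), r * np.sin(theta),
                                  np.zeros_like(theta)])
        a = _point_cloud_assembly(coords)
        assert radius_of_gyration(a) == pytest.approx(r, rel=1e-9)

    def test_single_point_is_zero(self):
        assert radius_of_gyration(_point_cloud_assembly([[3, 4, 5]])) == 0.0

    def test_two_points_give_half_separation(self):
        d = 4.2
        a = _point_cloud_assembly([[0, 0, 0], [2 * d, 0, 0]])
        assert radius_of_gyration(a) == pytest.approx(d, rel=1e-12)

    def test_invariant_under_rigid_motion(self):
        rng = np.random.default_rng(5)
        coords = rng.normal(size=(30, 3)) * 6
        rot = Rotation.from_rotvec([0.3, -1.2, 0.7])
        a = _point_cloud_assembly(coords)
        b = _point_cloud_assembly(rot.apply(coords) + 42.0)
        assert radius_of_gyration(b) == pytest.approx(radius_of_gyration(a),
                                                      rel=1e-9)


class TestRmsf:
    def test_identical_frames_give_zero(self):
        rng = np.random.default_rng(2)
        a = _point_cloud_assembly(rng.normal(size=(8, 3)) * 5)
        traj = Trajectory(a, np.stack([a.coord] * 4))
        df = rmsf_per_residue(traj, superpose_fit=False)
        assert np.allclose(df["rmsf"], 0.0)

    def test_symmetric_oscillation_amplitude(self):
        coords = np.zeros((5, 3))
        coords[:, 0] = np.arange(5) * 10.0
        up = coords.copy()
        up[2, 0] += 1.7
        down = coords.copy()
        down[2, 0] -= 1.7
        a = _point_cloud_assembly(coords)
        traj = Trajectory(a, np.stack([up, down]))
        df = rmsf_per_residue(traj, superpose_fit=False).set_index("res_id")
        assert df.loc[3, "rmsf"] == pytest.approx(1.7, abs=1e-9)
        assert df.loc[1, "rmsf"] == pytest.approx(0.0, abs=1e-9)

    def test_breathing_makes_termini_more_mobile_than_midpoint(self, small_spec):
        traj = make_breathing_trajectory(
            small_spec, BreathingSpec(k_open=0.3, k_close=0.3, n_unwrap_open=6,
                                      n_frames=60, seed=5))
        df = rmsf_per_residue(
            traj, sel=Selection.p_atoms(),
            fit_sel=Selection.histone_core()).set_index("res_id")
        mid = small_spec.n_bp // 2
        assert df.loc[1, "rmsf"] > df.loc[mid, "rmsf"]
        assert df.loc[small_spec.n_bp, "rmsf"] > df.loc[mid, "rmsf"]

    def test_single_frame_rejected(self):
        a = _point_cloud_assembly(np.zeros((4, 3)))
        with pytest.raises(TopologyError):
            rmsf_per_residue(Trajectory(a, a.coord[None]))


class TestAngle:
    @pytest.mark.parametrize("a,b,c,expected", [
        ((1, 0, 0), (0, 0, 0), (0, 1, 0), 90.0),
        ((1, 0, 0), (0, 0, 0), (1, 1, 0), 45.0),
        ((1, 0, 0), (0, 0, 0), (2, 0, 0), 0.0),
        ((1, 0, 0), (0, 0, 0), (-3, 0, 0), 180.0),
    ])
    def test_hand_derived_values(self, a, b, c, expected):
        assert angle(a, b, c) == pytest.approx(expected, abs=1e-9)

    def test_zero_length_ray_rejected(self):
        with pytest.raises(GeometryError):
            angle((0, 0, 0), (0, 0, 0), (1, 0, 0))

    def test_invariant_under_rigid_motion(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(3, 3)) * 4
        rot = Rotation.from_rotvec([1.0, 0.2, -0.4])
        moved = rot.apply(pts) + 13.0
        assert angle(*moved) == pytest.approx(angle(*pts), abs=1e-9)


class TestSeriesStat:
    def test_cross_replica_mean_and_sd_hand_computed(self):
        reps = [np.array([1.0, 2.0, 3.0]),
                np.array([3.0, 2.0, 1.0]),
                np.array([2.0, 2.0, 2.0])]
        agg = SeriesStat.from_replicas(reps)
        assert np.allclose(agg.frame_mean, [2.0, 2.0, 2.0])
        # population SD: frame 0 of (1,3,2) -> sqrt(2/3)
        assert agg.frame_sd[0] == pytest.approx(math.sqrt(2 / 3))
        assert agg.frame_sd[1] == 0.0
        assert agg.metadata["n_replicas"] == 3

    def test_constant_replica_series(self):
        agg = SeriesStat.from_replicas([np.full(4, 10.0), np.full(4, 20.0)])
        assert np.allclose(agg.frame_mean, 15.0)
        assert np.allclose(agg.frame_sd, 5.0)


def test_superpose_recovers_rigid_transform():
    rng = np.random.default_rng(3)
    ref = rng.normal(size=(12, 3)) * 5
    rot = Rotation.from_euler("xyz", [10, 20, 30], degrees=True)
    mobile = rot.apply(ref) + np.array([1.0, -2.0, 3.0])
    fitted = superpose(mobile, ref)
    assert np.abs(fitted - ref).max() < 1e-8
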