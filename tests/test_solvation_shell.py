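"""Ellipsoid metric, nearest-N cluster extraction and hierarchical weights."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ensemblecd.errors import DataError
from ensemblecd.landscape import Thermo
from ensemblecd.solvation_shell import (
    WeightTree,
    build_ellipsoid,
    cluster_ed_and_weights,
    cluster_site_matrix,
    ellipsoid_metric,
    extract_clusters,
    verify_frozen_solute,
)
from ensemblecd.synthetic import SolventSpec, _folded_chain, gen_solvated_constrained
from ensemblecd.trajectory_io import Selection, select


@pytest.fixture
def rng():
    return np.random.default_rng(53)


@pytest.fixture(scope="module")
def solvated():
    """Constrained 2-state solvated system shared by extraction tests."""
    spec = SolventSpec(n_molecules=120, box=1.9, occupancies=(0.6, 0.4), seed=9)
    traj, states = gen_solvated_constrained(spec, _folded_chain(), 300)
    return traj, states


def axis_points(a, b, c):
    return np.array([
        [a, 0, 0], [-a, 0, 0], [0, b, 0], [0, -b, 0], [0, 0, c], [0, 0, -c],
    ], dtype=float)


class TestEllipsoid:
    def test_axis_aligned_points(self):
        """Six points on the coordinate axes give those semi-axes + padding."""
        e = build_ellipsoid(axis_points(0.5, 0.3, 0.2), padding=0.1)
        np.testing.assert_allclose(e.semi_axes, [0.6, 0.4, 0.3], atol=1e-12)
        np.testing.assert_allclose(np.abs(e.axes_units), np.eye(3), atol=1e-10)
        np.testing.assert_allclose(e.center, 0.0, atol=1e-15)

    def test_rotation_equivariance(self):
        pts = axis_points(0.5, 0.3, 0.2)
        R = Rotation.from_euler("zyx", [30, 50, -20], degrees=True).as_matrix()
        e0 = build_ellipsoid(pts)
        e1 = build_ellipsoid(pts @ R.T)
        np.testing.assert_allclose(e1.semi_axes, e0.semi_axes, atol=1e-12)
        # rotated axes still diagonalize to the same principal frame
        np.testing.assert_allclose(np.abs(e1.axes_units @ R @ e0.axes_units.T),
                                   np.eye(3), atol=1e-9)

    def test_semi_axes_match_max_projection_oracle(self, rng):
        """Random cloud: semi-axes equal brute-force max |projection| per axis."""
        pts = rng.normal(size=(20, 3)) * [0.4, 0.2, 0.1]
        e = build_ellipsoid(pts, padding=0.05)
        centered = pts - pts.mean(axis=0)
        for k in range(3):
            brute = np.max(np.abs(centered @ e.axes_units[k])) + 0.05
            assert e.semi_axes[k] == pytest.approx(brute, abs=1e-12)
        assert np.all(np.diff(e.semi_axes) <= 0)

    def test_degenerate_planar_solute_floored(self):
        pts = np.array([[0.3, 0, 0], [-0.3, 0, 0], [0, 0.2, 0], [0, -0.2, 0]])
        e = build_ellipsoid(pts, padding=0.05)
        assert e.semi_axes[2] == pytest.approx(0.05)


class TestEllipsoidMetric:
    def test_center_is_zero(self):
        e = build_ellipsoid(axis_points(0.5, 0.3, 0.2))
        assert ellipsoid_metric(e, e.center, box=5.0) == pytest.approx(0.0)

    def test_surface_is_one(self):
        e = build_ellipsoid(axis_points(0.5, 0.3, 0.2))
        p = e.center + e.semi_axes[0] * e.axes_units[0]
        assert ellipsoid_metric(e, p, box=5.0) == pytest.approx(1.0, abs=1e-10)

    def test_sphere_reduces_to_scaled_distance(self, rng):
        """Equal semi-axes: m = |Delta|^2 / a^2 for any point."""
        from ensemblecd.solvation_shell import Ellipsoid

        a = 0.3
        R = Rotation.from_euler("xyz", [10, 70, -30], degrees=True).as_matrix()
        e = Ellipsoid(center=np.array([0.2, -0.1, 0.4]), axes_units=R,
                      semi_axes=np.full(3, a))
        box = 4.0
        for p in rng.uniform(-1, 1, (20, 3)):
            d = p - e.center
            d -= box * np.round(d / box)
            expected = np.dot(d, d) / a**2
            assert ellipsoid_metric(e, p, box) == pytest.approx(expected, rel=1e-9)

    def test_periodic_wrap(self):
        e = build_ellipsoid(axis_points(0.3, 0.3, 0.3))
        box = 2.0
        assert ellipsoid_metric(e, np.array([box, 0.0, 0.0]), box) == pytest.approx(
            ellipsoid_metric(e, np.zeros(3), box), abs=1e-12)


class TestExtractClusters:
    def test_cardinality_contract(self, solvated):
        """Every cluster frame carries exactly N solvent molecules."""
        traj, _ = solvated
        solute = select(traj, "not water")
        clusters = extract_clusters(traj, solute, n_solvent=30)
        assert all(c.n_solvent == 30 for c in clusters)
        assert len(clusters) == traj.n_frames

    def test_slot_order_and_optimality(self, solvated):
        """Slots ascend in metric and beat every excluded molecule (full sort)."""
        traj, _ = solvated
        solute = select(traj, "not water")
        clusters = extract_clusters(traj, solute, n_solvent=25)
        from ensemblecd.solvation_shell import _solvent_molecules, build_ellipsoid
        mol_ids, atom_idx = _solvent_molecules(traj)
        e = build_ellipsoid(traj.frames[0].coordinates[solute.indices])
        for f in (0, traj.n_frames // 2, traj.n_frames - 1):
            c = clusters[f]
            assert np.all(np.diff(c.metrics) >= 0)
            # oracle: full sort over all molecule metrics
            sites = traj.frames[f].coordinates[atom_idx][:, 0, :]  # OW site
            all_m = ellipsoid_metric(e, sites, traj.frames[f].box)
            worst_kept = c.metrics[-1]
            excluded = np.setdiff1d(mol_ids, c.molecule_ids)
            excl_m = all_m[np.searchsorted(mol_ids, excluded)]
            assert np.all(worst_kept <= excl_m + 1e-12)

    def test_enlarging_n_is_monotone(self, solvated):
        """Growing N never drops a previously selected molecule."""
        traj, _ = solvated
        solute = select(traj, "not water")
        small = extract_clusters(traj, solute, n_solvent=10)
        large = extract_clusters(traj, solute, n_solvent=20)
        for cs, cl in zip(small, large):
            assert set(cs.molecule_ids) <= set(cl.molecule_ids)

    def test_all_molecules_selectable(self, solvated):
        traj, _ = solvated
        solute = select(traj, "not water")
        clusters = extract_clusters(traj, solute, n_solvent=120)
        assert clusters[0].n_solvent == 120
        with pytest.raises(DataError):
            extract_clusters(traj, solute, n_solvent=121)

    def test_unfrozen_solute_rejected(self, solvated, rng):
        traj, _ = solvated
        bad_frames = [f for f in traj.frames]
        import copy
        bad = copy.deepcopy(traj)
        bad.frames[1].coordinates[0] += 0.05
        solute = select(bad, "not water")
        with pytest.raises(DataError, match="not frozen"):
            extract_clusters(bad, solute, n_solvent=10)

    def test_rigid_transform_invariance_of_selection(self, solvated):
        """Rotating solute+solvent together (about the box centre, then
        rewrapping) leaves the selected molecule set unchanged."""
        import copy
        traj, _ = solvated
        solute = select(traj, "not water")
        ref_sets = [set(c.molecule_ids) for c in
                    extract_clusters(traj, solute, n_solvent=15)]
        box = traj.frames[0].box
        R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        center = np.full(3, box / 2)
        moved = copy.deepcopy(traj)
        for fr in moved.frames:
            x = (fr.coordinates - center) @ R.T + center
            fr.coordinates = np.mod(x, box)
        moved_sets = [set(c.molecule_ids) for c in
                      extract_clusters(moved, solute, n_solvent=15)]
        assert moved_sets == ref_sets


class TestClusterWeights:
    def test_frozen_solvent_degenerate_single_basin(self, solvated):
        """Zero solvent variance collapses to one basin with p(1,i) = P(i)."""
        traj, _ = solvated
        solute = select(traj, "not water")
        clusters = extract_clusters(traj, solute, n_solvent=12)
        frozen = [clusters[0]] * 10  # identical frames
        model, basins, tree = cluster_ed_and_weights(
            frozen, Thermo.from_celsius(30), P_i=0.55, conformation_id="B1")
        assert len(basins) == 1
        df = tree.to_frame()
        assert df.p_ji.sum() == pytest.approx(0.55)

    def test_two_state_occupancy_recovery(self, solvated):
        """Recovered p(j,i)/P(i) split matches the 0.6/0.4 generator states.

        Slot relabelling of near-threshold bulk molecules fragments the
        landscape, so basins are grouped by the majority true state of
        their member frames before comparing against the occupancies.
        """
        traj, states = solvated
        solute = select(traj, "not water")
        clusters = extract_clusters(traj, solute, n_solvent=30)
        P_i = 0.8
        model, basins, tree = cluster_ed_and_weights(
            clusters, Thermo.from_celsius(30), P_i=P_i, conformation_id="B1",
            bins=(10, 10), cutoff=np.inf)
        by_state = np.zeros(2)
        for basin in basins:
            member_states = states[basin.frame_indices]
            majority = int(np.round(member_states.mean()))
            by_state[majority] += basin.population * P_i
            # basins must be essentially pure in the true state
            assert np.mean(member_states == majority) > 0.95
        n = len(states)
        se = 3 * np.sqrt(0.6 * 0.4 / n)
        assert by_state[0] / P_i == pytest.approx(0.6, abs=se + 0.02)
        # conservation at infinite cutoff
        df = tree.to_frame()
        assert df.p_ji.sum() == pytest.approx(P_i, abs=1e-12)

    def test_weight_tree_conservation_bookkeeping(self):
        tree = WeightTree()
        tree.add("B1", "B1", 0.6, 0.36)
        tree.add("B1", "B2", 0.6, 0.18)
        tree.add("B2", "B1", 0.4, 0.40)
        assert tree.conservation_deficit("B1", 0.6) == pytest.approx(0.06)
        assert tree.conservation_deficit("B2", 0.4) == pytest.approx(0.0)
        df = tree.to_frame(Thermo.from_celsius(30))
        # reference basin is the global max p(j,i)
        assert df.loc[df.p_ji.idxmax(), "delta_G_kJmol"] == pytest.approx(0.0)

    def test_slot_matrix_shape(self, solvated):
        traj, _ = solvated
        solute = select(traj, "not water")
        clusters = extract_clusters(traj, solute, n_solvent=7)
        X = cluster_site_matrix(clusters)
        assert X.shape == (traj.n_frames, 21)
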