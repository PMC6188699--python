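"""Trajectory observables: distances, occupancy, dihedrals, superposition,
fluctuations, clustering, order parameters and generalized correlations."""

import numpy as np
import pytest

import ionprobe as ip
from ionprobe import synthetic
from ionprobe.errors import ValidationError
from ionprobe.synthetic import IonEpisode, ToyTrajectorySpec
from ionprobe.trajectory import pairwise_rmsd_matrix, vector_order_parameter


def sel(indices, label="sel"):
    return ip.AtomSelection(np.asarray(indices), label)


def static_traj(points, n_frames=10, box=None):
    coords = np.tile(np.asarray(points, float)[None], (n_frames, 1, 1))
    b = None if box is None else np.tile(np.eye(3) * box, (n_frames, 1, 1))
    return ip.TrajectoryView(coords, box=b)


class TestDistances:
    def test_constant_pair_distance(self):
        traj = static_traj([[0, 0, 0], [0.35, 0, 0]])
        series = ip.min_distance_series(traj, sel([0]), sel([1]))
        np.testing.assert_allclose(series.values, 0.35, atol=1e-7)

    def test_minimum_image_wraps_across_box(self):
        traj = static_traj([[0.05, 0.5, 0.5], [0.95, 0.5, 0.5]], box=1.0)
        series = ip.min_distance_series(traj, sel([0]), sel([1]))
        np.testing.assert_allclose(series.values, 0.10, atol=1e-6)

    def test_union_selection_never_increases_minimum(self):
        rng = np.random.default_rng(0)
        coords = rng.uniform(0, 2, size=(5, 6, 3))
        traj = ip.TrajectoryView(coords)
        single = ip.min_distance_series(traj, sel([0]), sel([3]))
        union = ip.min_distance_series(traj, sel([0]), sel([3, 4, 5]))
        assert np.all(union.values <= single.values + 1e-12)

    def test_empty_selection_names_it(self):
        traj = static_traj([[0, 0, 0], [1, 0, 0]])
        with pytest.raises(ValidationError, match="ions"):
            ip.min_distance_series(traj, sel([], "ions"), sel([1]))


class TestOccupancy:
    @pytest.mark.parametrize("dist,expected", [(0.3, 100.0), (0.5, 0.0), (0.4, 0.0)])
    def test_constant_series(self, dist, expected):
        """Strict inequality: a frame exactly at the cutoff does not count."""
        series = ip.DistanceSeries("x", np.full(50, dist))
        assert ip.occupancy_percent(series, 0.4) == expected

    def test_constructed_fraction_and_reorder_invariance(self):
        values = np.concatenate([np.full(37, 0.3), np.full(63, 0.5)])
        series = ip.DistanceSeries("x", values)
        assert ip.occupancy_percent(series) == 37.00
        rng = np.random.default_rng(1)
        shuffled = ip.DistanceSeries("x", rng.permutation(values))
        assert ip.occupancy_percent(shuffled) == 37.00


class TestSaltBridges:
    def _topology(self, residues):
        """residues: list of (resnum, resname, [atom names])."""
        names, resnums, resnames = [], [], []
        for num, rn, atoms in residues:
            for a in atoms:
                names.append(a)
                resnums.append(num)
                resnames.append(rn)
        n = len(names)
        return ip.Topology(
            atom_names=np.array(names),
            residue_numbers=np.array(resnums),
            residue_names=np.array(resnames),
            elements=np.array(["N" if a.startswith("N") else "O" if a.startswith("O") else "C" for a in names]),
            masses=np.full(n, 14.0),
        )

    def test_one_lys_one_asp_single_series_plus_cterm(self):
        top = self._topology([(1, "LYS", ["NZ"]), (2, "ASP", ["CG", "C"])])
        traj = static_traj([[0, 0, 0], [0.3, 0, 0], [0.5, 0, 0]])
        series = ip.salt_bridge_series(traj, top)
        labels = {s.label for s in series}
        # Asp CG partner and the C-terminal backbone C of the last residue
        assert labels == {"LYS1-NZ--ASP2-CG", "LYS1-NZ--ASP2-Cterm"}

    def test_paf_like_partner_enumeration(self):
        """Every Lys NZ pairs with every Asp CG / Glu CD / Ser OG / C-term C."""
        top = self._topology(
            [
                (1, "LYS", ["NZ"]),
                (2, "LYS", ["NZ"]),
                (53, "ASP", ["CG"]),
                (54, "GLU", ["CD"]),
                (55, "SER", ["OG", "C"]),
            ]
        )
        coords = np.arange(6 * 3, dtype=float).reshape(6, 3) / 10.0
        traj = static_traj(coords)
        series = ip.salt_bridge_series(traj, top)
        assert len(series) == 2 * 4  # 2 Lys x (ASP-CG, GLU-CD, SER-OG, C-term)

    def test_no_lysine_returns_empty_list(self, caplog):
        top = self._topology([(1, "ASP", ["CG"])])
        traj = static_traj([[0, 0, 0]])
        assert ip.salt_bridge_series(traj, top) == []

    def test_distance_symmetric_in_pair_order(self):
        top = self._topology([(1, "LYS", ["NZ"]), (2, "ASP", ["CG", "C"])])
        traj = static_traj([[0, 0, 0], [0.31, 0, 0], [0.7, 0, 0]])
        fwd = ip.salt_bridge_series(traj, top)[0]
        rev = ip.min_distance_series(traj, sel([1]), sel([0]))
        np.testing.assert_allclose(fwd.values, rev.values)


class TestDihedrals:
    def test_planar_cis_is_zero(self):
        traj = static_traj([[0, 1, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0]], n_frames=1)
        assert ip.dihedral_series(traj, sel(range(4)))[0] == pytest.approx(0.0, abs=1e-10)

    def test_planar_trans_is_180(self):
        traj = static_traj([[0, 1, 0], [0, 0, 0], [1, 0, 0], [1, -1, 0]], n_frames=1)
        assert ip.dihedral_series(traj, sel(range(4)))[0] == pytest.approx(180.0)

    def test_tetrahedral_sixty_degrees_matches_mdanalysis(self):
        from MDAnalysis.lib.distances import calc_dihedrals

        rng = np.random.default_rng(3)
        for _ in range(10):
            pts = rng.normal(size=(4, 3))
            traj = static_traj(pts, n_frames=1)
            mine = ip.dihedral_series(traj, sel(range(4)))[0]
            ref = np.degrees(
                calc_dihedrals(pts[0][None] * 10, pts[1][None] * 10, pts[2][None] * 10, pts[3][None] * 10)
            )[0]
            assert mine == pytest.approx(ref, abs=1e-5)

    def test_gauche_sign_convention(self):
        # staggered +60 degree arrangement
        c = np.cos(np.radians(60)); s = np.sin(np.radians(60))
        pts = [[1, 0, -1], [0, 0, 0], [0, 0, 1], [c, s, 2]]
        traj = static_traj(pts, n_frames=1)
        ang = ip.dihedral_series(traj, sel(range(4)))[0]
        assert abs(ang) == pytest.approx(60.0, abs=1e-6)

    def test_collinear_yields_nan(self):
        traj = static_traj([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0]], n_frames=1)
        with pytest.warns(UserWarning):
            ang = ip.dihedral_series(traj, sel(range(4)))
        assert np.isnan(ang[0])

    def test_wrong_atom_count_rejected(self):
        traj = static_traj([[0, 0, 0], [1, 0, 0], [2, 0, 0]], n_frames=1)
        with pytest.raises(ValidationError):
            ip.dihedral_series(traj, sel(range(3)))


class TestSuperposition:
    def test_self_rmsd_zero(self):
        rng = np.random.default_rng(0)
        coords = rng.normal(size=(4, 8, 3))
        traj = ip.TrajectoryView(coords)
        r = ip.rmsd_series(traj, coords[0], sel(range(8)))
        assert r[0] == pytest.approx(0.0, abs=1e-12)

    def test_pure_rotation_translation_rmsd_zero(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(8, 3))
        ang = np.radians(77)
        R = np.array([[np.cos(ang), -np.sin(ang), 0], [np.sin(ang), np.cos(ang), 0], [0, 0, 1]])
        traj = ip.TrajectoryView((X @ R.T + 3.0)[None])
        assert ip.rmsd_series(traj, X, sel(range(8)))[0] < 1e-10

    def test_kabsch_beats_rotation_grid(self):
        """Optimal superposition never loses to a 10-degree SO(3) grid scan."""
        from scipy.spatial.transform import Rotation

        step = np.radians(10)
        a = np.arange(0, 2 * np.pi, step)
        b = np.arange(0, np.pi + 1e-9, step)
        grid = Rotation.from_euler(
            "zyz", np.array(np.meshgrid(a, b, a)).T.reshape(-1, 3)
        ).as_matrix()
        rng = np.random.default_rng(42)
        for _ in range(5):
            X = rng.normal(size=(8, 3))
            Y = rng.normal(size=(8, 3))
            kab = ip.rmsd_series(ip.TrajectoryView(Y[None]), X, sel(range(8)))[0]
            Xc = X - X.mean(0)
            Yc = Y - Y.mean(0)
            rot = np.einsum("gij,aj->gai", grid, Yc)
            grid_best = np.sqrt(np.mean(np.sum((rot - Xc) ** 2, axis=2), axis=1)).min()
            assert kab <= grid_best + 1e-12

    def test_too_few_atoms_rejected(self):
        traj = static_traj([[0, 0, 0], [1, 0, 0]])
        with pytest.raises(ValidationError):
            ip.superpose(traj, traj.coordinates[0], sel([0, 1]))


class TestFluctuations:
    def test_static_trajectory_zero_rmsf(self):
        spec = ToyTrajectorySpec(n_atoms=5, n_frames=20, fluctuation_sd=0.0, seed=0)
        top, traj, _ = synthetic.simulate_toy_trajectory(spec)
        rmsf = ip.rmsf_per_residue(traj, top)
        assert all(v == pytest.approx(0.0, abs=1e-10) for v in rmsf.values())

    def test_isotropic_jitter_rmsf_is_sigma_root_three(self):
        """Per-coordinate sd sigma gives per-atom RMSF sigma*sqrt(3); with
        enough atoms the 6 rigid-body DOF absorbed by the alignment are a
        negligible fraction of the 3N coordinate DOF."""
        sigma = 0.02
        spec = ToyTrajectorySpec(n_atoms=30, n_frames=10_000, fluctuation_sd=sigma, seed=2)
        top, traj, _ = synthetic.simulate_toy_trajectory(spec)
        rmsf = ip.rmsf_per_residue(traj, top)
        vals = np.array(list(rmsf.values()))
        assert np.mean(vals) == pytest.approx(sigma * np.sqrt(3), rel=0.05)

    def test_rmsf_scales_linearly_with_sigma(self):
        out = []
        for sigma in (0.01, 0.02):
            spec = ToyTrajectorySpec(n_atoms=8, n_frames=3000, fluctuation_sd=sigma, seed=3)
            top, traj, _ = synthetic.simulate_toy_trajectory(spec)
            out.append(np.mean(list(ip.rmsf_per_residue(traj, top).values())))
        assert out[1] / out[0] == pytest.approx(2.0, rel=0.05)

    def test_single_frame_warns_and_returns_zero(self):
        spec = ToyTrajectorySpec(n_atoms=5, n_frames=1, seed=0)
        top, traj, _ = synthetic.simulate_toy_trajectory(spec)
        with pytest.warns(UserWarning):
            rmsf = ip.rmsf_per_residue(traj, top)
        assert set(rmsf.values()) == {0.0}


class TestRadiusOfGyration:
    def test_two_equal_masses(self):
        traj = static_traj([[0, 0, 0], [1, 0, 0]], n_frames=1)
        assert ip.radius_of_gyration_series(traj, mass_weighted=False)[0] == pytest.approx(0.5)

    def test_uniform_ring_approaches_radius(self):
        theta = np.linspace(0, 2 * np.pi, 1000, endpoint=False)
        ring = np.stack([np.cos(theta), np.sin(theta), np.zeros_like(theta)], axis=1)
        traj = ip.TrajectoryView(ring[None])
        assert ip.radius_of_gyration_series(traj, mass_weighted=False)[0] == pytest.approx(1.0, rel=1e-3)

    def test_translation_invariance(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(9, 3))
        t1 = ip.TrajectoryView(pts[None])
        t2 = ip.TrajectoryView((pts + 7.5)[None])
        m = rng.uniform(1, 20, 9)
        assert ip.radius_of_gyration_series(t1, m)[0] == pytest.approx(
            ip.radius_of_gyration_series(t2, m)[0], rel=1e-12
        )


class TestClustering:
    def test_identical_frames_single_cluster_rep_zero(self):
        spec = ToyTrajectorySpec(n_atoms=5, n_frames=12, fluctuation_sd=0.0, seed=0)
        top, traj, _ = synthetic.simulate_toy_trajectory(spec)
        cl = ip.cluster_frames(traj, sel(range(5)), cutoff=0.15)
        assert cl.n_clusters == 1
        assert cl.sizes[0] == 12
        assert cl.representative_frames[0] == 0

    def test_two_conformers_sizes_and_representative(self):
        rng = np.random.default_rng(5)
        A = rng.normal(size=(5, 3))
        B = A + np.array([1.5, 0, 0]) * np.linspace(0, 1, 5)[:, None]
        frames = np.array([A] * 60 + [B] * 40) + rng.normal(scale=0.002, size=(100, 5, 3))
        cl = ip.cluster_frames(ip.TrajectoryView(frames), sel(range(5)), cutoff=0.15)
        assert list(cl.sizes) == [60, 40]
        assert cl.representative_frames[0] < 60  # drawn from conformer A
        assert np.sum(cl.sizes) == 100

    def test_infinite_cutoff_single_cluster(self):
        rng = np.random.default_rng(6)
        frames = rng.normal(size=(15, 5, 3))
        cl = ip.cluster_frames(ip.TrajectoryView(frames), sel(range(5)), cutoff=np.inf)
        assert cl.n_clusters == 1

    def test_assignments_and_representatives_consistent(self):
        rng = np.random.default_rng(7)
        frames = rng.normal(size=(20, 4, 3), scale=0.5)
        cl = ip.cluster_frames(ip.TrajectoryView(frames), sel(range(4)), cutoff=0.3)
        assert np.sum(cl.sizes) == 20
        for cid, rep in enumerate(cl.representative_frames):
            assert cl.assignments[rep] == cid


class TestOrderParameters:
    def test_static_vector_is_rigid(self):
        vecs = np.tile([[0.3, 0.4, 0.5]], (200, 1))
        assert vector_order_parameter(vecs) == pytest.approx(1.0)

    def test_isotropic_vectors_tend_to_zero(self):
        rng = np.random.default_rng(8)
        vecs = rng.normal(size=(10_000, 3))
        assert vector_order_parameter(vecs) < 0.03

    def test_diffusion_in_a_cone_closed_form(self):
        rng = np.random.default_rng(9)
        for theta0 in (20.0, 40.0, 60.0):
            c0 = np.cos(np.radians(theta0))
            cost = rng.uniform(c0, 1.0, 20_000)
            phi = rng.uniform(0, 2 * np.pi, 20_000)
            sint = np.sqrt(1 - cost**2)
            vecs = np.stack([sint * np.cos(phi), sint * np.sin(phi), cost], axis=1)
            expected = (c0 * (1 + c0) / 2) ** 2
            assert vector_order_parameter(vecs) == pytest.approx(expected, abs=0.02)

    def test_nh_vectors_from_topology_and_reconstruction(self):
        # two-residue backbone with explicit H on residue 1 only
        names = ["N", "H", "CA", "C", "N", "CA", "C"]
        resnums = [1, 1, 1, 1, 2, 2, 2]
        top = ip.Topology(
            atom_names=np.array(names),
            residue_numbers=np.array(resnums),
            residue_names=np.array(["GLY"] * 7),
            elements=np.array([n[0] for n in names]),
            masses=np.ones(7) * 12.0,
        )
        pts = np.array(
            [[0, 0, 0], [-0.08, -0.06, 0], [0.15, 0, 0], [0.25, 0.1, 0],
             [0.4, 0.1, 0], [0.5, 0.25, 0], [0.65, 0.2, 0]]
        )
        traj = static_traj(pts, n_frames=50)
        s2 = ip.nh_order_parameters(traj, top)
        assert s2[1] == pytest.approx(1.0)   # explicit H, static
        assert s2[2] == pytest.approx(1.0)   # reconstructed H, static


class TestGeneralizedCorrelation:
    def test_independent_atoms_near_zero(self):
        spec = ToyTrajectorySpec(n_atoms=4, n_frames=10_000, seed=10)
        top, traj, _ = synthetic.simulate_toy_trajectory(spec)
        cm = ip.generalized_correlation(traj, sel(range(4)))
        off = cm.values[~np.eye(4, dtype=bool)]
        assert np.all(off <= 0.05)

    def test_gaussian_pair_recovers_rho(self):
        spec = ToyTrajectorySpec(
            n_atoms=2, n_frames=10_000, seed=11, correlated_pairs=[(0, 1, 0.8)]
        )
        top, traj, _ = synthetic.simulate_toy_trajectory(spec)
        cm = ip.generalized_correlation(traj, sel([0, 1]))
        assert cm.values[0, 1] == pytest.approx(0.8, abs=0.02)

    def test_matrix_symmetric_unit_diagonal_in_range(self):
        spec = ToyTrajectorySpec(n_atoms=5, n_frames=2000, seed=12,
                                 correlated_pairs=[(1, 3, 0.5)])
        top, traj, _ = synthetic.simulate_toy_trajectory(spec)
        cm = ip.generalized_correlation(traj, sel(range(5)))
        np.testing.assert_allclose(cm.values, cm.values.T)
        np.testing.assert_allclose(np.diag(cm.values), 1.0)
        assert np.all((cm.values >= 0) & (cm.values <= 1))

    def test_static_atom_flagged_zero_off_diagonal(self):
        coords = np.zeros((500, 2, 3))
        rng = np.random.default_rng(13)
        coords[:, 1] = rng.normal(size=(500, 3))
        cm = ip.generalized_correlation(ip.TrajectoryView(coords), sel([0, 1]))
        assert 0 in cm.flagged
        assert cm.values[0, 1] == 0.0

    def test_abs_difference_of_identical_matrices_is_zero(self):
        spec = ToyTrajectorySpec(n_atoms=3, n_frames=500, seed=14)
        top, traj, _ = synthetic.simulate_toy_trajectory(spec)
        cm = ip.generalized_correlation(traj, sel(range(3)))
        assert np.all(ip.matrix_abs_difference(cm, cm) == 0.0)

    def test_shape_mismatch_rejected(self):
        a = ip.CorrelationMatrix(["a"], np.eye(2))
        b = ip.CorrelationMatrix(["b"], np.eye(3))
        with pytest.raises(ValidationError):
            ip.matrix_abs_difference(a, b)


def test_pairwise_rmsd_matrix_symmetric_zero_diagonal():
    rng = np.random.default_rng(15)
    traj = ip.TrajectoryView(rng.normal(size=(8, 6, 3)))
    m = pairwise_rmsd_matrix(traj, sel(range(6)))
    np.testing.assert_allclose(m, m.T)
    assert np.all(np.diag(m) == 0)
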