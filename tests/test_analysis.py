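"""Ensemble analytics: PCA, clustering, dihedrals, FES, distances, density."""

import numpy as np
import numpy.ma as ma
import pytest
from hypothesis import given, settings, strategies as st

from flexsemble.analysis import (
    EnsemblePCA, GromosClustering, AnalysisError, KT_298K_KJMOL,
    pca_fit, pca_project, cluster_gromos, cumulative_cluster_fraction,
    dihedral_series, free_energy_surface, min_free_energy_path,
    com_distance_series, density_map,
)
from flexsemble.structures import Ensemble
from flexsemble.geometry import RigidTransform
from flexsemble.synthetic import (
    SyntheticEnsembleSpec, HingeMode, generate_fragment_ensembles,
)
from tests.conftest import bead_structure


def _ca_idx(structure, domain_def):
    return np.flatnonzero(domain_def.mask(structure) & (structure.atom_names == "CA"))


class TestPCA:
    def test_identical_members_zero_eigenvalues(self, make_beads):
        s = make_beads(np.random.default_rng(0).normal(size=(20, 3)))
        ens = Ensemble([s.copy() for _ in range(5)])
        model = pca_fit(ens)
        assert model.eigenvalues_.max() < 1e-20

    def test_planted_hinge_mode_dominates(self, default_world):
        ab, _, truth = default_world
        model = pca_fit(
            ab,
            fit_indices=_ca_idx(ab[0], truth.domain_defs["B"]),
            analysis_indices=_ca_idx(ab[0], truth.domain_defs["A"]),
        )
        assert model.explained_variance_ratio_[0] > 0.95

    def test_two_modes_variance_ratio(self):
        # two orthogonal hinge axes with planted eigenvalues 2:1
        spec = SyntheticEnsembleSpec(
            seed=21, n_members=(1000, 2),
            hinge_modes=(
                HingeMode(axis=(0.0, 0.0, 1.0), eigvar_nm2=2.0e-2),
                HingeMode(axis=(1.0, 0.0, 0.0), eigvar_nm2=1.0e-2),
            ),
        )
        ab, _, truth = generate_fragment_ensembles(spec)
        model = pca_fit(
            ab,
            fit_indices=_ca_idx(ab[0], truth.domain_defs["B"]),
            analysis_indices=_ca_idx(ab[0], truth.domain_defs["A"]),
        )
        ratio = model.eigenvalues_[0] / model.eigenvalues_[1]
        assert ratio == pytest.approx(2.0, rel=0.10)

    def test_training_projection_variance_equals_eigenvalues(self, default_world):
        ab, _, truth = default_world
        model = pca_fit(ab, analysis_indices=_ca_idx(ab[0], truth.domain_defs["A"]))
        proj = model.transform(ab)
        var = proj.var(axis=0)  # 1/M normalization matches the fit
        np.testing.assert_allclose(
            var[:5], model.eigenvalues_[:5], rtol=1e-8, atol=1e-12
        )

    def test_mean_structure_projects_to_origin(self, make_beads):
        rng = np.random.default_rng(4)
        base = rng.normal(size=(12, 3))
        members = [make_beads(base + rng.normal(scale=0.1, size=base.shape))
                   for _ in range(30)]
        ens = Ensemble(members)
        model = EnsemblePCA().fit(ens)
        mean_member = members[0].with_coords(
            model.mean_structure_coords_
        )
        proj = model.transform(Ensemble([mean_member, mean_member]))
        assert np.abs(proj).max() < 1e-9

    def test_synthetic_displacement_along_component(self, make_beads):
        rng = np.random.default_rng(9)
        base = rng.normal(size=(10, 3))
        members = [make_beads(base + rng.normal(scale=0.05, size=base.shape))
                   for _ in range(40)]
        ens = Ensemble(members)
        model = EnsemblePCA(fit_indices=None).fit(ens)
        c = 0.37
        displaced = model.mean_structure_coords_ + c * model.components_[0].reshape(-1, 3)
        proj = model.transform(Ensemble([make_beads(displaced), make_beads(displaced)]))
        assert proj[0, 0] == pytest.approx(c, abs=1e-9)
        assert np.abs(proj[0, 1:]).max() < 1e-9

    def test_eigenvalue_sum_equals_total_variance(self, default_world):
        ab, _, truth = default_world
        idx = _ca_idx(ab[0], truth.domain_defs["A"])
        model = pca_fit(ab, fit_indices=_ca_idx(ab[0], truth.domain_defs["B"]),
                        analysis_indices=idx)
        proj = model.transform(ab)
        total = proj.var(axis=0).sum()
        assert model.eigenvalues_.sum() == pytest.approx(total, rel=1e-8)

    def test_cross_check_against_sklearn(self, make_beads):
        # with no fitting step the spectrum must match sklearn's PCA
        from sklearn.decomposition import PCA as SkPCA
        rng = np.random.default_rng(13)
        x = rng.normal(size=(50, 8, 3)) * 0.2
        ens = Ensemble([make_beads(c) for c in x])
        model = EnsemblePCA(fit_indices=None, n_passes=1).fit(ens)
        flat = x.reshape(50, -1)
        sk = SkPCA().fit(flat)
        # sklearn uses 1/(M-1); ours is 1/M
        np.testing.assert_allclose(
            model.eigenvalues_[:5], sk.explained_variance_[:5] * 49 / 50, rtol=1e-8
        )

    def test_topology_mismatch_rejected(self, default_world, make_beads):
        ab, _, _ = default_world
        model = pca_fit(ab)
        with pytest.raises(AnalysisError, match="topology"):
            model.transform(Ensemble([make_beads(np.zeros((3, 3)))] * 2))

    def test_single_member_rejected(self, make_beads):
        with pytest.raises(AnalysisError):
            pca_fit(Ensemble([make_beads(np.zeros((4, 3)))]))


class TestClustering:
    def _blob_ensemble(self, sizes, separation=10.0, scale=0.01, seed=0):
        rng = np.random.default_rng(seed)
        base = rng.normal(size=(12, 3))
        members = []
        for b, size in enumerate(sizes):
            center = base + b * separation
            for _ in range(size):
                members.append(
                    bead_structure(center + rng.normal(scale=scale, size=base.shape))
                )
        return Ensemble(members)

    def test_two_planted_blobs(self):
        ens = self._blob_ensemble([7, 4])
        result = cluster_gromos(ens, cutoff_nm=0.3)
        assert result.n_clusters == 2
        assert list(result.populations) == [7, 4]
        assert result.labels[:7].tolist() == [0] * 7
        assert result.labels[7:].tolist() == [1] * 4

    def test_infinite_cutoff_single_cluster(self):
        ens = self._blob_ensemble([3, 3, 3])
        result = cluster_gromos(ens, cutoff_nm=1e9)
        assert result.n_clusters == 1
        assert result.populations[0] == 9

    def test_tiny_cutoff_all_singletons(self):
        ens = self._blob_ensemble([5], scale=0.5)
        result = cluster_gromos(ens, cutoff_nm=1e-9)
        assert result.n_clusters == 5
        assert np.all(result.populations == 1)

    def test_permutation_invariance_up_to_relabeling(self):
        ens = self._blob_ensemble([6, 3, 2], seed=5)
        result = cluster_gromos(ens, cutoff_nm=0.3)
        perm = np.random.default_rng(8).permutation(len(ens))
        permuted = Ensemble([ens[i] for i in perm])
        result_p = cluster_gromos(permuted, cutoff_nm=0.3)
        assert list(result_p.populations) == list(result.populations)
        # same partition: members that share a label still share one
        labels_back = np.empty(len(ens), dtype=int)
        labels_back[perm] = result_p.labels
        for c in range(result.n_clusters):
            members = np.flatnonzero(result.labels == c)
            assert len(set(labels_back[members])) == 1

    def test_deterministic_tie_break_lowest_index(self, make_beads):
        # two distant singleton pairs; equal populations -> order by
        # lowest representative index
        rng = np.random.default_rng(2)
        base = rng.normal(size=(5, 3))
        members = [
            bead_structure(base),
            bead_structure(base + 100.0),
        ]
        result = cluster_gromos(Ensemble(members), cutoff_nm=0.1)
        assert list(result.representatives) == [0, 1]

    def test_estimator_interface(self):
        ens = self._blob_ensemble([4, 2])
        est = GromosClustering(cutoff=0.3)
        labels = est.fit_predict(ens)
        assert est.get_params()["cutoff"] == 0.3
        assert labels.shape == (6,)


class TestCumulativeFraction:
    def test_single_cluster(self):
        ens_labels = cluster_gromos(
            Ensemble([bead_structure(np.zeros((4, 3)))] * 3), cutoff_nm=1.0
        )
        np.testing.assert_allclose(cumulative_cluster_fraction(ens_labels, [1]), [1.0])

    def test_planted_populations(self):
        from flexsemble.analysis import ClusterResult
        result = ClusterResult(
            labels=np.repeat([0, 1, 2], [50, 30, 20]),
            representatives=np.array([0, 50, 80]),
            populations=np.array([50, 30, 20]),
            cutoff=0.1,
        )
        np.testing.assert_allclose(
            cumulative_cluster_fraction(result, [1, 2]), [0.5, 0.8]
        )

    @given(st.integers(0, 10_000))
    @settings(max_examples=100)
    def test_monotone_and_reaches_one(self, seed):
        from flexsemble.analysis import ClusterResult
        rng = np.random.default_rng(seed)
        pops = np.sort(rng.integers(1, 50, size=rng.integers(1, 12)))[::-1]
        labels = np.repeat(np.arange(len(pops)), pops)
        result = ClusterResult(
            labels=labels, representatives=np.arange(len(pops)),
            populations=pops, cutoff=0.1,
        )
        ks = np.arange(1, len(pops) + 1)
        fr = cumulative_cluster_fraction(result, ks)
        assert np.all(np.diff(fr) >= -1e-12)
        assert fr[-1] == pytest.approx(1.0)

    def test_bad_k_rejected(self):
        from flexsemble.analysis import ClusterResult
        result = ClusterResult(np.zeros(3, int), np.array([0]), np.array([3]), 0.1)
        with pytest.raises(AnalysisError):
            cumulative_cluster_fraction(result, [0])


class TestDihedralSeries:
    def test_single_member_histogram(self, default_world):
        _, bc, truth = default_world
        series = dihedral_series(Ensemble([bc[0]]), truth.dihedral_residues)
        assert series.angles.shape == (1,)
        assert series.histogram.sum() == 1
        assert len(series.peaks) == 1

    def test_planted_values_recovered_exactly(self, default_world):
        _, bc, truth = default_world
        series = dihedral_series(bc, truth.dihedral_residues)
        np.testing.assert_allclose(
            series.angles, truth.dihedral_targets_deg, atol=1e-9
        )

    def test_planted_mixture_peaks_within_one_bin(self):
        spec = SyntheticEnsembleSpec(seed=17, n_members=(2, 1500))
        _, bc, truth = generate_fragment_ensembles(spec)
        series = dihedral_series(bc, truth.dihedral_residues, bin_width=5.0)
        top2 = sorted(series.peaks[:2])
        assert abs(top2[0] - (-100.0)) <= 5.0
        assert abs(top2[1] - (-30.0)) <= 5.0

    def test_missing_ca_rejected(self, default_world):
        _, bc, _ = default_world
        with pytest.raises(AnalysisError, match="no C-alpha"):
            dihedral_series(bc, (99999, 1, 2, 3))


class TestFreeEnergySurface:
    def test_single_occupied_bin(self):
        xy = np.zeros((50, 2))
        fes = free_energy_surface(xy, bins=5)
        occupied = ~fes.free_energy.mask
        assert occupied.sum() == 1
        assert fes.free_energy[occupied][0] == 0.0

    def test_two_bin_ratio_closed_form(self):
        n = 1000
        x = np.concatenate([np.zeros(int(np.e * n)), np.ones(n)])
        xy = np.column_stack([x, np.zeros_like(x)])
        fes = free_energy_surface(xy, bins=2, kt_kjmol=KT_298K_KJMOL)
        vals = np.sort(fes.free_energy.compressed())
        # counts (e*n, n): delta F = kT ln(e) = kT (up to integer rounding)
        assert vals[1] - vals[0] == pytest.approx(KT_298K_KJMOL, rel=1e-3)

    def test_two_gaussians_weight_ratio(self):
        rng = np.random.default_rng(23)
        n = 100_000
        n1 = int(n * 10 / 11)
        a = rng.normal(loc=(-2.0, 0.0), scale=0.3, size=(n1, 2))
        b = rng.normal(loc=(+2.0, 0.0), scale=0.3, size=(n - n1, 2))
        fes = free_energy_surface(np.vstack([a, b]), bins=40)
        # basin depths: F at each Gaussian center bin
        f = fes.free_energy
        ia = np.unravel_index(
            np.argmin(ma.masked_array(f, mask=f.mask | (fes.x_centers[:, None] > 0))),
            f.shape,
        )
        ib = np.unravel_index(
            np.argmin(ma.masked_array(f, mask=f.mask | (fes.x_centers[:, None] < 0))),
            f.shape,
        )
        delta = abs(f[ib] - f[ia])
        assert delta == pytest.approx(KT_298K_KJMOL * np.log(10), rel=0.15)

    def test_count_ratio_identity(self):
        rng = np.random.default_rng(3)
        xy = rng.normal(size=(5000, 2))
        fes = free_energy_surface(xy, bins=10)
        occ = np.argwhere(fes.counts > 0)
        i, j = occ[0], occ[-1]
        lhs = fes.free_energy[tuple(i)] - fes.free_energy[tuple(j)]
        rhs = -fes.kt * np.log(fes.counts[tuple(i)] / fes.counts[tuple(j)])
        assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_no_samples_rejected(self):
        with pytest.raises(AnalysisError):
            free_energy_surface(np.empty((0, 2)))


class TestMinFreeEnergyPath:
    def _fes_from_f(self, f_grid, kt=KT_298K_KJMOL):
        """Build a surface whose free energies equal ``f_grid`` by sampling
        counts proportional to exp(-F/kT)."""
        from flexsemble.analysis import FreeEnergySurface
        counts = np.where(
            np.isfinite(f_grid), np.exp(-np.nan_to_num(f_grid) / kt) * 1e6, 0
        ).astype(int)
        f = ma.masked_array(
            np.where(np.isfinite(f_grid), f_grid, 0.0), mask=~np.isfinite(f_grid)
        )
        nx, ny = f_grid.shape
        return FreeEnergySurface(
            free_energy=f, x_edges=np.arange(nx + 1.0),
            y_edges=np.arange(ny + 1.0), counts=counts, kt=kt,
        )

    def test_flat_surface_zero_barrier(self):
        fes = self._fes_from_f(np.zeros((6, 6)))
        path, barrier = min_free_energy_path(fes, (0, 0), (5, 5))
        assert barrier == 0.0
        assert path[0] == (0, 0) and path[-1] == (5, 5)

    def test_planted_saddle_height(self):
        # 1D double well embedded in 2D: wall at x=3 with a 4 kJ/mol pass
        f = np.full((7, 5), 10.0)
        f[:, 2] = 0.0  # corridor along y=2... (transposed: use rows)
        f = np.zeros((7, 5))
        f[3, :] = 10.0
        f[3, 2] = 4.0  # the saddle
        fes = self._fes_from_f(f)
        path, barrier = min_free_energy_path(fes, (0, 2), (6, 2))
        assert barrier == pytest.approx(4.0, abs=1e-9)
        assert (3, 2) in path

    def test_equal_endpoints_empty_path(self):
        fes = self._fes_from_f(np.zeros((4, 4)))
        path, barrier = min_free_energy_path(fes, (1, 1), (1, 1))
        assert path == [] and barrier == 0.0

    def test_disconnected_basins_rejected(self):
        f = np.zeros((5, 5))
        f[2, :] = np.inf  # a fully masked wall
        fes = self._fes_from_f(f)
        with pytest.raises(AnalysisError, match="disconnected"):
            min_free_energy_path(fes, (0, 0), (4, 4))

    def test_empty_basin_rejected(self):
        f = np.zeros((4, 4))
        f[0, 0] = np.inf
        fes = self._fes_from_f(f)
        with pytest.raises(AnalysisError, match="empty bin"):
            min_free_energy_path(fes, (0, 0), (3, 3))

    def test_sampled_double_well_barrier(self):
        # samples drawn from exp(-F/kT) with a quartic double well along x:
        # F(x) = 4 (1 - x^2)^2, saddle 4 kJ/mol at x = 0
        rng = np.random.default_rng(29)
        kt = KT_298K_KJMOL
        grid = np.linspace(-1.6, 1.6, 2000)
        fx = 4.0 * (1 - grid**2) ** 2
        p = np.exp(-fx / kt)
        p /= p.sum()
        x = rng.choice(grid, size=200_000, p=p) + rng.normal(scale=2e-4, size=200_000)
        y = rng.uniform(-0.5, 0.5, size=x.size)
        fes = free_energy_surface(np.column_stack([x, y]), bins=40, kt_kjmol=kt)
        # basins: occupied bins nearest the two minima
        ix_a = np.argmin(np.abs(fes.x_centers - (-1.0)))
        ix_b = np.argmin(np.abs(fes.x_centers - (+1.0)))
        iy = np.argmin(np.abs(fes.y_centers))
        _, barrier = min_free_energy_path(fes, (ix_a, iy), (ix_b, iy))
        # one 0.08-wide bin changes the quartic by < 0.55 kJ/mol near its
        # steepest point; allow that plus sampling noise
        assert barrier == pytest.approx(4.0, abs=0.6)


class TestComDistance:
    def test_reference_member_is_zero(self, default_world):
        ab, _, truth = default_world
        idx_a = truth.ab_domain_indices["A"]
        idx_b = truth.ab_domain_indices["B"]
        series = com_distance_series(
            Ensemble([ab[0]]), idx_a, idx_b, reference=ab[0]
        )
        assert series.distances[0] < 1e-12

    def test_rigid_shift_of_mobile_domain(self, default_world):
        ab, _, truth = default_world
        idx_a = truth.ab_domain_indices["A"]
        idx_b = truth.ab_domain_indices["B"]
        member = ab[0].copy()
        member.coords[idx_a] += np.array([0.0, 0.0, 2.0])
        series = com_distance_series(
            Ensemble([member]), idx_a, idx_b, reference=ab[0]
        )
        assert series.distances[0] == pytest.approx(2.0, abs=1e-9)

    def test_invariant_under_global_rigid_motion(self, default_world):
        ab, _, truth = default_world
        idx_a = truth.ab_domain_indices["A"]
        idx_b = truth.ab_domain_indices["B"]
        sub = Ensemble(ab.members[:5])
        base = com_distance_series(sub, idx_a, idx_b, reference=ab[0])
        t = RigidTransform(
            np.array([[0.0, 1.0, 0.0], [0.0, 0.0, 1.0], [1.0, 0.0, 0.0]]),
            np.array([3.0, 1.0, -2.0]),
        )
        moved = Ensemble([t.apply_structure(m) for m in sub.members])
        out = com_distance_series(moved, idx_a, idx_b, reference=ab[0])
        np.testing.assert_allclose(out.distances, base.distances, atol=1e-9)


class TestDensityMap:
    def test_identical_coms_single_voxel(self, default_world):
        ab, _, truth = default_world
        ens = Ensemble([ab[0].copy() for _ in range(4)])
        dmap = density_map(
            ens, truth.ab_domain_indices["A"], truth.ab_domain_indices["B"]
        )
        assert (dmap.density > 0).sum() == 1
        assert dmap.density.max() == pytest.approx(1.0)

    def test_density_normalized(self, default_world):
        ab, _, truth = default_world
        dmap = density_map(
            ab, truth.ab_domain_indices["A"], truth.ab_domain_indices["B"]
        )
        assert dmap.density.sum() == pytest.approx(1.0, rel=1e-12)

    def test_planted_gaussian_cloud_mode(self, default_world):
        ab, _, truth = default_world
        rng = np.random.default_rng(31)
        idx_a = truth.ab_domain_indices["A"]
        center = np.array([1.0, -2.0, 0.5])
        members = []
        for _ in range(300):
            m = ab[0].copy()
            target = center + rng.normal(scale=0.15, size=3)
            m.coords[idx_a] += target - m.coords[idx_a].mean(axis=0)
            members.append(m)
        dmap = density_map(
            Ensemble(members), idx_a, truth.ab_domain_indices["B"],
            reference=ab[0], spacing=0.2,
        )
        assert np.linalg.norm(dmap.max_voxel_center() - center) <= 0.2 * np.sqrt(3)

    def test_isolevels_fractions_of_max(self, default_world):
        ab, _, truth = default_world
        dmap = density_map(
            ab, truth.ab_domain_indices["A"], truth.ab_domain_indices["B"]
        )
        levels = dmap.isolevels((0.1, 0.001))
        assert levels[0] == pytest.approx(0.1 * dmap.density.max())
        assert levels[1] == pytest.approx(0.001 * dmap.density.max())


class TestGlobalRigidInvariance:
    def test_analytics_unchanged_by_uniform_transform(self, default_world):
        ab, _, truth = default_world
        sub = Ensemble(ab.members[:8])
        t = RigidTransform(
            np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]]),
            np.array([-1.0, 4.0, 2.0]),
        )
        moved = Ensemble([t.apply_structure(m) for m in sub.members])
        fit_idx = _ca_idx(ab[0], truth.domain_defs["B"])
        ana_idx = _ca_idx(ab[0], truth.domain_defs["A"])
        e1 = pca_fit(sub, fit_idx, ana_idx).eigenvalues_
        e2 = pca_fit(moved, fit_idx, ana_idx).eigenvalues_
        np.testing.assert_allclose(e1[:5], e2[:5], rtol=1e-6, atol=1e-12)
        r1 = cluster_gromos(sub, ana_idx, fit_idx, 0.05)
        r2 = cluster_gromos(moved, ana_idx, fit_idx, 0.05)
        np.testing.assert_array_equal(r1.labels, r2.labels)
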