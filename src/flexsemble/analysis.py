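"""Ensemble analytics: essential-dynamics PCA, GROMOS-style clustering,
rotation-dihedral distributions, free-energy surfaces with minimax paths,
center-of-mass distance series and 3D density maps.

The PCA and clustering follow the usual MD-analysis conventions: every
member is least-square fitted on a rigid "fit" selection (e.g. the core of
the largest domain) before the "analysis" selection is examined, so the
extracted modes describe interdomain motion, not global tumbling.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass

import numpy as np
import numpy.ma as ma

from .structures import Structure, Ensemble
from .geometry import superpose, rmsd, dihedral, center_of_mass, GeometryError

logger = logging.getLogger(__name__)

#: kT at 298 K in kJ/mol
KT_298K_KJMOL = 2.478


class AnalysisError(ValueError):
    pass


# ---------------------------------------------------------------------------
# PCA


def _align_members(
    coords: np.ndarray, fit_indices: np.ndarray | None, reference: np.ndarray
) -> np.ndarray:
    """Superpose every member (M, N, 3) onto ``reference`` at fit_indices."""
    if fit_indices is None:
        return coords.copy()
    out = np.empty_like(coords)
    for k in range(coords.shape[0]):
        transform, _ = superpose(coords[k], reference, fit_indices)
        out[k] = transform.apply(coords[k])
    return out


class EnsemblePCA:
    """Essential-dynamics PCA of an ensemble.

    Members are iteratively superposed on ``fit_indices`` to the running mean
    conformation (``n_passes`` rounds, default 2), then the covariance of the
    flattened ``analysis_indices`` coordinates is diagonalized.

    Fitted attributes: ``components_`` (n_modes, 3n), ``eigenvalues_`` (nm^2,
    descending), ``explained_variance_ratio_``, ``cumulative_variance_``,
    ``mean_`` (flattened analysis coordinates of the mean conformation) and
    ``mean_structure_coords_`` (full mean coordinates used as fit reference).
    """

    def __init__(
        self,
        fit_indices: np.ndarray | None = None,
        analysis_indices: np.ndarray | None = None,
        n_passes: int = 2,
    ):
        self.fit_indices = fit_indices
        self.analysis_indices = analysis_indices
        self.n_passes = n_passes

    def get_params(self, deep: bool = True) -> dict:
        return {
            "fit_indices": self.fit_indices,
            "analysis_indices": self.analysis_indices,
            "n_passes": self.n_passes,
        }

    def set_params(self, **params) -> "EnsemblePCA":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def _analysis_idx(self, n_atoms: int) -> np.ndarray:
        if self.analysis_indices is None:
            return np.arange(n_atoms)
        return np.asarray(self.analysis_indices, dtype=int)

    def fit(self, ensemble: Ensemble) -> "EnsemblePCA":
        if len(ensemble) < 2:
            raise AnalysisError("PCA needs at least 2 members")
        coords = ensemble.coords
        fit_idx = None if self.fit_indices is None else np.asarray(self.fit_indices, int)
        reference = coords[0]
        aligned = coords
        for _ in range(max(self.n_passes, 1)):
            aligned = _align_members(coords, fit_idx, reference)
            reference = aligned.mean(axis=0)
        a_idx = self._analysis_idx(coords.shape[1])
        x = aligned[:, a_idx, :].reshape(len(ensemble), -1)
        mean = x.mean(axis=0)
        xc = x - mean
        # covariance with 1/M normalization so that training projection
        # variances reproduce the eigenvalues exactly
        cov = xc.T @ xc / len(ensemble)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals = np.clip(evals[order], 0.0, None)
        evecs = evecs[:, order]
        total = evals.sum()
        self.n_atoms_ = coords.shape[1]
        self.mean_ = mean
        self.mean_structure_coords_ = reference
        self.components_ = evecs.T
        self.eigenvalues_ = evals
        self.explained_variance_ratio_ = (
            evals / total if total > 0 else np.zeros_like(evals)
        )
        self.cumulative_variance_ = np.cumsum(self.explained_variance_ratio_)
        if total > 0:
            self.cumulative_variance_[-1] = 1.0
        return self

    def transform(self, ensemble: Ensemble) -> np.ndarray:
        """Project members onto the principal components, shape (M, n_modes)."""
        if not hasattr(self, "components_"):
            raise AnalysisError("PCA model is not fitted")
        coords = ensemble.coords
        if coords.shape[1] != self.n_atoms_:
            raise AnalysisError(
                f"topology mismatch: {coords.shape[1]} atoms vs fitted {self.n_atoms_}"
            )
        fit_idx = None if self.fit_indices is None else np.asarray(self.fit_indices, int)
        aligned = _align_members(coords, fit_idx, self.mean_structure_coords_)
        a_idx = self._analysis_idx(self.n_atoms_)
        x = aligned[:, a_idx, :].reshape(coords.shape[0], -1)
        return (x - self.mean_) @ self.components_.T

    def fit_transform(self, ensemble: Ensemble) -> np.ndarray:
        return self.fit(ensemble).transform(ensemble)


def pca_fit(
    ensemble: Ensemble,
    fit_indices: np.ndarray | None = None,
    analysis_indices: np.ndarray | None = None,
) -> EnsemblePCA:
    return EnsemblePCA(fit_indices, analysis_indices).fit(ensemble)


def pca_project(model: EnsemblePCA, ensemble: Ensemble) -> np.ndarray:
    return model.transform(ensemble)


# ---------------------------------------------------------------------------
# Clustering


@dataclass
class ClusterResult:
    """Partition of an ensemble into RMSD-neighborhood clusters.

    Clusters are ordered by population (descending, ties broken by lowest
    representative member index); ``labels`` maps each member to its cluster
    rank in that order; ``representatives`` are the centroid member indices.
    """

    labels: np.ndarray
    representatives: np.ndarray
    populations: np.ndarray
    cutoff: float

    @property
    def n_clusters(self) -> int:
        return len(self.representatives)


class GromosClustering:
    """Greedy neighbor-counting conformational clustering.

    The member with the largest number of RMSD neighbors within ``cutoff``
    becomes a cluster centroid; it and its neighbors are removed and the
    procedure repeats.  Deterministic: ties pick the lowest member index.
    Before the pairwise RMSD matrix is built, all members are superposed on
    ``fit_indices`` to the first member (RMSD is then taken over
    ``analysis_indices``).
    """

    def __init__(
        self,
        cutoff: float = 0.3,
        analysis_indices: np.ndarray | None = None,
        fit_indices: np.ndarray | None = None,
    ):
        self.cutoff = cutoff
        self.analysis_indices = analysis_indices
        self.fit_indices = fit_indices

    def get_params(self, deep: bool = True) -> dict:
        return {
            "cutoff": self.cutoff,
            "analysis_indices": self.analysis_indices,
            "fit_indices": self.fit_indices,
        }

    def set_params(self, **params) -> "GromosClustering":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, ensemble: Ensemble) -> "GromosClustering":
        if self.cutoff <= 0:
            raise AnalysisError("cutoff must be > 0")
        coords = ensemble.coords
        m = coords.shape[0]
        fit_idx = None if self.fit_indices is None else np.asarray(self.fit_indices, int)
        aligned = _align_members(coords, fit_idx, coords[0])
        a_idx = (
            np.arange(coords.shape[1])
            if self.analysis_indices is None
            else np.asarray(self.analysis_indices, int)
        )
        x = aligned[:, a_idx, :]
        n_sel = a_idx.size
        # pairwise RMSD via the Gram trick
        flat = x.reshape(m, -1)
        sq = np.sum(flat**2, axis=1)
        d2 = sq[:, None] + sq[None, :] - 2.0 * flat @ flat.T
        rmsd_mat = np.sqrt(np.clip(d2, 0.0, None) / n_sel)
        adj = rmsd_mat <= self.cutoff
        np.fill_diagonal(adj, True)

        labels = np.full(m, -1, dtype=int)
        reps: list[int] = []
        sizes: list[int] = []
        remaining = np.ones(m, dtype=bool)
        cluster_id = 0
        while remaining.any():
            counts = (adj & remaining[None, :]).sum(axis=1)
            counts[~remaining] = -1
            center = int(np.argmax(counts))  # argmax takes the lowest index on ties
            members = np.flatnonzero(adj[center] & remaining)
            labels[members] = cluster_id
            reps.append(center)
            sizes.append(members.size)
            remaining[members] = False
            cluster_id += 1
        # reorder by population descending, ties -> lowest representative index
        order = sorted(range(cluster_id), key=lambda c: (-sizes[c], reps[c]))
        relabel = np.empty(cluster_id, dtype=int)
        relabel[order] = np.arange(cluster_id)
        self.labels_ = relabel[labels]
        self.representative_indices_ = np.array([reps[c] for c in order], dtype=int)
        self.populations_ = np.array([sizes[c] for c in order], dtype=int)
        self.rmsd_matrix_ = rmsd_mat
        return self

    def fit_predict(self, ensemble: Ensemble) -> np.ndarray:
        return self.fit(ensemble).labels_

    def result_(self) -> ClusterResult:
        return ClusterResult(
            labels=self.labels_,
            representatives=self.representative_indices_,
            populations=self.populations_,
            cutoff=self.cutoff,
        )


def cluster_gromos(
    ensemble: Ensemble,
    analysis_indices: np.ndarray | None = None,
    fit_indices: np.ndarray | None = None,
    cutoff_nm: float = 0.3,
) -> ClusterResult:
    return (
        GromosClustering(cutoff_nm, analysis_indices, fit_indices)
        .fit(ensemble)
        .result_()
    )


def cumulative_cluster_fraction(result: ClusterResult, ks) -> np.ndarray:
    """Fraction of all members contained in the top-k most populated
    clusters, for each k in ``ks`` (ascending)."""
    ks = np.asarray(ks, dtype=int)
    if np.any(ks < 1):
        raise AnalysisError("k must be >= 1")
    if np.any(np.diff(ks) < 0):
        raise AnalysisError("ks must be sorted ascending")
    total = result.populations.sum()
    cum = np.cumsum(result.populations)
    kk = np.minimum(ks, result.n_clusters)
    return cum[kk - 1] / total


# ---------------------------------------------------------------------------
# Dihedral series


@dataclass
class DihedralSeries:
    """Per-member rotation dihedral plus its circular histogram."""

    angles: np.ndarray  # degrees, (-180, 180]
    bin_edges: np.ndarray
    histogram: np.ndarray
    peaks: np.ndarray  # bin-center positions of local maxima, degrees
    residues: tuple[int, int, int, int]


def _circular_peaks(hist: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Local maxima of a circular histogram, ordered by height (descending).

    A bin is a peak when it is strictly higher than both circular neighbors;
    if the histogram has mass but no strict local maximum (e.g. a plateau or
    a single occupied bin ring), the global maximum bin is reported.
    """
    n = hist.size
    idx = [
        i for i in range(n)
        if hist[i] > 0 and hist[i] > hist[(i - 1) % n] and hist[i] > hist[(i + 1) % n]
    ]
    if not idx and hist.max() > 0:
        idx = [int(np.argmax(hist))]
    idx.sort(key=lambda i: (-hist[i], i))
    return centers[np.asarray(idx, dtype=int)] if idx else np.empty(0)


def dihedral_series(
    ensemble: Ensemble,
    residues: tuple[int, int, int, int],
    chain_id: str | None = None,
    bin_width: float = 5.0,
) -> DihedralSeries:
    """Rotation dihedral over the ensemble, from the C-alpha atoms of four
    residues, with a circular histogram (default 5 degree bins) and detected
    peaks."""
    first = ensemble[0]
    idx = []
    for res in residues:
        mask = (first.res_ids == res) & (first.atom_names == "CA")
        if chain_id is not None:
            mask &= first.chain_ids == chain_id
        hits = np.flatnonzero(mask)
        if hits.size == 0:
            raise AnalysisError(f"no C-alpha atom for residue {res}")
        idx.append(hits[0])
    angles = np.array(
        [dihedral(*(m.coords[i] for i in idx)) for m in ensemble.members]
    )
    n_bins = int(round(360.0 / bin_width))
    edges = np.linspace(-180.0, 180.0, n_bins + 1)
    # angles live in (-180, 180]; fold the single +180 edge into the last bin
    shifted = np.where(angles == 180.0, np.nextafter(180.0, 0.0), angles)
    hist, _ = np.histogram(shifted, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    peaks = _circular_peaks(hist, centers)
    return DihedralSeries(
        angles=angles, bin_edges=edges, histogram=hist, peaks=peaks,
        residues=tuple(int(r) for r in residues),
    )


# ---------------------------------------------------------------------------
# Free-energy surfaces


@dataclass
class FreeEnergySurface:
    """Boltzmann-inverted 2D histogram: F = -kT ln(rho / rho_max), kJ/mol.

    ``free_energy`` is a masked array (empty bins masked); the minimum over
    occupied bins is exactly 0.
    """

    free_energy: ma.MaskedArray
    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray
    kt: float

    @property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @property
    def y_centers(self) -> np.ndarray:
        return 0.5 * (self.y_edges[:-1] + self.y_edges[1:])

    def minimum_bin(self) -> tuple[int, int]:
        flat = int(np.argmax(self.counts))
        return np.unravel_index(flat, self.counts.shape)  # type: ignore[return-value]


def free_energy_surface(
    projections: np.ndarray,
    bins: int | tuple[int, int] = 40,
    kt_kjmol: float = KT_298K_KJMOL,
    ranges=None,
) -> FreeEnergySurface:
    """Free-energy surface over two collective variables (columns of
    ``projections``)."""
    xy = np.asarray(projections, dtype=float)
    if xy.ndim != 2 or xy.shape[1] < 2:
        raise AnalysisError("projections must be (n_samples, >=2)")
    if xy.shape[0] < 1:
        raise AnalysisError("no samples")
    if kt_kjmol <= 0:
        raise AnalysisError("kT must be > 0")
    counts, x_edges, y_edges = np.histogram2d(
        xy[:, 0], xy[:, 1], bins=bins, range=ranges
    )
    occupied = counts > 0
    f = np.zeros_like(counts)
    f[occupied] = -kt_kjmol * np.log(counts[occupied] / counts.max())
    free_energy = ma.masked_array(f, mask=~occupied)
    return FreeEnergySurface(
        free_energy=free_energy, x_edges=x_edges, y_edges=y_edges,
        counts=counts.astype(int), kt=kt_kjmol,
    )


def min_free_energy_path(
    surface: FreeEnergySurface,
    basin_a: tuple[int, int],
    basin_b: tuple[int, int],
) -> tuple[list[tuple[int, int]], float]:
    """Minimax path between two occupied bins on the 8-connected bin graph.

    The path minimizes the maximum free energy encountered; the barrier is
    that maximum minus F(basin_a).  Disconnected basins (through occupied
    bins) are an error.
    """
    f = surface.free_energy
    occ = ~f.mask
    for name, b in (("basin_a", basin_a), ("basin_b", basin_b)):
        if not (0 <= b[0] < occ.shape[0] and 0 <= b[1] < occ.shape[1]):
            raise AnalysisError(f"{name} {b} outside the grid")
        if not occ[b]:
            raise AnalysisError(f"{name} {b} is an empty bin")
    basin_a = (int(basin_a[0]), int(basin_a[1]))
    basin_b = (int(basin_b[0]), int(basin_b[1]))
    if basin_a == basin_b:
        return [], 0.0
    data = f.filled(np.inf)
    best = np.full(occ.shape, np.inf)
    parent: dict[tuple[int, int], tuple[int, int]] = {}
    start_cost = data[basin_a]
    best[basin_a] = start_cost
    heap = [(start_cost, basin_a)]
    neighbors = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    while heap:
        cost, node = heapq.heappop(heap)
        if cost > best[node]:
            continue
        if node == basin_b:
            break
        i, j = node
        for di, dj in neighbors:
            ni, nj = i + di, j + dj
            if not (0 <= ni < occ.shape[0] and 0 <= nj < occ.shape[1]):
                continue
            if not occ[ni, nj]:
                continue
            new_cost = max(cost, data[ni, nj])
            if new_cost < best[ni, nj]:
                best[ni, nj] = new_cost
                parent[(ni, nj)] = node
                heapq.heappush(heap, (new_cost, (ni, nj)))
    if not np.isfinite(best[basin_b]):
        raise AnalysisError(
            "basins are disconnected through occupied bins; "
            "coarsen the histogram or add samples"
        )
    path = [basin_b]
    while path[-1] != basin_a:
        path.append(parent[path[-1]])
    path.reverse()
    barrier = float(best[basin_b] - data[basin_a])
    return path, barrier


# ---------------------------------------------------------------------------
# COM distances and density maps


@dataclass
class DistanceSeries:
    """Per-member distance of a mobile-domain center of mass from a fixed
    reference position (nm)."""

    distances: np.ndarray
    reference_label: str


def com_distance_series(
    ensemble: Ensemble,
    mobile_indices: np.ndarray,
    fit_indices: np.ndarray,
    reference: Structure,
    reference_com: np.ndarray | None = None,
    weighting: str = "uniform",
) -> DistanceSeries:
    """Distance of the mobile-domain COM from its position in a reference
    structure, after superposing each member on ``fit_indices`` onto the
    reference."""
    ref_coords = reference.coords
    if reference_com is None:
        reference_com = center_of_mass(reference, mobile_indices, weighting)
    reference_com = np.asarray(reference_com, dtype=float)
    fit_idx = np.asarray(fit_indices, dtype=int)
    mob_idx = np.asarray(mobile_indices, dtype=int)
    out = np.empty(len(ensemble))
    for k, member in enumerate(ensemble.members):
        transform, _ = superpose(member.coords, ref_coords, fit_idx)
        moved = transform.apply_structure(member)
        com = center_of_mass(moved, mob_idx, weighting)
        out[k] = np.linalg.norm(com - reference_com)
    return DistanceSeries(distances=out, reference_label=reference.label)


@dataclass
class DensityMap3D:
    """Normalized 3D occupancy of a point (e.g. a domain COM) on a regular
    grid; density sums to 1."""

    origin: np.ndarray  # nm, corner of voxel (0,0,0)
    spacing: float  # nm
    density: np.ndarray  # (nx, ny, nz)
    reference_note: str = ""

    def isolevels(self, fractions=(0.1, 0.001)) -> np.ndarray:
        """Density values at the stated fractions of the maximum (the
        conventional rendering levels are 1/10 and 1/1000 of max)."""
        return self.density.max() * np.asarray(fractions, dtype=float)

    def max_voxel_center(self) -> np.ndarray:
        idx = np.unravel_index(int(np.argmax(self.density)), self.density.shape)
        return self.origin + (np.asarray(idx) + 0.5) * self.spacing


def density_map(
    ensemble: Ensemble,
    mobile_indices: np.ndarray,
    fit_indices: np.ndarray,
    reference: Structure | None = None,
    spacing: float = 0.2,
    pad: float = 0.2,
    weighting: str = "uniform",
) -> DensityMap3D:
    """3D histogram of the mobile-domain COM after superposition of every
    member on ``fit_indices`` onto a reference (default: first member)."""
    if len(ensemble) == 0:
        raise AnalysisError("empty ensemble")
    if spacing <= 0:
        raise AnalysisError("spacing must be > 0")
    ref = reference if reference is not None else ensemble[0]
    fit_idx = np.asarray(fit_indices, dtype=int)
    mob_idx = np.asarray(mobile_indices, dtype=int)
    coms = np.empty((len(ensemble), 3))
    for k, member in enumerate(ensemble.members):
        transform, _ = superpose(member.coords, ref.coords, fit_idx)
        moved = transform.apply_structure(member)
        coms[k] = center_of_mass(moved, mob_idx, weighting)
    lo = coms.min(axis=0) - pad
    hi = coms.max(axis=0) + pad
    n_vox = np.maximum(np.ceil((hi - lo) / spacing).astype(int), 1)
    edges = [lo[d] + spacing * np.arange(n_vox[d] + 1) for d in range(3)]
    hist, _ = np.histogramdd(coms, bins=edges)
    density = hist / hist.sum()
    return DensityMap3D(
        origin=lo, spacing=spacing, density=density,
        reference_note=f"fitted on {fit_idx.size} atoms to {ref.label}",
    )
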