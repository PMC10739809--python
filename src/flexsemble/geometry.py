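"""Rigid-body geometry kernel: superposition, RMSD, dihedrals, centers of
mass, gyration/inertia summaries.

Conventions: lengths in nm, angles in degrees, dihedral sign follows the
IUPAC convention (cis = 0, range (-180, 180], exactly -180 reported as +180).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .structures import Structure

# Standard atomic masses (u).  Unknown elements are a hard error for mass
# weighting rather than a silent unit mass.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974,
    "S": 32.06, "Se": 78.971, "Fe": 55.845, "Zn": 65.38, "Mg": 24.305,
    "Ca": 40.078, "Na": 22.990, "K": 39.098, "Cl": 35.45,
}


class GeometryError(ValueError):
    pass


@dataclass(frozen=True)
class RigidTransform:
    """x -> rotation @ x + translation, with det(rotation) = +1."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise GeometryError("rigid transform must be 3x3 rotation + 3-vector")
        if abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise GeometryError("rotation determinant != +1")
        if np.max(np.abs(R @ R.T - np.eye(3))) > 1e-9:
            raise GeometryError("rotation not orthonormal")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    def apply_structure(self, structure: Structure) -> Structure:
        return structure.with_coords(self.apply(structure.coords))

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


@dataclass(frozen=True)
class GyrationSummary:
    """Radius of gyration plus the gyration-tensor spectrum.

    ``rg**2 == eigenvalues.sum()`` (trace identity); ``axes`` columns are the
    principal axes matching ``eigenvalues`` (descending, nm^2).
    """

    rg: float
    eigenvalues: np.ndarray
    axes: np.ndarray
    degenerate: bool = False


def _atom_weights(structure: Structure, indices: np.ndarray, weighting: str) -> np.ndarray:
    idx = np.asarray(indices, dtype=int)
    if weighting == "uniform":
        return np.ones(idx.size)
    if weighting == "mass":
        try:
            return np.array([ATOMIC_MASSES[e] for e in structure.elements[idx]])
        except KeyError as exc:
            raise GeometryError(f"no atomic mass for element {exc.args[0]!r}") from None
    raise ValueError(f"weighting must be 'mass' or 'uniform', got {weighting!r}")


def superpose(
    mobile: np.ndarray | Structure,
    target: np.ndarray | Structure,
    fit_indices: np.ndarray | None = None,
    weights: np.ndarray | None = None,
) -> tuple[RigidTransform, float]:
    """Optimal least-squares rigid superposition of ``mobile`` onto ``target``.

    Returns the transform and the weighted RMSD over the fit set after
    applying it.  The rotation is always proper (reflections are rejected by
    construction).  Degenerate (collinear or < 3 point) fit sets are an error.
    """
    mob = mobile.coords if isinstance(mobile, Structure) else np.asarray(mobile, float)
    tgt = target.coords if isinstance(target, Structure) else np.asarray(target, float)
    if fit_indices is not None:
        idx = np.asarray(fit_indices, dtype=int)
        mob_fit, tgt_fit = mob[idx], tgt[idx]
    else:
        mob_fit, tgt_fit = mob, tgt
    if mob_fit.shape != tgt_fit.shape:
        raise GeometryError(
            f"fit-set size mismatch: {mob_fit.shape} vs {tgt_fit.shape}"
        )
    n = mob_fit.shape[0]
    if n < 3:
        raise GeometryError(f"need >= 3 fit points, got {n}")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
        raise GeometryError("invalid fit weights")
    wn = w / w.sum()
    mob_com = wn @ mob_fit
    tgt_com = wn @ tgt_fit
    mc = mob_fit - mob_com
    tc = tgt_fit - tgt_com
    # collinearity check: second singular value of the centered cloud
    sv = np.linalg.svd(np.sqrt(wn)[:, None] * mc, compute_uv=False)
    if sv[1] < 1e-9 * max(sv[0], 1e-30) or sv[0] < 1e-12:
        raise GeometryError("degenerate (collinear or coincident) fit set")
    rot, _ = Rotation.align_vectors(tc, mc, weights=wn)
    R = rot.as_matrix()
    transform = RigidTransform(R, tgt_com - R @ mob_com)
    dev = transform.apply(mob_fit) - tgt_fit
    rmsd_fit = float(np.sqrt(np.sum(wn[:, None] * dev**2)))
    return transform, rmsd_fit


def rmsd(
    a: np.ndarray | Structure,
    b: np.ndarray | Structure,
    analysis_indices: np.ndarray | None = None,
    fit_indices: np.ndarray | None = None,
) -> float:
    """RMSD between two conformers over ``analysis_indices``; if
    ``fit_indices`` is given, ``a`` is first superposed onto ``b`` there."""
    ca = a.coords if isinstance(a, Structure) else np.asarray(a, float)
    cb = b.coords if isinstance(b, Structure) else np.asarray(b, float)
    if ca.shape != cb.shape:
        raise GeometryError("coordinate shape mismatch")
    if fit_indices is not None:
        transform, _ = superpose(ca, cb, fit_indices)
        ca = transform.apply(ca)
    if analysis_indices is not None:
        idx = np.asarray(analysis_indices, dtype=int)
        if idx.size == 0:
            raise GeometryError("empty analysis selection")
        ca, cb = ca[idx], cb[idx]
    if ca.shape[0] == 0:
        raise GeometryError("empty analysis selection")
    return float(np.sqrt(np.mean(np.sum((ca - cb) ** 2, axis=1))))


def dihedral(p1, p2, p3, p4) -> float:
    """Dihedral angle in degrees, IUPAC sign, range (-180, 180].

    Coincident consecutive points or a collinear triplet make the angle
    undefined and raise :class:`GeometryError`.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    for b in (b1, b2, b3):
        if np.linalg.norm(b) < 1e-12:
            raise GeometryError("coincident consecutive points in dihedral")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    scale = np.linalg.norm(b1) * np.linalg.norm(b2)
    if np.linalg.norm(n1) < 1e-9 * scale or np.linalg.norm(n2) < 1e-9 * np.linalg.norm(b2) * np.linalg.norm(b3):
        raise GeometryError("collinear triplet: dihedral undefined")
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b2 / np.linalg.norm(b2))
    ang = float(np.degrees(np.arctan2(y, x)))
    if ang <= -180.0:
        ang += 360.0
    return ang


def center_of_mass(
    structure: Structure,
    indices: np.ndarray | None = None,
    weighting: str = "mass",
) -> np.ndarray:
    """Weighted centroid of a selection (nm)."""
    idx = np.arange(structure.n_atoms) if indices is None else np.asarray(indices, int)
    if idx.size == 0:
        raise GeometryError("empty selection for center of mass")
    w = _atom_weights(structure, idx, weighting)
    return (w[:, None] * structure.coords[idx]).sum(axis=0) / w.sum()


def gyration_summary(
    structure: Structure,
    indices: np.ndarray | None = None,
    weighting: str = "mass",
) -> GyrationSummary:
    """Eigen-decomposition of the weighted gyration tensor.

    Rg^2 equals the tensor trace; the principal axes double as the inertia
    ellipsoid of the selection (the inertia and gyration tensors share
    eigenvectors).
    """
    idx = np.arange(structure.n_atoms) if indices is None else np.asarray(indices, int)
    if idx.size < 2:
        raise GeometryError("gyration summary needs >= 2 atoms")
    w = _atom_weights(structure, idx, weighting)
    wn = w / w.sum()
    x = structure.coords[idx] - wn @ structure.coords[idx]
    tensor = (wn[:, None] * x).T @ x
    evals, evecs = np.linalg.eigh(tensor)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    rg = float(np.sqrt(evals.sum()))
    # axes are ill-defined for a zero tensor or (near-)equal eigenvalues
    scale = max(evals[0], 1e-30)
    degenerate = bool(evals[0] < 1e-24 or np.min(-np.diff(evals)) < 1e-9 * scale)
    return GyrationSummary(rg=rg, eigenvalues=evals, axes=evecs, degenerate=degenerate)
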