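"""Synthetic multidomain fragment ensembles with planted ground truth.

The generator emulates the two conformer pools of a three-domain protein
(domains A-B-C, flexible linkers) that share the middle domain B: fragment
AB stands in for a tandem-SH2-like pool, fragment BC for a
C-SH2+catalytic-domain-like pool.  Domains are rigid pseudo-backbone bead
chains (N/CA/C per residue on a compact serpentine lattice, C-alpha spacing
0.38 nm); heterogeneity enters only through planted, exactly known degrees
of freedom:

* hinge rotations of domain A about axes through its linker pivot
  (recoverable as PCA eigenmodes),
* a rotation of domain C about the B-C linker axis whose value equals a
  planted interdomain dihedral drawn from a von Mises mixture
  (default modes at -100 and -30 degrees),
* the resulting per-pair A/C steric-clash counts, recorded by an O(N^2)
  brute force.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structures import Structure, Ensemble, DomainDefinition
from .assembly import AssemblyConfig
from .geometry import dihedral as _dihedral

CA_SPACING = 0.38  # nm, consecutive C-alpha distance
# backbone offsets along the CA polyline chosen so that the inter-residue
# C(i)-N(i+1) distance is 0.35 * step = 0.133 nm for the canonical step
_C_FRAC = 0.329
_N_FRAC = 0.321


class SyntheticError(ValueError):
    pass


@dataclass(frozen=True)
class HingeMode:
    """A planted rigid-rotation mode of domain A about the linker pivot.

    ``sigma_deg`` is the circular standard deviation of the rotation angle;
    alternatively ``eigvar_nm2`` fixes the linearized PCA eigenvalue
    (variance of the induced C-alpha displacement mode) and the angle width
    is derived from the lever arms.
    """

    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    sigma_deg: float | None = None
    eigvar_nm2: float | None = None


@dataclass
class SyntheticEnsembleSpec:
    """Stated world for the toy fragment pools.

    Defaults mirror the real system's proportions: domain bead counts
    100/100/250 (N-SH2- / C-SH2- / catalytic-domain-sized), 6-residue
    linkers, 20 members per fragment pool (the representative count used for
    pairwise recombination), hinge width ~5.7 deg (kappa = 100) and a
    bimodal interdomain dihedral at -100/-30 degrees with 60/40 weights.
    """

    seed: int = 1
    n_beads: tuple[int, int, int] = (100, 100, 250)
    linker_len: tuple[int, int] = (6, 6)
    kappa: float = 100.0
    n_members: tuple[int, int] = (20, 20)
    hinge_modes: tuple[HingeMode, ...] = (HingeMode(),)
    dihedral_means_deg: tuple[float, ...] = (-100.0, -30.0)
    dihedral_weights: tuple[float, ...] = (0.6, 0.4)
    dihedral_kappa: float = 33.0
    target_clash_fraction: float | None = None
    clash_cutoff: float = 0.20
    max_pair_grid: int = 500  # brute-force clash ground truth only up to this many pairs

    def __post_init__(self) -> None:
        if len(self.dihedral_means_deg) != len(self.dihedral_weights):
            raise SyntheticError("dihedral means/weights length mismatch")
        if abs(sum(self.dihedral_weights) - 1.0) > 1e-9:
            raise SyntheticError("dihedral weights must sum to 1")
        if min(self.n_beads) < 8:
            raise SyntheticError("domains need at least 8 beads")
        if min(self.linker_len) < 1:
            raise SyntheticError("linkers need at least 1 residue")
        if self.kappa <= 0 or self.dihedral_kappa <= 0:
            raise SyntheticError("concentration parameters must be > 0")


@dataclass
class GroundTruth:
    """Everything the generator planted, for recovery tests."""

    spec: SyntheticEnsembleSpec
    domain_defs: dict[str, DomainDefinition]
    ab_domain_indices: dict[str, np.ndarray]  # atom indices in the AB topology
    bc_domain_indices: dict[str, np.ndarray]
    com_a: np.ndarray  # (n_ab, 3) uniform-weight COM of domain A per member
    com_c: np.ndarray  # (n_bc, 3)
    com_b: np.ndarray  # (3,) shared-domain COM (identical in every member)
    hinge_axes: np.ndarray  # (n_modes, 3)
    hinge_sigmas_rad: np.ndarray
    mode_variances_nm2: np.ndarray  # linearized eigenvalue per planted mode
    hinge_angles_rad: np.ndarray  # (n_ab, n_modes) sampled angles
    dihedral_residues: tuple[int, int, int, int]
    dihedral_targets_deg: np.ndarray  # (n_bc,)
    pair_clash_counts: np.ndarray | None  # (n_ab, n_bc) brute force, or None
    rg_ab: np.ndarray
    rg_bc: np.ndarray
    junction_res: int

    def assembly_config(self, **overrides) -> AssemblyConfig:
        kwargs = dict(
            shared_domain=self.domain_defs["B"],
            mobile_domain=self.domain_defs["A"],
            static_domain=self.domain_defs["C"],
            clash_cutoff=self.spec.clash_cutoff,
            junction_res=self.junction_res,
        )
        kwargs.update(overrides)
        return AssemblyConfig(**kwargs)


# ---------------------------------------------------------------------------
# geometry builders


def _serpentine(n: int) -> np.ndarray:
    """Compact bead chain: boustrophedon walk over a cubic lattice confined
    to the smallest cube holding n sites; consecutive beads are adjacent."""
    side = int(np.ceil(n ** (1.0 / 3.0)))
    pts = []
    for iz in range(side):
        ys = range(side) if iz % 2 == 0 else range(side - 1, -1, -1)
        for k, iy in enumerate(ys):
            fwd = (iz * side + k) % 2 == 0
            xs = range(side) if fwd else range(side - 1, -1, -1)
            for ix in xs:
                pts.append((ix, iy, iz))
                if len(pts) == n:
                    coords = np.asarray(pts, dtype=float) * CA_SPACING
                    return coords - coords.mean(axis=0)
    raise AssertionError("unreachable")


def _rotation_about(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    x, y, z = axis
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    one_c = 1.0 - c
    return np.array([
        [c + x * x * one_c, x * y * one_c - z * s, x * z * one_c + y * s],
        [y * x * one_c + z * s, c + y * y * one_c, y * z * one_c - x * s],
        [z * x * one_c - y * s, z * y * one_c + x * s, c + z * z * one_c],
    ])


def _orient_cloud(cloud: np.ndarray, anchor_index: int, direction: np.ndarray) -> np.ndarray:
    """Rotate a centered cloud so that (centroid - anchor bead) points along
    ``direction``, then translate so the anchor bead sits at the origin."""
    direction = np.asarray(direction, float)
    direction = direction / np.linalg.norm(direction)
    v = cloud.mean(axis=0) - cloud[anchor_index]
    v_norm = np.linalg.norm(v)
    if v_norm < 1e-12:
        rot = np.eye(3)
    else:
        v_unit = v / v_norm
        axis = np.cross(v_unit, direction)
        s = np.linalg.norm(axis)
        c = float(np.dot(v_unit, direction))
        if s < 1e-12:
            rot = np.eye(3) if c > 0 else _rotation_about(
                _any_perpendicular(v_unit), np.pi
            )
        else:
            rot = _rotation_about(axis / s, np.arctan2(s, c))
    out = (cloud - cloud[anchor_index]) @ rot.T
    return out


def _any_perpendicular(v: np.ndarray) -> np.ndarray:
    trial = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(trial, v)) > 0.9:
        trial = np.array([0.0, 1.0, 0.0])
    p = np.cross(v, trial)
    return p / np.linalg.norm(p)


def _backbone_from_polyline(ca: np.ndarray) -> np.ndarray:
    """Expand a CA polyline (n, 3) into N/CA/C atoms (3n, 3) lying on it."""
    n = ca.shape[0]
    seg = np.diff(ca, axis=0)
    out = np.empty((3 * n, 3))
    for i in range(n):
        incoming = seg[i - 1] if i > 0 else seg[0]
        outgoing = seg[i] if i < n - 1 else seg[-1]
        out[3 * i + 0] = ca[i] - _N_FRAC * incoming
        out[3 * i + 1] = ca[i]
        out[3 * i + 2] = ca[i] + _C_FRAC * outgoing
    return out


def _chain_structure(ca: np.ndarray, res_ids: np.ndarray, label: str) -> Structure:
    n = ca.shape[0]
    coords = _backbone_from_polyline(ca)
    return Structure(
        atom_names=np.tile(np.array(["N", "CA", "C"]), n),
        elements=np.tile(np.array(["N", "C", "C"]), n),
        res_ids=np.repeat(res_ids, 3),
        res_names=np.repeat(np.full(n, "GLY", dtype="U5"), 3),
        chain_ids=np.full(3 * n, "A", dtype="U4"),
        coords=coords,
        label=label,
    )


# ---------------------------------------------------------------------------
# base layout


class _Layout:
    """Deterministic base pose of the full chain A-linker1-B-linker2-C.

    Domain C swings on a cone about the B-C linker axis (the planted
    dihedral); domain A is anchored pointing toward the position C's
    centroid occupies at ``approach_dihedral_deg``, so pairs whose planted
    angles bring the two domains together clash while others stay clear.
    ``approach_tilt_deg`` rotates A's base direction away from that contact
    direction (0 = maximal contact); it is the one knob the
    target-clash-fraction search is allowed to move.
    """

    def __init__(
        self,
        spec: SyntheticEnsembleSpec,
        approach_tilt_deg: float = 18.0,
        approach_dihedral_deg: float = -30.0,
    ):
        n_a, n_b, n_c = spec.n_beads
        l1, l2 = spec.linker_len
        self.res_a = np.arange(1, n_a + 1)
        self.res_l1 = np.arange(n_a + 1, n_a + l1 + 1)
        self.res_b = np.arange(n_a + l1 + 1, n_a + l1 + n_b + 1)
        self.res_l2 = np.arange(n_a + l1 + n_b + 1, n_a + l1 + n_b + l2 + 1)
        self.res_c = np.arange(
            n_a + l1 + n_b + l2 + 1, n_a + l1 + n_b + l2 + n_c + 1
        )

        b = _serpentine(n_b)
        self.ca_b = b - b.mean(axis=0)
        self.b_first = self.ca_b[0]
        self.b_last = self.ca_b[-1]

        d1 = (l1 + 1) * CA_SPACING
        d2 = (l2 + 1) * CA_SPACING
        self.u2 = np.array([1.0, 0.0, 0.0])
        self.pivot_a = self.b_first  # hinge point of domain A
        self.anchor_c = self.b_last + d2 * self.u2  # first CA of domain C
        self.axis_c = self.u2  # B->C linker axis; C rotates about it

        c = _serpentine(n_c)
        # domain C is anchored at its first bead with the centroid pushed
        # off the linker axis, so the planted dihedral sweeps it on a cone
        off = (self.u2 + np.array([0.0, 1.0, 0.0])) / np.sqrt(2.0)
        self.ca_c = _orient_cloud(c, 0, off) + self.anchor_c
        self.ca_l2 = self._linker(self.b_last, self.anchor_c, l2)

        # where C's centroid sits when the planted dihedral equals the
        # approach value; A's base direction points there (plus a tilt)
        base_dih = self._dihedral_of(self.ca_c)
        alpha = np.radians(_wrap_deg(approach_dihedral_deg - base_dih)) * self._dihedral_sign()
        c_at_approach = (
            (self.ca_c.mean(axis=0) - self.b_last)
            @ _rotation_about(self.axis_c, alpha).T + self.b_last
        )
        u1 = c_at_approach - self.b_first
        u1 /= np.linalg.norm(u1)
        tilt_axis = _any_perpendicular(u1)
        self.u1 = u1 @ _rotation_about(
            np.array([0.0, 0.0, 1.0])
            if abs(u1[2]) < 0.9 else tilt_axis,
            np.radians(approach_tilt_deg),
        ).T
        self.anchor_a = self.b_first + d1 * self.u1  # last CA of domain A

        a = _serpentine(n_a)
        # domain A extends outward along u1, anchored at its last bead
        self.ca_a = _orient_cloud(a, n_a - 1, self.u1) + self.anchor_a
        self.ca_l1 = self._linker(self.anchor_a, self.b_first, l1)

        if self._min_dist(self.ca_a, self.ca_b) < 0.5 * CA_SPACING:
            raise SyntheticError("infeasible geometry: domain A overlaps B at base pose")
        if self._min_dist(self.ca_c, self.ca_b) < 0.5 * CA_SPACING:
            raise SyntheticError("infeasible geometry: domain C overlaps B at base pose")

    def _dihedral_of(self, ca_c: np.ndarray) -> float:
        """Marker dihedral for a given C-domain pose."""
        markers = self.dihedral_residues_given(ca_c)
        return _dihedral(*markers)

    def dihedral_residues_given(self, ca_c: np.ndarray):
        p1 = self.ca_b[self._most_off_axis(self.ca_b)]
        p2 = self.b_last
        p3 = ca_c[0]
        p4 = ca_c[self._most_off_axis(ca_c)]
        return p1, p2, p3, p4

    def _most_off_axis(self, ca: np.ndarray) -> int:
        rel = ca - self.b_last
        perp = rel - np.outer(rel @ self.axis_c, self.axis_c)
        return int(np.argmax(np.sum(perp**2, axis=1)))

    def _dihedral_sign(self) -> float:
        """+1 if rotating C by +alpha about the axis raises the dihedral."""
        p1, p2, p3, p4 = self.dihedral_residues_given(self.ca_c)
        base = _dihedral(p1, p2, p3, p4)
        p4_rot = (p4 - self.b_last) @ _rotation_about(
            self.axis_c, np.radians(1.0)
        ).T + self.b_last
        return 1.0 if _wrap_deg(_dihedral(p1, p2, p3, p4_rot) - base) > 0 else -1.0

    @staticmethod
    def _linker(start: np.ndarray, end: np.ndarray, n: int) -> np.ndarray:
        t = (np.arange(1, n + 1) / (n + 1.0))[:, None]
        return start + t * (end - start)

    @staticmethod
    def _min_dist(x: np.ndarray, y: np.ndarray) -> float:
        d2 = np.sum((x[:, None, :] - y[None, :, :]) ** 2, axis=-1)
        return float(np.sqrt(d2.min()))

    # full-chain CA polylines -------------------------------------------------

    def ab_polyline(self) -> tuple[np.ndarray, np.ndarray]:
        ca = np.vstack([self.ca_a, self.ca_l1, self.ca_b])
        res = np.concatenate([self.res_a, self.res_l1, self.res_b])
        return ca, res

    def bc_polyline(self) -> tuple[np.ndarray, np.ndarray]:
        ca = np.vstack([self.ca_b, self.ca_l2, self.ca_c])
        res = np.concatenate([self.res_b, self.res_l2, self.res_c])
        return ca, res

    def full_polyline(self) -> tuple[np.ndarray, np.ndarray]:
        ca = np.vstack([self.ca_a, self.ca_l1, self.ca_b, self.ca_l2, self.ca_c])
        res = np.concatenate(
            [self.res_a, self.res_l1, self.res_b, self.res_l2, self.res_c]
        )
        return ca, res

    def domain_defs(self) -> dict[str, DomainDefinition]:
        return {
            "A": DomainDefinition("A", ((int(self.res_a[0]), int(self.res_a[-1])),)),
            "B": DomainDefinition("B", ((int(self.res_b[0]), int(self.res_b[-1])),)),
            "C": DomainDefinition("C", ((int(self.res_c[0]), int(self.res_c[-1])),)),
        }

    def dihedral_residues(self) -> tuple[int, int, int, int]:
        # p2/p3 sit on the rotation axis (B's last bead, C's first bead);
        # p1/p4 are the most off-axis beads of their domains, so rotating C
        # about the axis shifts the dihedral by exactly the rotation angle
        return (
            int(self.res_b[self._most_off_axis(self.ca_b)]),
            int(self.res_b[-1]),
            int(self.res_c[0]),
            int(self.res_c[self._most_off_axis(self.ca_c)]),
        )


# ---------------------------------------------------------------------------
# generation


def _mode_sigma_rad(mode: HingeMode, lever_sq: float) -> float:
    if mode.eigvar_nm2 is not None:
        return float(np.sqrt(mode.eigvar_nm2 / lever_sq))
    if mode.sigma_deg is not None:
        return float(np.radians(mode.sigma_deg))
    raise SyntheticError("hinge mode needs sigma_deg or eigvar_nm2")


def _brute_force_pair_clashes(
    a_coords: np.ndarray, c_coords: np.ndarray, cutoff: float
) -> np.ndarray:
    """All-pairs O(N^2) clash counts; a_coords (n1, Na, 3), c_coords
    (n2, Nc, 3).  Independent of the KD-tree production path."""
    n1, n2 = a_coords.shape[0], c_coords.shape[0]
    counts = np.empty((n1, n2), dtype=int)
    cut2 = cutoff * cutoff
    for i in range(n1):
        ai = a_coords[i]
        for j in range(n2):
            d2 = np.sum((ai[:, None, :] - c_coords[j][None, :, :]) ** 2, axis=-1)
            counts[i, j] = int(np.sum(d2 < cut2))
    return counts


def _sample_members(
    spec: SyntheticEnsembleSpec, layout: _Layout, rng: np.random.Generator
):
    """Draw hinge angles and dihedral targets, with a self-avoidance check
    (members whose A/C beads run into domain B are redrawn)."""
    n_ab, n_bc = spec.n_members
    modes = spec.hinge_modes
    default_sigma = 1.0 / np.sqrt(spec.kappa)

    # lever arms of each hinge mode over the A-domain C-alphas
    axes, sigmas, lever_sq = [], [], []
    for mode in modes:
        axis = np.asarray(mode.axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        disp = np.cross(axis, layout.ca_a - layout.pivot_a)
        lsq = float(np.sum(disp**2))
        if mode.sigma_deg is None and mode.eigvar_nm2 is None:
            mode = HingeMode(tuple(axis), sigma_deg=np.degrees(default_sigma))
        axes.append(axis)
        sigmas.append(_mode_sigma_rad(mode, lsq))
        lever_sq.append(lsq)
    axes = np.asarray(axes)
    sigmas = np.asarray(sigmas)
    mode_vars = sigmas**2 * np.asarray(lever_sq)

    hinge_angles = np.empty((n_ab, len(modes)))
    ab_ca = np.empty((n_ab,) + layout.ab_polyline()[0].shape)
    base_ab, _ = layout.ab_polyline()
    n_moving = layout.ca_a.shape[0] + layout.ca_l1.shape[0]
    for k in range(n_ab):
        for _attempt in range(200):
            angles = np.array(
                [rng.vonmises(0.0, 1.0 / s**2) if s > 0 else 0.0 for s in sigmas]
            )
            moved = base_ab[:n_moving] - layout.pivot_a
            for axis, ang in zip(axes, angles):
                moved = moved @ _rotation_about(axis, ang).T
            moved = moved + layout.pivot_a
            if _Layout._min_dist(moved[: layout.ca_a.shape[0]], layout.ca_b) >= 0.5 * CA_SPACING:
                break
        else:
            raise SyntheticError("could not draw a self-avoiding AB member")
        hinge_angles[k] = angles
        ab_ca[k] = np.vstack([moved, layout.ca_b])

    # base dihedral of the marker beads, and the rotation sign convention
    res_markers = layout.dihedral_residues()
    _, ab_res = layout.ab_polyline()
    bc_base, bc_res = layout.bc_polyline()
    marker_pos = {
        r: bc_base[np.flatnonzero(bc_res == r)[0]] for r in res_markers
    }
    base_dihedral = _dihedral(*(marker_pos[r] for r in res_markers))
    # empirical sign: rotate the p4 marker by +1 degree and see which way
    p4 = marker_pos[res_markers[3]]
    p4_rot = (p4 - layout.b_last) @ _rotation_about(layout.axis_c, np.radians(1.0)).T + layout.b_last
    trial = _dihedral(
        marker_pos[res_markers[0]], marker_pos[res_markers[1]],
        marker_pos[res_markers[2]], p4_rot,
    )
    sign = 1.0 if _wrap_deg(trial - base_dihedral) > 0 else -1.0

    means = np.asarray(spec.dihedral_means_deg, dtype=float)
    weights = np.asarray(spec.dihedral_weights, dtype=float)
    n_b_beads = layout.ca_b.shape[0]
    dihedral_targets = np.empty(n_bc)
    bc_ca = np.empty((n_bc,) + bc_base.shape)
    for k in range(n_bc):
        for _attempt in range(200):
            comp = rng.choice(len(means), p=weights)
            if np.isfinite(spec.dihedral_kappa):
                target = np.degrees(
                    rng.vonmises(np.radians(means[comp]), spec.dihedral_kappa)
                )
            else:  # rigid linker: the planted mode value, exactly
                target = float(means[comp])
            alpha = sign * np.radians(_wrap_deg(target - base_dihedral))
            rot = _rotation_about(layout.axis_c, alpha)
            moving = bc_base[n_b_beads:] - layout.b_last
            moved = moving @ rot.T + layout.b_last
            c_part = moved[layout.ca_l2.shape[0]:]
            if _Layout._min_dist(c_part, layout.ca_b) >= 0.5 * CA_SPACING:
                break
        else:
            raise SyntheticError("could not draw a self-avoiding BC member")
        dihedral_targets[k] = target
        bc_ca[k] = np.vstack([layout.ca_b, moved])
    return (
        ab_ca, bc_ca, hinge_angles, dihedral_targets,
        axes, sigmas, mode_vars, base_dihedral,
    )


def _wrap_deg(angle: float) -> float:
    """Wrap to (-180, 180]."""
    wrapped = (angle + 180.0) % 360.0 - 180.0
    return 180.0 if wrapped == -180.0 else wrapped


def generate_fragment_ensembles(
    spec: SyntheticEnsembleSpec,
) -> tuple[Ensemble, Ensemble, GroundTruth]:
    """Build the AB and BC fragment pools plus their ground truth.

    If ``spec.target_clash_fraction`` is set, the base direction of domain A
    is chosen (once, from a fixed candidate grid) so that the fraction of
    member pairs with at least 100 clashes is closest to the target.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.target_clash_fraction is None:
        layout = _Layout(spec)
        sampled = _sample_members(spec, layout, rng)
    else:
        best = None
        for tilt in np.linspace(0.0, 40.0, 11):
            trial_layout = _Layout(spec, approach_tilt_deg=tilt)
            trial_rng = np.random.default_rng(spec.seed)
            trial = _sample_members(spec, trial_layout, trial_rng)
            counts = _clash_counts_for(spec, trial_layout, trial)
            frac = float(np.mean(counts >= 100))
            score = abs(frac - spec.target_clash_fraction)
            if best is None or score < best[0]:
                best = (score, trial_layout, trial)
        _, layout, sampled = best
    (ab_ca, bc_ca, hinge_angles, dihedral_targets,
     axes, sigmas, mode_vars, _base_dih) = sampled

    _, ab_res = layout.ab_polyline()
    _, bc_res = layout.bc_polyline()
    ab_members = [
        _chain_structure(ab_ca[k], ab_res, f"synthetic-AB#{k}")
        for k in range(ab_ca.shape[0])
    ]
    bc_members = [
        _chain_structure(bc_ca[k], bc_res, f"synthetic-BC#{k}")
        for k in range(bc_ca.shape[0])
    ]
    ensemble_ab = Ensemble(ab_members)
    ensemble_bc = Ensemble(bc_members)

    defs = layout.domain_defs()
    ab_idx = {
        name: np.flatnonzero(defs[name].mask(ab_members[0]))
        for name in ("A", "B")
    }
    bc_idx = {
        name: np.flatnonzero(defs[name].mask(bc_members[0]))
        for name in ("B", "C")
    }

    com_a = np.array([
        m.coords[ab_idx["A"]].mean(axis=0) for m in ab_members
    ])
    com_c = np.array([
        m.coords[bc_idx["C"]].mean(axis=0) for m in bc_members
    ])
    com_b = ab_members[0].coords[ab_idx["B"]].mean(axis=0)

    pair_counts = None
    if ab_ca.shape[0] * bc_ca.shape[0] <= spec.max_pair_grid:
        pair_counts = _clash_counts_for(spec, layout, sampled)

    def _rg(m: Structure) -> float:
        x = m.coords - m.coords.mean(axis=0)
        return float(np.sqrt(np.mean(np.sum(x**2, axis=1))))

    junction = int(layout.res_b[len(layout.res_b) // 2])
    truth = GroundTruth(
        spec=spec,
        domain_defs=defs,
        ab_domain_indices=ab_idx,
        bc_domain_indices=bc_idx,
        com_a=com_a,
        com_c=com_c,
        com_b=com_b,
        hinge_axes=axes,
        hinge_sigmas_rad=sigmas,
        mode_variances_nm2=mode_vars,
        hinge_angles_rad=hinge_angles,
        dihedral_residues=layout.dihedral_residues(),
        dihedral_targets_deg=dihedral_targets,
        pair_clash_counts=pair_counts,
        rg_ab=np.array([_rg(m) for m in ab_members]),
        rg_bc=np.array([_rg(m) for m in bc_members]),
        junction_res=junction,
    )
    return ensemble_ab, ensemble_bc, truth


def _clash_counts_for(spec: SyntheticEnsembleSpec, layout: _Layout, sampled) -> np.ndarray:
    """Brute-force A-vs-C clash counts for every member pair, over the full
    N/CA/C atom sets (the shared domain B has an identical pose in both
    pools, so pairwise superposition at B is the identity)."""
    ab_ca, bc_ca = sampled[0], sampled[1]
    _, ab_res = layout.ab_polyline()
    _, bc_res = layout.bc_polyline()
    n_a = layout.ca_a.shape[0]
    a_atoms = np.stack([
        _backbone_from_polyline(ab_ca[k])[: 3 * n_a] for k in range(ab_ca.shape[0])
    ])
    n_b_l2 = layout.ca_b.shape[0] + layout.ca_l2.shape[0]
    c_atoms = np.stack([
        _backbone_from_polyline(bc_ca[k])[3 * n_b_l2:] for k in range(bc_ca.shape[0])
    ])
    return _brute_force_pair_clashes(a_atoms, c_atoms, spec.clash_cutoff)


def carve_parent(
    spec: SyntheticEnsembleSpec,
) -> tuple[Structure, Structure, Structure]:
    """One full-length conformer plus its two overlapping fragments.

    The fragments are atom subsets of the parent (residues up to the end of
    B, and from the start of B), so reassembling them at the default
    junction must reproduce the parent exactly.
    """
    rng = np.random.default_rng(spec.seed + 1)
    layout = _Layout(spec)
    full_ca, full_res = layout.full_polyline()

    # one draw of the planted degrees of freedom
    n_moving_a = layout.ca_a.shape[0] + layout.ca_l1.shape[0]
    moved = full_ca.copy()
    for mode in spec.hinge_modes:
        axis = np.asarray(mode.axis, float)
        axis = axis / np.linalg.norm(axis)
        sigma = (
            np.radians(mode.sigma_deg)
            if mode.sigma_deg is not None
            else 1.0 / np.sqrt(spec.kappa)
        )
        ang = rng.vonmises(0.0, 1.0 / sigma**2) if sigma > 0 else 0.0
        block = moved[:n_moving_a] - layout.pivot_a
        moved[:n_moving_a] = block @ _rotation_about(axis, ang).T + layout.pivot_a
    n_head = n_moving_a + layout.ca_b.shape[0]
    comp = rng.choice(len(spec.dihedral_means_deg), p=np.asarray(spec.dihedral_weights))
    if np.isfinite(spec.dihedral_kappa):
        target = np.degrees(
            rng.vonmises(np.radians(spec.dihedral_means_deg[comp]), spec.dihedral_kappa)
        )
    else:
        target = float(spec.dihedral_means_deg[comp])
    res_markers = layout.dihedral_residues()
    pos = {r: moved[np.flatnonzero(full_res == r)[0]] for r in res_markers}
    base_dih = _dihedral(*(pos[r] for r in res_markers))
    p4_rot = (pos[res_markers[3]] - layout.b_last) @ _rotation_about(
        layout.axis_c, np.radians(1.0)
    ).T + layout.b_last
    trial = _dihedral(pos[res_markers[0]], pos[res_markers[1]], pos[res_markers[2]], p4_rot)
    sign = 1.0 if _wrap_deg(trial - base_dih) > 0 else -1.0
    alpha = sign * np.radians(_wrap_deg(target - base_dih))
    tail = moved[n_head:] - layout.b_last
    moved[n_head:] = tail @ _rotation_about(layout.axis_c, alpha).T + layout.b_last

    parent = _chain_structure(moved, full_res, "synthetic-parent")
    b_end = int(layout.res_b[-1])
    b_start = int(layout.res_b[0])
    idx_ab = np.flatnonzero(parent.res_ids <= b_end)
    idx_bc = np.flatnonzero(parent.res_ids >= b_start)
    frag_ab = parent.subset(idx_ab, label="synthetic-parent-AB")
    frag_bc = parent.subset(idx_bc, label="synthetic-parent-BC")
    return parent, frag_ab, frag_bc
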