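"""Fragment-pair recombination with steric-clash filtering.

Two fragment ensembles sharing a common (middle) domain are cross-combined:
each mobile-fragment representative is rigidly superposed onto each
static-fragment representative at the shared domain's C-alpha atoms, clashes
between the two non-shared domains are counted, pairs below the clash-count
threshold are kept, and accepted pairs are stitched into full-length
conformers at a junction residue inside the shared domain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structures import Structure, Ensemble, DomainDefinition, select, StructureError
from .geometry import superpose, RigidTransform

logger = logging.getLogger(__name__)


class AssemblyError(ValueError):
    pass


@dataclass
class AssemblyConfig:
    """Settings for pairwise recombination.

    ``clash_cutoff`` is the heavy-atom distance below which a cross pair of
    atoms counts as one clash (nm); ``clash_threshold`` is the number of
    clashes at which a pair is discarded (pass iff count < threshold, default
    100).  ``junction_res`` is the residue where the stitched conformer
    switches from the mobile fragment to the static fragment; it must lie
    inside the shared domain (default: first residue of the shared domain's
    second half).
    """

    shared_domain: DomainDefinition
    mobile_domain: DomainDefinition
    static_domain: DomainDefinition
    clash_cutoff: float = 0.20
    clash_threshold: int = 100
    junction_res: int | None = None

    def __post_init__(self) -> None:
        if self.clash_cutoff <= 0:
            raise AssemblyError("clash_cutoff must be > 0")
        if self.clash_threshold < 0:
            raise AssemblyError("clash_threshold must be >= 0")
        if self.junction_res is None:
            residues = [r for a, b in self.shared_domain.ranges for r in range(a, b + 1)]
            self.junction_res = residues[len(residues) // 2]
        inside = any(a <= self.junction_res <= b for a, b in self.shared_domain.ranges)
        if not inside:
            raise AssemblyError(
                f"junction residue {self.junction_res} lies outside the shared domain"
            )


@dataclass(frozen=True)
class ClashReport:
    """Clash count for one representative pair (i: mobile, j: static)."""

    i: int
    j: int
    clash_count: int
    passed: bool


@dataclass
class ClashReportSet:
    """All pairwise reports plus the counts matrix and summary."""

    reports: list[ClashReport]
    counts: np.ndarray  # (n_mobile, n_static)
    threshold: int

    def summary(self) -> dict:
        flat = self.counts.ravel()
        return {
            "n_pairs": int(flat.size),
            "n_zero_clash": int(np.sum(flat == 0)),
            "n_pass": int(np.sum(flat < self.threshold)),
            "n_fail": int(np.sum(flat >= self.threshold)),
        }

    def passing_pairs(self) -> list[tuple[int, int]]:
        return [(r.i, r.j) for r in self.reports if r.passed]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.i, r.j, r.clash_count, r.passed) for r in self.reports],
            columns=["i", "j", "count", "passed"],
        )

    def to_csv(self, path: str) -> None:
        self.to_dataframe().to_csv(path, index=False)


def count_clashes(
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    cutoff: float,
) -> int:
    """Number of cross pairs (a in A, b in B) with distance strictly below
    ``cutoff``, via KD-trees (identical to the all-pairs brute force; the
    strict inequality is realized by querying at nextafter(cutoff, 0))."""
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise AssemblyError("empty selection in clash count")
    r = np.nextafter(cutoff, 0.0)  # largest double < cutoff
    return int(cKDTree(a).count_neighbors(cKDTree(b), r))


def _shared_ca_indices(structure: Structure, config: AssemblyConfig) -> np.ndarray:
    return select(structure, config.shared_domain, atom_names=("CA",))


def pair_filter(
    mobile_reps: Ensemble | list[Structure],
    static_reps: Ensemble | list[Structure],
    config: AssemblyConfig,
) -> ClashReportSet:
    """Evaluate every (mobile_i, static_j) combination.

    For each pair the mobile representative is superposed onto the static one
    at the shared-domain C-alpha atoms; clashes are then counted between the
    mobile domain of the (transformed) mobile fragment and the static domain
    of the static fragment, over heavy atoms.
    """
    mob = list(mobile_reps)
    sta = list(static_reps)
    if not mob or not sta:
        raise AssemblyError("empty representative set")
    mob_shared = _shared_ca_indices(mob[0], config)
    sta_shared = _shared_ca_indices(sta[0], config)
    if mob_shared.size != sta_shared.size:
        raise AssemblyError(
            "shared-domain C-alpha counts differ between fragment ensembles "
            f"({mob_shared.size} vs {sta_shared.size})"
        )
    mob_move = select(mob[0], config.mobile_domain, heavy_only=True)
    sta_static = select(sta[0], config.static_domain, heavy_only=True)

    counts = np.empty((len(mob), len(sta)), dtype=int)
    reports: list[ClashReport] = []
    for j, b in enumerate(sta):
        tree_b = cKDTree(b.coords[sta_static])
        target = b.coords[sta_shared]
        for i, a in enumerate(mob):
            try:
                transform, _ = superpose(a.coords[mob_shared], target)
            except Exception as exc:
                raise AssemblyError(f"superposition failed for pair ({i}, {j}): {exc}") from exc
            moved = transform.apply(a.coords[mob_move])
            r = np.nextafter(config.clash_cutoff, 0.0)
            c = int(cKDTree(moved).count_neighbors(tree_b, r))
            counts[i, j] = c
            reports.append(ClashReport(i, j, c, passed=c < config.clash_threshold))
    reports.sort(key=lambda r: (r.i, r.j))
    return ClashReportSet(reports=reports, counts=counts, threshold=config.clash_threshold)


@dataclass(frozen=True)
class JunctionReport:
    """Continuity diagnostics for a stitched conformer."""

    junction_res: int
    seam_bond_nm: float | None  # C(junction-1) - N(junction) distance
    seam_bond_kind: str  # "C-N" or "CA-CA" fallback
    shared_fit_rmsd_nm: float


def assemble_full_length(
    mobile: Structure,
    static: Structure,
    config: AssemblyConfig,
    check_passed: ClashReport | None = None,
) -> tuple[Structure, JunctionReport]:
    """Stitch one accepted pair into a full-length conformer.

    Residues numbered below the junction come from the mobile fragment
    (after superposition at the shared-domain C-alphas), residues at or above
    it from the static fragment.  Because the junction sits inside the
    rigid, superposed shared domain, backbone continuity across the seam is
    inherited from the fit quality.
    """
    if check_passed is not None and not check_passed.passed:
        raise AssemblyError(
            f"pair ({check_passed.i}, {check_passed.j}) failed the clash filter; "
            "pass check_passed=None to override"
        )
    jres = config.junction_res
    if not np.any(mobile.res_ids < jres) or not np.any(mobile.res_ids >= jres):
        raise AssemblyError(f"junction residue {jres} not bracketed by mobile fragment")
    if jres not in static.res_ids:
        raise AssemblyError(f"junction residue {jres} missing in static fragment")
    if jres - 1 not in mobile.res_ids:
        raise AssemblyError(f"junction residue {jres} (-1) missing in mobile fragment")
    mob_shared = _shared_ca_indices(mobile, config)
    sta_shared = _shared_ca_indices(static, config)
    if mob_shared.size != sta_shared.size:
        raise AssemblyError(
            "shared-domain C-alpha counts differ between fragments "
            f"({mob_shared.size} vs {sta_shared.size})"
        )
    transform, fit_rmsd = superpose(mobile.coords[mob_shared], static.coords[sta_shared])
    moved = transform.apply_structure(mobile)

    idx_low = np.flatnonzero(moved.res_ids < jres)
    idx_high = np.flatnonzero(static.res_ids >= jres)
    low = moved.subset(idx_low)
    high = static.subset(idx_high)
    merged = Structure(
        atom_names=np.concatenate([low.atom_names, high.atom_names]),
        elements=np.concatenate([low.elements, high.elements]),
        res_ids=np.concatenate([low.res_ids, high.res_ids]),
        res_names=np.concatenate([low.res_names, high.res_names]),
        chain_ids=np.concatenate([low.chain_ids, high.chain_ids]),
        coords=np.vstack([low.coords, high.coords]),
        label=f"assembled({mobile.label}|{static.label})@res{jres}",
    )

    def _atom(struct: Structure, res: int, name: str) -> np.ndarray | None:
        hits = np.flatnonzero((struct.res_ids == res) & (struct.atom_names == name))
        return struct.coords[hits[0]] if hits.size else None

    c_prev = _atom(low, jres - 1, "C")
    n_next = _atom(high, jres, "N")
    if c_prev is not None and n_next is not None:
        seam = float(np.linalg.norm(n_next - c_prev))
        kind = "C-N"
    else:
        ca_prev = _atom(low, jres - 1, "CA")
        ca_next = _atom(high, jres, "CA")
        if ca_prev is None or ca_next is None:
            raise AssemblyError(f"no backbone atoms flanking junction residue {jres}")
        seam = float(np.linalg.norm(ca_next - ca_prev))
        kind = "CA-CA"
    report = JunctionReport(
        junction_res=jres, seam_bond_nm=seam, seam_bond_kind=kind,
        shared_fit_rmsd_nm=fit_rmsd,
    )
    return merged, report


def assemble_passing(
    mobile_reps: Ensemble | list[Structure],
    static_reps: Ensemble | list[Structure],
    clash_set: ClashReportSet,
    config: AssemblyConfig,
) -> tuple[Ensemble | None, list[JunctionReport]]:
    """Assemble every passing pair; returns None if nothing passed."""
    mob = list(mobile_reps)
    sta = list(static_reps)
    members, junctions = [], []
    for i, j in clash_set.passing_pairs():
        merged, rep = assemble_full_length(mob[i], sta[j], config)
        members.append(merged)
        junctions.append(rep)
    if not members:
        logger.warning("clash filter passed zero pairs: empty assembled ensemble")
        return None, junctions
    return Ensemble(members), junctions
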