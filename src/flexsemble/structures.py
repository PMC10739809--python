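"""Structures, ensembles and residue-range selections.

All coordinates are stored in nanometres; PDB files (which use Angstrom)
are converted at the I/O boundary.  Residue numbers are kept exactly as
authored in the file (including negative numbers and gaps), so residues can
be addressed by their published identifiers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as bst
import biotite.structure.io.pdb as bst_pdb

logger = logging.getLogger(__name__)

NM_PER_ANGSTROM = 0.1


class StructureError(ValueError):
    """Raised for malformed structures, files, or selections."""


@dataclass
class Structure:
    """A single conformer: parallel per-atom annotation arrays plus coordinates.

    Attributes
    ----------
    atom_names : array of str, e.g. ``"CA"``.
    elements : array of str, element symbols, e.g. ``"C"``; ``"X"`` marks an
        unresolvable element.
    res_ids : array of int, author residue numbering (may be negative).
    res_names : array of str.
    chain_ids : array of str.
    coords : (n_atoms, 3) float array, nm.
    label : free-text provenance (file name, model number, generator tag).
    """

    atom_names: np.ndarray
    elements: np.ndarray
    res_ids: np.ndarray
    res_names: np.ndarray
    chain_ids: np.ndarray
    coords: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.atom_names = np.asarray(self.atom_names, dtype="U6")
        self.elements = np.asarray(self.elements, dtype="U2")
        self.res_ids = np.asarray(self.res_ids, dtype=int)
        self.res_names = np.asarray(self.res_names, dtype="U5")
        self.chain_ids = np.asarray(self.chain_ids, dtype="U4")
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.atom_names)
        if self.coords.shape != (n, 3):
            raise StructureError(
                f"coords shape {self.coords.shape} does not match {n} atoms"
            )
        for arr, name in (
            (self.elements, "elements"),
            (self.res_ids, "res_ids"),
            (self.res_names, "res_names"),
            (self.chain_ids, "chain_ids"),
        ):
            if len(arr) != n:
                raise StructureError(f"{name} length {len(arr)} != {n} atoms")
        if n and not np.all(np.isfinite(self.coords)):
            raise StructureError("non-finite coordinates")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    def copy(self) -> "Structure":
        return Structure(
            self.atom_names.copy(),
            self.elements.copy(),
            self.res_ids.copy(),
            self.res_names.copy(),
            self.chain_ids.copy(),
            self.coords.copy(),
            self.label,
        )

    def with_coords(self, coords: np.ndarray, label: str | None = None) -> "Structure":
        """Same topology, new coordinates (no copy of annotations)."""
        return Structure(
            self.atom_names,
            self.elements,
            self.res_ids,
            self.res_names,
            self.chain_ids,
            np.asarray(coords, dtype=float),
            self.label if label is None else label,
        )

    def subset(self, indices: np.ndarray, label: str | None = None) -> "Structure":
        idx = np.asarray(indices, dtype=int)
        return Structure(
            self.atom_names[idx],
            self.elements[idx],
            self.res_ids[idx],
            self.res_names[idx],
            self.chain_ids[idx],
            self.coords[idx],
            self.label if label is None else label,
        )

    def same_topology(self, other: "Structure") -> bool:
        return (
            self.n_atoms == other.n_atoms
            and np.array_equal(self.atom_names, other.atom_names)
            and np.array_equal(self.res_ids, other.res_ids)
            and np.array_equal(self.chain_ids, other.chain_ids)
        )


@dataclass
class DomainDefinition:
    """A named domain as inclusive residue-number intervals on one chain.

    ``chain_id=None`` matches any chain.  Intervals must be sorted and
    non-overlapping.
    """

    name: str
    ranges: tuple[tuple[int, int], ...]
    chain_id: str | None = None

    def __post_init__(self) -> None:
        rngs = tuple((int(a), int(b)) for a, b in self.ranges)
        for a, b in rngs:
            if a > b:
                raise StructureError(f"domain {self.name}: bad interval ({a}, {b})")
        for (a1, b1), (a2, b2) in zip(rngs, rngs[1:]):
            if a2 <= b1:
                raise StructureError(
                    f"domain {self.name}: intervals overlap or unsorted"
                )
        self.ranges = rngs

    def mask(self, structure: Structure) -> np.ndarray:
        m = np.zeros(structure.n_atoms, dtype=bool)
        for a, b in self.ranges:
            m |= (structure.res_ids >= a) & (structure.res_ids <= b)
        if self.chain_id is not None:
            m &= structure.chain_ids == self.chain_id
        return m


@dataclass
class Ensemble:
    """Ordered, weighted collection of conformers sharing one topology."""

    members: list[Structure]
    weights: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.members:
            raise StructureError("empty ensemble")
        first = self.members[0]
        for k, m in enumerate(self.members[1:], start=1):
            if not m.same_topology(first):
                raise StructureError(f"member {k} topology differs from member 0")
        if self.weights is None:
            w = np.full(len(self.members), 1.0 / len(self.members))
        else:
            w = np.asarray(self.weights, dtype=float)
            if w.shape != (len(self.members),):
                raise StructureError("weights length mismatch")
            if np.any(w < 0):
                raise StructureError("negative weights")
            total = w.sum()
            if total <= 0:
                raise StructureError("weights sum to zero")
            w = w / total
        self.weights = w

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def __getitem__(self, k: int) -> Structure:
        return self.members[k]

    @property
    def coords(self) -> np.ndarray:
        """(n_members, n_atoms, 3) stacked coordinates, nm."""
        return np.stack([m.coords for m in self.members])


def _check_pdb_records(path: str) -> None:
    """Pre-scan ATOM/HETATM records so parse failures carry a line number."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec not in ("ATOM", "HETATM"):
                continue
            try:
                float(line[30:38])
                float(line[38:46])
                float(line[46:54])
                int(line[22:26])
            except (ValueError, IndexError):
                raise StructureError(
                    f"{path}: unparsable {rec} record at line {lineno}: {line.rstrip()!r}"
                ) from None


def _resolve_altloc(atoms: bst.AtomArray | bst.AtomArrayStack):
    """Keep one altloc per atom site: highest occupancy, ties to altloc 'A'
    (alphabetically first)."""
    altloc = getattr(atoms, "altloc_id", None)
    if altloc is None:
        return atoms
    occ = getattr(atoms, "occupancy", None)
    if occ is None:
        occ = np.ones(atoms.array_length())
    keep = np.ones(atoms.array_length(), dtype=bool)
    sites: dict[tuple, list[int]] = {}
    for i in range(atoms.array_length()):
        key = (atoms.chain_id[i], atoms.res_id[i], atoms.ins_code[i], atoms.atom_name[i])
        sites.setdefault(key, []).append(i)
    for idx in sites.values():
        if len(idx) == 1:
            continue
        # occupancy descending, then altloc id ascending; deterministic
        best = min(idx, key=lambda i: (-occ[i], str(altloc[i])))
        for i in idx:
            keep[i] = i == best
    return atoms[..., keep] if isinstance(atoms, bst.AtomArrayStack) else atoms[keep]


def read_pdb(path: str, model_policy: str = "all") -> Ensemble:
    """Read a (possibly multi-model) PDB file into an :class:`Ensemble`.

    Parameters
    ----------
    path : PDB v3.x file.
    model_policy : ``"first"`` reads MODEL 1 only; ``"all"`` reads every model.

    Coordinates are converted Angstrom -> nm.  Alternate locations are
    resolved to the highest-occupancy conformer (ties -> 'A').
    """
    if model_policy not in ("first", "all"):
        raise ValueError(f"model_policy must be 'first' or 'all', got {model_policy!r}")
    _check_pdb_records(path)
    pdb_file = bst_pdb.PDBFile.read(path)
    try:
        atoms = pdb_file.get_structure(
            model=1 if model_policy == "first" else None,
            altloc="all",
            extra_fields=["occupancy"],
        )
    except Exception as exc:  # biotite error types vary
        raise StructureError(f"{path}: cannot parse PDB structure: {exc}") from exc
    atoms = _resolve_altloc(atoms)
    if atoms.array_length() == 0:
        raise StructureError(f"{path}: no atoms")

    def to_structure(arr: bst.AtomArray, model_no: int) -> Structure:
        elements = np.array(
            [e.capitalize() if e else "X" for e in arr.element], dtype="U2"
        )
        return Structure(
            atom_names=arr.atom_name,
            elements=elements,
            res_ids=arr.res_id,
            res_names=arr.res_name,
            chain_ids=arr.chain_id,
            coords=arr.coord * NM_PER_ANGSTROM,
            label=f"{path}#model{model_no}",
        )

    if isinstance(atoms, bst.AtomArrayStack):
        members = [to_structure(atoms[k], k + 1) for k in range(atoms.stack_depth())]
    else:
        members = [to_structure(atoms, 1)]
    return Ensemble(members)


def write_pdb(ensemble: Ensemble | Structure, path: str) -> None:
    """Write an ensemble as a multi-model PDB file (one MODEL per member)."""
    if isinstance(ensemble, Structure):
        ensemble = Ensemble([ensemble])
    first = ensemble[0]
    if np.any(first.res_ids > 9999) or np.any(first.res_ids < -999):
        bad = first.res_ids[(first.res_ids > 9999) | (first.res_ids < -999)][0]
        raise StructureError(
            f"residue number {bad} does not fit the fixed-width PDB field"
        )
    all_coords_A = ensemble.coords / NM_PER_ANGSTROM
    if np.any(np.abs(all_coords_A) > 9999.999):
        raise StructureError("coordinates exceed the fixed-width PDB field (Angstrom)")

    n = first.n_atoms
    template = bst.AtomArray(n)
    template.atom_name = first.atom_names
    template.res_id = first.res_ids
    template.res_name = first.res_names
    template.chain_id = np.array([c if c else "A" for c in first.chain_ids], dtype="U4")
    template.element = np.char.upper(first.elements)
    template.hetero = np.zeros(n, dtype=bool)
    stack = bst.AtomArrayStack(len(ensemble), n)
    for cat in template.get_annotation_categories():
        stack.set_annotation(cat, template.get_annotation(cat))
    stack.coord = all_coords_A
    pdb_file = bst_pdb.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(path)


def select(
    structure: Structure,
    domain_def: DomainDefinition,
    atom_names: tuple[str, ...] | None = None,
    heavy_only: bool = False,
) -> np.ndarray:
    """Sorted atom indices of a domain, optionally filtered by atom name
    (e.g. ``("CA",)``) or restricted to heavy (non-hydrogen) atoms.

    Residues in range that contribute no atoms after the atom-name filter are
    reported with a logged warning; an entirely empty selection is an error.
    """
    mask = domain_def.mask(structure)
    if not mask.any():
        raise StructureError(
            f"selection for domain {domain_def.name!r} "
            f"(ranges {list(domain_def.ranges)}) matched no atoms"
        )
    if atom_names is not None:
        name_mask = np.isin(structure.atom_names, np.asarray(atom_names, dtype="U6"))
        in_range_res = np.unique(structure.res_ids[mask])
        kept_res = np.unique(structure.res_ids[mask & name_mask])
        missing = np.setdiff1d(in_range_res, kept_res)
        if missing.size:
            logger.warning(
                "domain %s: %d residue(s) have no atom named %s (e.g. residue %d)",
                domain_def.name, missing.size, "/".join(atom_names), missing[0],
            )
        mask &= name_mask
    if heavy_only:
        mask &= structure.elements != "H"
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise StructureError(
            f"selection for domain {domain_def.name!r} is empty after filters"
        )
    return idx
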