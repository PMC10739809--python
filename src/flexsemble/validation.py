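"""Checks against downloadable reference data (manual-download workflow).

These checks compare package output with published solution-scattering and
crystallographic observables of the SHP2 system:

* Guinier Rg of the experimental SAXS curves of wild-type SHP2 (SASBDB
  SASDEN4, 2.69 nm) and of the constitutively open E76K mutant (SASDEP4,
  2.94 nm);
* the N-SH2/PTP rotation dihedral (C-alpha atoms of Glu139, Ser134, Pro454,
  Cys459) of the autoinhibited crystal structure, PDB 4DGP, about 20 deg;
* the hydration-corrected model Rg range (max about 3.4 nm) and the
  clash-filter pass count (about 275 of 400) over deposited full-length
  seed models and fragment representatives (Zenodo 10.5281/zenodo.10057715).

Remote fetching is deliberately not implemented; place the files under a
data directory:

    data_dir/
      SASDEN4.dat      3-column (q, I, sigma); q unit flag below
      SASDEP4.dat
      4dgp.pdb
      seed_models.pdb  multi-model PDB of full-length seed models (optional)
      tandem_reps.pdb + dnsh2_reps.pdb  fragment representatives (optional)
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .structures import DomainDefinition, read_pdb, select
from .geometry import dihedral
from .saxs import SAXSConfig, read_saxs_curve, guinier_fit, saxs_debye, apply_hydration_offset
from .assembly import AssemblyConfig, pair_filter

# Domain boundaries of human SHP2 (author numbering of the deposited
# structures): N-SH2, C-SH2, PTP; the rotation-dihedral marker residues sit
# at the ends of the C-SH2 betaB strand and the PTP betaM strand.
SHP2_N_SH2 = DomainDefinition("N-SH2", ((1, 104),))
SHP2_C_SH2 = DomainDefinition("C-SH2", ((112, 216),))
SHP2_PTP = DomainDefinition("PTP", ((221, 524),))
SHP2_DIHEDRAL_RESIDUES = (139, 134, 454, 459)


def rotation_dihedral_of_structure(path: str) -> float:
    """C-SH2/PTP rotation dihedral (degrees) of a crystal structure."""
    structure = read_pdb(path, model_policy="first")[0]
    points = []
    for res in SHP2_DIHEDRAL_RESIDUES:
        idx = select(structure, DomainDefinition(f"res{res}", ((res, res),)),
                     atom_names=("CA",))
        points.append(structure.coords[idx[0]])
    return dihedral(*points)


def experimental_rg(path: str, q_unit: str = "nm^-1", qmax_rg: float = 1.3) -> float:
    """Guinier Rg (nm) of an experimental curve file."""
    curve = read_saxs_curve(path, q_unit=q_unit)
    return guinier_fit(curve, qmax_rg).rg


def model_rg_range(path: str, qmax_rg: float = 1.3) -> dict:
    """Hydration-corrected Guinier Rg statistics over a multi-model PDB of
    full-length models (atomic contrast, Gaussian dummy-atom solvent)."""
    ensemble = read_pdb(path, model_policy="all")
    config = SAXSConfig(q=np.linspace(0.0, 1.5, 76))
    rgs = []
    for member in ensemble:
        heavy = np.flatnonzero(member.elements != "H")
        curve = saxs_debye(member.subset(heavy), config)
        rgs.append(apply_hydration_offset(guinier_fit(curve, qmax_rg).rg, config))
    rgs = np.asarray(rgs)
    return {"min_nm": float(rgs.min()), "max_nm": float(rgs.max()),
            "n_models": int(rgs.size)}


def representative_pair_filter(
    tandem_path: str, dnsh2_path: str, clash_cutoff: float = 0.20,
    clash_threshold: int = 100,
) -> dict:
    """Clash filter over deposited fragment representatives (20 x 20)."""
    tandem = read_pdb(tandem_path, model_policy="all")
    dnsh2 = read_pdb(dnsh2_path, model_policy="all")
    config = AssemblyConfig(
        shared_domain=SHP2_C_SH2, mobile_domain=SHP2_N_SH2,
        static_domain=SHP2_PTP, clash_cutoff=clash_cutoff,
        clash_threshold=clash_threshold,
    )
    return pair_filter(tandem, dnsh2, config).summary()


def accession_checks(data_dir: str) -> dict:
    """Run every reference-data check for which the input file is present.

    Raises FileNotFoundError if the data directory or all required files
    are missing (nothing can be checked).
    """
    root = Path(data_dir)
    if not root.is_dir():
        raise FileNotFoundError(
            f"reference data directory {data_dir!r} not found; download the "
            "SASBDB curves (SASDEN4/SASDEP4), PDB 4DGP and the deposited "
            "ensembles manually (see module docstring)"
        )
    results: dict = {}
    sasden4 = root / "SASDEN4.dat"
    sasdep4 = root / "SASDEP4.dat"
    if sasden4.exists():
        results["rg_sasden4_nm"] = experimental_rg(str(sasden4), q_unit="A^-1")
    if sasdep4.exists():
        results["rg_sasdep4_nm"] = experimental_rg(str(sasdep4), q_unit="A^-1")
    pdb_4dgp = root / "4dgp.pdb"
    if pdb_4dgp.exists():
        results["dihedral_4dgp_deg"] = rotation_dihedral_of_structure(str(pdb_4dgp))
    seeds = root / "seed_models.pdb"
    if seeds.exists():
        results["seed_model_rg"] = model_rg_range(str(seeds))
    tandem = root / "tandem_reps.pdb"
    dnsh2 = root / "dnsh2_reps.pdb"
    if tandem.exists() and dnsh2.exists():
        results["pair_filter"] = representative_pair_filter(str(tandem), str(dnsh2))
    if not results:
        raise FileNotFoundError(
            f"no reference files found under {data_dir!r}; expected "
            "SASDEN4.dat / SASDEP4.dat / 4dgp.pdb / seed_models.pdb / "
            "tandem_reps.pdb + dnsh2_reps.pdb"
        )
    return results
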