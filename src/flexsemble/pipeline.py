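"""Configuration-driven orchestration of the full workflow.

Stages: load or generate the two fragment pools -> cluster each pool and
take the top-k representatives -> pairwise clash filter at the shared
domain -> stitch passing pairs into full-length conformers -> per-conformer
SAXS + Guinier (+ hydration offset) and ensemble SAXS (optionally compared
to an experimental curve) -> ensemble analytics (clustering, PCA,
free-energy surface, rotation dihedral, COM distances, density map) ->
JSON report plus CSV/Dat/PDB artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .structures import (
    Structure, Ensemble, DomainDefinition, read_pdb, write_pdb, select,
)
from .assembly import AssemblyConfig, pair_filter, assemble_passing
from .saxs import (
    SAXSConfig, SAXSCurve, saxs_debye, ensemble_saxs, guinier_fit,
    apply_hydration_offset, fit_scale_and_compare, read_saxs_curve,
    write_saxs_curve, SAXSError,
)
from .analysis import (
    cluster_gromos, cumulative_cluster_fraction, pca_fit,
    dihedral_series, free_energy_surface, min_free_energy_path,
    com_distance_series, density_map, KT_298K_KJMOL, AnalysisError,
)
from .synthetic import SyntheticEnsembleSpec, generate_fragment_ensembles, carve_parent

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All knobs of the end-to-end workflow.

    Either ``synthetic`` (a generator spec) or both fragment paths plus
    explicit domain definitions must be provided.  Defaults follow the
    production workflow: 20 representatives per pool, clash threshold 100,
    hydration Rg offset 0.076 nm, kT at 298 K.
    """

    out_dir: str = "flexsemble_out"
    seed: int = 1
    synthetic: SyntheticEnsembleSpec | None = None
    fragment_ab_path: str | None = None
    fragment_bc_path: str | None = None
    mobile_domain: DomainDefinition | None = None
    shared_domain: DomainDefinition | None = None
    static_domain: DomainDefinition | None = None
    dihedral_residues: tuple[int, int, int, int] | None = None
    junction_res: int | None = None
    n_representatives: int = 20
    cluster_cutoff_nm: float = 0.3
    clash_cutoff_nm: float = 0.20
    clash_threshold: int = 100
    q_max: float = 3.0
    q_points: int = 61
    n_orientations: int = 2000
    delta_rg_nm: float = 0.076
    scatterer_mode: str = "uniform-bead"
    guinier_qmax_rg: float = 1.3
    experimental_curve: str | None = None
    experimental_q_unit: str = "nm^-1"
    fes_bins: int = 24
    kt_kjmol: float = KT_298K_KJMOL
    dihedral_bin_deg: float = 5.0
    density_spacing_nm: float = 0.2
    cluster_fraction_ks: tuple[int, ...] = (1, 2, 5, 10, 20, 50)

    def __post_init__(self) -> None:
        if self.n_representatives < 1:
            raise ValueError("n_representatives must be >= 1")
        if self.synthetic is None and not (
            self.fragment_ab_path and self.fragment_bc_path
            and self.mobile_domain and self.shared_domain and self.static_domain
        ):
            # default world: fully synthetic, seeded from the pipeline seed
            self.synthetic = SyntheticEnsembleSpec(seed=self.seed)

    def config_hash(self) -> str:
        payload = _jsonable(asdict(self))
        payload.pop("out_dir", None)  # identical runs hash equal regardless of location
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _representatives(ensemble: Ensemble, fit_idx, analysis_idx, cutoff: float, k: int):
    result = cluster_gromos(ensemble, analysis_idx, fit_idx, cutoff)
    take = result.representatives[: min(k, result.n_clusters)]
    reps = Ensemble([ensemble[i] for i in take])
    return reps, result


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the workflow; returns the report dict (also written to
    ``out_dir/report.json``).  Deterministic for a fixed config."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }
    t_start = time.perf_counter()

    # ----- stage 1: fragment pools -------------------------------------
    stage = "fragments"
    try:
        if config.fragment_ab_path and config.fragment_bc_path:
            ab = read_pdb(config.fragment_ab_path, "all")
            bc = read_pdb(config.fragment_bc_path, "all")
            truth = None
            mobile_def = config.mobile_domain
            shared_def = config.shared_domain
            static_def = config.static_domain
            dihedral_res = config.dihedral_residues
            reference = None
        else:
            spec = config.synthetic
            ab, bc, truth = generate_fragment_ensembles(spec)
            mobile_def = truth.domain_defs["A"]
            shared_def = truth.domain_defs["B"]
            static_def = truth.domain_defs["C"]
            dihedral_res = config.dihedral_residues or truth.dihedral_residues
            reference, _, _ = carve_parent(spec)
        report["stages"][stage] = {
            "n_ab": len(ab), "n_bc": len(bc),
            "synthetic": truth is not None,
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # ----- stage 2: representatives ------------------------------------
    stage = "representatives"
    try:
        shared_ca_ab = select(ab[0], shared_def, atom_names=("CA",))
        shared_ca_bc = select(bc[0], shared_def, atom_names=("CA",))
        ca_ab = np.flatnonzero(ab[0].atom_names == "CA")
        ca_bc = np.flatnonzero(bc[0].atom_names == "CA")
        reps_ab, clus_ab = _representatives(
            ab, shared_ca_ab, ca_ab, config.cluster_cutoff_nm, config.n_representatives
        )
        reps_bc, clus_bc = _representatives(
            bc, shared_ca_bc, ca_bc, config.cluster_cutoff_nm, config.n_representatives
        )
        report["stages"][stage] = {
            "n_clusters_ab": clus_ab.n_clusters, "n_clusters_bc": clus_bc.n_clusters,
            "n_reps_ab": len(reps_ab), "n_reps_bc": len(reps_bc),
            "top_cluster_fraction_ab": float(clus_ab.populations[0] / len(ab)),
            "top_cluster_fraction_bc": float(clus_bc.populations[0] / len(bc)),
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # ----- stage 3: pairwise clash filter ------------------------------
    stage = "pair_filter"
    try:
        asm_config = AssemblyConfig(
            shared_domain=shared_def,
            mobile_domain=mobile_def,
            static_domain=static_def,
            clash_cutoff=config.clash_cutoff_nm,
            clash_threshold=config.clash_threshold,
            junction_res=config.junction_res
            if config.junction_res is not None
            else (truth.junction_res if truth is not None else None),
        )
        clash_set = pair_filter(reps_ab, reps_bc, asm_config)
        clash_set.to_csv(out / "clash_matrix.csv")
        report["stages"][stage] = clash_set.summary()
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # ----- stage 4: assembly -------------------------------------------
    stage = "assembly"
    try:
        assembled, junctions = assemble_passing(reps_ab, reps_bc, clash_set, asm_config)
        if assembled is None:
            logger.warning("no pair passed the clash filter: empty ensemble")
            report["stages"][stage] = {"n_assembled": 0, "warning": "empty ensemble"}
            report["elapsed_s"] = round(time.perf_counter() - t_start, 3)
            (out / "report.json").write_text(json.dumps(_jsonable(report), indent=2))
            return report
        write_pdb(assembled, str(out / "assembled.pdb"))
        report["stages"][stage] = {
            "n_assembled": len(assembled),
            "junction_res": asm_config.junction_res,
            "seam_bond_nm_mean": float(np.mean([j.seam_bond_nm for j in junctions])),
            "shared_fit_rmsd_nm_max": float(
                max(j.shared_fit_rmsd_nm for j in junctions)
            ),
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # ----- stage 5: SAXS + Guinier -------------------------------------
    stage = "saxs"
    try:
        ca_full = np.flatnonzero(assembled[0].atom_names == "CA")
        saxs_members = (
            Ensemble([m.subset(ca_full) for m in assembled])
            if config.scatterer_mode == "uniform-bead"
            else assembled
        )
        saxs_config = SAXSConfig(
            q=np.linspace(0.0, config.q_max, config.q_points),
            n_orientations=config.n_orientations,
            delta_rg=config.delta_rg_nm,
            scatterer_mode=config.scatterer_mode,
        )
        rg_values = []
        for member in saxs_members:
            curve = saxs_debye(member, saxs_config)
            try:
                fit = guinier_fit(curve, config.guinier_qmax_rg)
                rg_values.append(apply_hydration_offset(fit.rg, saxs_config))
            except SAXSError:
                rg_values.append(np.nan)
        rg_values = np.asarray(rg_values)
        ens_curve = ensemble_saxs(saxs_members, saxs_config)
        write_saxs_curve(ens_curve, str(out / "ensemble_saxs.dat"))
        ens_fit = guinier_fit(ens_curve, config.guinier_qmax_rg)
        saxs_report = {
            "per_model_rg_nm": {
                "min": float(np.nanmin(rg_values)),
                "max": float(np.nanmax(rg_values)),
                "mean": float(np.nanmean(rg_values)),
                "n_failed_fits": int(np.sum(np.isnan(rg_values))),
            },
            "hydration_offset_nm": config.delta_rg_nm,
            "ensemble_rg_nm": apply_hydration_offset(ens_fit.rg, saxs_config),
            "ensemble_rg_bare_nm": ens_fit.rg,
        }
        if config.experimental_curve:
            exp = read_saxs_curve(config.experimental_curve, config.experimental_q_unit)
            comparison = fit_scale_and_compare(ens_curve, exp, fit_constant_background=True)
            saxs_report["chi2_reduced_vs_experiment"] = comparison["chi2_reduced"]
            saxs_report["scale"] = comparison["scale"]
        report["stages"][stage] = saxs_report
        np.savetxt(
            out / "per_model_rg.csv",
            np.column_stack([np.arange(rg_values.size), rg_values]),
            header="model,rg_hydrated_nm", delimiter=",", comments="",
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # ----- stage 6: ensemble analytics ---------------------------------
    stage = "analytics"
    try:
        first = assembled[0]
        fit_idx = select(first, static_def, atom_names=("CA",))
        mobile_idx = select(first, mobile_def, atom_names=("CA",))
        shared_idx = select(first, shared_def, atom_names=("CA",))
        all_ca = np.flatnonzero(first.atom_names == "CA")

        clusters = cluster_gromos(
            assembled, all_ca, fit_idx, config.cluster_cutoff_nm
        )
        ks = [k for k in config.cluster_fraction_ks if k <= clusters.n_clusters]
        fractions = cumulative_cluster_fraction(clusters, ks) if ks else np.array([])

        analysis_idx = np.concatenate([mobile_idx, shared_idx])
        pca = pca_fit(assembled, fit_indices=fit_idx, analysis_indices=analysis_idx)
        projections = pca.transform(assembled)
        np.savetxt(
            out / "projections.csv",
            projections[:, :2], header="pc1,pc2", delimiter=",", comments="",
        )
        fes = free_energy_surface(
            projections[:, :2], bins=config.fes_bins, kt_kjmol=config.kt_kjmol
        )
        np.savetxt(out / "fes.txt", fes.free_energy.filled(np.inf),
                   header="free energy kJ/mol, rows = PC1 bins")
        barrier = None
        occupied = np.argwhere(fes.counts > 0)
        if occupied.shape[0] >= 2:
            min_bin = fes.minimum_bin()
            far = occupied[
                np.argmax(np.sum((occupied - np.asarray(min_bin)) ** 2, axis=1))
            ]
            try:
                _, barrier = min_free_energy_path(fes, min_bin, tuple(far))
            except AnalysisError:
                barrier = None

        dihedrals = None
        if dihedral_res is not None:
            series = dihedral_series(
                assembled, dihedral_res, bin_width=config.dihedral_bin_deg
            )
            dihedrals = {
                "residues": list(dihedral_res),
                "peaks_deg": [float(p) for p in series.peaks[:4]],
                "mean_deg": float(
                    np.degrees(np.angle(np.mean(np.exp(1j * np.radians(series.angles)))))
                ),
            }

        com_report = None
        if reference is not None:
            ref_mobile = select(reference, mobile_def, atom_names=("CA",))
            ref_fit = select(reference, static_def, atom_names=("CA",))
            # map member fit selection onto the reference's by position
            dists = com_distance_series(
                Ensemble([m.subset(np.concatenate([mobile_idx, fit_idx])) for m in assembled]),
                mobile_indices=np.arange(mobile_idx.size),
                fit_indices=np.arange(mobile_idx.size, mobile_idx.size + fit_idx.size),
                reference=reference.subset(np.concatenate([ref_mobile, ref_fit])),
                reference_com=None,
            )
            com_report = {
                "min_nm": float(dists.distances.min()),
                "max_nm": float(dists.distances.max()),
                "modal_nm": float(np.median(dists.distances)),
            }

        dmap = density_map(
            assembled, mobile_idx, fit_idx, spacing=config.density_spacing_nm
        )
        np.savetxt(
            out / "density_map.txt",
            np.column_stack([np.argwhere(dmap.density > 0),
                             dmap.density[dmap.density > 0]]),
            header=(
                f"occupied voxels (i j k density); origin {dmap.origin.tolist()} nm; "
                f"spacing {dmap.spacing} nm; isolevels(0.1,0.001 of max) "
                f"{dmap.isolevels().tolist()}"
            ),
        )
        report["stages"][stage] = {
            "n_clusters": clusters.n_clusters,
            "cumulative_cluster_fractions": {
                str(k): float(f) for k, f in zip(ks, fractions)
            },
            "pca_cumulative_variance_5": [
                float(v) for v in pca.cumulative_variance_[:5]
            ],
            "fes_barrier_kjmol": None if barrier is None else float(barrier),
            "dihedral": dihedrals,
            "com_distance_nm": com_report,
            "density_max_voxel_nm": dmap.max_voxel_center().tolist(),
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report["elapsed_s"] = round(time.perf_counter() - t_start, 3)
    payload = dict(report)
    payload.pop("elapsed_s")  # keep report.json byte-identical across runs
    (out / "report.json").write_text(json.dumps(_jsonable(payload), indent=2))
    logger.info("pipeline finished in %.1f s", report["elapsed_s"])
    return report
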