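"""End-to-end studies: complex binding energetics and monomer ensembles.

``run_binding_study`` assembles the MM-GBSA table, the per-residue
decomposition, the residue–residue contact map and the per-frame
energy time course for a peptide–receptor complex.
``run_monomer_study`` produces reaction-coordinate series, the
secondary-structure profile, the free-energy landscape and k-means
clusters with representative structures for a monomer ensemble.

Both are deterministic given the config (every stochastic step is
seeded) and write plain TSV tables so that two identical runs produce
byte-identical files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .binding import (
    BindingEnergyComponents,
    aggregate_replicas,
    mmgbsa_frame,
    per_residue_decomposition,
    residue_rmsf,
)
from .constants import ANGSTROM_PER_NM, DEFAULT_TEMPERATURE
from .energetics import GBConfig, lj_coulomb_interaction
from .ensemble import (
    EnsembleSeries,
    InteractionMap,
    SecondaryStructureProfile,
    interaction_map,
    reaction_coordinates,
    secondary_structure_profile,
)
from .entropy import EntropyTerm, interaction_entropy, wsas_entropy
from .fel import ClusterSet, FELGrid, build_fel, kmeans_cluster
from .pdbio import write_multimodel_pdb
from .sasa import SasaConfig
from .topology import Topology, Trajectory

logger = logging.getLogger("taur2")


class WorkflowError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class RunConfig:
    """Validated settings shared by the two studies."""

    seed: int = 0
    entropy_method: str = "wsas"        # "wsas" | "ie" | "none"
    discard: float = 0.25
    fel_bins: int = 50
    k: int = 2
    temperature: float = DEFAULT_TEMPERATURE
    contact_cutoff_nm: float = 0.3
    gb: GBConfig = field(default_factory=GBConfig)
    sasa: SasaConfig = field(default_factory=SasaConfig)
    wsas_weights: dict | None = None
    output_dir: str | None = None

    def __post_init__(self):
        if self.entropy_method not in ("wsas", "ie", "none"):
            raise ValueError(f"unknown entropy method {self.entropy_method!r}")
        if not 0.0 <= self.discard < 1.0:
            raise ValueError("discard must be in [0, 1)")
        if self.fel_bins < 2 or self.k < 1:
            raise ValueError("fel_bins >= 2 and k >= 1 required")
        logger.info("run config: %s", {
            k: v for k, v in asdict(self).items() if k != "wsas_weights"
        })


def _float_fmt(x: float) -> str:
    return f"{x:.6f}"


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6f",
              lineterminator="\n")


@dataclass(frozen=True)
class BindingStudyResult:
    components: BindingEnergyComponents
    per_residue: pd.DataFrame
    contact_map: InteractionMap
    timecourse: pd.DataFrame
    rmsf: np.ndarray


def run_binding_study(config: RunConfig, topology: Topology,
                      replicas: list[Trajectory]) -> BindingStudyResult:
    """The complex study: MM-GBSA table, decomposition, contact map."""
    if not replicas:
        raise WorkflowError("binding study: no trajectories supplied")
    if not topology.ligand_atoms or not topology.receptor_atoms:
        raise WorkflowError("binding study: topology lacks a partition")

    try:
        per_frame = []
        rows = []
        for rep_i, traj in enumerate(replicas):
            frames = []
            for f in range(traj.n_frames):
                fe = mmgbsa_frame(
                    topology, traj.coordinates[f], config.gb, config.sasa,
                    frame_index=f,
                )
                frames.append(fe)
                rows.append({
                    "replica": rep_i, "frame": f,
                    "time_ps": traj.frame_times[f],
                    "de_vdw": fe.e_vdw, "de_eel": fe.e_eel,
                    "dg_polar": fe.g_polar, "dg_nonpolar": fe.g_nonpolar,
                    "enthalpy": fe.enthalpy,
                })
            per_frame.append(frames)
        timecourse = pd.DataFrame(rows)
    except Exception as exc:
        raise WorkflowError(f"binding study, energy stage: {exc}") from exc

    try:
        if config.entropy_method == "none":
            entropy = None
        elif config.entropy_method == "wsas":
            entropy = [
                wsas_entropy(topology, traj, weights=config.wsas_weights,
                             temperature=config.temperature,
                             sasa_config=config.sasa)
                for traj in replicas
            ]
        else:  # interaction entropy from gas-phase ΔE_vdw + ΔE_eel
            entropy = []
            for frames in per_frame:
                series = np.array([f.e_vdw + f.e_eel for f in frames])
                entropy.append(
                    interaction_entropy(series, config.temperature)
                )
    except Exception as exc:
        raise WorkflowError(f"binding study, entropy stage: {exc}") from exc

    try:
        components = aggregate_replicas(per_frame, entropy, config.discard)
    except Exception as exc:
        raise WorkflowError(f"binding study, aggregation: {exc}") from exc

    try:
        contributions = per_residue_decomposition(
            topology, replicas[0], config.gb, config.sasa
        )
        per_residue = pd.DataFrame([{
            "residue": c.residue_index,
            "energy": c.energy,
            "mean_min_distance_nm": c.mean_min_distance / ANGSTROM_PER_NM,
            "e_vdw": c.e_vdw, "e_eel": c.e_eel,
            "e_polar": c.e_polar, "e_nonpolar": c.e_nonpolar,
        } for c in contributions])
        cmap = interaction_map(topology, replicas[0],
                               config.contact_cutoff_nm)
        rmsf = (residue_rmsf(replicas[0]) if replicas[0].n_frames >= 2
                else np.zeros(topology.n_residues))
    except Exception as exc:
        raise WorkflowError(f"binding study, decomposition: {exc}") from exc

    result = BindingStudyResult(components, per_residue, cmap, timecourse,
                                rmsf)
    if config.output_dir is not None:
        _write_binding_outputs(result, config)
    return result


def _write_binding_outputs(res: BindingStudyResult, config: RunConfig) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    c = res.components
    summary = pd.DataFrame([{
        "de_vdw": c.de_vdw.mean, "de_vdw_sd": c.de_vdw.spread,
        "de_eel": c.de_eel.mean, "de_eel_sd": c.de_eel.spread,
        "dg_polar": c.dg_polar.mean, "dg_polar_sd": c.dg_polar.spread,
        "dg_nonpolar": c.dg_nonpolar.mean,
        "dg_nonpolar_sd": c.dg_nonpolar.spread,
        "t_delta_s": c.t_delta_s.mean, "t_delta_s_sd": c.t_delta_s.spread,
        "dg_bind": c.dg_bind.mean, "dg_bind_sd": c.dg_bind.spread,
        "n_replicas": c.n_replicas,
    }])
    _write_tsv(summary, out / "binding_summary.tsv")
    _write_tsv(res.per_residue, out / "per_residue.tsv")
    rows = []
    for a, lr in enumerate(res.contact_map.ligand_residues):
        for b, rr in enumerate(res.contact_map.receptor_residues):
            rows.append({"ligand_res": int(lr), "receptor_res": int(rr),
                         "occupancy": res.contact_map.occupancy[a, b]})
    _write_tsv(pd.DataFrame(rows), out / "interaction_map.tsv")
    _write_tsv(res.timecourse, out / "energy_timecourse.tsv")


@dataclass(frozen=True)
class MonomerStudyResult:
    series: EnsembleSeries
    ss_profile: SecondaryStructureProfile
    fel: FELGrid
    clusters: ClusterSet


def run_monomer_study(config: RunConfig, traj: Trajectory
                      ) -> MonomerStudyResult:
    """The monomer study: reaction coordinates, SS, FEL and clusters."""
    if traj.n_frames < 1:
        raise WorkflowError("monomer study: empty trajectory")
    try:
        series = reaction_coordinates(traj, sasa_config=config.sasa)
    except Exception as exc:
        raise WorkflowError(f"monomer study, series stage: {exc}") from exc
    try:
        ss = secondary_structure_profile(traj.topology, traj)
    except Exception as exc:
        raise WorkflowError(
            f"monomer study, secondary-structure stage: {exc}"
        ) from exc
    try:
        fel = build_fel(series.e2e, series.rg, config.fel_bins,
                        config.temperature)
        points = np.stack([series.e2e, series.rg], axis=1)
        clusters = kmeans_cluster(points, config.k, config.seed)
    except Exception as exc:
        raise WorkflowError(f"monomer study, FEL stage: {exc}") from exc

    result = MonomerStudyResult(series, ss, fel, clusters)
    if config.output_dir is not None:
        _write_monomer_outputs(result, config, traj)
    return result


def _write_monomer_outputs(res: MonomerStudyResult, config: RunConfig,
                           traj: Trajectory) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    s = res.series
    _write_tsv(pd.DataFrame({
        "frame": np.arange(len(s.rg)),
        "rg_nm": s.rg, "e2e_nm": s.e2e,
        "sasa_nm2": s.sasa, "rmsd_nm": s.rmsd,
    }), out / "series.tsv")

    prop = res.ss_profile.per_residue_propensity
    _write_tsv(pd.DataFrame({
        "residue": np.arange(res.ss_profile.classes.shape[1]),
        "helix_percent": prop["H"],
        "beta_percent": prop["E"],
        "coil_percent": prop["C"],
    }), out / "ss_profile.tsv")

    xc = 0.5 * (res.fel.axis1_edges[:-1] + res.fel.axis1_edges[1:])
    yc = 0.5 * (res.fel.axis2_edges[:-1] + res.fel.axis2_edges[1:])
    rows = []
    for i, x in enumerate(xc):
        for j, y in enumerate(yc):
            g = res.fel.delta_g[i, j]
            if np.isfinite(g):
                rows.append({"e2e_nm": x, "rg_nm": y, "delta_g": g})
    _write_tsv(pd.DataFrame(rows), out / "fel.tsv")

    _write_tsv(pd.DataFrame({
        "cluster": np.arange(res.clusters.k),
        "center_e2e_nm": res.clusters.centers[:, 0],
        "center_rg_nm": res.clusters.centers[:, 1],
        "population": res.clusters.populations,
        "representative_frame": res.clusters.representative_frames,
    }), out / "clusters.tsv")

    reps = res.clusters.representative_frames
    rep_traj = Trajectory(
        coordinates=traj.coordinates[reps],
        frame_times=np.arange(len(reps), dtype=float),
        topology=traj.topology,
    )
    write_multimodel_pdb(rep_traj, out / "representatives.pdb")
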