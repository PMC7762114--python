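"""End-to-end orchestration: synthetic or file input → analyses → report.

A :class:`RunConfig` describes one run (input, enabled analyses,
parameters, output directory, seed).  :func:`run` executes jump leveling
and the enabled analyses in dependency order, writes every product in the
formats declared per module (CSV/TSV/JSON) and returns a
:class:`RunReport` with a file manifest and headline numbers.  Stage
failures are recorded in the report and leave earlier products intact.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dynamics import (assign_leaflets, leaflet_msd_fits, radius_of_gyration)
from .entropy import entropy_time_curve
from .interactions import (InteractionParams, build_interaction_map,
                           detect_frame, interaction_time_series,
                           records_to_frame)
from .pbc import level_jumps
from .pdbio import read_multimodel_pdb, write_multimodel_pdb
from .profiles import (bilayer_thickness, electron_density_profile,
                       interior_water_count, penetration_depth)
from .rheology import gser_moduli
from .synthetic import (SyntheticSpec, generate_topology, generate_trajectory,
                        inject_jumps, plant_contacts, write_ground_truth)

log = logging.getLogger(__name__)

ANALYSES = ("interactions", "msd", "rheology", "entropy", "profiles")


@dataclass
class RunConfig:
    synthetic: SyntheticSpec | None = None
    input_pdb: str | None = None
    outdir: str = "results/run"
    seed: int | None = None
    analyses: tuple = ANALYSES
    interaction_params: InteractionParams = field(
        default_factory=InteractionParams)
    interaction_scope: str = "protein-lipid"
    interaction_kinds: tuple = ("hbond", "hp", "ionic", "water_bridge")
    interaction_stride: int = 10
    temperature: float = 310.0
    fit_range: tuple | None = None
    n_omega: int = 40
    entropy_points: int = 20
    entropy_max_molecules: int = 30
    frame_interval: float = 0.05
    write_pdb: bool = False

    def validate(self) -> None:
        if (self.synthetic is None) == (self.input_pdb is None):
            raise ValueError("exactly one of synthetic spec or input "
                             "PDB must be given")
        if not self.analyses:
            raise ValueError("at least one analysis must be enabled")
        unknown = set(self.analyses) - set(ANALYSES)
        if unknown:
            raise ValueError(f"unknown analyses: {sorted(unknown)}")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


@dataclass
class RunReport:
    outdir: str
    seed: int | None
    manifest: dict = field(default_factory=dict)
    headline: dict = field(default_factory=dict)
    errors: dict = field(default_factory=dict)
    config_hash: str = ""
    version: str = ""

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _config_hash(config: RunConfig) -> str:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        return str(o)
    blob = json.dumps(dataclasses.asdict(config), default=default,
                      sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _load_inputs(config: RunConfig, outdir: Path):
    if config.synthetic is not None:
        spec = config.synthetic
        if config.seed is not None:
            spec = dataclasses.replace(spec, rng_seed=config.seed)
        topology = generate_topology(spec)
        trajectory = generate_trajectory(topology, spec)
        planted = None
        if spec.planted_interactions:
            trajectory, planted = plant_contacts(trajectory, topology,
                                                 spec.planted_interactions)
        if spec.jump_frames:
            trajectory = inject_jumps(trajectory, topology, spec.jump_frames)
        write_ground_truth(outdir / "ground_truth.json", spec, topology,
                           planted)
        if config.write_pdb:
            write_multimodel_pdb(outdir / "system.pdb", topology, trajectory)
        return topology, trajectory
    topology, trajectory = read_multimodel_pdb(
        config.input_pdb, frame_interval=config.frame_interval)
    return topology, trajectory


def _stage_interactions(config, topology, trajectory, outdir, report):
    frames = range(0, trajectory.n_frames, config.interaction_stride)
    series = interaction_time_series(
        trajectory, topology, config.interaction_params,
        scope=config.interaction_scope, kinds=config.interaction_kinds,
        frames=frames)
    series.to_csv(outdir / "interaction_timeseries.tsv", sep="\t",
                  index=False)
    report.manifest["interaction_timeseries"] = "interaction_timeseries.tsv"
    last = trajectory.n_frames - 1
    records = detect_frame(trajectory.coords[last], topology,
                           config.interaction_params, trajectory.box,
                           frame=last, kinds=config.interaction_kinds)
    # dump protein-involving and bridge records; the bulk intra-bilayer HP
    # records are summarized by the time series and maps instead
    dump = [r for r in records
            if "protein" in r.scope or r.kind == "water_bridge"
            or r.scope in ("lipid-water", "ion")]
    records_to_frame(dump, topology).to_csv(
        outdir / "interaction_records_final.tsv", sep="\t", index=False)
    report.manifest["interaction_records_final"] = \
        "interaction_records_final.tsv"
    for kind, fname in (("hbond", "map_hbond_residue_x_lipid_atom.csv"),
                        ("hp", "map_hp_residue_x_lipid_atom.csv")):
        m = build_interaction_map(
            [r for r in records if r.kind == kind
             and r.scope == "protein-lipid"], topology)
        m.to_csv(outdir / fname)
        report.manifest[f"map_{kind}"] = fname
    bridges = [r for r in records if r.kind == "water_bridge"
               and r.scope == "lipid-lipid"]
    build_interaction_map(bridges, topology,
                          rows=("lipid", "atom_name"),
                          cols=("lipid", "atom_name")).to_csv(
        outdir / "map_water_bridges_lipid_atoms.csv")
    report.manifest["map_water_bridges"] = "map_water_bridges_lipid_atoms.csv"
    final = series[series["frame"] == series["frame"].max()]
    for _, row in final.iterrows():
        report.headline[f"{row['kind']}_count_final"] = int(row["count"])
        report.headline[f"{row['kind']}_lipids_final"] = int(row["n_lipids"])


def _stage_msd(config, topology, trajectory, outdir, report):
    fits = leaflet_msd_fits(trajectory, topology, fit_range=config.fit_range)
    fit_rows = {}
    for label, (msd, fit) in fits.items():
        pd.DataFrame({"t_ns": msd.t, "msd_A2": msd.msd}).to_csv(
            outdir / f"msd_{label}.csv", index=False)
        report.manifest[f"msd_{label}"] = f"msd_{label}.csv"
        fit_rows[label] = {
            "alpha": fit.alpha, "std_alpha": fit.std_alpha,
            "D_alpha_A2ns": fit.d_alpha, "std_D_A2ns": fit.std_d,
            "D_alpha_cm2s": fit.d_alpha_cm2s,
            "t_min_ns": fit.t_min, "t_max_ns": fit.t_max,
            "n_molecules": msd.n_molecules,
        }
        report.headline[f"alpha_{label}"] = fit.alpha
        report.headline[f"D_alpha_A2ns_{label}"] = fit.d_alpha
    with open(outdir / "msd_fits.json", "w") as fh:
        json.dump(fit_rows, fh, indent=1)
    report.manifest["msd_fits"] = "msd_fits.json"
    return fits


def _stage_rheology(config, topology, trajectory, outdir, report, fits):
    rg_mean, _ = radius_of_gyration(trajectory, topology, "lipid")
    report.headline["lipid_Rg_A"] = rg_mean
    for label, (_, fit) in fits.items():
        moduli = gser_moduli(fit, config.temperature, rg_mean,
                             n_omega=config.n_omega)
        moduli.to_frame().to_csv(outdir / f"moduli_{label}.csv", index=False)
        report.manifest[f"moduli_{label}"] = f"moduli_{label}.csv"
        mid = len(moduli.omega) // 2
        report.headline[f"Gprime_over_Gdoubleprime_{label}"] = float(
            moduli.g_prime_kpa[mid] / moduli.g_double_prime_kpa[mid])


def _stage_entropy(config, topology, trajectory, outdir, report):
    mols = None
    if topology.molecules("protein"):
        leaflets = assign_leaflets(topology, trajectory)
        mols = sorted(m for m, l in leaflets.items() if l == "contact")
    else:
        mols = topology.molecules("lipid")
    mols = mols[:config.entropy_max_molecules]
    eval_frames = np.unique(np.linspace(
        2, trajectory.n_frames, min(config.entropy_points,
                                    trajectory.n_frames - 1)).astype(int))
    result = entropy_time_curve(trajectory, topology, config.temperature,
                                molecule_ids=mols, eval_frames=eval_frames)
    pd.DataFrame({
        "time_ns": result.times,
        "S_mean_kcal_per_molK": result.s_mean,
        "S_std_over_lipids": result.s_std,
    }).to_csv(outdir / "entropy_curve.csv", index=False)
    report.manifest["entropy_curve"] = "entropy_curve.csv"
    report.headline["entropy_plateau_kcal_per_molK"] = float(result.s_mean[-1])


def _stage_profiles(config, topology, trajectory, outdir, report):
    profile = electron_density_profile(trajectory, topology)
    profile.to_frame().to_csv(outdir / "electron_density.csv", index=False)
    report.manifest["electron_density"] = "electron_density.csv"
    summary = {}
    summary["thickness_A"] = bilayer_thickness(profile)
    report.headline["bilayer_thickness_A"] = summary["thickness_A"]
    waters = interior_water_count(trajectory, topology, profile)
    summary["interior_waters_final"] = int(waters[-1])
    if topology.molecules("protein"):
        leaflets = assign_leaflets(topology, trajectory)
        contact = sorted(m for m, l in leaflets.items() if l == "contact")
        rep = penetration_depth(trajectory, topology, contact)
        summary["penetration_depth_final_A"] = float(rep.depth[-1])
        summary["deepest_residue_final"] = rep.deepest_residues[-1]
        report.headline["penetration_depth_A"] = float(rep.depth[-1])
        pd.DataFrame({"frame": np.arange(trajectory.n_frames),
                      "depth_A": rep.depth,
                      "deepest_residue": rep.deepest_residues}).to_csv(
            outdir / "penetration_depth.csv", index=False)
        report.manifest["penetration_depth"] = "penetration_depth.csv"
    with open(outdir / "profile_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    report.manifest["profile_summary"] = "profile_summary.json"


def run(config: RunConfig) -> RunReport:
    """Execute a configured run; products land in ``config.outdir``."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(outdir=str(outdir), seed=config.seed,
                       config_hash=_config_hash(config), version=__version__)
    topology, trajectory = _load_inputs(config, outdir)
    if trajectory.box is not None:
        trajectory = level_jumps(trajectory, topology)
    fits = None
    for stage in ("interactions", "msd", "rheology", "entropy", "profiles"):
        if stage not in config.analyses:
            continue
        if stage == "rheology" and fits is None:
            # rheology consumes the MSD fits
            try:
                fits = leaflet_msd_fits(trajectory, topology,
                                        fit_range=config.fit_range)
            except Exception as exc:          # noqa: BLE001
                report.errors["rheology"] = f"msd prerequisite failed: {exc}"
                continue
        try:
            if stage == "interactions":
                _stage_interactions(config, topology, trajectory, outdir,
                                    report)
            elif stage == "msd":
                fits = _stage_msd(config, topology, trajectory, outdir,
                                  report)
            elif stage == "rheology":
                _stage_rheology(config, topology, trajectory, outdir,
                                report, fits)
            elif stage == "entropy":
                _stage_entropy(config, topology, trajectory, outdir, report)
            elif stage == "profiles":
                _stage_profiles(config, topology, trajectory, outdir, report)
        except Exception as exc:              # noqa: BLE001
            log.exception("stage %s failed", stage)
            report.errors[stage] = str(exc)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=1)
    report.manifest["report"] = "report.json"
    return report


def compare_runs(report_a: RunReport | dict,
                 report_b: RunReport | dict) -> pd.DataFrame:
    """Side-by-side headline numbers of two runs with ratios.

    Keys present in only one report are skipped (logged); disjoint key sets
    yield an empty table with a warning.
    """
    ha = report_a.headline if isinstance(report_a, RunReport) else \
        report_a.get("headline", {})
    hb = report_b.headline if isinstance(report_b, RunReport) else \
        report_b.get("headline", {})
    shared = sorted(set(ha) & set(hb))
    skipped = sorted(set(ha) ^ set(hb))
    if skipped:
        log.info("keys present in one run only, skipped: %s", skipped)
    if not shared:
        log.warning("no overlapping headline keys between the runs")
        return pd.DataFrame(columns=["key", "a", "b", "ratio_a_over_b"])
    rows = []
    for key in shared:
        a, b = ha[key], hb[key]
        try:
            ratio = float(a) / float(b) if float(b) != 0 else np.nan
        except (TypeError, ValueError):
            ratio = np.nan
        rows.append({"key": key, "a": a, "b": b, "ratio_a_over_b": ratio})
    return pd.DataFrame(rows)
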