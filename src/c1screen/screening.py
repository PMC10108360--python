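"""Screening orchestration: run every analysis stage per candidate and emit
a machine-readable report.

The pipeline order is fixed: equilibration trim, orientation heat map and
verdict, partial density profiles with interface localization, H-bond block
statistics, SASA block statistics, ligand clustering. A stage failure for
one candidate is recorded in the report and the run continues with the
remaining candidates. Every threshold, cutoff, bin width and seed is echoed
into the report, so any number in it can be regenerated from the inputs
plus the echo.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .aggregation import DEFAULT_CLUSTER_CUTOFF, cluster_timeseries
from .density import locate_interface, partial_density
from .errors import C1ScreenError, ConfigError
from .geometry import LigandSpec, orientation_samples
from .hbonds import HBondCriterion, hbond_block_stats, lipid_partner, water_partner
from .orientation import (
    DEFAULT_DEPTH_BIN,
    DEFAULT_THETA_BIN,
    ClassifierThresholds,
    accumulate_heatmap,
    classify_orientation,
)
from .sasa import SasaSettings, group_sasa_block_stats
from .synthgen import ScenarioConfig, generate_scenario, reference_scenarios
from .trajio import Trajectory, read_gro, read_index_groups

__all__ = ["run_screening", "load_config", "DEFAULT_TRIM_FRACTION"]

# default equilibration trim: 1/16 of the span (100 ns of a 1.6 us run)
DEFAULT_TRIM_FRACTION = 1.0 / 16.0


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("screening config must be a YAML mapping")
    return cfg


def _trim(traj: Trajectory, trim_time: float | None) -> tuple[Trajectory, dict]:
    times = traj.times
    t0, t1 = float(times[0]), float(times[-1])
    total = t1 - t0
    if trim_time is None:
        trim_time = total * DEFAULT_TRIM_FRACTION
    if trim_time < 0:
        raise ConfigError("trim time must be >= 0")
    keep = [fr for fr in traj.frames if fr.time >= t0 + trim_time]
    if not keep:
        raise ConfigError(
            f"equilibration trim ({trim_time} ps) leaves an empty analyzed span"
        )
    trimmed = Trajectory(atoms=traj.atoms, frames=keep)
    discarded = keep[0].time - t0
    span = {
        "total_span_ps": total,
        "trim_time_ps": float(trim_time),
        "discarded_prefix_ps": float(discarded),
        "analyzed_span_ps": float(t1 - keep[0].time),
        "n_frames_total": traj.n_frames,
        "n_frames_analyzed": len(keep),
    }
    return trimmed, span


def _load_candidate(cand: dict, seed: int):
    """Resolve one candidate entry to (Trajectory, groups, spec, ground_truth)."""
    if "scenario" in cand:
        refs = reference_scenarios(seed=seed)
        base = cand["scenario"]
        if isinstance(base, str):
            if base not in refs:
                raise ConfigError(
                    f"unknown scenario {base!r}; built-ins: {sorted(refs)}"
                )
            scen = refs[base]
        else:
            scen = ScenarioConfig(**base)
        overrides = dict(cand.get("overrides") or {})
        if overrides:
            scen = ScenarioConfig(**{**dataclasses.asdict(scen), **overrides})
        traj, groups, gt = generate_scenario(scen)
    elif "trajectory" in cand:
        traj = read_gro(cand["trajectory"])
        groups = read_index_groups(cand["index"], traj.atoms)
        gt = None
    else:
        raise ConfigError("candidate needs either 'scenario' or 'trajectory'")
    lig = cand.get("ligand", {})
    spec = LigandSpec.from_selection_groups(
        groups, lig.get("resname", "LIG"), int(lig.get("n_copies", 4))
    )
    if "lipids" not in groups or "water" not in groups:
        raise ConfigError("index groups must include 'lipids' and 'water'")
    return traj, groups, spec, gt


def _block_row(name: str, ba) -> dict:
    return {
        "observable": name,
        "grand_mean": ba.grand_mean,
        "sd": ba.sd,
        "n_blocks": ba.n_blocks,
        "block_duration_ps": ba.block_duration,
    }


def run_screening(config: dict | str | Path, output_dir: str | Path | None = None) -> dict:
    """Run the full screening pipeline described by ``config``.

    ``config`` is a mapping (or path to a YAML file) with a ``candidates``
    list; each candidate names a built-in synthetic scenario (plus optional
    overrides) or a GRO trajectory with an NDX group file. Returns the
    report dict and writes ``report.json``, ``report.txt`` and per-candidate
    CSV artifacts (plus PNG plots when ``plots: true``) into the output
    directory.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    outdir = Path(output_dir or config.get("output_dir", "c1screen_out"))
    outdir.mkdir(parents=True, exist_ok=True)

    seed = int(config.get("seed", 0))
    theta_bin = float(config.get("theta_bin", DEFAULT_THETA_BIN))
    depth_bin = float(config.get("depth_bin", DEFAULT_DEPTH_BIN))
    density_bin = float(config.get("density_bin", 0.1))
    n_blocks = int(config.get("n_blocks", 5))
    cluster_cutoff = float(config.get("cluster_cutoff", DEFAULT_CLUSTER_CUTOFF))
    thresholds = ClassifierThresholds(**(config.get("thresholds") or {}))
    crit = HBondCriterion(**(config.get("hbond") or {}))
    sasa_settings = SasaSettings(**(config.get("sasa") or {}))
    trim_time = config.get("trim_time")
    make_plots = bool(config.get("plots", False))

    report: dict = {
        "output_dir": str(outdir),
        "config_echo": {
            "seed": seed,
            "trim_time_ps": trim_time,
            "default_trim_fraction": DEFAULT_TRIM_FRACTION,
            "theta_bin_deg": theta_bin,
            "depth_bin_nm": depth_bin,
            "density_bin_nm": density_bin,
            "n_blocks": n_blocks,
            "cluster_cutoff_nm": cluster_cutoff,
            "thresholds": dataclasses.asdict(thresholds),
            "hbond_criterion": dataclasses.asdict(crit),
            "sasa": dataclasses.asdict(sasa_settings),
        },
        "candidates": {},
    }

    for cand in config.get("candidates", []):
        name = cand.get("name") or cand.get("scenario", "candidate")
        entry: dict = {"errors": {}}
        report["candidates"][name] = entry
        try:
            traj, groups, spec, gt = _load_candidate(cand, seed)
            traj, span = _trim(traj, trim_time)
            entry["span"] = span
            if gt is not None:
                entry["scenario_config"] = gt["config"]
        except C1ScreenError as exc:
            entry["errors"]["load"] = str(exc)
            continue

        lipids = groups["lipids"]
        water = groups["water"]

        # --- orientation heat map and verdict -------------------------------
        try:
            samples = orientation_samples(traj, spec, lipids)
            depth_max = float(
                np.ceil(traj.frames[0].box[2] / 2.0 / depth_bin) * depth_bin
            )
            hmap = accumulate_heatmap(samples, theta_bin, depth_bin, depth_max=depth_max)
            verdict = classify_orientation(hmap, thresholds)
            entry["verdict"] = dataclasses.asdict(verdict)
            grid = pd.DataFrame(
                hmap.counts,
                index=pd.Index(hmap.theta_centers, name="theta_deg"),
                columns=pd.Index(np.round(hmap.depth_centers, 6), name="depth_nm"),
            )
            grid.to_csv(outdir / f"{name}_heatmap.csv")
            if make_plots:
                from .plots import plot_heatmap

                plot_heatmap(hmap, outdir / f"{name}_heatmap.png", title=name)
        except C1ScreenError as exc:
            entry["errors"]["orientation"] = str(exc)

        # --- partial density profiles and interface -------------------------
        try:
            profs = [
                partial_density(traj, lipids, density_bin, lipids, label="lipids"),
                partial_density(traj, water, density_bin, lipids, label="water"),
                partial_density(
                    traj,
                    np.concatenate(spec.all_atoms),
                    density_bin,
                    lipids,
                    label=f"{spec.resname} (all)",
                ),
            ]
            if spec.oh_group is not None:
                profs.append(
                    partial_density(
                        traj,
                        np.concatenate(spec.oh_group),
                        density_bin,
                        lipids,
                        label=f"{spec.resname} (OH)",
                    )
                )
            interface = locate_interface(profs[1], profs[0])
            entry["interface_nm"] = interface
            dens = pd.DataFrame({"z_nm": profs[0].bin_centers})
            for p in profs:
                dens[p.label] = p.density
            dens.to_csv(outdir / f"{name}_density.csv", index=False)
            if make_plots:
                from .plots import plot_density_profiles

                plot_density_profiles(
                    profs, outdir / f"{name}_density.png", interface=interface
                )
        except C1ScreenError as exc:
            entry["errors"]["density"] = str(exc)

        # --- hydrogen-bond block statistics ----------------------------------
        try:
            partners = [water_partner(traj.atoms, water), lipid_partner(traj.atoms, lipids)]
            rows = []
            for group in ("oh", "oono"):
                grp_sel = spec.oh_group if group == "oh" else spec.oono_group
                if grp_sel is None:
                    continue
                for partner in partners:
                    ba = hbond_block_stats(traj, spec, group, partner, crit, n_blocks)
                    rows.append(_block_row(f"hbonds {group} vs {partner.label}", ba))
            entry["hbonds"] = rows
            pd.DataFrame(rows).to_csv(outdir / f"{name}_hbonds.csv", index=False)
        except C1ScreenError as exc:
            entry["errors"]["hbonds"] = str(exc)

        # --- SASA block statistics -------------------------------------------
        try:
            rows = []
            for group in ("oh", "oono"):
                grp_sel = spec.oh_group if group == "oh" else spec.oono_group
                if grp_sel is None:
                    continue
                ba = group_sasa_block_stats(traj, spec, group, sasa_settings, n_blocks)
                rows.append(_block_row(f"sasa {group} (nm^2)", ba))
            entry["sasa"] = rows
            pd.DataFrame(rows).to_csv(outdir / f"{name}_sasa.csv", index=False)
        except C1ScreenError as exc:
            entry["errors"]["sasa"] = str(exc)

        # --- ligand clustering -----------------------------------------------
        try:
            states, summary = cluster_timeseries(traj, spec, cluster_cutoff)
            entry["clusters"] = summary
            pd.DataFrame(
                {
                    "time_ps": [s.frame_time for s in states],
                    "largest_cluster_size": [s.largest_cluster_size for s in states],
                    "n_clusters": [s.n_clusters for s in states],
                }
            ).to_csv(outdir / f"{name}_clusters.csv", index=False)
        except C1ScreenError as exc:
            entry["errors"]["clusters"] = str(exc)

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=_jsonable)
    _write_text_report(report, outdir / "report.txt")
    return report


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _write_text_report(report: dict, path) -> None:
    lines = ["c1screen screening report", "=" * 60]
    for name, entry in report["candidates"].items():
        lines.append(f"\ncandidate: {name}")
        if "span" in entry:
            sp = entry["span"]
            lines.append(
                f"  span: total {sp['total_span_ps']:.0f} ps, discarded prefix "
                f"{sp['discarded_prefix_ps']:.0f} ps, analyzed {sp['analyzed_span_ps']:.0f} ps"
            )
        if "verdict" in entry:
            v = entry["verdict"]
            lines.append(
                f"  verdict: {v['label']} (mode θ = {v['mode_theta']:.1f}°, "
                f"mode depth = {v['mode_depth']:.3f} nm, secondary population "
                f"{v['secondary_population_fraction']:.3f})"
            )
        if "interface_nm" in entry:
            i = entry["interface_nm"]
            lines.append(
                f"  lipid-water interface: ±{i['upper']:.2f} / {i['lower']:.2f} nm"
            )
        for key in ("hbonds", "sasa"):
            for row in entry.get(key, []):
                lines.append(
                    f"  {row['observable']}: {row['grand_mean']:.3g} ± {row['sd']:.2g} "
                    f"({row['n_blocks']} blocks of {row['block_duration_ps']:.0f} ps)"
                )
        if "clusters" in entry:
            c = entry["clusters"]
            lines.append(
                f"  clusters: fraction of frames with a dimer+ "
                f"{c['clustered_frame_fraction']:.3f}, mean largest size "
                f"{c['mean_largest_cluster_size']:.2f}"
            )
        for stage, msg in entry.get("errors", {}).items():
            lines.append(f"  ERROR [{stage}]: {msg}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
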