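"""Configuration-driven end-to-end analysis runs.

A run configuration (YAML or dict) names one or more systems and, per
stage, either user-supplied input files or a synthetic specification.
:func:`run_pipeline` produces a report bundle in the output directory:

* ``bilayer_metrics.csv``  — thickness / area-per-lipid / hydrogen-bond
  table (mean +/- standard error over replicates, one row per system)
* ``permeant_depth.csv``   — time, replicate-mean minimum distance to the
  midplane, pointwise standard deviation
* ``diffusivity_profile.csv`` + ``diffusivity_summary.json`` — D(z) per
  system, region averages, and the control-vs-treatment percent change
* ``run_log.json``         — every parameter, seed and truncation lag used

A failure in any stage aborts the run with the stage name and the
offending input; partially written outputs are removed. Bundles are
byte-reproducible for a fixed config and seed.

Display rounding in the CSV tables follows the conventions of the
observables: thickness 2 decimals, area-per-lipid 3 decimals, hydrogen
bonds 2 decimals, diffusivity two significant figures. Full-precision
values are kept in the JSON summary and log.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import bilayer as bl
from . import diffusivity as dz
from . import interactions as ia
from . import synthetic as syn
from .io import read_timeseries, read_trajectory
from .model import AnalysisWindow, ConfigurationError, ScpermeateError, Trajectory
from .selections import select_atoms

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "load_config"]

_DEFAULT_SELECTORS = {
    "headgroup": "atom_name == HG and (residue_name == CER or residue_name == FFA)",
    "reference": "atom_name == HG and residue_name in {CER, CHL, FFA}",
    "donors": "residue_name == DON",
    "acceptors": "residue_name in {ACC, DCA}",
}


class PipelineError(ScpermeateError):
    """A stage failed; carries the stage name and offending input."""

    def __init__(self, stage: str, detail: str):
        self.stage = stage
        super().__init__(f"stage {stage!r}: {detail}")


@dataclass
class RunConfig:
    """Validated run configuration."""

    seed: int = 0
    output_dir: Path = Path("scpermeate_out")
    temperature: float = 310.0
    window: AnalysisWindow = field(default_factory=AnalysisWindow)
    selectors: dict[str, str] = field(default_factory=lambda: dict(_DEFAULT_SELECTORS))
    systems: list[dict[str, Any]] = field(default_factory=list)
    adsorption: dict[str, Any] | None = None
    diffusivity: dict[str, Any] | None = None

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        window = raw.get("window", {})
        selectors = dict(_DEFAULT_SELECTORS)
        selectors.update(raw.get("selectors", {}))
        return cls(
            seed=int(raw.get("seed", 0)),
            output_dir=Path(raw.get("output_dir", "scpermeate_out")),
            temperature=float(raw.get("temperature", 310.0)),
            window=AnalysisWindow(
                t_start=float(window.get("t_start", 80_000.0)),
                t_end=float(window.get("t_end", 100_000.0)),
            ),
            selectors=selectors,
            systems=list(raw.get("systems", [])),
            adsorption=raw.get("adsorption"),
            diffusivity=raw.get("diffusivity"),
        )


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: configuration must be a mapping")
    return RunConfig.from_dict(raw)


def _two_sig(x: float) -> str:
    """Two-significant-figure scientific notation, e.g. 2.4e-06."""
    return f"{x:.1e}"


def _synthetic_bilayer_trajectory(
    spec_dict: dict[str, Any], n_frames: int, window: AnalysisWindow, seed: int
) -> Trajectory:
    frames = []
    dt_frame = (window.t_end - window.t_start) / max(n_frames, 1)
    for i in range(n_frames):
        spec = syn.BilayerSpec(**{**spec_dict, "seed": seed + i})
        frame = syn.build_synthetic_bilayer(spec)
        frame.time = window.t_start + i * dt_frame
        frames.append(frame)
    return Trajectory(frames=frames)


def _bilayer_stage(config: RunConfig) -> pd.DataFrame | None:
    if not config.systems:
        return None
    rows = []
    for sys_idx, system in enumerate(config.systems):
        label = system.get("label", f"system-{sys_idx}")
        replicate_trajs: list[Trajectory] = []
        if "replicates" in system:
            for path in system["replicates"]:
                try:
                    replicate_trajs.append(read_trajectory(path))
                except ScpermeateError as exc:
                    raise PipelineError("bilayer", f"{label}: {exc}") from exc
        elif "synthetic" in system:
            spec_dict = dict(system["synthetic"])
            n_frames = int(system.get("n_frames", 10))
            n_reps = int(system.get("n_replicates", 2))
            for r in range(n_reps):
                replicate_trajs.append(
                    _synthetic_bilayer_trajectory(
                        spec_dict,
                        n_frames,
                        config.window,
                        config.seed + 1000 * sys_idx + 100_000 * r,
                    )
                )
        else:
            raise PipelineError(
                "bilayer", f"{label}: needs either 'replicates' or 'synthetic'"
            )
        thick, apl, hb = [], [], []
        for traj in replicate_trajs:
            try:
                thick.append(
                    bl.bilayer_thickness(
                        traj, config.selectors["headgroup"], config.window
                    ).mean
                )
                apl_frames = []
                hb_frames = []
                for frame in config.window.select_frames(traj):
                    leaflets = bl.assign_leaflets(frame, config.selectors["reference"])
                    apl_frames.append(
                        bl.area_per_lipid(frame, leaflets=leaflets).frame_mean
                    )
                    donors = select_atoms(frame, config.selectors["donors"])
                    acceptors = select_atoms(frame, config.selectors["acceptors"])
                    hb_frames.append(
                        len(ia.detect_hbonds(frame, donors, acceptors))
                    )
                apl.append(float(np.mean(apl_frames)))
                hb.append(float(np.mean(hb_frames)))
            except ScpermeateError as exc:
                raise PipelineError("bilayer", f"{label}: {exc}") from exc
        t_mean, t_se = bl.aggregate_replicates(thick)
        a_mean, a_se = bl.aggregate_replicates(apl)
        h_mean, h_se = bl.aggregate_replicates(hb)
        rows.append(
            {
                "system": label,
                "thickness_nm": round(t_mean, 2),
                "thickness_se": round(t_se, 2),
                "apl_nm2": round(a_mean, 3),
                "apl_se": round(a_se, 3),
                "hbond_count": round(h_mean, 2),
                "hbond_se": round(h_se, 2),
                "n_replicates": len(replicate_trajs),
            }
        )
    return pd.DataFrame(rows)


def _adsorption_stage(config: RunConfig) -> pd.DataFrame | None:
    if config.adsorption is None:
        return None
    ads = config.adsorption
    try:
        if "series_files" in ads:
            traces = []
            for r, path in enumerate(ads["series_files"]):
                ts = read_timeseries(path)
                traces.append(
                    ia.DistanceSeries(
                        times=ts.times, distances=ts.values, replicate_id=r
                    )
                )
        elif "synthetic" in ads:
            params = dict(ads["synthetic"])
            params.setdefault("seed", config.seed + 7)
            traces = syn.simulate_adsorption_traces(**params)
        else:
            raise ConfigurationError(
                "adsorption stage needs 'series_files' or 'synthetic'"
            )
        avg = ia.average_series(traces)
    except ScpermeateError as exc:
        raise PipelineError("adsorption", str(exc)) from exc
    return pd.DataFrame(
        {"time_ps": avg.times, "mean_distance_nm": avg.mean, "std_nm": avg.std}
    )


def _diffusivity_system(
    spec: dict[str, Any], config: RunConfig, truncation, label: str, sys_index: int
) -> dz.DiffusivityProfile:
    if "windows" in spec:
        series = []
        for w in spec["windows"]:
            try:
                ts = read_timeseries(w["file"])
            except ScpermeateError as exc:
                raise PipelineError(
                    "diffusivity", f"{label}: window file {w.get('file')}: {exc}"
                ) from exc
            series.append(
                dz.ForceSeries(
                    values=ts.values,
                    dt=ts.dt,
                    window_center_z=float(w["center"]),
                    spring_k=float(w.get("k", 1000.0)),
                    temperature=float(w.get("temperature", config.temperature)),
                )
            )
    elif "synthetic" in spec:
        s = spec["synthetic"]
        land = s["landscape"]
        landscape = syn.LandscapeSpec(
            z_knots=np.asarray(land["z_knots"], dtype=float),
            d_knots=np.asarray(land["d_knots"], dtype=float),
            pmf_knots=(
                np.asarray(land["pmf_knots"], dtype=float)
                if "pmf_knots" in land
                else None
            ),
            temperature=float(s.get("temperature", config.temperature)),
        )
        series = syn.simulate_permeant_windows(
            landscape,
            centers=[float(c) for c in s["centers"]],
            k=float(s.get("k", 1000.0)),
            dt=float(s.get("dt", 0.1)),
            duration=float(s.get("duration", 10_000.0)),
            seed=config.seed + 31 + 1000 * sys_index,
        )
    else:
        raise PipelineError(
            "diffusivity", f"{label}: needs 'windows' or 'synthetic'"
        )
    try:
        return dz.assemble_profile(series, truncation=truncation)
    except ScpermeateError as exc:
        raise PipelineError("diffusivity", f"{label}: {exc}") from exc


def _diffusivity_stage(
    config: RunConfig,
) -> tuple[pd.DataFrame, dict[str, Any]] | None:
    if config.diffusivity is None:
        return None
    diff = config.diffusivity
    truncation = diff.get("truncation", "first_zero_crossing")
    if isinstance(truncation, str) and truncation != "first_zero_crossing":
        raise PipelineError(
            "diffusivity", f"unknown truncation {truncation!r}"
        )
    z_min, z_max = diff.get("region", (-2.3, 2.3))
    profiles: dict[str, dz.DiffusivityProfile] = {}
    for i, key in enumerate(k for k in ("control", "treatment") if k in diff):
        profiles[key] = _diffusivity_system(diff[key], config, truncation, key, i)
    if not profiles:
        raise PipelineError("diffusivity", "needs a 'control' system")
    rows = []
    summary: dict[str, Any] = {"region_nm": [z_min, z_max], "systems": {}}
    for key, profile in profiles.items():
        for w in profile.windows:
            rows.append(
                {
                    "system": key,
                    "z_nm": w.z,
                    "D_cm2_s": float(_two_sig(w.D)),
                    "truncation_lag_ps": w.truncation_lag,
                    "n_samples": w.n_samples,
                }
            )
        avg = dz.region_average(profile, z_min, z_max)
        summary["systems"][key] = {
            "region_average_cm2_s": avg,
            "n_windows": len(profile.windows),
            "failed_windows": profile.failures,
        }
    if "control" in profiles and "treatment" in profiles:
        pct_int, pct = dz.percent_change(
            summary["systems"]["control"]["region_average_cm2_s"],
            summary["systems"]["treatment"]["region_average_cm2_s"],
        )
        summary["percent_change"] = pct_int
        summary["percent_change_unrounded"] = pct
    return pd.DataFrame(rows), summary


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute every configured stage and write the report bundle.

    Returns a mapping from artifact name to written path. On any stage
    failure the partially written outputs are removed and a
    :class:`PipelineError` naming the stage propagates.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    log: dict[str, Any] = {
        "seed": config.seed,
        "temperature_K": config.temperature,
        "window_ps": [config.window.t_start, config.window.t_end],
        "selectors": config.selectors,
        "stages": {},
    }
    try:
        table = _bilayer_stage(config)
        if table is not None:
            path = outdir / "bilayer_metrics.csv"
            table.to_csv(path, index=False)
            written["bilayer_metrics"] = path
            log["stages"]["bilayer"] = {
                "n_systems": len(table),
                "systems": table["system"].tolist(),
            }
        depth = _adsorption_stage(config)
        if depth is not None:
            path = outdir / "permeant_depth.csv"
            depth.to_csv(path, index=False)
            written["permeant_depth"] = path
            log["stages"]["adsorption"] = {"n_points": len(depth)}
        diff = _diffusivity_stage(config)
        if diff is not None:
            profile_df, summary = diff
            path = outdir / "diffusivity_profile.csv"
            profile_df.to_csv(path, index=False)
            written["diffusivity_profile"] = path
            path = outdir / "diffusivity_summary.json"
            path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
            written["diffusivity_summary"] = path
            log["stages"]["diffusivity"] = {
                "truncation": config.diffusivity.get(
                    "truncation", "first_zero_crossing"
                ),
                "truncation_lags_ps": {
                    row["system"] + f"@z={row['z_nm']}": row["truncation_lag_ps"]
                    for row in profile_df.to_dict("records")
                },
                "summary": summary,
            }
        log_path = outdir / "run_log.json"
        log_path.write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
        written["run_log"] = log_path
    except ScpermeateError:
        for path in written.values():
            path.unlink(missing_ok=True)
        raise
    return written
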