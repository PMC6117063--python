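"""End-to-end orchestration: generate → analyze → report.

``run_pipeline`` executes every analysis stage on synthetic data for one
scenario and collects the headline quantities into a single
machine-readable report: per-stage derived metrics, the exponential growth
fit, log-rate balance residuals, apical occupancy and trap verdicts,
heatmap uniformity statistics, actin zone extents, cortical ratios and the
mechanics trajectory summary.  Reports are deterministic given (config,
scenario, seed) — they carry a config hash and the seed, but no timestamps
— so repeated invocations are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from pathlib import Path
from typing import Any

import numpy as np
from scipy import stats as sp_stats

from . import __version__
from ._errors import ValidationError
from ._log import get_logger
from ._rng import child_rng
from .apical import (
    FrustumParams,
    annulus_uniformity,
    apical_occupancy,
    density_heatmap,
    division_angle_stats,
    fit_sphere,
    project_equal_area,
    trap_analysis,
)
from .config import PipelineConfig, Scenario
from .datamodel import StageTable, write_stage_table
from .growth import decompose_table, derive_stage_metrics, exponential_growth_fit
from .mechanics import scenario_trajectory
from .profiles import average_profiles, cortical_ratios, detect_basal_zone
from .proliferation import cycle_lengths
from .synthetic import (
    SphericalCap,
    effective_calibration,
    generate_cell_cycle_tracks,
    generate_cortical_traces,
    generate_division_angles,
    generate_intensity_profiles,
    generate_mitotic_coordinates,
    generate_stage_table,
)

__all__ = ["run_pipeline", "compare_scenarios", "REPORT_SCHEMA_VERSION"]

log = get_logger("pipeline")

REPORT_SCHEMA_VERSION = "1"

#: relative aspect-ratio drift below which tissue scaling counts as isotropic
ISOTROPY_DRIFT_TOLERANCE = 0.15


def _config_hash(config: PipelineConfig) -> str:
    def default(obj: Any):
        if dataclasses.is_dataclass(obj):
            return dataclasses.asdict(obj)
        raise TypeError(type(obj))

    payload = json.dumps(
        {
            "seed": config.seed,
            "stages": config.stages,
            "analysis": dataclasses.asdict(config.analysis),
            "calibrations": {str(k): dataclasses.asdict(v) for k, v in config.calibrations.items()},
        },
        sort_keys=True,
        default=default,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stage_summary(table: StageTable, config: PipelineConfig) -> dict:
    metrics = derive_stage_metrics(table, config.analysis)
    return {
        f"{m.stage_hpf:g}": {
            "mean_cell_volume_um3": m.mean_cell_volume,
            "mean_cell_cross_section_um2": m.mean_cell_cross_section,
            "corrected_thickness_um": m.corrected_thickness,
            "cell_density_per_um3": m.cell_density,
            "cell_aspect_ratio": m.cell_aspect_ratio,
            "tissue_aspect_ratio": m.tissue_aspect_ratio,
            "nuclear_stacking": m.nuclear_stacking,
            "apical_to_basal_layers": m.apical_to_basal_layers,
            "n_embryos": m.n_embryos,
        }
        for m in metrics
    }


def _occupancy_section(table: StageTable) -> dict:
    per_stage = {}
    for stage, rows in table.groupby_stage().items():
        vals = [
            apical_occupancy(r.mitotic_diameters, r.n_mitotic, r.apical_area)
            for r in rows
            if r.mitotic_diameters
        ]
        per_stage[f"{stage:g}"] = float(np.mean(vals)) if vals else float("nan")
    finite = [v for v in per_stage.values() if not math.isnan(v)]
    return {
        "per_stage": per_stage,
        "max_over_stages": max(finite) if finite else float("nan"),
    }


def _trap_section(table: StageTable, config: PipelineConfig, scenario: Scenario) -> dict:
    out = {}
    for stage, rows in table.groupby_stage().items():
        cal = effective_calibration(config, stage, scenario)
        diameters = [d for r in rows for d in r.mitotic_diameters]
        if not diameters:
            continue
        density = float(np.mean([r.n_cells / r.tissue_volume for r in rows]))
        thickness = float(
            np.mean([np.mean(r.thickness_samples) for r in rows])
        ) * (config.analysis.thickness_correction_factor if config.analysis.thickness_correction else 1.0)
        frustum = FrustumParams.from_tissue(
            thickness=thickness,
            mitotic_diameter=float(np.mean(diameters)),
            apical_to_basal_area_ratio=cal.apical_to_basal_area_ratio,
            cell_density=density,
            t_cc=cal.cell_cycle_mean,
            t_m=cal.mitosis_duration,
        )
        res = trap_analysis(frustum)
        out[f"{stage:g}"] = {
            "n_measured": res.n_measured,
            "n_max": res.n_max,
            "trap": res.trap,
            "at_capacity": res.at_capacity,
        }
    return {"per_stage": out, "any_trap": any(v["trap"] for v in out.values())}


def _heatmap_section(config: PipelineConfig, scenario: Scenario, seed: int) -> dict:
    cap = SphericalCap(radius=100.0, max_colatitude=math.pi / 2)
    out = {}
    for stage in config.stages:
        cal = effective_calibration(config, stage, scenario)
        n = max(int(round(cal.mean_cells * cal.mitotic_index)) * 10, 50)  # pooled over embryos
        pts = generate_mitotic_coordinates(
            n, cap, density_mode="uniform", seed=int(child_rng(seed, "heatmap", f"{stage:g}").integers(2**31))
        )
        fit = fit_sphere(pts)
        xy, _ = project_equal_area(pts, fit, pole=np.array([0.0, 0.0, 1.0]))
        grid = density_heatmap(xy, bins=config.analysis.heatmap_bins,
                               smooth_bandwidth=config.analysis.heatmap_smooth_bandwidth)
        max_rho = 2.0 * cap.radius * math.sin(cap.max_colatitude / 2.0)
        chi2, p = annulus_uniformity(xy, max_radius=max_rho)
        out[f"{stage:g}"] = {
            "n_events": int(n),
            "uniformity_p": p,
            "heatmap_mass": grid.total_mass(),
        }
    angles = generate_division_angles(150, concentration=0.0,
                                      seed=int(child_rng(seed, "angles").integers(2**31)))
    ang = division_angle_stats(angles, config.analysis.sector_width_deg)
    return {
        "per_stage": out,
        "division_angles": {
            "resultant_length": ang.resultant_length,
            "p_uniform": ang.p_uniform,
        },
    }


def _cycle_section(config: PipelineConfig, scenario: Scenario, seed: int) -> dict:
    out = {}
    for stage in config.stages:
        cal = effective_calibration(config, stage, scenario)
        tracks = generate_cell_cycle_tracks(
            60, cal, seed=int(child_rng(seed, "tracks", f"{stage:g}").integers(2**31))
        )
        stats = cycle_lengths(tracks, [stage], config.analysis.stage_bin_halfwidth)[0]
        out[f"{stage:g}"] = {
            "mean_cycle_h": stats.mean_cycle_length,
            "cov": stats.cycle_cov,
            "mean_mitosis_h": stats.mean_mitosis_duration,
            "n_cycles": stats.n_cycles,
        }
    return out


def _zone_section(config: PipelineConfig, scenario: Scenario, seed: int) -> dict:
    out = {}
    for stage in config.stages:
        cal = effective_calibration(config, stage, scenario)
        pairs = generate_intensity_profiles(config, stage, scenario, n_profiles=9, seed=seed)
        actin_mean, _ = average_profiles([a for a, _ in pairs])
        zone = detect_basal_zone(actin_mean, tissue_height=cal.mean_thickness)
        out[f"{stage:g}"] = {
            "basal_extent_fraction": zone.basal_extent_fraction,
            "basal_extent_um": zone.basal_extent_um,
            "absent": zone.absent,
        }
    return out


def _ratio_section(config: PipelineConfig, scenario: Scenario, seed: int, n_samples: int = 5) -> dict:
    per_stage: dict[str, list[float]] = {}
    for stage in config.stages:
        vals = []
        for i in range(n_samples):
            traces = generate_cortical_traces(
                config, stage, scenario,
                seed=int(child_rng(seed, "cortical", f"{stage:g}", str(i)).integers(2**31)),
            )
            vals.append(cortical_ratios(*traces).basal_to_lateral)
        per_stage[f"{stage:g}"] = vals
    first, last = f"{config.stages[0]:g}", f"{config.stages[-1]:g}"
    mw = sp_stats.mannwhitneyu(per_stage[first], per_stage[last], alternative="two-sided")
    return {
        "basal_to_lateral_mean": {k: float(np.mean(v)) for k, v in per_stage.items()},
        "first_vs_last_p": float(mw.pvalue),
        "redistribution_significant": bool(mw.pvalue < 0.05),
    }


def _mechanics_section(config: PipelineConfig, scenario: Scenario) -> dict:
    mech_scenario = scenario if scenario is Scenario.HDAC1 else Scenario.CONTROL
    traj = scenario_trajectory(config, mech_scenario)
    ar = traj["aspect_ratio"].to_numpy()
    drift = abs(ar[-1] / ar[0] - 1.0)
    return {
        "scenario": mech_scenario.value,
        "max_height_um": float(traj["height_um"].max()),
        "final_height_um": float(traj["height_um"].iloc[-1]),
        "aspect_ratio_start": float(ar[0]),
        "aspect_ratio_end": float(ar[-1]),
        "aspect_ratio_drift": float(drift),
        "aspect_ratio_constant": bool(drift < ISOTROPY_DRIFT_TOLERANCE),
        "aspect_ratio_monotone_decreasing": bool(np.all(np.diff(ar) < 0)),
    }


def run_pipeline(
    config: PipelineConfig,
    scenario: Scenario | str = Scenario.CONTROL,
    seed: int | None = None,
    out_dir: str | Path | None = None,
    n_embryos: int = 10,
) -> dict:
    """Run every analysis stage on synthetic data and assemble the report.

    Deterministic given (config, scenario, seed).  When ``out_dir`` is
    given, writes the generated stage table, diameters and ``report.json``.
    """
    scenario = Scenario(scenario)
    seed = config.seed if seed is None else int(seed)
    log.info("pipeline start: scenario=%s seed=%d", scenario.value, seed)

    table = generate_stage_table(config, scenario, n_embryos=n_embryos, seed=seed)
    grouped = table.groupby_stage()
    times = np.array([t for t, rows in grouped.items() for _ in rows])
    volumes = np.array([r.tissue_volume for rows in grouped.values() for r in rows])
    fit = exponential_growth_fit(times, volumes)
    rates = decompose_table(table, config.analysis)
    balance = {
        "stages": list(rates.stages),
        "residual_cell": rates.residual_cell.tolist(),
        "residual_geometry": rates.residual_geometry.tolist(),
        "pooled_sd_cell": rates.pooled_sd_cell.tolist(),
        "pooled_sd_geometry": rates.pooled_sd_geometry.tolist(),
        "within_pooled_sd": bool(
            np.all(np.abs(rates.residual_cell) <= rates.pooled_sd_cell)
            and np.all(np.abs(rates.residual_geometry) <= rates.pooled_sd_geometry)
        ),
    }

    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "provenance": {
            "package_version": __version__,
            "seed": seed,
            "scenario": scenario.value,
            "config_hash": _config_hash(config),
            "n_embryos": n_embryos,
        },
        "derived_metrics": _stage_summary(table, config),
        "growth_fit": fit.to_dict(),
        "log_rate_balance": balance,
        "apical_occupancy": _occupancy_section(table),
        "trap": _trap_section(table, config, scenario),
        "heatmaps": _heatmap_section(config, scenario, seed),
        "cell_cycle": _cycle_section(config, scenario, seed),
        "actin_zones": _zone_section(config, scenario, seed),
        "cortical_ratios": _ratio_section(config, scenario, seed),
        "mechanics": _mechanics_section(config, scenario),
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_stage_table(table, out / "stage_table.csv", out / "mitotic_diameters.csv")
        with open(out / "report.json", "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
        log.info("report written to %s", out / "report.json")
    return report


def _diff(a: Any, b: Any) -> Any:
    if isinstance(a, dict) and isinstance(b, dict):
        return {k: _diff(a[k], b[k]) for k in a if k in b}
    if isinstance(a, bool) or isinstance(b, bool):
        return {"a": a, "b": b, "equal": a == b}
    if isinstance(a, (int, float)) and isinstance(b, (int, float)):
        return float(b) - float(a)
    if isinstance(a, list) and isinstance(b, list) and len(a) == len(b):
        return [_diff(x, y) for x, y in zip(a, b)]
    return {"a": a, "b": b}


def compare_scenarios(report_a: dict, report_b: dict) -> dict:
    """Per-quantity differences (b − a) between two pipeline reports."""
    va = report_a.get("schema_version")
    vb = report_b.get("schema_version")
    if va != vb:
        raise ValidationError(f"report schema mismatch: {va!r} vs {vb!r}")
    sections = [k for k in report_a if k not in ("schema_version", "provenance")]
    return {
        "schema_version": va,
        "scenario_a": report_a["provenance"]["scenario"],
        "scenario_b": report_b["provenance"]["scenario"],
        "differences": {k: _diff(report_a[k], report_b[k]) for k in sections},
    }
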