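"""Synthetic-retina generator: every input the pipeline consumes.

The generator emulates the statistical structure of the measured data so
the whole analysis is testable without the original microscopy: exponential
tissue-volume growth with multiplicative (lognormal) noise, stage-dependent
mitotic index and gamma-distributed cell-cycle lengths, mitoses uniform per
unit area on a spherical-cap apical surface (optionally with an azimuthal
density wave emulating the neurogenic naso-temporal front), and apicobasal
actin profiles with a basal plateau whose extent shrinks over development
in the control and persists in the hdac1 scenario.

All draws are deterministic under a fixed seed; with every coefficient of
variation at zero each output equals its calibration exactly (count draws
switch from Poisson/binomial to rounded means in that limit, so the
zero-noise contract holds for integers too).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._errors import ValidationError
from ._rng import as_rng, child_rng
from .apical import MitoticPointSet
from .config import PipelineConfig, Scenario, StageCalibration
from .datamodel import StageMeasurement, StageTable
from .proliferation import ROUNDING, SEGREGATION, LineageTrack
from .profiles import ApicobasalProfile

__all__ = [
    "SphericalCap",
    "effective_calibration",
    "generate_stage_table",
    "generate_mitotic_coordinates",
    "generate_cell_cycle_tracks",
    "generate_intensity_profiles",
    "generate_cortical_traces",
    "generate_division_angles",
]


def effective_calibration(
    config: PipelineConfig, stage_hpf: float, scenario: Scenario
) -> StageCalibration:
    """Stage calibration with the scenario's phenomenology applied.

    * hdac1: actin extent frozen at its 30-hpf (earliest pre-transition
      stage) value; proliferation unchanged; the 55 μm thickness cap is
      applied at draw time.
    * rockout: after the treatment onset the basolateral actin pool is
      abolished and proliferation is strongly suppressed (cell count frozen
      at the onset-stage calibration, mitotic index at 4% of control —
      the residual division activity seen under ROCK inhibition).
    * hua: proliferation fully blocked after onset; actin as in control.
    """
    cal = config.calibration(stage_hpf)
    scenario = Scenario(scenario)
    if scenario is Scenario.CONTROL:
        return cal
    if scenario is Scenario.HDAC1:
        freeze_stage = min(
            (s for s in config.stages if s <= config.analysis.transition_hpf),
            key=lambda s: abs(s - 30.0),
        )
        frozen = config.calibration(freeze_stage).actin_basal_extent_fraction
        return cal.replace(actin_basal_extent_fraction=frozen)
    onset = config.analysis.perturbation_onset_hpf
    if stage_hpf <= onset:
        return cal
    onset_stages = [s for s in config.stages if s <= onset]
    if not onset_stages:
        raise ValidationError(f"no calibration stage at or before onset {onset} hpf")
    frozen_cells = config.calibration(max(onset_stages)).mean_cells
    if scenario is Scenario.ROCKOUT:
        return cal.replace(
            mean_cells=frozen_cells,
            mitotic_index=cal.mitotic_index * 0.04,
            actin_basal_extent_fraction=0.0,
        )
    if scenario is Scenario.HUA:
        return cal.replace(mean_cells=frozen_cells, mitotic_index=0.0)
    raise ValidationError(f"unhandled scenario {scenario}")


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    """Normal draws redrawn until positive (negligible mass for cv << 1)."""
    if sd == 0:
        return np.full(size, mean)
    out = rng.normal(mean, sd, size)
    bad = out <= 0
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out <= 0
    return out


def generate_stage_table(
    config: PipelineConfig,
    scenario: Scenario | str = Scenario.CONTROL,
    n_embryos: int = 10,
    seed: int | None = None,
    n_thickness_positions: int = 5,
) -> StageTable:
    """Per-embryo morphometric records for every configured stage.

    Tissue volume is lognormal about the calibration mean; surface areas
    derive from each embryo's own volume and thickness (so the geometric
    balance V = A·h holds up to the configured area noise) and are split
    apical/basal by the calibrated area ratio; counts are Poisson about a
    lognormal mean with mitoses binomial at the mitotic index.
    """
    seed = config.seed if seed is None else seed
    scenario = Scenario(scenario)
    rng = child_rng(seed, "stage_table", scenario.value)
    rows: list[StageMeasurement] = []
    ratio_cap = config.analysis.hdac1_thickness_cap
    for stage in config.stages:
        cal = effective_calibration(config, stage, scenario)
        for e in range(n_embryos):
            volume = cal.mean_tissue_volume * math.exp(rng.normal(0.0, cal.volume_cv))
            thickness = _truncated_normal(
                rng, cal.mean_thickness, cal.thickness_cv * cal.mean_thickness,
                n_thickness_positions,
            )
            if scenario is Scenario.HDAC1:
                thickness = np.minimum(thickness, ratio_cap)
            if cal.count_cv > 0:
                n_cells = int(rng.poisson(cal.mean_cells * math.exp(rng.normal(0.0, cal.count_cv))))
                n_cells = max(n_cells, 1)
                n_mitotic = int(rng.binomial(n_cells, cal.mitotic_index))
            else:  # zero-noise limit: deterministic counts
                n_cells = int(round(cal.mean_cells))
                n_mitotic = int(round(n_cells * cal.mitotic_index))
            n_diam = int(rng.integers(15, 21))
            diameters = _truncated_normal(
                rng, cal.mean_mitotic_diameter, cal.diameter_cv * cal.mean_mitotic_diameter,
                n_diam,
            )
            mean_area = volume / float(np.mean(thickness)) * math.exp(
                rng.normal(0.0, cal.area_noise_cv)
            )
            total_area = 2.0 * mean_area
            rho = cal.apical_to_basal_area_ratio
            apical_area = total_area * rho / (1.0 + rho)
            zone = float(_truncated_normal(
                rng, cal.nuclear_zone_height, cal.nuclear_size_cv * cal.nuclear_zone_height, 1,
            )[0])
            axis = float(_truncated_normal(
                rng, cal.nuclear_long_axis, cal.nuclear_size_cv * cal.nuclear_long_axis, 1,
            )[0])
            rows.append(
                StageMeasurement(
                    embryo_id=f"{scenario.value}-s{stage:g}-e{e + 1:02d}",
                    stage_hpf=stage,
                    tissue_volume=volume,
                    apical_area=apical_area,
                    total_surface_area=total_area,
                    thickness_samples=list(thickness),
                    n_cells=n_cells,
                    n_mitotic=min(n_mitotic, n_cells),
                    nuclear_zone_height=zone,
                    nuclear_long_axis=axis,
                    mitotic_diameters=list(diameters),
                )
            )
    return StageTable(rows=rows)


@dataclass(frozen=True)
class SphericalCap:
    """Apical reference surface: spherical cap of given angular aperture."""

    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    radius: float = 100.0
    max_colatitude: float = math.pi / 2  # radians from the pole (+z)

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValidationError("cap radius must be positive")
        if not 0 < self.max_colatitude <= math.pi:
            raise ValidationError("max colatitude must lie in (0, π]")


def generate_mitotic_coordinates(
    n: int,
    cap: SphericalCap,
    density_mode: str = "uniform",
    seed: int | None = 0,
    wave_amplitude: float = 0.8,
) -> MitoticPointSet:
    """Mitotic positions on the apical cap.

    ``uniform`` samples uniformly per unit area (cos-colatitude inversion);
    ``gradient`` modulates density with an azimuthal wave
    w(φ) ∝ 1 + a·cos φ, emulating the naso-temporal neurogenic front, via
    rejection sampling.
    """
    if n < 0:
        raise ValidationError("n must be >= 0")
    if density_mode not in ("uniform", "gradient"):
        raise ValidationError(f"unknown density_mode {density_mode!r}")
    rng = child_rng(seed if seed is not None else 0, "mitotic_coordinates", density_mode)
    if n == 0:
        return MitoticPointSet(points=np.zeros((0, 3)))
    cos_max = math.cos(cap.max_colatitude)
    u = rng.random(n)
    cos_theta = 1.0 - u * (1.0 - cos_max)
    if density_mode == "uniform":
        phi = rng.uniform(0.0, 2.0 * math.pi, n)
    else:
        if not 0 < wave_amplitude <= 1:
            raise ValidationError("wave amplitude must lie in (0, 1]")
        phi = np.empty(n)
        filled = 0
        while filled < n:
            cand = rng.uniform(0.0, 2.0 * math.pi, 2 * (n - filled))
            accept = rng.random(cand.size) < (1.0 + wave_amplitude * np.cos(cand)) / (
                1.0 + wave_amplitude
            )
            take = cand[accept][: n - filled]
            phi[filled : filled + take.size] = take
            filled += take.size
    sin_theta = np.sqrt(np.clip(1.0 - cos_theta**2, 0.0, 1.0))
    xyz = cap.radius * np.column_stack(
        [sin_theta * np.cos(phi), sin_theta * np.sin(phi), cos_theta]
    ) + np.asarray(cap.center)
    return MitoticPointSet(points=xyz)


def generate_cell_cycle_tracks(
    n_tracks: int,
    calibration: StageCalibration,
    seed: int | None = 0,
    n_cycles: int = 2,
) -> list[LineageTrack]:
    """Lineage tracks with gamma-distributed cycle lengths.

    Cycle lengths are gamma with the calibrated mean and CV (gamma keeps
    positivity and matches a mean/CV summary); each mitosis contributes a
    rounding event T_M before its segregation.  The first cycle is centred
    on the calibration stage with ±2 h jitter, matching the convention that
    a cycle is labelled by its midpoint.
    """
    if calibration.cell_cycle_mean <= calibration.mitosis_duration:
        raise ValidationError("cell_cycle_mean must exceed mitosis_duration")
    rng = child_rng(seed if seed is not None else 0, "cell_cycle_tracks",
                    f"{calibration.stage_hpf:g}")
    mean, cv = calibration.cell_cycle_mean, calibration.cell_cycle_cv
    t_m = calibration.mitosis_duration
    tracks: list[LineageTrack] = []
    for i in range(n_tracks):
        if cv > 0:
            shape = 1.0 / cv**2
            cycles = rng.gamma(shape, mean / shape, n_cycles)
        else:
            cycles = np.full(n_cycles, mean)
        jitter = rng.uniform(-2.0, 2.0)
        first_seg = calibration.stage_hpf + jitter - cycles[0] / 2.0
        seg_times = first_seg + np.concatenate([[0.0], np.cumsum(cycles)])
        events: list[tuple[str, float]] = []
        for t_seg in seg_times:
            events.append((ROUNDING, t_seg - t_m))
            events.append((SEGREGATION, t_seg))
        tracks.append(LineageTrack(track_id=f"t{i + 1:04d}", events=events))
    return tracks


_PROFILE_GRID = np.linspace(0.0, 1.0, 101)
_EDGE_WIDTH = 0.008   # logistic edge scale of the basal plateau
_APICAL_SCALE = 0.03  # Gaussian scale of the apical cortical peak
_NUCLEAR_APICAL_MARGIN = 0.04


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def generate_intensity_profiles(
    config: PipelineConfig,
    stage_hpf: float,
    scenario: Scenario | str = Scenario.CONTROL,
    n_profiles: int = 9,
    seed: int | None = None,
) -> list[tuple[ApicobasalProfile, ApicobasalProfile]]:
    """(actin, nuclear) profile pairs for one stage and scenario.

    The actin profile is a lateral baseline plus an apical cortical peak and
    a basal plateau occupying the calibrated basal fraction (logistic edge,
    half-height exactly at the calibrated boundary); the nuclear profile is
    an occupancy band that vanishes inside the plateau, giving the negative
    spatial correlation of the exclusion zone.  Gaussian noise with the
    calibrated sd is added to both channels.
    """
    seed = config.seed if seed is None else seed
    scenario = Scenario(scenario)
    cal = effective_calibration(config, stage_hpf, scenario)
    rng = child_rng(seed, "intensity_profiles", scenario.value, f"{stage_hpf:g}")
    x = _PROFILE_GRID
    extent = cal.actin_basal_extent_fraction
    boundary = 1.0 - extent
    pairs = []
    for i in range(n_profiles):
        actin = cal.actin_baseline + (cal.actin_apical_peak - cal.actin_baseline) * np.exp(
            -((x / _APICAL_SCALE) ** 2)
        )
        if extent > 0:
            actin = actin + (cal.actin_plateau - cal.actin_baseline) * _sigmoid(
                (x - boundary) / _EDGE_WIDTH
            )
        nuclear_hi = 1.0 - extent if extent > 0 else 0.98
        nuclear = 0.1 + 0.85 * (
            _sigmoid((x - _NUCLEAR_APICAL_MARGIN) / 0.02)
            - _sigmoid((x - nuclear_hi) / _EDGE_WIDTH)
        )
        if cal.profile_noise_sd > 0:
            actin = actin + rng.normal(0.0, cal.profile_noise_sd, x.size)
            nuclear = nuclear + rng.normal(0.0, cal.profile_noise_sd, x.size)
        pairs.append(
            (
                ApicobasalProfile(channel="actin", positions=x.copy(), intensities=actin,
                                  stage_hpf=stage_hpf, embryo_id=f"p{i + 1:02d}"),
                ApicobasalProfile(channel="nuclear", positions=x.copy(), intensities=nuclear,
                                  stage_hpf=stage_hpf, embryo_id=f"p{i + 1:02d}"),
            )
        )
    return pairs


def generate_cortical_traces(
    config: PipelineConfig,
    stage_hpf: float,
    scenario: Scenario | str = Scenario.CONTROL,
    seed: int | None = None,
    n_peaks: int = 8,
    n_samples: int = 250,
    noise_sd: float = 0.02,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(apical, basal, lateral) line-scan traces for cortical-ratio analysis.

    Each trace is a baseline with ``n_peaks`` Gaussian cortical peaks; peak
    heights in the apical and basal traces are scaled by the calibrated
    apical/lateral and basal/lateral ratios.  hdac1 freezes both ratios at
    their earliest-stage values (no redistribution).
    """
    seed = config.seed if seed is None else seed
    scenario = Scenario(scenario)
    cal = config.calibration(stage_hpf)
    if scenario is Scenario.HDAC1:
        first = config.calibration(min(config.stages))
        basal_ratio, apical_ratio = first.basal_lateral_ratio, first.apical_lateral_ratio
    else:
        basal_ratio, apical_ratio = cal.basal_lateral_ratio, cal.apical_lateral_ratio
    rng = child_rng(seed, "cortical_traces", scenario.value, f"{stage_hpf:g}")
    x = np.linspace(0.0, 1.0, n_samples)

    def trace(height: float) -> np.ndarray:
        centers = rng.uniform(0.05, 0.95, n_peaks)
        widths = rng.uniform(0.008, 0.015, n_peaks)
        heights = height * rng.normal(1.0, 0.08, n_peaks)
        y = np.full(n_samples, 0.2)
        for c, w, h in zip(centers, widths, heights):
            y = y + h * np.exp(-(((x - c) / w) ** 2))
        return y + rng.normal(0.0, noise_sd, n_samples)

    lateral = trace(1.0)
    basal = trace(basal_ratio)
    apical = trace(apical_ratio)
    return apical, basal, lateral


def generate_division_angles(
    n: int, concentration: float = 0.0, seed: int | None = 0, mu: float = 0.0
) -> np.ndarray:
    """In-plane division angles (radians): von Mises, uniform at κ = 0."""
    if concentration < 0:
        raise ValidationError("concentration must be >= 0")
    rng = child_rng(seed if seed is not None else 0, "division_angles")
    if concentration == 0:
        return rng.uniform(-math.pi, math.pi, n)
    return as_rng(rng).vonmises(mu, concentration, n)
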