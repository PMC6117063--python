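"""Pipeline configuration: stage calibrations, analysis options, scenarios.

The packaged reference configuration transcribes the stage means of the
wild-type growth series (six stages, 20–48 hpf): cell counts rising from
2,177 to 18,000, interphase cell volumes falling from 440 to 140 μm³, tissue
thickness in the 48–63 μm band, cell-cycle means shortening from 8.5 h to
5.3 h, and a basolateral actin accumulation whose basal extent shrinks from
28% to 5% of the apicobasal axis.  Mean tissue volume is the product of mean
cell count and mean cell volume, so the volumetric balance identity
V = N · v holds exactly at the calibration means.  Embryo-level coefficients
of variation are calibration choices (the source measurements report only
stage-level scatter) and are flagged as such in the YAML comments.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass, field, fields
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml

from ._errors import SchemaError, ValidationError
from ._log import get_logger

__all__ = [
    "Scenario",
    "StageCalibration",
    "AnalysisOptions",
    "PipelineConfig",
    "load_config",
    "default_config",
]

log = get_logger("config")

DEFAULT_SEED = 0


class Scenario(str, enum.Enum):
    """Biological condition emulated by the synthetic generator.

    * ``control`` — wild type: actin redistributes, cells elongate.
    * ``hdac1`` — hdac1−/− mutant: continued proliferation, no differentiation;
      the basolateral actin accumulation persists (frozen at its 30-hpf
      extent) and cells do not elongate past the 55 μm cap.
    * ``rockout`` — ROCK inhibition: the basolateral actin pool is abolished
      from the treatment onset and proliferation is strongly suppressed.
    * ``hua`` — hydroxyurea/aphidicolin: proliferation blocked from onset,
      actin behaves as in the control.
    """

    CONTROL = "control"
    HDAC1 = "hdac1"
    ROCKOUT = "rockout"
    HUA = "hua"


def _from_mapping(cls, mapping: Mapping[str, Any], context: str):
    """Build a dataclass from a mapping, rejecting unknown keys (no typo tolerance)."""
    known = {f.name for f in fields(cls)}
    unknown = sorted(set(mapping) - known)
    if unknown:
        raise SchemaError(f"{context}: unknown key(s) {unknown}; known keys are {sorted(known)}")
    return cls(**mapping)


@dataclass(frozen=True)
class StageCalibration:
    """Generator calibration for one developmental stage (units: μm, h)."""

    stage_hpf: float
    mean_cells: float
    mean_cell_volume: float          # μm³, interphase
    mean_tissue_volume: float        # μm³ (= mean_cells × mean_cell_volume)
    tissue_growth_rate: float        # 1/h, exponential fit across stages
    mean_thickness: float            # μm
    apical_to_basal_area_ratio: float
    mitotic_index: float             # fraction of cells in mitosis
    mean_mitotic_diameter: float     # μm (widest cross-section of rounded cell)
    cell_cycle_mean: float           # h
    cell_cycle_cv: float
    mitosis_duration: float          # h (T_M)
    actin_basal_extent_fraction: float
    nuclear_zone_height: float       # μm
    nuclear_long_axis: float         # μm
    basal_lateral_ratio: float       # cortical actin, basal/lateral peak ratio
    apical_lateral_ratio: float
    # noise model (embryo-level variation; calibration choices, see module docstring)
    volume_cv: float = 0.12
    thickness_cv: float = 0.05
    count_cv: float = 0.08
    diameter_cv: float = 0.08
    area_noise_cv: float = 0.03
    nuclear_size_cv: float = 0.05
    # actin profile shape
    actin_baseline: float = 0.25
    actin_apical_peak: float = 1.0
    actin_plateau: float = 0.75
    profile_noise_sd: float = 0.05

    def __post_init__(self) -> None:
        fractions = {
            "mitotic_index": self.mitotic_index,
            "actin_basal_extent_fraction": self.actin_basal_extent_fraction,
        }
        for name, value in fractions.items():
            if not (0.0 <= value < 1.0):
                raise ValidationError(f"{name} must lie in [0, 1), got {value}")
        for name in (
            "volume_cv", "thickness_cv", "count_cv", "diameter_cv",
            "area_noise_cv", "nuclear_size_cv", "cell_cycle_cv", "profile_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not self.mitosis_duration < self.cell_cycle_mean:
            raise ValidationError(
                f"mitosis_duration ({self.mitosis_duration}) must be shorter than "
                f"cell_cycle_mean ({self.cell_cycle_mean})"
            )
        for name in (
            "mean_cells", "mean_cell_volume", "mean_tissue_volume", "mean_thickness",
            "apical_to_basal_area_ratio", "mean_mitotic_diameter", "cell_cycle_mean",
            "mitosis_duration", "nuclear_zone_height", "nuclear_long_axis",
            "basal_lateral_ratio", "apical_lateral_ratio",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")

    def replace(self, **changes) -> "StageCalibration":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class AnalysisOptions:
    """Tunable analysis settings shared by the pipeline stages."""

    thickness_correction: bool = True        # 5% decrease compensating the thinner CMZ rim
    thickness_correction_factor: float = 0.95
    interphase_volume_correction: float = 0.9  # mitotic cells are ~10% larger than interphase
    heatmap_bins: int = 64
    heatmap_smooth_bandwidth: float = 0.0    # μm of projected plane; 0 = no smoothing
    sector_width_deg: float = 10.0           # rose-plot sector width (axial data)
    stage_bin_halfwidth: float = 3.0         # h; cycle statistics binned as stage ± 3 h
    hdac1_thickness_cap: float = 55.0        # μm; mutant cells do not elongate past this
    perturbation_onset_hpf: float = 30.0     # rockout / HU+A treatment start
    transition_hpf: float = 35.5             # differentiation + actin-redistribution onset
    ramp_duration_h: float = 6.0             # tension-ratio ramp length (control)
    division_rate: float = 0.11              # 1/h, progenitor division rate k
    p_progenitor_after: float = 0.65         # P(division -> 2 progenitors) after transition
    alpha_symmetric: float = 1.0             # differentiative divisions assumed symmetric
    n_initial: float = 2177.0                # cells at t_initial
    t_initial: float = 20.0                  # hpf


@dataclass
class PipelineConfig:
    """Seed, stage list, per-stage calibrations and analysis options."""

    seed: int = DEFAULT_SEED
    stages: list[float] = field(default_factory=list)
    analysis: AnalysisOptions = field(default_factory=AnalysisOptions)
    calibrations: dict[float, StageCalibration] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.stages = [float(s) for s in self.stages]
        if sorted(self.stages) != self.stages or len(set(self.stages)) != len(self.stages):
            raise ValidationError(f"stages must be strictly increasing, got {self.stages}")
        missing = [s for s in self.stages if s not in self.calibrations]
        if missing:
            raise ValidationError(f"stages without calibration block: {missing}")

    def calibration(self, stage_hpf: float) -> StageCalibration:
        key = float(stage_hpf)
        if key not in self.calibrations:
            raise ValidationError(f"no calibration for stage {stage_hpf} hpf")
        return self.calibrations[key]


_TOP_LEVEL_KEYS = {"seed", "stages", "analysis", "calibrations"}


def _parse_config(data: Mapping[str, Any], context: str) -> PipelineConfig:
    if not isinstance(data, Mapping):
        raise SchemaError(f"{context}: expected a mapping at top level")
    unknown = sorted(set(data) - _TOP_LEVEL_KEYS)
    if unknown:
        raise SchemaError(f"{context}: unknown top-level key(s) {unknown}")
    seed = int(data.get("seed", DEFAULT_SEED))
    if "seed" not in data:
        log.info("no seed in config; default seed %d applied", seed)
    analysis = _from_mapping(AnalysisOptions, data.get("analysis", {}) or {}, f"{context}:analysis")
    raw_cals = data.get("calibrations", {}) or {}
    calibrations: dict[float, StageCalibration] = {}
    for key, block in raw_cals.items():
        stage = float(key)
        block = dict(block or {})
        block.setdefault("stage_hpf", stage)
        cal = _from_mapping(StageCalibration, block, f"{context}:calibrations[{key}]")
        calibrations[stage] = cal
    stages = [float(s) for s in data.get("stages", sorted(calibrations))]
    config = PipelineConfig(seed=seed, stages=stages, analysis=analysis, calibrations=calibrations)
    log.info("config loaded (%s): %d stages, seed %d", context, len(stages), seed)
    return config


def load_config(path) -> PipelineConfig:
    """Load a YAML configuration file.

    Absent optional keys take defaults; unknown keys are a hard error.
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if data is None:
        raise SchemaError(f"{path}: empty configuration file")
    return _parse_config(data, str(path))


def default_config(seed: int | None = None) -> PipelineConfig:
    """The packaged reference configuration (six stages, 20–48 hpf)."""
    ref = resources.files("psegrowth.data").joinpath("reference_config.yaml")
    data = yaml.safe_load(ref.read_text(encoding="utf-8"))
    config = _parse_config(data, "reference_config.yaml")
    if seed is not None:
        config.seed = int(seed)
    return config
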