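"""Growth decomposition: cell-level metrics and logarithmic rate balances.

Tissue-level measurements (volume V, mean surface area A, thickness h, cell
number N) decompose volumetric growth through two exact identities,

    V = N · v_cell        and        V = A · h,

so the cumulative logarithmic rates of change satisfy

    Δln V = Δln N + Δln v_cell        Δln V = Δln A + Δln h.

Each quantity is measured independently (counts from nuclear detection, cell
volume from mitotic-sphere diameters, areas and thickness from 3D
segmentation), so the balance residuals quantify measurement consistency:
they vanish exactly on algebraically consistent inputs and should stay
within the pooled embryo-level standard deviation on real or emulated data.

Aspect ratios are height divided by the square root of area, at cell scale
(cross-sectional cell area) or tissue scale (mean tissue surface area);
constancy of the tissue ratio is the operational definition of isotropic
scaling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import MissingDataError, ValidationError
from .config import AnalysisOptions
from .datamodel import StageTable

__all__ = [
    "interphase_cell_volume",
    "mean_cell_cross_section",
    "corrected_thickness",
    "aspect_ratio",
    "nuclear_stacking",
    "apical_to_basal_layers",
    "DerivedCellMetrics",
    "derive_stage_metrics",
    "LogRateSeries",
    "log_rate_decomposition",
    "decompose_table",
    "ExponentialFit",
    "exponential_growth_fit",
]


def interphase_cell_volume(diameters: Sequence[float], correction: float = 0.9) -> float:
    """Mean interphase cell volume (μm³) from rounded mitotic-cell diameters.

    Mitotic cells are nearly spherical, so each diameter d gives a volume
    (π/6)·d³.  Mitotic cells are on average 10% larger than interphase
    cells, hence the multiplicative ``correction`` of 0.9.
    """
    if len(diameters) == 0:
        raise MissingDataError("no mitotic diameters measured for this record")
    d = np.asarray(diameters, dtype=float)
    if np.any(d <= 0):
        raise ValidationError("mitotic diameters must be positive")
    return float(correction * np.mean(np.pi / 6.0 * d**3))


def mean_cell_cross_section(apical_area: float, total_surface_area: float, n_cells: int) -> float:
    """Mean cross-sectional cell area: average of apical and basal endfoot areas.

    The basal tissue area is the total segmented surface area minus the
    apical area; each is divided by the cell count and the two per-cell
    endfoot areas are averaged arithmetically.
    """
    if n_cells <= 0:
        raise ValidationError(f"n_cells must be positive, got {n_cells}")
    basal_area = total_surface_area - apical_area
    if basal_area <= 0:
        raise ValidationError(
            f"basal area (total - apical) must be positive, got {basal_area}"
        )
    return 0.5 * (apical_area / n_cells + basal_area / n_cells)


def corrected_thickness(samples: Sequence[float], enabled: bool = True, factor: float = 0.95) -> float:
    """Mean tissue thickness (μm), optionally decreased by 5%.

    The correction compensates for the thinner ciliary marginal zone rim,
    which the point-sampled thickness positions do not cover.
    """
    if len(samples) == 0:
        raise MissingDataError("no thickness samples")
    mean = float(np.mean(np.asarray(samples, dtype=float)))
    return factor * mean if enabled else mean


def aspect_ratio(height: float, area: float) -> float:
    """height / sqrt(area); serves both cell- and tissue-scale ratios."""
    if height <= 0 or area <= 0:
        raise ValidationError("height and area must be positive")
    return height / math.sqrt(area)


def nuclear_stacking(zone_height: float, nuclear_long_axis: float) -> float:
    """Nuclei stacked in the nuclear zone: zone height / nuclear long axis (unrounded)."""
    if zone_height <= 0 or nuclear_long_axis <= 0:
        raise ValidationError("zone height and nuclear long axis must be positive")
    return zone_height / nuclear_long_axis


def apical_to_basal_layers(thickness: float, nuclear_long_axis: float) -> float:
    """Nuclear layers fitting along the entire apicobasal axis (unrounded)."""
    if thickness <= 0 or nuclear_long_axis <= 0:
        raise ValidationError("thickness and nuclear long axis must be positive")
    return thickness / nuclear_long_axis


@dataclass(frozen=True)
class DerivedCellMetrics:
    """Cell-level metrics derived from one stage's pooled measurements."""

    stage_hpf: float
    mean_cell_volume: float        # μm³, from mitotic diameters (10% corrected)
    mean_cell_cross_section: float  # μm²
    corrected_thickness: float     # μm
    cell_density: float            # cells/μm³
    cell_aspect_ratio: float
    tissue_aspect_ratio: float
    nuclear_stacking: float
    apical_to_basal_layers: float
    n_embryos: int


def derive_stage_metrics(table: StageTable, options: AnalysisOptions | None = None) -> list[DerivedCellMetrics]:
    """Per-stage cell-level metrics pooled across embryos."""
    options = options or AnalysisOptions()
    out = []
    for stage, rows in table.groupby_stage().items():
        diameters = [d for r in rows for d in r.mitotic_diameters]
        cell_volume = (
            interphase_cell_volume(diameters, options.interphase_volume_correction)
            if diameters
            else float("nan")
        )
        cross = float(np.mean([
            mean_cell_cross_section(r.apical_area, r.total_surface_area, r.n_cells) for r in rows
        ]))
        thick = float(np.mean([
            corrected_thickness(
                r.thickness_samples, options.thickness_correction, options.thickness_correction_factor
            )
            for r in rows
        ]))
        density = float(np.mean([r.n_cells / r.tissue_volume for r in rows]))
        tissue_area = float(np.mean([0.5 * r.total_surface_area for r in rows]))
        stacking = float(np.mean([
            nuclear_stacking(r.nuclear_zone_height, r.nuclear_long_axis) for r in rows
        ]))
        layers = float(np.mean([
            apical_to_basal_layers(
                corrected_thickness(
                    r.thickness_samples,
                    options.thickness_correction,
                    options.thickness_correction_factor,
                ),
                r.nuclear_long_axis,
            )
            for r in rows
        ]))
        out.append(
            DerivedCellMetrics(
                stage_hpf=stage,
                mean_cell_volume=cell_volume,
                mean_cell_cross_section=cross,
                corrected_thickness=thick,
                cell_density=density,
                cell_aspect_ratio=aspect_ratio(thick, cross),
                tissue_aspect_ratio=aspect_ratio(thick, tissue_area),
                nuclear_stacking=stacking,
                apical_to_basal_layers=layers,
                n_embryos=len(rows),
            )
        )
    return out


@dataclass(frozen=True)
class LogRateSeries:
    """Cumulative logarithmic rates of change and their balance residuals.

    ``cumulative[q][i]`` is ln(Q_i / Q_0) for quantity q at stage i.  The
    residuals are the cumulative rates of ln V − ln N − ln v (cell balance)
    and ln V − ln A − ln h (geometry balance).  ``pooled_sd_*`` propagates
    per-stage embryo-level SDs of the log quantities through each balance
    (delta method), when those SDs are supplied.
    """

    stages: tuple[float, ...]
    cumulative: Mapping[str, np.ndarray]
    residual_cell: np.ndarray
    residual_geometry: np.ndarray
    pooled_sd_cell: np.ndarray | None = None
    pooled_sd_geometry: np.ndarray | None = None


_CELL_KEYS = ("tissue_volume", "n_cells", "cell_volume")
_GEOM_KEYS = ("tissue_volume", "tissue_area", "thickness")
_ALL_KEYS = ("tissue_volume", "n_cells", "cell_volume", "tissue_area", "thickness")


def log_rate_decomposition(
    stages: Sequence[float],
    quantities: Mapping[str, Sequence[float]],
    log_sds: Mapping[str, Sequence[float]] | None = None,
) -> LogRateSeries:
    """Cumulative log rates for per-stage means of V, N, v, A, h.

    Parameters
    ----------
    stages:
        Strictly increasing stage values (hpf), ≥ 2.
    quantities:
        Mapping with keys ``tissue_volume``, ``n_cells``, ``cell_volume``,
        ``tissue_area``, ``thickness`` — per-stage positive means.
    log_sds:
        Optional per-stage embryo-level SDs of the *log* quantities, used to
        pool an uncertainty band for each residual.
    """
    stages = tuple(float(s) for s in stages)
    if len(stages) < 2:
        raise ValidationError("need at least 2 stages for rate decomposition")
    if any(b <= a for a, b in zip(stages, stages[1:])):
        raise ValidationError(f"stages must be strictly increasing, got {stages}")
    missing = [k for k in _ALL_KEYS if k not in quantities]
    if missing:
        raise ValidationError(f"missing quantities {missing}")
    arrays: dict[str, np.ndarray] = {}
    for key in _ALL_KEYS:
        q = np.asarray(quantities[key], dtype=float)
        if q.shape != (len(stages),):
            raise ValidationError(f"{key}: expected {len(stages)} per-stage values")
        if np.any(q <= 0):
            raise ValidationError(f"{key}: all values must be positive")
        arrays[key] = np.log(q) - np.log(q[0])
    residual_cell = arrays["tissue_volume"] - arrays["n_cells"] - arrays["cell_volume"]
    residual_geom = arrays["tissue_volume"] - arrays["tissue_area"] - arrays["thickness"]

    pooled_cell = pooled_geom = None
    if log_sds is not None:
        var = {}
        for key in _ALL_KEYS:
            s = np.asarray(log_sds[key], dtype=float)
            var[key] = s**2 + s[0] ** 2  # cumulative rate references stage 0
        pooled_cell = np.sqrt(sum(var[k] for k in _CELL_KEYS))
        pooled_geom = np.sqrt(sum(var[k] for k in _GEOM_KEYS))
    return LogRateSeries(
        stages=stages,
        cumulative=arrays,
        residual_cell=residual_cell,
        residual_geometry=residual_geom,
        pooled_sd_cell=pooled_cell,
        pooled_sd_geometry=pooled_geom,
    )


def decompose_table(table: StageTable, options: AnalysisOptions | None = None) -> LogRateSeries:
    """Log-rate decomposition of a stage table (means and SDs across embryos)."""
    options = options or AnalysisOptions()
    grouped = table.groupby_stage()
    stages = list(grouped)
    means: dict[str, list[float]] = {k: [] for k in _ALL_KEYS}
    sds: dict[str, list[float]] = {k: [] for k in _ALL_KEYS}

    def push(key: str, values: list[float]) -> None:
        logs = np.log(np.asarray(values, dtype=float))
        means[key].append(float(np.exp(np.mean(logs))))
        sds[key].append(float(np.std(logs, ddof=1)) if len(logs) > 1 else 0.0)

    for stage, rows in grouped.items():
        push("tissue_volume", [r.tissue_volume for r in rows])
        push("n_cells", [r.n_cells for r in rows])
        cell_volumes = [
            interphase_cell_volume(r.mitotic_diameters, options.interphase_volume_correction)
            for r in rows
            if r.mitotic_diameters
        ]
        if not cell_volumes:
            raise MissingDataError(f"stage {stage}: no mitotic diameters in any embryo")
        push("cell_volume", cell_volumes)
        push("tissue_area", [0.5 * r.total_surface_area for r in rows])
        push("thickness", [
            corrected_thickness(
                r.thickness_samples, options.thickness_correction, options.thickness_correction_factor
            )
            for r in rows
        ])
    return log_rate_decomposition(stages, means, sds)


@dataclass(frozen=True)
class ExponentialFit:
    """Least-squares exponential growth fit of ln Q against time."""

    rate: float            # 1/h
    doubling_time: float   # h; inf when the rate is not positive (undefined)
    fold_change: float     # exp(rate × span)
    span: float            # h, last − first time
    rate_se: float
    log_intercept: float

    def to_dict(self) -> dict:
        return {
            "rate_per_h": self.rate,
            "doubling_time_h": self.doubling_time,
            "fold_change": self.fold_change,
            "span_h": self.span,
            "rate_se": self.rate_se,
        }


def exponential_growth_fit(times: Sequence[float], volumes: Sequence[float]) -> ExponentialFit:
    """Fit V(t) = V0·exp(rate·t) by least squares on ln V.

    Doubling time is ln 2 / rate (reported as ``inf`` — undefined — for a
    non-positive rate); fold change is exp(rate · span).
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(volumes, dtype=float)
    if t.size < 3:
        raise ValidationError("need at least 3 time points for an exponential fit")
    if np.any(v <= 0):
        raise ValidationError("volumes must be positive")
    res = stats.linregress(t, np.log(v))
    rate = float(res.slope)
    span = float(t.max() - t.min())
    doubling = math.log(2.0) / rate if rate > 0 else math.inf
    return ExponentialFit(
        rate=rate,
        doubling_time=doubling,
        fold_change=math.exp(rate * span),
        span=span,
        rate_se=float(res.stderr) if res.stderr is not None else float("nan"),
        log_intercept=float(res.intercept),
    )


def metrics_frame(metrics: Sequence[DerivedCellMetrics]) -> pd.DataFrame:
    """Tabulate derived metrics (one row per stage)."""
    return pd.DataFrame([m.__dict__ for m in metrics])
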