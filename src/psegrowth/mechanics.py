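"""Tension-balance cell-shape model and coupled tissue trajectories.

A PSE cell is idealized as a truncated cone of apical radius r_a, basal
radius r_b and height h at fixed volume V.  Cortical mechanics enter
through apical and basal line tensions Λ_a, Λ_b acting on the two
perimeters and a lateral surface tension T_l on the slanted face, giving
the energy

    E = 2π r_a Λ_a + 2π r_b Λ_b + T_l · π (r_a + r_b) √(h² + (r_b − r_a)²).

The equilibrium shape minimizes E subject to fixed V, optionally with the
apical-to-basal area ratio held constant (the fitting strategy that keeps
the solver one-dimensional).  Under the cylinder constraint r_a = r_b the
minimizer has the closed form h = (Λ_a + Λ_b)/T_l, independent of V — the
internal oracle for the numerical solver.

Tissue trajectories couple the cell shape to growth: cell volume is tissue
volume over cell number at each time, the tension ratio follows a schedule
(constant before the differentiation transition, ramping to a higher
plateau as actin redistributes in the control; constant throughout for the
hdac1 scenario), and tissue area and aspect ratio follow from the solved
cell shape.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from ._errors import ConvergenceError, ValidationError
from .config import PipelineConfig, Scenario
from .proliferation import GrowthModelParams, simulate_growth_model

__all__ = [
    "TensionParams",
    "CellShape",
    "cone_energy",
    "cell_shape_from_tensions",
    "TensionSchedule",
    "calibrate_schedule",
    "isotropic_schedule",
    "tissue_trajectory",
    "scenario_trajectory",
]


@dataclass(frozen=True)
class TensionParams:
    """Apical/basal line tensions and lateral surface tension (arbitrary units)."""

    lambda_a: float
    lambda_b: float
    t_l: float

    def __post_init__(self) -> None:
        if min(self.lambda_a, self.lambda_b, self.t_l) <= 0:
            raise ValidationError("all tensions must be positive")

    @property
    def ratio(self) -> float:
        """(Λ_a + Λ_b)/T_l — the length scale that sets the cell height."""
        return (self.lambda_a + self.lambda_b) / self.t_l


@dataclass(frozen=True)
class CellShape:
    r_a: float     # μm
    r_b: float     # μm
    h: float       # μm
    volume: float  # μm³
    energy: float

    def __post_init__(self) -> None:
        if min(self.r_a, self.r_b, self.h, self.volume) <= 0:
            raise ValidationError("cell shape dimensions must be positive")
        v = frustum_cell_volume(self.r_a, self.r_b, self.h)
        if abs(v - self.volume) > 1e-9 * self.volume:
            raise ValidationError(
                f"inconsistent shape: frustum volume {v} vs recorded {self.volume}"
            )

    @property
    def mean_cross_section(self) -> float:
        return 0.5 * math.pi * (self.r_a**2 + self.r_b**2)


def frustum_cell_volume(r_a: float, r_b: float, h: float) -> float:
    return math.pi / 3.0 * h * (r_a**2 + r_b**2 + r_a * r_b)


def cone_energy(r_a: float, r_b: float, h: float, tensions: TensionParams) -> float:
    lateral = math.pi * (r_a + r_b) * math.hypot(h, r_b - r_a)
    return (
        2.0 * math.pi * r_a * tensions.lambda_a
        + 2.0 * math.pi * r_b * tensions.lambda_b
        + tensions.t_l * lateral
    )


def cell_shape_from_tensions(
    volume: float,
    tensions: TensionParams,
    area_ratio: float = 1.0,
) -> CellShape:
    """Energy-minimizing truncated cone at fixed volume.

    ``area_ratio`` fixes the apical-to-basal cell area ratio (r_a/r_b)², the
    measured tissue-level constant; 1.0 is the cylinder constraint.  The
    minimization is a bounded scalar search over the basal radius, bracketed
    around the cylinder closed-form scale.
    """
    if volume <= 0:
        raise ValidationError("cell volume must be positive")
    if area_ratio <= 0:
        raise ValidationError("area ratio must be positive")
    s = math.sqrt(area_ratio)  # r_a = s · r_b
    shape_factor = s**2 + s + 1.0  # V = (π/3) h r_b² (s² + s + 1)

    def height(r_b: float) -> float:
        return 3.0 * volume / (math.pi * r_b**2 * shape_factor)

    def objective(r_b: float) -> float:
        return cone_energy(s * r_b, r_b, height(r_b), tensions)

    h_star = tensions.ratio  # cylinder closed form, the right scale generally
    r_star = math.sqrt(3.0 * volume / (math.pi * h_star * shape_factor))
    lo, hi = r_star * 1e-3, r_star * 1e3
    res = optimize.minimize_scalar(
        objective, bounds=(lo, hi), method="bounded",
        options={"xatol": r_star * 1e-12, "maxiter": 500},
    )
    if not res.success:
        raise ConvergenceError(f"cell-shape minimization failed: {res.message}")
    r_b = float(res.x)
    if not lo * 1.01 < r_b < hi * 0.99:
        raise ConvergenceError(
            f"cell-shape minimizer at bracket edge (r_b = {r_b:.3g}, bracket {lo:.3g}–{hi:.3g})"
        )
    r_a = s * r_b
    h = height(r_b)
    return CellShape(r_a=r_a, r_b=r_b, h=h, volume=volume, energy=float(res.fun))


@dataclass(frozen=True)
class TensionSchedule:
    """(Λ_a+Λ_b)/T_l as a function of time.

    Constant at ``ratio_pre`` before the transition, linear ramp of length
    ``ramp_duration`` to ``ratio_post``, constant after.  A constant
    schedule (hdac1: no actin redistribution) has ratio_post = ratio_pre.
    """

    ratio_pre: float
    ratio_post: float
    t_transition: float = 35.5
    ramp_duration: float = 6.0

    def __post_init__(self) -> None:
        if min(self.ratio_pre, self.ratio_post) <= 0:
            raise ValidationError("tension ratios must be positive")
        if self.ramp_duration < 0:
            raise ValidationError("ramp duration must be >= 0")

    def ratio(self, t: float) -> float:
        if t <= self.t_transition or self.ramp_duration == 0:
            return self.ratio_pre if t <= self.t_transition else self.ratio_post
        frac = min(1.0, (t - self.t_transition) / self.ramp_duration)
        return self.ratio_pre + frac * (self.ratio_post - self.ratio_pre)

    @property
    def is_constant(self) -> bool:
        return self.ratio_pre == self.ratio_post


def calibrate_schedule(
    reference_heights: dict[float, float],
    t_transition: float = 35.5,
    ramp_duration: float = 6.0,
) -> TensionSchedule:
    """Invert the cylinder closed form h = (Λ_a+Λ_b)/T_l against references.

    One reference height gives a constant schedule; two give pre/post
    plateaus, with the earlier reference required at or before the
    transition and the later at or after the end of the ramp (heights
    inside the ramp window are not reachable exactly by a two-plateau
    schedule).
    """
    if not reference_heights:
        raise ValidationError("need at least one reference height")
    if any(h <= 0 for h in reference_heights.values()):
        raise ValidationError("reference heights must be positive")
    times = sorted(reference_heights)
    if len(times) == 1:
        h = reference_heights[times[0]]
        return TensionSchedule(h, h, t_transition, ramp_duration)
    if len(times) > 2:
        raise ValidationError("at most two reference heights are supported")
    t0, t1 = times
    if t0 > t_transition:
        raise ValidationError(f"earlier reference ({t0} hpf) must precede the transition")
    if t1 < t_transition + ramp_duration:
        raise ValidationError(
            f"later reference ({t1} hpf) lies inside the ramp; unreachable by a plateau"
        )
    return TensionSchedule(reference_heights[t0], reference_heights[t1],
                           t_transition, ramp_duration)


def isotropic_schedule(
    h_pre: float,
    growth_rate: float,
    t_start: float,
    t_end: float,
    t_transition: float = 35.5,
    ramp_duration: float = 6.0,
) -> TensionSchedule:
    """Control schedule calibrated by the isotropic-scaling condition.

    For a tissue of cylinder-like cells, the aspect ratio h/√A returns to
    its starting value at ``t_end`` when the final height satisfies
    h_end = h_pre · (V(t_end)/V(t_start))^(1/3); the post-transition plateau
    is set to that height.
    """
    h_post = h_pre * math.exp(growth_rate * (t_end - t_start) / 3.0)
    return TensionSchedule(h_pre, h_post, t_transition, ramp_duration)


def tissue_trajectory(
    times: np.ndarray,
    tissue_volumes: np.ndarray,
    n_cells: np.ndarray,
    schedule: TensionSchedule,
    t_l: float = 1.0,
    area_ratio: float = 1.0,
) -> pd.DataFrame:
    """Coupled time series of cell height, cell volume, tissue area and aspect ratio.

    At each time the cell volume is V_tissue/N, the cell shape is solved
    from the scheduled tension ratio (split evenly between Λ_a and Λ_b),
    tissue area is N × the mean cell cross-section, and the tissue aspect
    ratio is h/√area.
    """
    times = np.asarray(times, dtype=float)
    V = np.asarray(tissue_volumes, dtype=float)
    N = np.asarray(n_cells, dtype=float)
    if not (times.shape == V.shape == N.shape):
        raise ValidationError("times, volumes and cell numbers must share a grid")
    if np.any(V <= 0) or np.any(N <= 0):
        raise ValidationError("volumes and cell numbers must be positive")
    records = []
    for t, v_tissue, n in zip(times, V, N):
        ratio = schedule.ratio(float(t))
        tensions = TensionParams(lambda_a=0.5 * ratio * t_l, lambda_b=0.5 * ratio * t_l, t_l=t_l)
        v_cell = v_tissue / n
        shape = cell_shape_from_tensions(v_cell, tensions, area_ratio=area_ratio)
        area = n * shape.mean_cross_section
        records.append(
            {
                "time_hpf": float(t),
                "height_um": shape.h,
                "cell_volume_um3": v_cell,
                "tissue_area_um2": area,
                "aspect_ratio": shape.h / math.sqrt(area),
                "tension_ratio": ratio,
            }
        )
    return pd.DataFrame.from_records(records)


def scenario_trajectory(
    config: PipelineConfig,
    scenario: Scenario | str = Scenario.CONTROL,
    t_start: float | None = None,
    t_end: float = 48.0,
    n_points: int = 57,
) -> pd.DataFrame:
    """Reference trajectory for a scenario under the packaged calibration.

    Tissue volume follows the calibrated exponential growth law; cell number
    follows the mean-field division/differentiation model.  The control
    schedule is calibrated to the pre-transition reference height (the
    30-hpf thickness) and, post transition, to the isotropic-scaling
    condition; hdac1 holds the pre-transition ratio constant (no actin
    redistribution), so the solved height never leaves the 30-hpf value.
    """
    scenario = Scenario(scenario)
    ana = config.analysis
    if t_start is None:
        t_start = ana.t_initial
    base = config.calibration(min(config.stages))
    ref_stage = 30.0 if 30.0 in config.stages else min(config.stages, key=lambda s: abs(s - 30.0))
    h_pre = config.calibration(ref_stage).mean_thickness
    if scenario is Scenario.HDAC1:
        schedule = TensionSchedule(h_pre, h_pre, ana.transition_hpf, ana.ramp_duration_h)
    else:
        schedule = isotropic_schedule(
            h_pre, base.tissue_growth_rate, ana.t_initial, t_end,
            ana.transition_hpf, ana.ramp_duration_h,
        )
    times = np.linspace(t_start, t_end, n_points)
    V0 = base.mean_tissue_volume
    V = V0 * np.exp(base.tissue_growth_rate * (times - ana.t_initial))
    params = GrowthModelParams(
        k=ana.division_rate,
        p=ana.p_progenitor_after,
        alpha=ana.alpha_symmetric,
        t_transition=ana.transition_hpf,
        n0=ana.n_initial,
        t0=ana.t_initial,
    )
    model = simulate_growth_model(params, times)
    traj = tissue_trajectory(times, V, model["total"].to_numpy(), schedule)
    traj["scenario"] = scenario.value
    return traj
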