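"""Cell-cycle statistics and the progenitor division/differentiation model.

Lineage tracks record, per tracked cell, the times of cell rounding (mitosis
entry) and chromosome segregation (mitosis exit) over successive divisions.
Cycle length is the interval between consecutive segregations; mitosis
duration T_M is the rounding-to-segregation interval.  Statistics are binned
by developmental stage, each cycle assigned to the bin containing its
midpoint (bins are stage ± 3 h by default).

The growth model is a two-population mean-field description: progenitors P
divide at a constant rate k (division events per progenitor per hour); each
event yields 2 progenitors with probability p, 2 committed precursors or
neurons with probability (1−p)·α, or one of each with probability
(1−p)(1−α).  Before the neurogenesis transition all divisions are
proliferative (p = 1).  The mean-field equations

    dP/dt   = k (2p − 1) P
    dNeu/dt = k (1 − p) (1 + α) P

have piecewise closed-form solutions, used here; a stochastic agent-based
realization of the same rules (exponential waiting times) is provided as an
independent cross-check of the mean-field maths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._errors import ValidationError
from ._rng import as_rng

__all__ = [
    "LineageTrack",
    "CellCycleStats",
    "cycle_lengths",
    "mitotic_index",
    "GrowthModelParams",
    "simulate_growth_model",
    "simulate_growth_agents",
    "pure_proliferation_count",
    "absolute_neuron_counts",
]

ROUNDING = "rounding"
SEGREGATION = "segregation"


@dataclass
class LineageTrack:
    """One manually tracked cell: time-ordered rounding/segregation events."""

    track_id: str
    events: list[tuple[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        times = [t for _, t in self.events]
        if times != sorted(times):
            raise ValidationError(f"track {self.track_id}: events must be time-ordered")
        kinds = [k for k, _ in self.events]
        if any(k not in (ROUNDING, SEGREGATION) for k in kinds):
            raise ValidationError(f"track {self.track_id}: unknown event kind in {kinds}")
        # rounding and segregation must alternate, starting with either
        for a, b in zip(kinds, kinds[1:]):
            if a == b:
                raise ValidationError(
                    f"track {self.track_id}: consecutive '{a}' events do not alternate"
                )

    def segregation_times(self) -> list[float]:
        return [t for k, t in self.events if k == SEGREGATION]

    def mitosis_durations(self) -> list[tuple[float, float]]:
        """(rounding time, duration) for each complete rounding→segregation pair."""
        out = []
        pending: float | None = None
        for kind, t in self.events:
            if kind == ROUNDING:
                pending = t
            elif pending is not None:
                out.append((pending, t - pending))
                pending = None
        return out


@dataclass(frozen=True)
class CellCycleStats:
    """Cycle statistics for one stage bin (bin midpoint in hpf)."""

    stage_hpf: float
    mean_cycle_length: float   # h
    cycle_cov: float
    mean_mitosis_duration: float  # h (nan when no pairs fall in the bin)
    n_cycles: int
    n_mitoses: int


def _nearest_bin(value: float, centers: Sequence[float], halfwidth: float) -> float | None:
    centers = np.asarray(centers, dtype=float)
    idx = int(np.argmin(np.abs(centers - value)))
    if abs(centers[idx] - value) <= halfwidth:
        return float(centers[idx])
    return None


def cycle_lengths(
    tracks: Iterable[LineageTrack],
    stage_bins: Sequence[float],
    halfwidth: float = 3.0,
) -> list[CellCycleStats]:
    """Bin cycle lengths and mitosis durations by developmental stage.

    A cycle is the interval between consecutive segregations, assigned to the
    bin containing its midpoint; a mitosis duration is assigned to the bin
    containing its rounding time.  Tracks with fewer than two segregations
    contribute mitosis durations only.
    """
    if len(stage_bins) == 0:
        raise ValidationError("stage_bins must be non-empty")
    cycles: dict[float, list[float]] = {float(s): [] for s in stage_bins}
    mitoses: dict[float, list[float]] = {float(s): [] for s in stage_bins}
    for track in tracks:
        segs = track.segregation_times()
        for t0, t1 in zip(segs, segs[1:]):
            bin_ = _nearest_bin(0.5 * (t0 + t1), stage_bins, halfwidth)
            if bin_ is not None:
                cycles[bin_].append(t1 - t0)
        for t_round, dur in track.mitosis_durations():
            bin_ = _nearest_bin(t_round, stage_bins, halfwidth)
            if bin_ is not None:
                mitoses[bin_].append(dur)
    out = []
    for stage in sorted(cycles):
        cyc = np.asarray(cycles[stage], dtype=float)
        mit = np.asarray(mitoses[stage], dtype=float)
        mean = float(np.mean(cyc)) if cyc.size else float("nan")
        cov = float(np.std(cyc, ddof=1) / mean) if cyc.size > 1 and mean > 0 else 0.0
        out.append(
            CellCycleStats(
                stage_hpf=stage,
                mean_cycle_length=mean,
                cycle_cov=cov,
                mean_mitosis_duration=float(np.mean(mit)) if mit.size else float("nan"),
                n_cycles=int(cyc.size),
                n_mitoses=int(mit.size),
            )
        )
    return out


def mitotic_index(n_mitotic: int, n_cells: int) -> float:
    """Fraction of all cells currently in mitosis."""
    if n_cells <= 0:
        raise ValidationError(f"n_cells must be positive, got {n_cells}")
    if not 0 <= n_mitotic <= n_cells:
        raise ValidationError("need 0 <= n_mitotic <= n_cells")
    return n_mitotic / n_cells


@dataclass(frozen=True)
class GrowthModelParams:
    """Parameters of the progenitor division/differentiation model.

    ``k`` is the instantaneous division-event rate per progenitor (1/h);
    ``p`` the post-transition probability that a division yields two
    progenitors; ``alpha`` the probability that a differentiative division
    is symmetric (both daughters committed).  Before ``t_transition`` every
    division is proliferative.  Defaults: k = 0.11/h, 35% differentiating
    divisions (p = 0.65) after 35 hpf, alpha = 1, 2,177 cells at 20 hpf.
    """

    k: float = 0.11
    p: float = 0.65
    alpha: float = 1.0
    t_transition: float = 35.0
    n0: float = 2177.0
    t0: float = 20.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0 and 0.0 <= self.alpha <= 1.0):
            raise ValidationError("p and alpha must lie in [0, 1]")
        if self.k < 0:
            raise ValidationError("division rate k must be >= 0")
        if self.n0 <= 0:
            raise ValidationError("initial cell count must be positive")


def _advance(P: float, Neu: float, p: float, alpha: float, k: float, dt: float) -> tuple[float, float]:
    """Closed-form advance of (P, Neu) over dt at fixed fate probabilities."""
    g = k * (2.0 * p - 1.0)
    c = k * (1.0 - p) * (1.0 + alpha)
    if abs(g) > 1e-300:
        P1 = P * np.exp(g * dt)
        Neu1 = Neu + (c / g) * (P1 - P)
    else:  # p = 1/2: progenitor pool constant, neurons accrue linearly
        P1 = P
        Neu1 = Neu + c * P * dt
    return float(P1), float(Neu1)


def simulate_growth_model(params: GrowthModelParams, t_grid: Sequence[float]) -> pd.DataFrame:
    """Deterministic mean-field trajectories P(t), Neu(t), Total(t).

    Piecewise closed form: exponential progenitor growth at rate k before the
    transition (p = 1), then rate k(2p−1) with neurons accumulating in
    proportion.  Returns a DataFrame with columns ``time_hpf``,
    ``progenitors``, ``neurons``, ``total``.
    """
    t = np.asarray(t_grid, dtype=float)
    if np.any(t < params.t0):
        raise ValidationError(f"t_grid must start at or after t0 = {params.t0}")
    P_out = np.empty_like(t)
    N_out = np.empty_like(t)
    for i, ti in enumerate(t):
        P, Neu = params.n0, 0.0
        t_pre_end = min(ti, params.t_transition)
        if t_pre_end > params.t0:
            P, Neu = _advance(P, Neu, 1.0, params.alpha, params.k, t_pre_end - params.t0)
        if ti > params.t_transition:
            start = max(params.t0, params.t_transition)
            P, Neu = _advance(P, Neu, params.p, params.alpha, params.k, ti - start)
        P_out[i], N_out[i] = P, Neu
    return pd.DataFrame(
        {"time_hpf": t, "progenitors": P_out, "neurons": N_out, "total": P_out + N_out}
    )


def simulate_growth_agents(
    params: GrowthModelParams,
    t_end: float,
    seed_or_rng,
    n0: int | None = None,
) -> tuple[int, int]:
    """Stochastic (Gillespie) realization of the division/differentiation rules.

    Exponential waiting times between division events at total rate k·P; each
    event resolves fates by the (p, alpha) probabilities in force at the
    event time.  Returns final (progenitors, neurons).  This validates the
    mean-field solution, not the gamma-shaped cycle-length distribution.
    """
    rng = as_rng(seed_or_rng)
    P = int(n0 if n0 is not None else round(params.n0))
    Neu = 0
    t = params.t0
    while P > 0:
        t += rng.exponential(1.0 / (params.k * P))
        if t >= t_end:
            break
        if t < params.t_transition:
            P += 1  # proliferative: 1 progenitor -> 2 progenitors
        else:
            u = rng.random()
            if u < params.p:
                P += 1
            elif u < params.p + (1.0 - params.p) * params.alpha:
                P -= 1
                Neu += 2
            else:
                Neu += 1
    return P, Neu


def pure_proliferation_count(n0: float, k: float, dt: float) -> float:
    """Counterfactual count if every cell kept dividing at rate k: n0·exp(k·Δt)."""
    if dt < 0:
        raise ValidationError("time interval must be non-negative")
    return float(n0 * np.exp(k * dt))


def absolute_neuron_counts(
    relative_fractions: Mapping[str, float], total_cells: float
) -> dict[str, float]:
    """Convert relative neuronal-subtype fractions to absolute counts."""
    fractions = {k: float(v) for k, v in relative_fractions.items()}
    if any(not 0.0 <= f <= 1.0 for f in fractions.values()):
        raise ValidationError("fractions must lie in [0, 1]")
    if sum(fractions.values()) > 1.0 + 1e-12:
        raise ValidationError(f"fractions sum to {sum(fractions.values()):.4f} > 1")
    return {k: f * total_cells for k, f in fractions.items()}
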