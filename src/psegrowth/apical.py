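"""Spatial statistics on the curved apical surface of the retinal cup.

All mitoses in a pseudostratified epithelium occur at the apical surface.
To ask whether proliferation is spatially uniform, 3D mitotic coordinates
are referred to a fitted sphere, expressed in polar coordinates about a
projection pole, and flattened with the Lambert azimuthal equal-area
projection ρ = 2R·sin(θ/2) — equal areas of the spherical surface map to
equal areas of the plane, so planar point density is a faithful surface
density.  Division orientations in the epithelial plane are axial data
(period π) and are tested for uniformity with a Rayleigh test on doubled
angles.

The mitotic-frustum analysis asks whether apical surface availability
limits proliferation ("proliferative trap"): the truncated-cone tissue unit
beneath one rounded mitotic cell can hold a measured number of nuclei
(tissue cell density × frustum volume), while cell-cycle timing caps the
sustainable number at (T_CC − T_M)/T_M; a trap exists only when the
measured number exceeds that capacity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage, stats

from ._errors import MissingDataError, ValidationError

__all__ = [
    "MitoticPointSet",
    "SphereFit",
    "fit_sphere",
    "project_equal_area",
    "HeatmapGrid",
    "density_heatmap",
    "division_angle_stats",
    "rayleigh_test",
    "apical_occupancy",
    "frustum_volume",
    "FrustumParams",
    "TrapResult",
    "trap_analysis",
    "annulus_uniformity",
]


@dataclass
class MitoticPointSet:
    """3D Cartesian coordinates (μm) of mitotic events for one sample."""

    points: np.ndarray  # (n, 3)
    embryo_id: str | None = None
    stage_hpf: float | None = None

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.size == 0:
            self.points = self.points.reshape(0, 3)
        if self.points.shape[1] != 3:
            raise ValidationError(f"points must be (n, 3), got {self.points.shape}")
        if not np.all(np.isfinite(self.points)):
            raise ValidationError("points must be finite")

    def __len__(self) -> int:
        return self.points.shape[0]


@dataclass(frozen=True)
class SphereFit:
    center: np.ndarray  # (3,)
    radius: float
    rms_residual: float


def fit_sphere(points: np.ndarray | MitoticPointSet) -> SphereFit:
    """Algebraic linear least-squares sphere fit.

    Solves ``|x|² = 2 c·x + (r² − |c|²)`` for center c and radius r; needs at
    least 4 points not lying on a common plane.
    """
    pts = points.points if isinstance(points, MitoticPointSet) else np.asarray(points, float)
    if pts.shape[0] < 4:
        raise ValidationError("sphere fit needs at least 4 points")
    A = np.column_stack([2.0 * pts, np.ones(len(pts))])
    b = np.sum(pts**2, axis=1)
    sol, _, rank, sv = np.linalg.lstsq(A, b, rcond=None)
    if rank < 4 or sv[-1] < 1e-9 * sv[0]:
        raise ValidationError("degenerate point configuration (coplanar or collinear)")
    center = sol[:3]
    r_sq = sol[3] + center @ center
    if r_sq <= 0:
        raise ValidationError("sphere fit produced a non-positive radius")
    radius = math.sqrt(r_sq)
    residuals = np.linalg.norm(pts - center, axis=1) - radius
    return SphereFit(center=center, radius=radius, rms_residual=float(np.sqrt(np.mean(residuals**2))))


def _orthonormal_basis(pole: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic in-plane basis perpendicular to the pole."""
    helper = np.zeros(3)
    helper[int(np.argmin(np.abs(pole)))] = 1.0
    e1 = np.cross(pole, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(pole, e1)
    return e1, e2


def project_equal_area(
    points: np.ndarray | MitoticPointSet,
    fit: SphereFit,
    pole: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Lambert azimuthal equal-area projection of points about a fitted sphere.

    Points are expressed as (colatitude θ from the pole, azimuth φ) and
    mapped to ρ = 2R·sin(θ/2), (ρ·cosφ, ρ·sinφ).  The default pole is the
    unit vector from the sphere center through the centroid of the points.
    Returns (xy, antipodal_mask); points at θ = π land on the boundary
    circle ρ = 2R and are flagged.
    """
    pts = points.points if isinstance(points, MitoticPointSet) else np.asarray(points, float)
    if pts.size == 0:
        return np.zeros((0, 2)), np.zeros(0, dtype=bool)
    d = pts - fit.center
    norms = np.linalg.norm(d, axis=1)
    if np.any(norms == 0):
        raise ValidationError("a point coincides with the sphere center")
    u = d / norms[:, None]
    if pole is None:
        centroid = np.mean(u, axis=0)
        n = np.linalg.norm(centroid)
        if n < 1e-12:
            raise ValidationError("points have no mean direction; supply a pole explicitly")
        pole = centroid / n
    else:
        pole = np.asarray(pole, dtype=float)
        n = np.linalg.norm(pole)
        if not math.isclose(n, 1.0, rel_tol=1e-6):
            raise ValidationError("pole must be a unit vector")
        pole = pole / n
    e1, e2 = _orthonormal_basis(pole)
    cos_theta = np.clip(u @ pole, -1.0, 1.0)
    theta = np.arccos(cos_theta)
    phi = np.arctan2(u @ e2, u @ e1)
    rho = 2.0 * fit.radius * np.sin(theta / 2.0)
    xy = np.column_stack([rho * np.cos(phi), rho * np.sin(phi)])
    antipodal = theta >= math.pi - 1e-9
    return xy, antipodal


@dataclass
class HeatmapGrid:
    """Binned planar density (events per unit projected area)."""

    density: np.ndarray      # (nx, ny)
    x_edges: np.ndarray
    y_edges: np.ndarray
    smooth_bandwidth: float = 0.0

    @property
    def bin_area(self) -> float:
        return float((self.x_edges[1] - self.x_edges[0]) * (self.y_edges[1] - self.y_edges[0]))

    def total_mass(self) -> float:
        """Σ density × bin area; equals the point count for unsmoothed grids."""
        return float(np.sum(self.density) * self.bin_area)


def density_heatmap(
    xy: np.ndarray,
    bins: int = 64,
    extent: tuple[float, float, float, float] | None = None,
    smooth_bandwidth: float = 0.0,
) -> HeatmapGrid:
    """2D density heatmap of projected mitotic positions.

    ``smooth_bandwidth`` (same units as the coordinates) applies Gaussian
    smoothing; mass is conserved exactly when unsmoothed and up to boundary
    truncation when smoothed.
    """
    xy = np.atleast_2d(np.asarray(xy, dtype=float)) if np.size(xy) else np.zeros((0, 2))
    if extent is None:
        if len(xy) == 0:
            extent = (-1.0, 1.0, -1.0, 1.0)
        else:
            lim = float(np.max(np.abs(xy))) * 1.05 + 1e-9
            extent = (-lim, lim, -lim, lim)
    x_edges = np.linspace(extent[0], extent[1], bins + 1)
    y_edges = np.linspace(extent[2], extent[3], bins + 1)
    counts, _, _ = np.histogram2d(xy[:, 0], xy[:, 1], bins=[x_edges, y_edges])
    bin_area = (x_edges[1] - x_edges[0]) * (y_edges[1] - y_edges[0])
    density = counts / bin_area
    if smooth_bandwidth > 0:
        sigma_bins = smooth_bandwidth / (x_edges[1] - x_edges[0])
        density = ndimage.gaussian_filter(density, sigma=sigma_bins, mode="constant")
    return HeatmapGrid(density=density, x_edges=x_edges, y_edges=y_edges,
                       smooth_bandwidth=smooth_bandwidth)


def rayleigh_test(angles: Sequence[float]) -> tuple[float, float]:
    """Rayleigh uniformity test for circular data (radians, period 2π).

    Returns (resultant length R, p-value) using the standard finite-n
    approximation of the null distribution.
    """
    a = np.asarray(angles, dtype=float)
    n = a.size
    if n == 0:
        raise ValidationError("no angles supplied")
    C, S = np.sum(np.cos(a)), np.sum(np.sin(a))
    R = math.hypot(C, S) / n
    z = n * R**2
    p = math.exp(math.sqrt(1.0 + 4.0 * n + 4.0 * (n**2 - (R * n) ** 2)) - (1.0 + 2.0 * n))
    return R, min(p, 1.0)


@dataclass(frozen=True)
class DivisionAngleStats:
    sector_edges: np.ndarray   # radians on [0, π), axial convention
    sector_counts: np.ndarray
    resultant_length: float    # of doubled angles
    p_uniform: float


def division_angle_stats(angles: Sequence[float], sector_width_deg: float = 10.0) -> DivisionAngleStats:
    """Rose counts and uniformity test for in-plane division angles.

    A division axis has no sign, so angles are axial (period π): antipodal
    directions are identified, and the Rayleigh test is applied to doubled
    angles.
    """
    a = np.mod(np.asarray(angles, dtype=float), math.pi)
    if a.size == 0:
        raise ValidationError("no angles supplied")
    width = math.radians(sector_width_deg)
    n_sectors = max(1, int(round(math.pi / width)))
    edges = np.linspace(0.0, math.pi, n_sectors + 1)
    counts, _ = np.histogram(a, bins=edges)
    R, p = rayleigh_test(2.0 * a)
    return DivisionAngleStats(sector_edges=edges, sector_counts=counts,
                              resultant_length=R, p_uniform=p)


def apical_occupancy(
    mitotic_diameters: Sequence[float], n_mitotic: int, apical_area: float
) -> float:
    """Fraction of the apical surface occupied by rounded mitotic cells.

    Each mitotic cell presents a circular cross-section at its widest
    diameter; the occupied area is n_mitotic · π(d̄/2)² with d̄ the mean
    measured diameter, divided by the tissue-wide 3D apical surface area.
    """
    if apical_area <= 0:
        raise ValidationError("apical_area must be positive")
    if n_mitotic < 0:
        raise ValidationError("n_mitotic must be >= 0")
    if n_mitotic == 0:
        return 0.0
    if len(mitotic_diameters) == 0:
        raise MissingDataError("no mitotic diameters measured")
    d_mean = float(np.mean(np.asarray(mitotic_diameters, dtype=float)))
    return n_mitotic * math.pi * (d_mean / 2.0) ** 2 / apical_area


def frustum_volume(h: float, R: float, r: float) -> float:
    """Volume of a truncated cone: (π/3)·h·(R² + r² + R·r)."""
    if h <= 0:
        raise ValidationError("frustum height must be positive")
    if not 0 <= r <= R:
        raise ValidationError(f"need 0 <= r <= R, got r={r}, R={R}")
    return math.pi / 3.0 * h * (R**2 + r**2 + R * r)


@dataclass(frozen=True)
class FrustumParams:
    """Geometry and timing of one mitotic frustum.

    ``R`` is the mitotic-cell radius at the apical (large) base; ``r`` the
    basal (small) base radius — the large base *area* shrunk by the
    apical-to-basal tissue area ratio, i.e. r = R/√ratio; ``h`` the tissue
    height; ``cell_density`` in cells/μm³; cycle times in hours.
    """

    h: float
    R: float
    r: float
    cell_density: float
    t_cc: float
    t_m: float

    def __post_init__(self) -> None:
        if not (self.t_cc > self.t_m > 0):
            raise ValidationError("need T_CC > T_M > 0")
        if self.cell_density <= 0:
            raise ValidationError("cell density must be positive")

    @classmethod
    def from_tissue(
        cls,
        thickness: float,
        mitotic_diameter: float,
        apical_to_basal_area_ratio: float,
        cell_density: float,
        t_cc: float,
        t_m: float,
    ) -> "FrustumParams":
        R = mitotic_diameter / 2.0
        return cls(
            h=thickness,
            R=R,
            r=R / math.sqrt(apical_to_basal_area_ratio),
            cell_density=cell_density,
            t_cc=t_cc,
            t_m=t_m,
        )


@dataclass(frozen=True)
class TrapResult:
    n_measured: float   # cells in the frustum (density × volume)
    n_max: float        # (T_CC − T_M) / T_M
    trap: bool          # measured strictly exceeds capacity
    at_capacity: bool   # boundary equality (within float tolerance)


def trap_analysis(f: FrustumParams) -> TrapResult:
    """Proliferative-trap test for one frustum.

    Apical mitoses exclude each other in time: while one cell occupies the
    apical spot for T_M, the others must fit their interphases in, so
    (T_CC − T_M) ≥ T_M · N caps the sustainable nuclei at
    N_max = (T_CC − T_M)/T_M.  A trap exists only when the measured count
    strictly exceeds N_max; equality is reported as "at capacity".
    """
    volume = frustum_volume(f.h, f.R, f.r)
    n_measured = f.cell_density * volume
    n_max = (f.t_cc - f.t_m) / f.t_m
    at_capacity = math.isclose(n_measured, n_max, rel_tol=1e-12, abs_tol=1e-12)
    return TrapResult(
        n_measured=n_measured,
        n_max=n_max,
        trap=bool(n_measured > n_max and not at_capacity),
        at_capacity=at_capacity,
    )


def annulus_uniformity(
    xy: np.ndarray, max_radius: float, n_annuli: int = 8
) -> tuple[float, float]:
    """Chi-square test of uniform planar density over equal-area annuli.

    Because the projection preserves area, a uniform surface density maps to
    a uniform planar density; equal-area annuli about the pole then carry
    equal expected counts.  Returns (chi² statistic, p-value).
    """
    xy = np.atleast_2d(np.asarray(xy, dtype=float))
    if len(xy) < n_annuli:
        raise ValidationError("too few points for the annulus test")
    rho = np.hypot(xy[:, 0], xy[:, 1])
    edges = max_radius * np.sqrt(np.linspace(0.0, 1.0, n_annuli + 1))  # equal areas
    counts, _ = np.histogram(np.clip(rho, 0, max_radius), bins=edges)
    chi2, p = stats.chisquare(counts)
    return float(chi2), float(p)
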