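# Methods

This note documents the models, estimators and numerical choices behind
`psegrowth`, and what the synthetic-retina generator does and does not
emulate.

## The system and the questions

The zebrafish retinal neuroepithelium is a curved pseudostratified
epithelium (PSE): a single cell layer whose nuclei occupy many apicobasal
positions, with all mitoses at the apical surface.  Between 20 and 48 hours
post fertilization (hpf) it grows several-fold in volume while keeping its
cup shape — isotropic scaling.  The package decomposes that growth into
cell-level contributions and asks four quantitative questions:

1. How do tissue volume V, cell number N, cell volume v, tissue area A and
   height h co-vary?  (log-rate balance: V = N·v and V = A·h)
2. Is proliferation spatially uniform and unconstrained by apical crowding?
   (equal-area density maps; the mitotic-frustum "proliferative trap" test)
3. What sets the basal nuclear exclusion zone?  (apicobasal actin/nuclear
   intensity profiles and their negative correlation)
4. Can a minimal tension balance explain timely cell elongation and shape
   maintenance, and its failure when actin does not redistribute (hdac1)?

## Growth decomposition

Cell volume is estimated from rounded mitotic cells, which are nearly
spherical: v = 0.9 · mean((π/6)d³) over measured diameters d, where the
0.9 corrects for mitotic cells being ~10% larger than interphase cells.
Mean cell cross-section is the average of the apical and basal per-cell
endfoot areas (basal tissue area = total segmented area − apical area).
Thickness is the mean of 5 sampled positions, decreased by 5% to
compensate the thinner ciliary marginal zone rim (toggleable).  Aspect
ratio is height/√area at cell or tissue scale; constancy of the tissue
ratio is the operational definition of isotropy.  Nuclear stacking is the
nuclear-zone height divided by the mean nuclear long axis, unrounded.

Cumulative logarithmic rates ln(Q_i/Q_0) are computed from per-stage
geometric means; the two balance residuals are exactly zero on
algebraically consistent inputs and are compared against a pooled
embryo-level SD (delta method on the per-stage SDs of the log quantities,
the scale at which the source data plot mean ± SD).

## Calibration of the synthetic generator

The packaged calibration (six stages: 20, 24, 30, 36, 42, 48 hpf)
transcribes the published stage anchors: 2,177 → 18,000 cells, 440 → 140
μm³ cell volumes (both interpolated exponentially), thickness 48 → 63 μm,
cell-cycle means 8.5 → 5.3 h with falling CoV, constant mitosis duration
T_M = 0.42 h (25 min), basal actin extents 28/27/26/20/8/5% of the axis,
and nuclear stacking rising from ~2.8 to 5.5 nuclei between 36 and 42 hpf
(nuclear long axis 11 μm).  Mean tissue volume is defined as
N·v (implied growth rate 0.0345/h), so the volumetric balance holds exactly
at the calibration means.  The published endpoint summaries for tissue
volume (≈4.4-fold, 0.055/h), cell count (8-fold) and cell volume
(0.32-fold) are mutually inconsistent as printed (8 × 0.32 ≈ 2.6-fold);
this package resolves the conflict in favour of the balance identity, which
the rest of the analysis depends on, and keeps 0.055/h for the analytic
doubling-time arithmetic.

Mitotic index per stage (1.2–2.2%, peaking at 36 hpf) is on the
phospho-histone-3 scale and is chosen jointly consistent with the measured
bound that mitotic cells never occupy more than 20% of the apical surface,
given the anchored counts, cell sizes and areas.  The apical-to-basal
tissue area ratio is the constant 3.0 implied by strong cup curvature.

Noise model (embryo-level CVs are calibration choices; the source reports
only stage-level scatter): tissue volume is lognormal, mean·exp(N(0, cv))
with cv 0.12; thickness, diameters and nuclear sizes are truncated normal
(cv 3–8%); counts are Poisson about a lognormal mean (cv 0.08) with
mitoses binomial; surface areas derive from each embryo's own volume and
thickness (so V = A·h holds per embryo up to 3% area noise) and are split
by the area ratio.  In the zero-noise limit every draw equals its
calibration exactly; count draws switch from Poisson/binomial to rounded
means so the limit holds for integers too.

Scenarios: `hdac1` freezes the actin extent at the 30-hpf value, caps
thickness at 55 μm, and leaves proliferation untouched; `rockout` abolishes
the basal actin pool after the 30-hpf onset and reduces the mitotic index
to 4% of control (the residual activity under ROCK inhibition) with the
cell count frozen; `hua` blocks proliferation after onset with control-like
actin.

What the generator does **not** emulate: spatial correlations within one
retina (embryos are i.i.d. draws), interkinetic nuclear migration dynamics,
deviations of the apical surface from a spherical cap, segmentation bias,
and any coupling between mitotic index and cell-cycle length.  Passing
recovery tests therefore demonstrates estimator correctness under the
declared statistical structure, not robustness to real-microscopy artifacts.

## Cell-cycle statistics and the growth model

Tracks carry rounding (mitosis entry) and segregation (mitosis exit)
events.  Cycle length is the inter-segregation interval, assigned to the
stage bin containing its midpoint (bins: stage ± 3 h); T_M is the
rounding-to-segregation interval, binned by rounding time.  Generator
cycles are gamma(mean, CV) — positive support and exactly the two reported
moments — with the first cycle centred on the stage ± 2 h, matching the
midpoint-labelling convention and keeping the bin estimator unbiased.

The growth model is mean-field: progenitors P divide at constant rate
k = 0.11/h (division events per progenitor per hour — the only reading
that reproduces the ≈47,000-cell counterfactual from 2,177 cells over
28 h).  Before t = 35 hpf all divisions are proliferative; after, a
division yields 2 progenitors w.p. p = 0.65, 2 committed cells w.p.
(1−p)α with α = 1, else one of each.  The ODEs dP/dt = k(2p−1)P,
dNeu/dt = k(1−p)(1+α)P are solved piecewise in closed form; a Gillespie
realization of the same rules (exponential waiting times — it validates
the mean-field maths, not the gamma cycle-length shape) is the
cross-check.  With these printed parameters the model reaches ≈32,000
cells at 48 hpf, above the measured ≈18,000; the discrepancy is a known
limitation of the constant-k reading, and stage-varying rates can be
passed explicitly where needed.

## Apical-surface statistics

The reference sphere is an algebraic linear least-squares fit
(|x|² = 2c·x + const).  Points are expressed as (colatitude θ, azimuth φ)
about a pole — by default the unit vector from the fitted center through
the point centroid — and flattened with the Lambert azimuthal equal-area
projection ρ = 2R sin(θ/2), whose Jacobian makes planar density a faithful
surface density (patch areas map as R²·solid angle, exactly).  Heatmaps
are normalized per unit projected area; Σ density × bin area equals the
point count exactly when unsmoothed.  Uniformity is tested by chi-square
over equal-area annuli.  Division axes are axial data (period π): the
Rayleigh test runs on doubled angles, with the standard finite-n p-value
approximation.

The frustum test uses the truncated-cone volume (π/3)h(R² + r² + Rr) with
R the mean mitotic radius and r = R/√(area ratio) (the large base *area*
shrunk by the apical-to-basal tissue area ratio).  Measured nuclei per
frustum = tissue cell density × frustum volume; the timing capacity is
N_max = (T_CC − T_M)/T_M.  A trap requires strictly more than capacity;
equality is reported "at capacity".

## Intensity profiles

Profiles are min-max normalized and linearly resampled to a fixed 101-point
grid (0 = apical).  The basal-zone rule: lateral baseline = median over
[0.15, 0.5] of the axis (clear of the apical belt and of plateaus up to
~0.6 extent); plateau level = median over the most basal 2%; boundary =
linearly interpolated half-height crossing of the contiguous basal
super-threshold run; extent = 1 − boundary; a plateau rise below 0.05
normalized units is "absent".  The narrow basal window makes detection
exact for any plateau extent down to 2% of the axis on clean profiles,
which a wider window cannot achieve; under the calibrated noise (sd 0.05,
9 profiles averaged) extents are recovered within ±2 points.  Cortical
ratios take local maxima with prominence ≥ 10% of the region's intensity
range as the cortical signal and compare mean peak heights; small-n group
comparisons use the exact rank-sum test.

## Mechanics

The cell is a truncated cone at fixed volume with energy
E = 2π r_a Λ_a + 2π r_b Λ_b + T_l·π(r_a+r_b)√(h² + (r_b−r_a)²) — line
tensions on the apical and basal perimeters, surface tension on the
lateral face; this is the minimal functional consistent with that tension
assignment (no pressure or apical/basal surface-tension terms).  The
apical-to-basal cell area ratio is imposed as a constraint (it is measured
to be constant), keeping the solver one-dimensional: bounded scalar
minimization over r_b, bracketed around the cylinder scale, xatol 10⁻¹²
relative.  Under the cylinder constraint the closed form
h = (Λ_a + Λ_b)/T_l (independent of V) is the internal oracle; the solver
matches it to better than 10⁻⁶ relative.

Tissue trajectories: v_cell(t) = V(t)/N(t) with V the calibrated
exponential law and N the mean-field model; the tension ratio follows a
schedule — constant before the 35.5-hpf transition, 6-h linear ramp to a
plateau after (control), constant throughout (hdac1).  The control
pre-transition ratio is calibrated to the 30-hpf reference height (55 μm);
the post-transition plateau is set by the isotropic-scaling condition
h_end = h_pre·(V_end/V_start)^{1/3}, so the endpoint aspect-ratio drift
over 20–48 hpf is zero by construction and the reported "drift" statistic
is the net endpoint change.  A transient aspect-ratio dip before the
transition is intrinsic to any constant-height phase under exponential
growth and is visible in the measured series too.  The hdac1 schedule
pins the solved height at 55 μm while area keeps growing, so the tissue
aspect ratio strictly decreases — the mutant phenotype.

## Numerical conventions and degenerate inputs

Stage grouping rounds hpf to 0.1 h.  Unknown config keys are hard errors.
Doubling time for a non-positive fitted rate is reported as infinity.
Empty diameter lists raise a missing-data error except in
`apical_occupancy` with zero mitoses (occupancy 0).  A constant intensity
profile has no defined normalization and raises.  Sphere fits reject
coplanar configurations via the smallest singular value.  All randomness
flows from a single seed through named child streams (stable hash of the
stream name), so one module's draw count cannot shift another's.

## Problem sizes

Default analyses use 10 embryos/stage, 254 tracks for cycle recovery, 9
profiles per zone call, 5 samples/stage for cortical ratios, ~10³–10⁴
points for projection/heatmap checks and 57 time points for trajectories —
the scale of the source study, and enough for every recovery target's
standard error to sit well inside its tolerance.
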