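# Reference calibration for the synthetic retina generator: six stages of
# proliferative growth of the zebrafish retinal pseudostratified epithelium.
#
# Stage means transcribe the wild-type growth series: cell counts 2,177 -> 18,000
# (8-fold), interphase cell volumes 440 -> 140 um^3, thickness 48 -> 63 um,
# cell-cycle means 8.5 -> 5.3 h, basolateral actin extent 28% -> 5% of the axis.
# Counts and cell volumes are interpolated exponentially between the anchored
# endpoints; mean tissue volume is their product, so the volumetric balance
# V = N * v holds exactly at the calibration means (implied tissue growth rate
# 0.03455/h).  Mean mitotic diameter is the sphere diameter whose volume, after
# the 10% mitotic-inflation correction, equals the interphase cell volume.
#
# Embryo-level CVs (volume_cv, thickness_cv, count_cv, diameter_cv,
# area_noise_cv, nuclear_size_cv, profile_noise_sd) are calibration choices:
# the source measurements report only stage-level scatter, and 3-15% is the
# scale that scatter implies for 10 embryos/stage.

seed: 0

stages: [20.0, 24.0, 30.0, 36.0, 42.0, 48.0]

analysis:
  thickness_correction: true
  thickness_correction_factor: 0.95
  interphase_volume_correction: 0.9
  heatmap_bins: 64
  heatmap_smooth_bandwidth: 0.0
  sector_width_deg: 10.0
  stage_bin_halfwidth: 3.0
  hdac1_thickness_cap: 55.0
  perturbation_onset_hpf: 30.0
  transition_hpf: 35.5
  ramp_duration_h: 6.0
  division_rate: 0.11
  p_progenitor_after: 0.65
  alpha_symmetric: 1.0
  n_initial: 2177.0
  t_initial: 20.0

calibrations:
  20.0:
    mean_cells: 2177.0
    mean_cell_volume: 440.0
    mean_tissue_volume: 957880.0
    tissue_growth_rate: 0.034546
    mean_thickness: 48.0
    apical_to_basal_area_ratio: 3.0
    mitotic_index: 0.012
    mean_mitotic_diameter: 9.774
    cell_cycle_mean: 8.5
    cell_cycle_cv: 0.30
    mitosis_duration: 0.42
    actin_basal_extent_fraction: 0.28
    nuclear_zone_height: 30.0
    nuclear_long_axis: 11.0
    basal_lateral_ratio: 1.0
    apical_lateral_ratio: 1.1
  24.0:
    mean_cells: 2944.0
    mean_cell_volume: 373.60
    mean_tissue_volume: 1099878.0
    tissue_growth_rate: 0.034546
    mean_thickness: 50.0
    apical_to_basal_area_ratio: 3.0
    mitotic_index: 0.014
    mean_mitotic_diameter: 9.255
    cell_cycle_mean: 8.0
    cell_cycle_cv: 0.28
    mitosis_duration: 0.42
    actin_basal_extent_fraction: 0.27
    nuclear_zone_height: 30.5
    nuclear_long_axis: 11.0
    basal_lateral_ratio: 1.1
    apical_lateral_ratio: 1.15
  30.0:
    mean_cells: 4629.0
    mean_cell_volume: 292.31
    mean_tissue_volume: 1353103.0
    tissue_growth_rate: 0.034546
    mean_thickness: 55.0
    apical_to_basal_area_ratio: 3.0
    mitotic_index: 0.016
    mean_mitotic_diameter: 8.528
    cell_cycle_mean: 7.3
    cell_cycle_cv: 0.26
    mitosis_duration: 0.42
    actin_basal_extent_fraction: 0.26
    nuclear_zone_height: 31.0
    nuclear_long_axis: 11.0
    basal_lateral_ratio: 1.2
    apical_lateral_ratio: 1.2
  36.0:
    mean_cells: 7280.0
    mean_cell_volume: 228.71
    mean_tissue_volume: 1665009.0
    tissue_growth_rate: 0.034546
    mean_thickness: 56.0
    apical_to_basal_area_ratio: 3.0
    mitotic_index: 0.022
    mean_mitotic_diameter: 7.858
    cell_cycle_mean: 6.3
    cell_cycle_cv: 0.22
    mitosis_duration: 0.42
    actin_basal_extent_fraction: 0.20
    nuclear_zone_height: 30.8
    nuclear_long_axis: 11.0
    basal_lateral_ratio: 1.45
    apical_lateral_ratio: 1.3
  42.0:
    mean_cells: 11447.0
    mean_cell_volume: 178.94
    mean_tissue_volume: 2048326.0
    tissue_growth_rate: 0.034546
    mean_thickness: 61.0
    apical_to_basal_area_ratio: 3.0
    mitotic_index: 0.019
    mean_mitotic_diameter: 7.241
    cell_cycle_mean: 5.3
    cell_cycle_cv: 0.16
    mitosis_duration: 0.42
    actin_basal_extent_fraction: 0.08
    nuclear_zone_height: 60.5
    nuclear_long_axis: 11.0
    basal_lateral_ratio: 1.8
    apical_lateral_ratio: 1.45
  48.0:
    mean_cells: 18000.0
    mean_cell_volume: 140.0
    mean_tissue_volume: 2520000.0
    tissue_growth_rate: 0.034546
    mean_thickness: 63.0
    apical_to_basal_area_ratio: 3.0
    mitotic_index: 0.013
    mean_mitotic_diameter: 6.672
    cell_cycle_mean: 5.3
    cell_cycle_cv: 0.15
    mitosis_duration: 0.42
    actin_basal_extent_fraction: 0.05
    nuclear_zone_height: 62.0
    nuclear_long_axis: 11.0
    basal_lateral_ratio: 2.0
    apical_lateral_ratio: 1.5
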