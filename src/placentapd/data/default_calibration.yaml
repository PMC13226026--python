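# Default study calibration: a three-arm L-NAME rat preeclampsia study with
# mid-gestation pravastatin rescue, monitored systemically at GD7/10/13/18 and
# by placental imaging at GD14/16/18.
#
# Provenance of numbers
# ---------------------
#   * Disease- and treated-arm anchors (GD18 group means) and trajectory slopes
#     for the systemic markers, and all six trajectory slopes, are the printed
#     endpoint summaries of the emulated study (mean +/- SEM, n = 8/group).
#   * `anchor_from_fri` marks a RECONSTRUCTED anchor: healthy-control values are
#     not printed anywhere, so control anchors for SBP/protein are recovered by
#     inverting the Functional Recovery Index
#         FRI = 100 * (X_treated - X_disease) / (X_control - X_disease),
#     and treated anchors for the imaging markers are recovered from the printed
#     FRI given free-choice control/disease anchors.  Control/disease imaging
#     anchors and all control slopes are free physiological defaults, not facts.
#   * Dispersions: printed SEMs are converted to SDs with sqrt(8).  The SD is
#     partitioned into a between-dam intercept SD and a per-session residual SD
#     such that per-subject slope scatter matches the printed slope SEMs
#     (SD_slope = sd_residual / sqrt(sum (gd - mean gd)^2)) and the GD18
#     cross-subject SD matches the printed endpoint (or FRI) SEM.  For UtA-RI
#     the two printed dispersions are mutually inconsistent; the values below
#     are a documented compromise (see docs/methods.md).

design:
  groups: [control, disease, treated]
  n_per_group: 8
  systemic_gd_grid: [7, 10, 13, 18]
  imaging_gd_grid: [14, 16, 18]

markers:
  sbp:
    unit: mmHg
    orientation: decrease          # a fall in SBP is recovery
    grid: systemic
    valid_range: [60.0, 260.0]
    sd_intercept: 23.0             # sqrt((9.0*sqrt(8))^2 - sd_residual^2)
    sd_residual: 5.7               # slope SEM 0.25 * sqrt(8) * sqrt(66)
    groups:
      disease: {anchor: 162.9, slope: 3.91}
      treated: {anchor: 143.9, slope: 2.15}
      control: {anchor_from_fri: 51.1, slope: 0.5}   # anchor -> 125.72 mmHg
  urinary_protein:
    unit: mg/L
    orientation: decrease
    grid: systemic
    valid_range: [0.0, 3000.0]
    sd_intercept: 310.0
    sd_residual: 66.0
    # proteinuria spans a 4x dynamic range over gestation; a constant additive
    # intercept of this magnitude would clip ~30% of GD7 values at the zero
    # floor and bias slopes low, so the intercept scales with trajectory level
    # (endpoint dispersion is unchanged: it is anchored at GD18)
    intercept_scaling: proportional
    groups:
      disease: {anchor: 662.6, slope: 43.84}
      treated: {anchor: 506.3, slope: 29.55}
      control: {anchor_from_fri: 32.0, slope: 0.0}   # anchor -> 174.16 mg/L
  so2:                             # photoacoustic oxygen saturation, percent
    unit: '%'
    orientation: increase
    grid: imaging
    valid_range: [0.0, 100.0]
    sd_intercept: 4.0
    sd_residual: 0.9
    coupled_to_rescue: true
    groups:
      control: {anchor: 70.0, slope: 0.0}
      disease: {anchor: 48.0, slope: -0.70}
      treated: {anchor_from_fri: 92.7, slope: 1.95}  # anchor -> 68.394 %
  wiauc:                           # CEUS wash-in area under the curve
    unit: a.u.
    orientation: increase
    grid: imaging
    valid_range: [0.0, 200000.0]
    sd_intercept: 2100.0
    sd_residual: 370.0
    coupled_to_rescue: true
    groups:
      control: {anchor: 30000.0, slope: 2500.0}
      disease: {anchor: 18000.0, slope: 1454.0}
      treated: {anchor_from_fri: 88.1, slope: 3259.0}  # anchor -> 28572 a.u.
  vi:                              # MV-flow vascular index, percent of ROI
    unit: '%'
    orientation: increase
    grid: imaging
    valid_range: [0.0, 100.0]
    sd_intercept: 8.0
    sd_residual: 1.2
    groups:
      control: {anchor: 40.0, slope: -0.2}
      disease: {anchor: 25.0, slope: -1.07}
      treated: {anchor_from_fri: 68.3, slope: -0.73}  # anchor -> 35.245 %
  uta_ri:                          # uterine artery resistance index
    unit: ''
    orientation: decrease
    grid: imaging
    valid_range: [0.0, 1.0]
    sd_intercept: 0.012
    sd_residual: 0.022
    groups:
      control: {anchor: 0.55, slope: -0.005}
      disease: {anchor: 0.75, slope: 0.01}
      treated: {anchor_from_fri: 43.9, slope: -0.005} # anchor -> 0.6622

endpoints:
  # Latent "functional rescue" factor: one z-score per dam.  In the treated arm
  # it loads on the intercepts of the functional markers (so2, wiauc; flagged
  # coupled_to_rescue above) and on fetal weight, so functional recovery and
  # fetal outcome share a cause while resistance recovery does not.
  rescue_coupling: 0.8             # corr(rescue z, functional-marker intercept), treated arm
  fetal_weight:
    unit: g
    group_means: {control: 3.8, disease: 2.93, treated: 3.30}
    rescue_loading: {control: 0.0, disease: 0.0, treated: 0.87}   # g per z
    noise_sd: {control: 0.6, disease: 0.65, treated: 0.48}
    valid_range: [0.5, 8.0]
  placental_weight:
    unit: g
    group_means: {control: 0.53, disease: 0.51, treated: 0.47}
    noise_sd: 0.05
    valid_range: [0.1, 1.5]
  hif1a:                           # % positive area; rises as sO2 falls
    unit: '%'
    intercept: 65.0
    slope_per_so2: -0.8            # % area per sO2 percentage point
    noise_sd: 7.5
    valid_range: [0.0, 100.0]
  cd31:                            # % positive area; rises with microvascular density
    unit: '%'
    intercept: 2.0
    slope_per_vi: 0.4
    noise_sd: 5.5
    valid_range: [0.0, 100.0]

measurement:
  pa:                              # dual-wavelength photoacoustics
    wavelengths: [750.0, 850.0]    # nm
    extinction_hbo2: [518.0, 1058.0]   # cm^-1 M^-1 at 750/850 nm
    extinction_hb: [1405.24, 691.32]
    total_hb: 1.0                  # a.u. chromophore concentration scale
    fluence: [1.0, 1.0]            # per-wavelength fluence factors
    noise_sd: 5.0                  # a.u., on signals of order 500-2000
  ceus:                            # bolus time-intensity curve
    t0: 5.0                        # s, bolus arrival
    mu: 3.0                        # lognormal log-mean (mode exp(mu-sigma^2) ~ 15.6 s)
    sigma: 0.5                     # lognormal log-SD
    baseline: 100.0                # a.u.
    duration: 60.0                 # s
    dt: 0.5                        # s
    noise_sd: 2.0                  # a.u.
  doppler:
    psv_ref: 80.0                  # mm/s, uterine artery peak systolic velocity
    n_cycles: 5
    noise_sd: 1.5                  # mm/s per cycle
  mvflow:
    grid_shape: [256, 256]
    contrast: 100.0                # a.u. vessel signal
    noise_sd: 10.0                 # a.u. everywhere
    threshold: 50.0                # constant colour threshold, all subjects/sessions

analysis:
  alpha: 0.05
  strong_alpha: 0.01               # attenuated-progression vs partial-mitigation split
  fri_guard_rel: 1.0e-9            # relative guard on |control - disease| reference gap
  fri_near_complete: 80.0          # % FRI flagged as near-complete functional recovery
  gg_correction: true              # Greenhouse-Geisser on within-subject effects
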