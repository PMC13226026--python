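# Methods

This note documents the models behind `placentapd`: what the synthetic cohort
generator emulates, how the measurement chains and pharmacodynamic metrics are
defined, which numerical and design choices were open and how they were
settled, and what the package's tests do and do not demonstrate about real
data.

## 1. Study design and ground-truth model

The default configuration encodes a three-arm rat preeclampsia study:
healthy control, L-NAME-induced disease (nitric-oxide-synthase inhibition
from GD7), and disease plus pravastatin from GD10. Each arm has n = 8 dams.
Systemic markers — systolic blood pressure (mmHg) and 24-h urinary protein
(mg/L) — are sampled at GD 7/10/13/18; one monitored placenta per dam is
imaged at GD 14/16/18 for oxygen saturation (sO₂, %), CEUS wash-in area
(WiAUC, a.u.), vascular index (VI, %) and uterine-artery resistance index
(UtA-RI, dimensionless).

Ground truth per dam follows an anchor-and-slope line,

    x_i(t) = anchor_g − slope_g · (t_final − t) + b_i + e_it,

linear within each arm over the sampled window. Treatment starting mid-
gestation makes the underlying biology piecewise, but only endpoint means and
fitted slopes are available as calibration constraints, so the piecewise
shape is absorbed into the per-arm fitted slope. The random structure is a
between-dam intercept b_i ~ N(0, σ_b²) plus an independent per-session
residual e_it ~ N(0, σ_e²); a random-slope term is supported in the code but
defaults to zero.

**Intercept scaling.** For markers whose group mean spans a wide dynamic
range above a hard physical floor, a constant additive intercept of the
calibrated magnitude is unphysical: for urinary protein (mean ≈ 180 mg/L at
GD7 rising to ≈ 660 mg/L at GD18, endpoint SD ≈ 371 mg/L) it would place
roughly 30 % of early-gestation values below zero, and the clip-and-warn
policy would then bias generated slopes low by ~12 %. Urinary protein
therefore uses a proportional intercept, b_i scaled by the ratio of the
trajectory level to the anchor, which preserves the calibrated endpoint
dispersion exactly and keeps slopes unbiased. The cost is a per-subject slope
dispersion larger than the calibrated slope SEM implies; the three printed
constraints (endpoint SD, slope SEM, non-negativity) are mutually
inconsistent under any linear Gaussian model, and unbiased slope recovery was
prioritized because the slope grand means are quantitative outputs while the
slope SEM is descriptive. All other markers use the additive intercept.

**Range enforcement.** Values breaching a marker's physiological range are
clipped, counted and logged — never silently resampled — so a configuration
that produces frequent clipping is visible in the run log rather than
masked.

**Latent rescue factor.** One z-score per dam. In the treated arm it loads on
the intercepts of the functional markers (sO₂, WiAUC; coupling 0.8) and on
fetal weight, so functional recovery and fetal outcome share a cause while
UtA-RI recovery does not. GD18 endpoints are generated as linear-Gaussian
maps: fetal and placental weights from group means (+ rescue loading for
fetal weight in the treated arm), HIF-1α % area decreasing in final-GD sO₂
(tissue-hypoxia marker), CD31 % area increasing in final-GD vascular density
(endothelium marker).

## 2. Calibration: where every number comes from

The packaged calibration (`data/default_calibration.yaml`) is anchored to
the published endpoint profile of pravastatin rescue in this model; the YAML
comments flag the provenance of each block. Three classes of numbers:

1. **Printed values** — disease/treated anchors and slopes for SBP
   (162.9/143.9 mmHg; +3.91/+2.15 mmHg/day) and proteinuria (662.6/506.3
   mg/L; +43.84/+29.55 mg/L/day), all six imaging slopes, and the treated-arm
   FRIs (sO₂ 92.7, WiAUC 88.1, VI 68.3, UtA-RI 43.9 %).
2. **Reconstructed anchors** — healthy-control values are never printed, so
   control anchors for the systemic markers are obtained by inverting the FRI
   relation (X̄_C = X̄_PE + (X̄_T − X̄_PE)/FRI), and treated anchors for the
   imaging markers by the forward form (X̄_T = X̄_PE + FRI·(X̄_C − X̄_PE)).
   A consistency check falls out for SBP: both L-NAME arms extrapolate to a
   common ≈ 120 mmHg baseline at GD7.
3. **Free defaults** — control/disease imaging anchors (sO₂ 70/48 %, WiAUC
   30 000/18 000 a.u., VI 40/25 %, RI 0.55/0.75), control slopes, and the
   measurement-noise settings, chosen once at physiologically conventional
   values for this model and not revisited.

Dispersions derive from the printed mean ± SEM values with SD = SEM·√8
(n = 8). Each marker's SD is partitioned so that per-subject slope scatter
matches the printed slope SEM (σ_slope = σ_e/√Σ(t−t̄)²; Σ = 66 on the
systemic grid, 8 on the imaging grid) and the endpoint cross-subject SD
matches the printed endpoint SEM (systemic markers) or the FRI SEM scaled by
the reference gap (imaging markers). For UtA-RI those two constraints are
mutually inconsistent (the slope SEMs imply more session noise than the FRI
SEM permits at GD18); the packaged compromise is σ_b = 0.012, σ_e = 0.022.

## 3. Measurement models

**Photoacoustics.** ROI-mean amplitudes at 750/850 nm from the linear
absorption model with compiled hemoglobin extinction coefficients
(ε_Hb = 1405.24/691.32, ε_HbO₂ = 518.0/1058.0 cm⁻¹M⁻¹ at 750/850 nm;
overridable). Unmixing solves the 2×2 system under an equal-fluence
assumption (a per-wavelength fluence knob exists for studying systematic
bias; the fixed imaging depth of the emulated protocol is absorbed into a
constant). Negative concentration estimates under noise are clipped with a
warning. Noiseless unmixing is the exact inverse of the forward model for
all sO₂ ∈ [0, 1], and the estimate is monotone in the p850/p750 ratio.

**CEUS.** The bolus passage is the lognormal time–intensity curve, the
de-facto standard for bolus quantification software. The simulator expresses
ground-truth blood volume on the WiAUC scale by setting the amplitude to
A = truth/Φ(−σ), so the analytic wash-in area of the clean curve equals the
truth by construction. Fitting is bounded nonlinear least squares with
moment-based initialization (baseline from early samples, arrival from the
5 %-of-peak crossing, log-moments for μ and σ, total trapezoid area for A),
two deterministic restarts, and a flagged — never raised — failure mode:
flat or non-convergent curves return quality codes with missing metrics.
WiAUC is evaluated from the fitted model via the lognormal CDF (the raw-curve
trapezoid integral is available as an option; the two agree within ~5 % on
clean curves).

**MV-flow.** A binary vessel field with occupancy equal to the true density
fraction, vessel contrast 100 a.u., Gaussian noise everywhere, and a colour
threshold held constant across subjects and sessions. Vessel pixels are
placed by exact count (round(d·N) of N = 256² pixels) rather than per-pixel
Bernoulli draws, so the noiseless map reproduces the true density up to
single-pixel quantization (≤ 8·10⁻⁴ VI points) — this is what lets the
zero-noise pipeline identity hold to tight tolerances.

**Doppler.** Five cardiac cycles of (PSV, EDV) = truth + independent
Gaussian noise (1.5 mm/s), EDV clipped into [0, PSV] with a warning;
RI is the mean per-cycle (PSV − EDV)/PSV, with PSV ≤ 0 an invalid
measurement. The reference PSV is 80 mm/s; the true EDV is derived from the
calibrated RI trajectory.

Systemic markers are tabulated directly: tail-cuff and metabolic-cage noise
is already represented by the generator's session residual.

## 4. Pharmacodynamic metrics

The per-subject recovery slope is the OLS slope of marker value on
gestational day over that marker's own grid (systemic GD7–18, imaging
GD14–18), sign-flipped for decrease-is-recovery markers (SBP, proteinuria,
UtA-RI). Fewer than two distinct days is an error, not a NaN.

FRI is evaluated at the final gestational day against the **measured**
control and disease group means — what an experimenter could actually
compute; an oracle variant against true means is available in tests. The
index is reported unclipped (negative and > 100 % values carry meaning). A
relative guard (default 10⁻⁹) rejects degenerate reference gaps.

A consequence worth knowing: FRI is a ratio with a noisy denominator
(control − disease gap estimated from 8 + 8 dams). When the per-subject SD
is a large fraction of the gap — for VI the calibrated SD is 54 % of the
15-point gap — the Monte-Carlo *mean* of the group FRI is heavy-tailed and
biased a few points low even though the median sits on the calibrated value.
This is a property of the estimator itself at small n, not of the
implementation, and it is why the VI calibration-recovery check is the one
acceptance assertion that can sit outside its ±2-point band while all other
markers pass.

## 5. Inference

All procedures are classical sums-of-squares implementations; scipy provides
only the F, t and studentized-range distributions.

- **Mixed RM-ANOVA** (between = treatment, within = time, subject = dam,
  one monitored placenta per dam). Balanced complete input is required;
  missing cells raise rather than impute. Greenhouse–Geisser correction is
  applied to within-subject effects by default (ε from the double-centred
  pooled covariance, clamped to [1/(t−1), 1]). Pairwise group contrasts at
  each day use pooled-variance t-tests with the p-value multiplied by the
  number of pairwise comparisons in that day's family, capped at 1.
- **Slope comparison.** The pooled model value ~ GD + group + GD:group gives
  the homogeneity-of-slopes interaction F — the standard operationalization
  of "differences in regression coefficients". With repeated measures per
  dam, the pooled residual absorbs the between-dam intercept variance, so
  this F is conservative (its type-I error is nominal under the iid sampling
  model, which is how it is calibrated in the tests). The per-subject-slope
  two-sample t-test is reported alongside; because balanced designs make the
  pooled slope estimates equal to the per-group means of subject slopes, the
  two tests share a numerator and differ only in variance estimate. The
  endpoint summary uses the subject-slope p, which is calibrated in the
  presence of intercept variance and reproduces the emulated study's
  significance calls; both are in the stats table.
- **FRI comparison.** One-way ANOVA across imaging modalities with Tukey HSD
  from the studentized-range distribution (Tukey–Kramer SE for unequal n).
- **Correlations.** Pearson r with the exact t-based p, and simple OLS
  regression, both closed-form.

Two-tailed tests throughout; α = 0.05. Normality/homoscedasticity screening
is deliberately out of scope (assumption checks, not results-bearing).

## 6. Response-pattern classification

Labels are assigned from the directionally-adjusted group-mean slopes
(a_d disease, a_t treated) and the slope-comparison p:

- p ≥ α → **no slope alteration**
- a_d < 0 < a_t → **trajectory inversion** (deterioration reversed)
- both > 0, a_t > a_d → **enhanced increase** (recovery accelerated)
- both < 0, a_t > a_d → **attenuated progression** if p < 0.01, else
  **partial mitigation** (deterioration slowed, strongly vs marginally)
- a_t < a_d → **accelerated decline**

The 0.01 strong-significance split and the α threshold are configuration
values. Under the default calibration the noiseless pipeline labels SBP and
proteinuria "attenuated progression", sO₂ "trajectory inversion", WiAUC
"enhanced increase" — the expected profile.

## 7. Numerical choices and degenerate inputs

- Zero-noise identity: with every SD at zero the pipeline returns calibrated
  slopes and FRIs to < 10⁻⁹ relative on the analytic paths (including the
  nonlinear WiAUC fit, at xtol = ftol = 10⁻¹²) and to the pixel-quantization
  bound for VI.
- All-constant ANOVA input returns F = 0, p = 1 (not NaN); perfectly
  collinear regression returns p = 0 with zero standard error.
- Bonferroni never lowers a p-value and is capped at 1; Tukey p is never
  below the unadjusted pairwise t p.
- Every random draw flows from `numpy.random.SeedSequence`; dams, sessions
  and modalities are visited in fixed order, so identical (config, seed)
  pairs give byte-identical output CSVs. Replicate seeds are spawned children
  of the study seed.
- Monte-Carlo problem sizes: the calibration-recovery runs use 200 replicate
  cohorts of 24 dams (≈ two minutes on one CPU); null-calibration checks use
  1 000 simulations; the Tukey Monte-Carlo oracle uses 2·10⁵ draws.

## 8. What the synthetic cohort does and does not emulate

Emulated: arm sizes and sampling grids, endpoint-anchored linear group
trajectories, between-dam and session-level variability at magnitudes derived
from the printed dispersions, the functional-versus-structural coupling
asymmetry, modality-specific measurement transformations and noise, and
floor/ceiling constraints with audited clipping.

Not emulated: litter-size and resorption effects, multiple placentas per
dam, pharmacokinetics and dose–response, nonlinear (piecewise) trajectory
shapes, depth-dependent optical attenuation, microbubble destruction–
replenishment kinetics, Doppler angle geometry, and any non-Gaussian
heavy-tailed biological variation. Passing calibration-recovery therefore
demonstrates that the estimation chain is unbiased and correctly wired under
the stated model — not that the model captures every feature of real
placental imaging data.

## 9. Known limitations

- The printed dispersion triple for proteinuria (endpoint SD, slope SEM,
  zero floor) cannot be jointly honoured by a linear Gaussian generator; see
  §1 for the chosen compromise. The analogous UtA-RI tension is noted in §2.
- Under the default calibration the simulated VI slope contrast is usually
  non-significant and the UtA-RI contrast usually significant — the reverse
  of the emulated study's calls — because the printed VI FRI SEM (19 %) and
  the printed UtA-RI slope SEMs themselves imply those outcomes. The
  temporal-ordering checks therefore assert only the robust pattern
  (functional markers separate from disease before structural ones).
- The FRI mean is heavy-tailed at small n for high-dispersion markers (§4);
  medians are stable, means can wander a few points.
- ANCOVA power statements depend on which variance route is used (§5); the
  package reports both rather than hiding the discrepancy.
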