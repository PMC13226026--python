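# placentapd

**Longitudinal multimodal placental pharmacodynamics, in silico.**

Preeclampsia drug screening suffers from a blind spot: the clinical workhorse
metric, uterine-artery resistance index (UtA-RI), reflects macrovascular
architecture and reacts slowly, so an effective drug can look inert for days
while tissue-level oxygenation and perfusion are already recovering.
`placentapd` is a Python library for studying exactly that temporal mismatch.
It simulates three-arm preclinical studies in the L-NAME rat model of
preeclampsia (healthy control, untreated disease, pravastatin-treated),
forward-models four placental imaging modalities, and quantifies the
therapeutic trajectory with the two exploratory pharmacodynamic metrics used
in this setting — the directionally-adjusted recovery slope and the
Functional Recovery Index — plus the classical inference around them.

It is intended for imaging scientists and biostatisticians who want to
prototype analysis pipelines, power study designs, or stress-test recovery
metrics without animal data.

## The model

**Cohort.** Each arm has *n* = 8 dams; systemic markers (SBP in mmHg, 24-h
urinary protein in mg/L) are sampled on gestational days 7/10/13/18 and one
monitored placenta per dam is imaged on GD 14/16/18. Ground truth for dam *i*
follows a linear group trajectory anchored at the final gestational day,

&nbsp;&nbsp;&nbsp;&nbsp;x<sub>i</sub>(t) = anchor<sub>g</sub> − slope<sub>g</sub>·(t<sub>final</sub> − t) + b<sub>i</sub> + e<sub>it</sub>,

with a between-dam intercept b<sub>i</sub> and per-session residual
e<sub>it</sub>. A latent "functional rescue" factor couples, in the treated
arm only, the functional-marker intercepts (sO₂, WiAUC) to GD18 fetal weight
— resistance recovery deliberately does not share it.

**Measurement.** Truth is never observed directly; it is pushed through each
modality's forward model and back through its quantification operator:

| modality | forward model | quantification |
|---|---|---|
| photoacoustics | p<sub>λ</sub> = Φ<sub>λ</sub>(ε<sub>HbO₂,λ</sub>C<sub>HbO₂</sub> + ε<sub>Hb,λ</sub>C<sub>Hb</sub>) + noise at 750/850 nm | linear spectral unmixing → sO₂ = C<sub>HbO₂</sub>/(C<sub>HbO₂</sub>+C<sub>Hb</sub>) |
| CEUS | lognormal bolus TIC, I(t) = O + A·f(t−t₀; μ, σ) | nonlinear fit → WiAUC = A·Φ(−σ) (wash-in area, arrival→peak) |
| MV-flow | binary vessel field at the true density + noise | VI = % of ROI pixels above a constant colour threshold |
| pulse-wave Doppler | per-cycle PSV/EDV + noise, 3–5 cycles | RI = mean (PSV − EDV)/PSV |

**Metrics.** Per subject, the recovery slope β is the OLS slope of a marker
against gestational day, sign-flipped for markers where a decrease means
improvement, so β<sub>adj</sub> > 0 always reads "moving toward healthy". At
GD18 each treated dam gets a Functional Recovery Index

&nbsp;&nbsp;&nbsp;&nbsp;FRI = 100 · (X<sub>i</sub> − X̄<sub>PE</sub>) / (X̄<sub>Control</sub> − X̄<sub>PE</sub>) %,

where the reference means are the measured control and disease group means:
100 % is complete normalization, 0 % no improvement, negative values
deterioration; values are never clipped.

**Inference.** Mixed repeated-measures ANOVA (treatment × time, with
Greenhouse–Geisser correction) plus Bonferroni contrasts per day,
homogeneity-of-slopes ANCOVA with a per-subject-slope t-test alongside,
one-way ANOVA with Tukey HSD across modality FRIs, and Pearson/simple
regression for endpoint associations — all implemented from the classical
sums-of-squares formulas (scipy supplies only the reference distributions).

## A worked example

```python
from placentapd import default_config, run_single

cfg = default_config()           # packaged three-arm calibration
run = run_single(cfg, seed=42)   # simulate -> measure -> metrics -> inference
print(run.summary.round(4).to_string(index=False))
```

```
         marker  slope_disease  slope_disease_sem  slope_treated  slope_treated_sem  slope_p  fri_mean  fri_sem       response_pattern
            sbp         4.1328             0.1448         2.4021             0.3095   0.0002   43.3930  13.2883 attenuated progression
urinary_protein        67.9865             7.7028        28.4551             4.2279   0.0005   64.6624   9.7025 attenuated progression
            so2        -0.8004             0.1302         1.9505             0.1218   0.0000   94.4105   4.1510   trajectory inversion
          wiauc      1473.0015            53.5532      3229.1263            34.0434   0.0000  100.6671   4.5138      enhanced increase
             vi        -0.9204             0.1206        -0.9262             0.1528   0.9766   69.8011  18.4774    no slope alteration
         uta_ri         0.0060             0.0031        -0.0066             0.0028   0.0087   46.9677   4.3411   trajectory inversion
```

One row per marker: disease- and treated-arm per-subject slopes ± SEM, the
slope-comparison p, the treated-arm FRI ± SEM at GD18, and a response-pattern
label. In this replicate the oxygenation slope inverts (−0.80 → +1.95 %/day)
and its FRI reaches ~94 %, while arterial resistance recovers less than half
of the control–disease gap — the functional-before-structural signature the
platform is built to expose. Single replicates are deliberately noisy (n = 8
dams/arm); `run_study(cfg, seed, replicates=200)` reports Monte-Carlo means
that settle onto the calibrated profile.

The `examples/` directory walks through each capability (cohort generation,
measurement models, metrics, inference, full study); each script prints and
explains its numbers. A thin CLI mirrors the stages:

```bash
placentapd run --seed 42 --out results/run42
placentapd simulate --seed 7 --out results/sim7
```

## Layout

- `src/placentapd/calibration.py` — study configuration, packaged default calibration, FRI anchor inversion
- `src/placentapd/cohort.py` — seeded cohort generator (trajectories, random effects, endpoint couplings)
- `src/placentapd/measure/` — the four modality forward models and quantification operators
- `src/placentapd/metrics.py` — recovery slope β and FRI
- `src/placentapd/stats.py` — classical inference (RM-ANOVA, ANCOVA, Tukey, correlation)
- `src/placentapd/pipeline.py` — orchestration, Monte-Carlo replication, response classification
- `docs/methods.md` — the full methods note: model assumptions, calibration derivations, numerical choices, limitations
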