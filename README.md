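# vtcycle

Cycle-length variability analysis of ventricular tachycardia (VT)
episodes recorded by implantable cardioverter defibrillators (ICDs).

ICD shocks are painful and associated with excess mortality, yet many
treated VT episodes would have terminated on their own. An ICD logs each
episode as a series of beat-to-beat **cycle lengths** (CLs, ms), and the
first ~10 CLs (about 3.4 s of tachycardia) are available before a
therapy decision must be made. `vtcycle` asks: *can the stability of
those first 10 CLs tell a spontaneously terminating VT from a sustained
one?* It is written for cardiac electrophysiologists and biostatisticians
working with device-logged arrhythmia data.

The package implements, end to end:

- **Feature extraction** per episode, on the first 10 CLs (CL1 being the
  interval from the initiating premature ventricular contraction):
  mean, sample SD, RMSSD, NN50/pNN50, TINN (triangular interpolation of
  the CL histogram), Poincaré SD1/SD2, and an AR(1) stability fit
  x_t = c + φ·x_{t−1} + ε_t (coefficient φ, constant c, residual SD);
  plus whole-episode descriptors (duration, beat count, overall CL SD,
  initiation-to-shortest-CL dynamics).
- **Group statistics**: per-feature terminating-vs-sustained comparison
  with Shapiro–Wilk-gated Student's t / Mann–Whitney U tests.
- **Classification**: a random forest over the first-10-CL features with
  mean-importance feature selection, evaluated by stratified 10-fold
  cross-validation with pooled out-of-fold predictions (accuracy,
  sensitivity, specificity, PPV, NPV, AUROC).
- **Synthetic cohorts**: clinical ICD episode data are not publicly
  available, so a trend-plus-AR(1)-noise generator produces labelled
  cohorts (default 36 terminating / 33 sustained episodes from 27
  patients) whose first-10-CL statistics are *calibrated* by Monte Carlo
  against the published group means — see `docs/methods.md`.

## Worked example

```bash
vtcycle simulate --seed 1 -o cohort.csv        # calibrated synthetic cohort
vtcycle run cohort.csv --seed 1 -o out/        # features, report, metrics, figures
```

or, step by step, the numbered drivers:

```bash
python analysis/01_calibrate.py   # generator calibration report
python analysis/02_simulate.py    # results/cohort.csv
python analysis/03_features.py    # results/features.csv
python analysis/04_compare.py     # results/compare.md (+ .csv)
python analysis/05_classify.py    # results/metrics.json
python analysis/06_figures.py     # Poincaré / box / 3-D scatter figures
```

On the seed-1 cohort this prints:

```
group means of the headline features:
             sd_cl10  ar_phi  tinn10  episode_sd  mean_cl10
sustained     11.279   0.226  33.144      10.949    317.628
terminating   19.035   0.397  46.007      18.825    336.385

10-fold CV, positive class = spontaneous termination (seed 1):
  accuracy    0.696 (95% CI 0.587-0.804)
  sensitivity 0.722  specificity 0.667
  PPV         0.703  NPV         0.688
  AUROC       0.778
  majority-selected features: mean_cl10, sd_cl10, rmssd10, ar_phi, ar_resid_sd, ar_const
```

Read: spontaneously terminating episodes have roughly twice the
first-10-CL variability (sd_cl10 ≈ 19 vs 11 ms) and a higher AR(1)
coefficient (φ ≈ 0.40 vs 0.23 here) — their rhythm wanders rather than
locking in — and those features let a forest classify a single 69-episode
cohort with ~0.7–0.8 accuracy. Single-seed numbers move a few points from
seed to seed; the multi-seed averages are what the acceptance script
reports.

As a library:

```python
from vtcycle.simulate import CohortSpec, generate_cohort
from vtcycle.features import features_table
from vtcycle.classify import ClassifierConfig, cross_validate

ft = features_table(generate_cohort(CohortSpec(seed=1)))
res = cross_validate(ft, ClassifierConfig(seed=1))
print(res.accuracy, res.auroc)
```

Cohorts travel as long-format CSV
(`episode_id,patient_id,label,beat_index,cl_ms`); `vtcycle features`,
`compare` and `classify` accept files in that format from any source,
not just the simulator.

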