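# ehrjoint

When is a joint model for longitudinal and time-to-event data worth its
complexity, compared with a Cox model that only uses the most recent
biomarker value? `ehrjoint` is a simulation and evaluation toolkit for
answering that question on longitudinal primary-care / EHR biomarker
data, aimed at biostatisticians and clinical-prediction researchers.

It provides:

* a **synthetic cohort generator** for longitudinal biomarker + survival
  data with controllable data-quality parameters: sample size N, noise SD
  σ_ε, responder fraction p, pre-diagnosis slope duration t_m,
  measurements per year n_abs, intercept shift Δ_b, and slope mean/SD
  μ_m, σ_m — cases get piecewise-linear trajectories that leave their
  flat baseline 12·t_m months before diagnosis;
* three **candidate risk models**: a baseline Cox model
  `h_i(t) = h_0(t)·exp(γ₁Sex + γ₂Age + γ₃Smoking)`, a last-value Cox
  model adding `γ₄·ỹᵢ`, and a **shared-random-effects joint model**
  coupling the mixed model `y_i(t) = x_i'β + b_i0 + b_i1·t + ε_i(t)` to
  the hazard `h_i(t) = h_0(t)·exp(γ'w_i + α·m_i(t))`, fitted by full
  maximum likelihood with pseudo-adaptive Gauss–Hermite quadrature and
  analytic gradients;
* the **time-varying concordance index**
  `tvC(t) = Σ_{k∈S1} Σ_{l∈S2} 1{r_k(t) > r_l(t)} / (n₁·n₂)`, comparing
  subjects diagnosed in the trailing year against subjects event-free
  through the coming year, plus its follow-up mean over months 60–120;
* a **scenario-grid study runner** (one-at-a-time parameter variation,
  repeated simulation, 0.05/0.95 prediction intervals); and
* a **guideline checker** that estimates the same data-quality parameters
  from real long-format data (after log / min-max normalization) and
  reports whether a joint model is expected to outperform
  (thresholds: N ≥ 200, σ_ε > 0.075, p ≥ 80%, n_abs ≥ 1, Δ_b ≥ 0.1,
  σ_m ≤ 0.005).

## Worked example

```python
import numpy as np
import ehrjoint as ej

# reference setting: N=500, sigma_eps=0.15, p=1, t_m=3y, 2 meas/year,
# delta_b=0.1, sigma_b=0.05, mu_m=sigma_m=0.005/month
cohort = ej.simulate_cohort(ej.REFERENCE_CONFIG.replace(seed=7))
subjects = cohort.survival_table().merge(cohort.covariate_table(), on="subject_id")

fit = ej.fit_joint(cohort.observations, subjects)          # full ML
print(f"alpha = {fit.alpha:.1f}, sigma_eps = {fit.resid_sd:.3f}")

at_risk = ej.filter_at_risk(cohort.survival_table(), 60)
subj_at = subjects.set_index("subject_id").loc[at_risk.subject_id].reset_index()
risks = ej.predict_risk_joint(fit, cohort.observations, subj_at,
                              np.arange(60, 121), 60)
print(f"mean tvC (joint) = {ej.mean_tvc(risks, cohort.survival_table()):.3f}")
```

prints

```
alpha = 16.9, sigma_eps = 0.150
mean tvC (joint) = 0.872
```

The association α ≈ 17 means a 0.1 increase in the current (noise-free)
marker level multiplies the hazard by e^1.7 ≈ 5.4; the measurement-noise
SD matches the generative 0.15; and the joint model's follow-up mean
time-varying C-index of 0.87 compares with 0.73 for the last-value
Cox model and 0.64 for the covariate-only Cox model on the same cohort
(`ehrjoint.study.run_iteration` computes all three in one call).

Command-line equivalents:

```bash
ehrjoint simulate --n 500 --seed 7 --out runs/ref
ehrjoint fit --cohort runs/ref --model joint --out runs/ref-joint
ehrjoint evaluate --risks runs/ref-joint/risks.csv \
    --survival runs/ref/subjects.csv --out runs/ref-joint/tvc.csv
ehrjoint check-guidelines --longitudinal data/long.csv \
    --survival data/surv.csv --t-m 3 --log-transform
```

## Data formats

Long-format CSVs, times in months: `observations.csv`
(`subject_id,time,value`), `subjects.csv`
(`subject_id,event_time,event_observed,sex,age,smoking`, latent truth
columns only under `--with-truth`), and a YAML config snapshot per run
directory sufficient to reproduce it bit for bit.

See `docs/methods.md` for the model, estimation details, design
decisions and known limitations.
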