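# graftrisk

Joint latent class modelling of serum-creatinine trajectories and
kidney graft failure, with individualized dynamic prediction of
ten-year graft-failure risk.

## The problem

After kidney transplantation, serum creatinine (SCr) is the routinely
collected marker of graft function, and clinicians want an early,
individual answer to "what is this patient's risk of losing the graft
within ten years?".  `graftrisk` is for biostatisticians and
transplant-epidemiology researchers who want to model a cohort's SCr
histories jointly with graft survival, classify patients into latent
trajectory groups, and turn a new patient's first-year data into a
personalised risk curve with uncertainty bands.

## The model

A joint latent class mixed model (JLCM): the population is a mixture of
`G` latent classes, and conditional on class the marker and the event
are independent.  For subject *i* in class *g*:

* membership:  `pi_ig = softmax(xi_g' x_ci)` (donor age ≥ 60 by default);
* trajectory:  a monotone link `H(·; eta)` (quadratic I-splines,
  beta-CDF, or linear) maps SCr to a latent Gaussian scale where
  `H(Y_ij) = beta_g'(1, t_ij, t_ij²) + b_i'(1, t_ij) + e_ij`,
  `b_i ~ N(0, B)`, `e_ij ~ N(0, 1)`;
* survival:  Weibull proportional hazards with class-specific baseline,
  `Lambda_g(t|x_s) = (zeta_1g t)^{zeta_2g} exp(x_s' delta)`, with
  right censoring (death with functioning graft) and optional left
  truncation.

Dynamic prediction conditions on a subject's history up to a landmark
`s` and on being event-free at `s`:

    P(s, t) = sum_g  pi_g(s) · [1 − S_g(t|x_s) / S_g(s|x_s)],

where `pi_g(s)` is the posterior class probability given the history.
95% bands come from Monte-Carlo draws of the parameters from their
asymptotic normal.  See `docs/methods.md` for assumptions, numerical
choices, and limitations.

## Worked example

```python
import numpy as np
import graftrisk as gr

# a 616-subject synthetic cohort with the default three-class structure
cfg = gr.paper_like_preset()
cfg.n_subjects = 616
cfg.delayed_entry = True            # >=1-year inclusion as left truncation
cohort, truth = gr.generate_cohort(cfg, seed=1)

fit = gr.fit(cohort, G=3, link_family="linear",
             config=gr.FitConfig(n_starts=2, seed=0))
print({k: round(v, 2) for k, v in fit.criteria.items()})
print((np.bincount(fit.modal_class) / cohort.n_subjects).round(4))

for idx in (0, 2):
    subj = cohort.subjects[idx]
    t, y = cohort.measurements_for(subj.subject_id)
    curve = gr.risk_curve_with_ci(fit, subj, t, y, s=1.0,
                                  grid=np.linspace(1, 10, 37),
                                  n_draws=500, seed=0)
    print(subj.subject_id, round(curve.median[-1], 3),
          round(curve.lower95[-1], 3), round(curve.upper95[-1], 3),
          gr.classify_curve(curve))
```

Output from this exact script:

```
{'AIC': 27121.36, 'BIC': 27245.21}
[0.2841 0.6542 0.0617]
S0001 0.999 0.925 1.0 predicted_failure
S0003 0.291 0.199 0.411 predicted_survival
```

The first line is the fitted model's AIC/BIC; the second says the fit
assigned 28.4% / 65.4% / 6.2% of subjects to the three classes
(generating split 29.4% / 64.5% / 6.2%).  Each subject line gives the
predicted ten-year failure probability from the one-year landmark —
median with the 95% band — and the decision rule's reading: S0001 (a
steeply rising creatinine trajectory) is a near-certain predicted
failure, while S0003's band stays below the rule's thresholds and reads
as a predicted survivor.

The same pipeline is scriptable from the shell:

```bash
graftrisk simulate --seed 1 --n-subjects 300 --out-dir data
graftrisk fit --long-csv data/long.csv --subjects-csv data/subjects.csv \
              --g-range 1,2,3 --link linear --n-starts 2 --out-dir out
graftrisk predict  --model out/model.json --long-csv data/long.csv \
                   --subjects-csv data/subjects.csv --out-dir out
graftrisk evaluate --model out/model.json --long-csv data/long.csv \
                   --subjects-csv data/subjects.csv --out-dir out --force
```

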