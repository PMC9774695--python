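# herdsurv

Joint modelling of first-lactation sensor data and survival for dairy
cows, with dynamic culling-risk prediction.

A dairy cow pays back her rearing cost only from the second lactation
onward, so the decision a farmer faces with every first-parity cow is
whether she is likely to still be in the herd at the second and third
calving.  `herdsurv` answers that from data most automatic milking
systems already record — daily milk yield (kg), body weight (kg) and
rumination time (min) — plus the calving/culling register, with no
hand-crafted features: the raw daily series drive the prediction.

## The model

Three linear mixed models with natural cubic splines of days in milk
(DIM) share one stacked random-effects vector b_i ~ N(0, D) (q = 13,
unstructured D), and a proportional-hazards model for culling is coupled
to them through the current *slopes* of the smoothed trajectories:

    y_ik(t) = β_0k + β_1kᵀ ns_k(t) + β_2k AFC_i + β_3k SEAS_i(t)
              + b_i0k + b_i1kᵀ ns_k(t) + ε_ik(t),        k = MY, BW, RUM
    h_i(t)  = h₀(t) exp( γ₁ AFC_i + Σ_k α_k m′_ik(t) ),
    m′_ik(t) = (β_1k + b_i1k)ᵀ ns_k′(t)

A falling rumination trajectory (α_RUM < 0), for example, raises the
culling hazard while it falls.  The model is fitted by MCMC
(Metropolis-within-Gibbs), and for a new cow observed through day v the
survival curve

    π_i(u|v) = Pr{ T_i ≥ u | T_i > v, sensor data to v, training fit }

is computed by Monte Carlo over the posterior and updates as data accrue.
Accuracy is scored by repeated 3-fold cross-validation with
time-dependent AUC (discrimination) and a censoring-aware expected
prediction error (calibration), under six scenarios: v ∈ {60, 150, 240}
DIM × horizons t1 (second calving) and t2 (third calving).

Because no farm data are public, the package ships a synthetic-herd
generator with exactly the model's statistical structure (spline mean
curves, correlated random effects, slope-coupled hazard, administrative
censoring, recording-error outliers) — the ground truth for every test.
See `docs/methods.md` for the full account.

## Worked example

```python
import numpy as np
from herdsurv import (SyntheticConfig, generate_herd, preprocess, build_design,
                      fit_mcmc, predict_survival, classify, make_knots, MCMCConfig)
from herdsurv.io import OUTCOME_KINDS

herd, truth = generate_herd(SyntheticConfig(n_cows=150, seed=11))
clean, report, quart = preprocess(herd)
specs = {k: make_knots(clean.sensor["dim"].to_numpy(), k) for k in OUTCOME_KINDS}
design = build_design(clean, specs, obs_thin=3, afc_quartiles=quart)
fit = fit_mcmc(design, MCMCConfig(chains=2, burn=500, keep=500), seed=2)
print(fit.summary().round(3).to_string(index=False))

cow = clean.cows["cow_id"].iloc[4]
pred = predict_survival(fit, clean.sensor[clean.sensor["cow_id"] == cow],
                        clean.cows[clean.cows["cow_id"] == cow].iloc[0],
                        v=150, seed=0)
print(f"pi(t1|150) = {pred.at(414):.3f} -> {classify(pred, 414)}")
```

prints (the preprocessing log first reports `retained 146/150 cows;
196 outlier days removed`):

```
           param   mean    sd  ci_lo  ci_hi  p_neg
        alpha_MY -0.514 2.301 -5.485  3.817  0.609
        alpha_BW  0.609 0.376 -0.076  1.381  0.042
       alpha_RUM -0.414 0.426 -1.202  0.468  0.836
gamma_afc_medium  0.598 0.579 -0.323  1.792  0.162
  gamma_afc_high  0.361 0.654 -0.963  1.810  0.299
pi(t1|150) = 0.964 -> alive
```

The `alpha_*` rows are the slope associations per natural unit (kg/day
for milk and weight, min/day for rumination): here the posterior puts 84%
of its mass on a negative rumination-slope association (the herd was
generated with α_RUM = −0.6 and only ~30 culled cows, so the sign, not
the decimal, is the message), and `p_neg` is that posterior mass.  The
predicted 96% survival to the second calving for this cow — truly
censored at day 587, i.e. still alive — would read as a clear "keep"
decision at the 0.5 threshold.

The same pipeline is scriptable from the shell:

```
herdsurv simulate --n-cows 150 --seed 11 --out herd/
herdsurv preprocess --in herd/ --out clean/
herdsurv fit --in herd/ --out fit/ --config cfg.yaml
herdsurv predict --fit fit/ --in herd/ --cow cow0004 --v 150 --out pred/
herdsurv evaluate --in herd/ --out eval/ --config cfg.yaml
```

`evaluate` writes `fold_metrics.csv` (9 CV runs × 6 scenarios) and
`summary.csv` with means, SDs, 95% CIs and significance flags against the
random-guessing nulls (AUC > 0.50, PE < 0.25).

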