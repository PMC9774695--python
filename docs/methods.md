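# Methods

## The problem

A dairy cow only becomes profitable from her second lactation onward, so a
farmer deciding which first-parity cows to breed again wants, as early as
possible, each cow's probability of still being in the herd at the second
and third calving.  Automatic milking systems record daily milk yield (MY,
kg), body weight (BW, kg) and rumination time (RUM, min) through the first
lactation; `herdsurv` turns those raw daily series, plus the culling
record, into individualized, dynamically updated survival predictions.

## Model

### Longitudinal submodels

For cow *i* and outcome *k* ∈ {MY, BW, RUM}, the observed daily value at
*t* days in milk (DIM) is modelled as

y_ik(t) = β_0k + β_1kᵀ ns_k(t) + β_2k AFC_i + β_3k SEAS_i(t)
        + b_i0k + b_i1kᵀ ns_k(t) + ε_ik(t),     ε_ik(t) ~ N(0, σ_k²),

where ns_k(t) is a natural cubic spline basis of DIM (three interior knots
at the DIM quartiles for MY and BW, one at the median for RUM; boundary
knots at the observed extremes), AFC is the age-at-first-calving category
(low/medium/high by herd quartiles, low as reference) and SEAS the binary
warm season (April–October).  Each cow gets a random intercept and one
random coefficient per spline column; the stacked vector

b_i = (b_i,MY, b_i,BW, b_i,RUM) ~ N(0, D),  dim = (1+4)+(1+4)+(1+2) = 13,

with *unstructured* D, which is what correlates the three sensor streams.

### Hazard submodel and slope association

Culling follows a proportional-hazards model whose log-hazard is linear in
the AFC category and in the current *slopes* of the three smoothed
trajectories:

h_i(t) = h₀(t) exp( γ₁ AFC_i + Σ_k α_k m′_ik(t) ),
m′_ik(t) = (β_1k + b_i1k)ᵀ ns_k′(t).

The slope — not the current value — is used because a disturbance (e.g.
disease) shows up as a *deviation* of the trajectory from its usual shape;
a value association (`association: value`) is also implemented.  AFC and
season are flat or piecewise-constant in time and contribute zero slope.
The baseline hazard h₀ is piecewise-constant on six intervals split at the
event-time sextiles of the training herd, which keeps every cumulative
hazard a sum of closed-form-weighted quadrature pieces and gives a
closed-form baseline survival function for testing.

### Dynamic prediction

For a new cow with sensor data Y_i(v) through day v, survival to day u is

π_i(u|v) = Pr{ T_i ≥ u | T_i > v, Y_i(v), training fit }
         = E_θ E_{b|Y_i(v), T_i>v, θ} [ exp(−H_i(v, u; θ, b)) ],

estimated with one Metropolis draw of b per retained posterior draw θ
(independence proposal from the exact Gaussian longitudinal conditional,
accepted on the survival factor exp(−H_i(0,v))), 500 draws by default;
pointwise 95% bounds are the 2.5/97.5 percentiles of the per-draw curves.
A cow is classified "culled at t_j" when π_i(t_j|v) ≤ c with c = 0.5.

## Estimation

Metropolis-within-Gibbs on internally standardized outcomes (z-scored on
the training data):

* σ_k² and D have exact conjugate updates (inverse-gamma,
  inverse-Wishart).
* β_k and every b_i are updated by independence Metropolis whose proposal
  is the exact Gaussian conditional of the longitudinal part plus prior;
  the accept/reject step involves only the survival likelihood, so the
  update collapses to plain Gibbs when α = 0 and needs no tuning.  All
  b_i updates are vectorized across cows.
* α, γ and the six log baseline rates use scalar adaptive random-walk
  Metropolis tuned to ≈30% acceptance during burn-in.

Internally the association covariate is the trajectory slope per unit of
*scaled* time (t−a)/(b−a) on the standardized outcome, which makes it
O(1); a per-day slope over a ~300-day lactation is O(1/300) and would let
the prior dominate.  Posterior α's are reported back per natural unit of
slope (kg/day or min/day).

Priors (standardized scale): β ~ N(0, 10⁴); σ² ~ InvGamma(0.01, 0.01);
D ~ InvWishart(q+2, I); α, γ ~ N(0, 10); log h₀ gets N(level; log crude
rate, 3²) on the first interval and a Gaussian random walk (SD 1) across
intervals.  Defaults: 2 chains × (1500 burn-in + 1500 kept), thin 1;
split-R̂ is recorded for α and γ and values above 1.1 are logged as
warnings, not fatal.  Every fit, partition and simulation seed is explicit
in the configuration.

The natural-spline basis is built from truncated powers on scaled time
with the linear-tail (natural) constraints, then the columns are centered
and orthonormalized over a fixed 201-point reference grid (unit RMS).  Raw
truncated-power columns have condition numbers in the hundreds; the
recombination spans the identical function space, keeps C² smoothness and
exact linear extrapolation beyond the boundary knots, and is fully
determined by the knots, so serialized fits rebuild it bit-for-bit.  Raw
spline coefficients are parameterization-dependent; fitted curves are the
comparable quantities.

## Preprocessing rules

Applied in this order, each only *removing* rows or cows (never altering a
value), with every removal tallied in a cleaning report:

1. 2-hourly rumination slots summed to daily minutes; a day missing any of
   the 12 slots is missing.
2. Survival time T = days from first calving to culling; no culling date →
   censored at the dataset end date.
3. 3-SD rule per outcome against herd mean/SD computed once on the raw
   data; a cow with ≥ 30 flagged days for an outcome keeps them all
   (sustained deviation is treated as real abnormal behaviour, not
   recording error; the boundary case of exactly 30 counts as "kept").
4. Cows with T < 50 dropped; observations outside 5–305 DIM dropped.
5. A cow is dropped when, for any outcome, retained days /
   (min(T, 305) − 4) < 0.90.

AFC quartiles (Q1 and Q3 inclusive to "medium") and spline knots are
recomputed on each CV training fold, so test cows never influence either.
The whole-farm AFC coding used outside CV is computed on the post-filter
herd.

## Evaluation protocol

Repeated 3-fold cross-validation (3 repeats → 9 runs), six scenarios:
observation windows v ∈ {60, 150, 240} DIM × horizons t1 (second calving)
and t2 (third calving), with t1 the mean calving interval and t2 = 2·t1
(configurable; the default synthetic herd uses 414/828 days).  Test cows
must have survived at least 240 DIM.  Metrics per run:

* **PE** — censoring-weighted expected squared prediction error: alive
  cows contribute (1−π)², culled cows π², and a cow censored at T inside
  the window contributes the mixture weighted by the model's own
  conditional survival π(t_j|T).  With no censoring this is the Brier
  score, so constant 0.5 predictions score exactly 0.25.
* **AUC** — comparable-pairs concordance between observed events in
  (v, t_j] and cows known alive at t_j, ties ½, cows censored inside the
  window excluded.  No events ⇒ non-estimable (missing, not zero).
* Significance: t-based 95% CI (mean ± t·SD/√m over the m ≤ 9 non-missing
  runs) against the random-guessing nulls 0.50 (AUC, above) and 0.25 (PE,
  below).  An SD-based interval would not be a CI for the mean, so the
  standard error is used.
* Levene's classic W (deviations from group means) across herds per
  scenario for variance homogeneity of the metrics.

## Synthetic herds

No commercial herd data are public, so the generator emulates exactly the
structure the model assumes — which makes it the ground truth for
parameter-recovery and end-to-end tests, and means passing tests certify
the *method*, not its behaviour on real farms (real data have non-Gaussian
noise, missing-not-at-random days, heat-stress waves, disease outbreaks
and management-driven culling that the generator does not produce).

Mean curves are specified as anchor-day values (solved exactly for spline
coefficients, hence basis-independent): milk rising to a ~35 kg/day peak
near DIM 60 then declining to ~18; body weight dipping post-calving then
regrowing 560→620 kg; rumination flat around 450–480 min.  Defaults, all
overridable: residual SDs (3 kg, 15 kg, 60 min); random-effect SDs of
4.5/50/80 units for the intercepts and 0.8–25 units for the shape columns,
with correlation 0.3 between the three intercepts and −0.2 between each
intercept and its first shape coefficient; AFC category probabilities
(0.25, 0.50, 0.25) with category-consistent AFC days (660–880); first
calvings staggered uniformly over a year with administrative censoring 900
days after the window start (so realized censoring spans ~535–900 days and
exercises the censored branch of PE); 2% missing days; optional
recording-error injection displacing random cow-days by ≥ 6 herd-SDs.
Culling times are drawn by inverse-transform sampling — bracket the drawn
Exp(1) variate on the piecewise-smooth cumulative hazard, then Brent
refinement to 10⁻¹⁰ — and returned as whole days (ceiling), matching
culling dates derived from daily milk records.  The default true
association is α = (0, 0.1, −0.6) per kg/day, kg/day, min/day — a weak
positive weight effect and a clear negative rumination-slope effect; these
are illustrative defaults, not estimates.  The default baseline rate
(2·10⁻⁴/day) puts the culled-before-t1 fraction near 10%, the middle of
the 6–18% range reported across commercial herds, and is scalable to
either end.

## Numerical choices

* Cumulative hazards use 15-point Gauss–Legendre per smooth segment —
  baseline intervals additionally split at spline knots (and, in
  prediction, at every evaluation time) — agreeing with dense-trapezoid
  integration to < 10⁻⁵ relative.
* The hazard's linear predictor is guarded at |lp| ≤ 50; the public
  `hazard` raises, while sampler proposals beyond the guard are rejected.
* Beyond the last baseline cut the rate extrapolates as constant; beyond
  the spline boundary knots trajectories extrapolate linearly (slopes
  constant).
* Event-time ties need no special handling: the likelihood is continuous
  in time and integer-day data are treated as continuous.
* Degenerate inputs fail loudly: non-PSD covariances, zero herd SD with
  varying data, empty post-filter herds, cows without observations for an
  outcome, prediction grids before the observation window.

## Problem sizes and test design

The test suite runs the full machinery at desk scale, chosen as the
smallest sizes at which each property is statistically decidable: recovery
uses 15 herds × 150 cows with every-3rd-day observations and 2×800 MCMC
iterations; the discrimination experiments use 200-cow herds with 1×600
iterations, every-5th-day observations and 200 prediction draws; the null
(no-association) experiment uses two herds with a raised culling level so
the pooled concordance estimate carries enough events to be conclusive.
Production defaults (2×3000 iterations, daily data, 500 draws) are set in
`MCMCConfig`/`PipelineConfig`.

## Limitations

* Only the first lactation is modelled; no multi-lactation trajectories,
  no disease events, no competing risks or cure fraction.
* The baseline-hazard family (piecewise-constant, six intervals) is a
  modelling choice; splined baselines would be smoother but lose the
  semi-closed-form survival integral used throughout the tests.
* Coefficient-level comparisons across natural-spline parameterizations
  are meaningless; compare fitted curves or associations per natural slope
  unit.
* With few events per CV fold the time-dependent AUC is extremely noisy;
  the prediction-error (calibration) metric is far more stable — the same
  asymmetry the protocol exhibits on real farms.
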