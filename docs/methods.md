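# Methods

## Ice growth

Daily thickness of the surface ice layer follows the Stefan degree-day
approach with a snow correction. Freezing degree-days accumulate as
`S(t) = Σ max(0, −T_air)` (°C·day) from the first sub-zero day ("freeze-up";
accumulation from the series start is available via
`grow_series(..., accumulate_from="start")` since the field convention
varies). Thickness solves

    h_i = sqrt(2 · k_s/i(h_i) · S_sec / (ρ · L)),      S_sec = 86 400 · S,

with `k_s/i = (h_i + h_s) / (h_i/k_i + h_s/k_s)`, the series conductivity of
the stacked ice–snow sandwich. Because `k_s/i` depends on the unknown
thickness, each day is solved by fixed-point iteration from the bare-ice
start; convergence to 1e-12 relative typically takes < 20 iterations and is
verified over `k_s ∈ [0.05, 0.5]`, `h_s ∈ [0, 1]` m, `S ∈ [0, 3000]` °C·day.
Each day is a static solve at the current `(S, h_s)` — the model is an
approximation of standing-ice thickness, not an incremental growth ODE, so
thickness can decrease when fresh snow deepens the insulation.

Defaults: ρ = 1000 kg·m⁻³, L = 333 400 J·kg⁻¹, k_i = 2.24 and
k_s = 0.2 W·m⁻¹·K⁻¹. The conductivities are standard literature values
(they are not identifiable from a thickness series alone) and are
configurable. Snow shoveling on the ice — done in the field to keep PIT
antennas within range — resets the *effective* snow layer to 3 cm; fresh
accumulation (positive increments of the observed depth) then adds again,
and melt thins the effective layer only once the observed pack drops below
it. Weekly means of the daily series form the detection covariate, averaged
again over pooled windows for the biweekly occasions.

## Encounter histories and fates

Weekly detections become a 27-bit history (marking + 26 occasions).
Movement between successive detections is classified against the 0.5 m
tracking accuracy (coordinates increase upstream from the downstream reach
end, so direction is a sign test). A fish is **transient** if it was never
redetected, or if all discernible moves were downstream or none (a pattern
indistinguishable from a shed tag or carcass) *and* it had no lateral
activity *and* it was not recaptured at the spring electrofishing; everyone
else is resident. The transient definition is deliberately conservative:
some genuine residents that happened never to move beyond accuracy are
excluded, which is the accepted cost of keeping dead tags out of the
survival estimate.

Within-reach mortality truncation (zeroing bits after the last upstream
move) requires a caller-supplied cessation criterion — the number of
trailing silent weeks is a configuration parameter with no default, because
no principled universal value exists. Truncation precedes pooling, since the
rule is defined at weekly resolution. Adjacent weeks are then pooled by
logical OR into 14 occasions (marking + 13 biweekly) to reduce sparseness.

Per-fish covariates: Fulton condition `K = 100·W/L³` (g, cm) at tagging;
mean over detections of the used subreach's mean depth and structural
complexity (the CV of maximum depths, from the autumn survey table — depths
are not re-measured per occasion); mean distance to the nearer reach end;
and tag burden (tag weight / body weight). Fish without positional
detections fall back to their tagging subreach with a warning.

## CJS model

Apparent survival φ_t (interval t → t+1) and detection p_t (occasion t)
are logit-linear in design columns built from model strings. A crossed term
expands as cell indicators of its categorical factors (g: 3 groups, t:
13 intervals) times all products over subsets of its continuous factors, so
`φ(t × cond)` gives 13 intercepts + 13 condition slopes and `p(g × ice)`
gives 3 intercepts + 3 group-specific ice slopes. Redundant columns across
additive terms are allowed; identifiability is resolved numerically.

The likelihood is evaluated per individual (individual covariates preclude
sufficient statistics), conditioning on release:

    log L_i = Σ_{t=f..l-1} [log φ_t + y_{t+1} log p_{t+1} + (1−y_{t+1}) log(1−p_{t+1})] + log χ_l,
    χ_T = 1,  χ_t = (1−φ_t) + φ_t (1−p_{t+1}) χ_{t+1},

where l is the last detection. An m-array multinomial formulation
(algebraically identical when no individual covariates are present; the
identity is asserted in the tests) provides a fast path for the
simulation-heavy GOF procedure.

**Optimization.** BFGS from zero coefficients with a batched
forward-difference gradient, in unit-RMS-scaled column space — raw covariate
scales (structural complexity ≈ 19–46) otherwise condition the surface badly
enough to stall quasi-Newton line searches. Jittered restarts engage only
while unconverged (capped at 25), and a simulated-annealing fallback
(`scipy.optimize.dual_annealing` in [−15, 15], then a BFGS polish) handles
the rare residual failures.

**Estimability and SEs.** The Hessian of the negative log-likelihood is
computed by central finite differences; its eigendecomposition gives the
estimable parameter count (eigenvalues above 1e-6 × the largest — the
threshold sits two decades above the finite-difference noise floor
(~1e-7 relative, measured) and four below the smallest genuinely estimable
eigenvalue in the tested designs), a pseudo-inverse covariance on the
estimable subspace, and delta-method SEs for real-scale estimates. In
time-dependent models only the product φ_{T−1}·p_T is identified; the rank
comes out 2T−3 for a single group and the confound is flagged
(`terminal_confounded`). For the full study-structure model
`{φ(t×cond)p(g×ice+complex×t)}` the engine reports its own numerical rank
(32 of 58 columns on default synthetic data); published analyses of this
model class report counts that depend on the software's counting convention,
so no specific value is forced.

## Model selection and overdispersion

QAICc = −2 log L/ĉ + 2K + 2K(K+1)/(n_eff − K − 1), with K the estimable
count and n_eff the number of released individuals (a contested convention;
configurable). Akaike weights follow from the usual Δ transformation.

Median-ĉ: the covariate-free global model (individual covariates are
excluded from GOF by convention) is fitted via the m-array route; the
statistic is deviance/df, with df = free multinomial cells − K held fixed
across replicates. For each candidate level c, `n_rep` datasets are
simulated from the fitted model with histories replicated in clusters of
size ≈ c (floor/ceil mixing for fractional c), refitted (warm-started), and
a binomial GLM of `1(stat_sim ≥ stat_obs)` on level is solved for the level
at probability ½; estimates outside the level range return the boundary
with a warning. Adjustment multiplies the covariance by ĉ (floored at 1,
with a warning below 1).

The estimator's per-dataset sampling noise is dominated by the observed
deviance statistic, sd ≈ sqrt(2/df) mapped through the level-response slope
(≈ 0.05–0.07 in ĉ units at study scale); calibration tests therefore judge
the median over independent datasets, and study-scale designs (T = 14,
three groups) are used to keep df large.

## Synthetic data

The generator emulates a boreal winter tracking study: 182 sculpin, 50
juvenile and 161 adult brown trout; 26 weekly occasions from 1 November;
lengths uniform within tagging bounds (> 70 mm, 110–150 mm, > 150 mm);
Fulton condition drawn per group (sculpin 1.10 ± 0.12, trout 1.00 ± 0.10 —
no within-group distribution is established for such studies, so a normal
is used and is configurable) and weight set exactly from the cube law, so
condition recovery is exact. Weekly survival is
logit φ = 4.6 + 1.6·K (≈ 0.998 at K = 1, matching high observed winter
survival); weekly detection is
logit p = a_g + b_g·ice_m + (−0.03)·(complex − 33) with a = {0.65, 0.60,
1.60} and b = {−6.2, −4.0, −1.7}, calibrated once so biweekly detection
spans ≈ 0.05–0.86 (sculpin), 0.2–0.86 (juvenile) and 0.85–0.97 (adult
trout) over the simulated ice range. Transient fractions are 4/8/25 % per
group, with spawning adults 2.1× as transient as spent ones (the group mean
preserved), and 5 % of adults shed their tag in week 1, leaving a
stationary tag whose readings jitter below the 0.5-m accuracy. Weather is a
sinusoidal seasonal curve (offset 2 °C, amplitude 9 °C, noise sd 3 °C) with
stochastic snowfall, 3 %/day settling, melt above freezing and three
shoveling dates — producing ≈ 25–35 cm of snow-ice by late January and a
maximum near 0.5–0.9 m, i.e. a severe but realistic boreal winter.

What the generator does **not** emulate: anchor ice and aufeis events,
2-D space use and home ranges (positions are 1-D along-stream with a
lateral-activity flag), temporary emigration, tag collisions, and
observer-varying accuracy. Passing recovery tests therefore demonstrates
correctness of the estimators under the stated generating process, not
robustness to these real-data phenomena.

## Numerical choices and degenerate inputs

Probabilities are clipped to [1e-12, 1−1e-12] inside log-likelihoods;
boundary estimates (e.g. p̂ → 1 when every fish is always detected) surface
as large |β| with the rank diagnostics flagging flat directions. Ties in
QAICc ranking are broken stably by input order. Empty tracking files,
zero-margin contingency tables, non-physical ice parameters
(k_snow ≥ k_ice) and histories not starting with the marking detection all
raise immediately with named errors. CV in return-rate summaries uses the
sample (ddof = 1) standard deviation; the max/min factor is undefined (NaN)
when an occasion had zero detections.

## Problem sizes in the shipped experiments

Simulation-based tests run at the scale of the emulated study: parameter
recovery uses 100 replicates of ~393 fish × 14 occasions; model selection
20 replicates × 4 candidates; median-ĉ calibration 100 replicates per level
at 5 levels (plus a 3-seed median check at 30 replicates). The acceptance
script runs one full pipeline (50 GOF replicates per level) in well under a
minute.

## Known limitations

- Real parameters near the [0, 1] boundary make Wald intervals and the
  delta method optimistic; profile likelihood is not implemented.
- The median-ĉ cluster construction is one standard choice among several;
  other overdispersion mechanisms (e.g. beta-binomial detection) would give
  a different level scale.
- The m-array fast path requires group-constant designs; time × individual
  covariate interactions always go through the slower individual route.
- No temporary-emigration or multi-state structure: transience is
  all-or-nothing at release.
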