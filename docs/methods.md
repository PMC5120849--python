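# Methods

## The model

`moorburn` models above-ground carbon dynamics of *Calluna vulgaris*–
dominated moorland managed by rotational prescribed burning, with
unplanned wildfires superimposed.  It has four layers:

1. **Biomass-accumulation curves.**  Stand biomass (t ha⁻¹) of each fuel
   fraction — live *Calluna* canopy and litter — is a function of stand
   age (years since the last fire).  Two forms are supported: a
   saturating Gompertz curve `y = a·exp(−b·cᵗ)` with asymptote `a`,
   shape `b ≥ 0` and annual rate `c ∈ (0, 1)`, and a log-linear power
   law `ln y = a + b·ln(t+1)` for sites where biomass keeps increasing
   over the observed range.  Four British sites are built in (Kerloch,
   Moor House, Howden, Dorset), each with one fitted curve per fraction
   and standard errors per parameter.  Howden's litter curve was fitted
   in g m⁻² and carries `unit_scale = 0.01` to express predictions in
   t ha⁻¹.

2. **Stand-age dynamics.**  The landscape is a vector of area
   proportions over age classes 1..A_max.  Under a rotation interval R
   (8–50 yr), stands younger than 8 years are ineligible; each eligible
   stand burns with annual probability `p = 1/(R−7)` and re-enters age
   class 1.  The 7 in the denominator counts the ineligible ages 1–7
   and is the unique choice for which the stationary annual burned area
   is exactly 1/R.  The chain's stationary distribution is closed-form:
   `π_k = 1/R` for k = 1..7 and `π_k = (1/R)(1−p)^(k−8)` for k ≥ 8.  A
   transient mode steps the vector year by year from any initial state
   (post-wildfire runs start with all area at age 1).

3. **Carbon accounting.**  Biomass converts to carbon with measured
   mass fractions (48.3% canopy, 49.0% litter).  The annual
   prescribed-burning loss at rotation R,

   `C_lossPBA = Σ_{k≥8} p·π_k·[CC_cal·C_cal(k) + CC_lit·C_lit(k)]`,

   weights combusted carbon by the age mixture of the stands actually
   burned (total burned area 1/R per year), using prescribed-fire
   combustion completeness CC of 71.4% (canopy) and 54.5% (litter).
   The whole-landscape stock `Σ_k π_k·C(k)` is exposed separately; the
   burned-stand convention (not the landscape mean) is the one that
   reproduces the published loss range, since young stands carry less
   fuel than the landscape average.

4. **200-year budgets.**  `C_lossPB200` simulates the transient chain
   from post-wildfire conditions; at deterministic wildfire years W,
   2W, …, 200 (end inclusive) the prescribed step is skipped, the fire
   consumes the full standing stock of every age class (CC = 100%) and
   the state resets to age 1.  The initiating year-0 fire is a boundary
   condition, not an emission.  The no-management baseline is
   `(200/W) ×` the combustible carbon of a 50-year-old stand.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| rotation interval R | grid 8–50 | yr | management variable under study |
| minimum burn age | 8 | yr | regulatory/ecological constraint, fixed |
| wildfire interval W | 50 / 100 / 200 | yr | scenario variable |
| horizon | 200 | yr | budget window (= 4 × 50-yr cycles) |
| A_max | 200 | yr | age-class truncation, absorbing top class |
| carbon fractions | 0.483 / 0.490 (sd 0.001) | — | canopy / litter |
| prescribed CC | 0.714 / 0.545 (sd 0.026 / 0.028) | — | canopy / litter |
| wildfire CC | 1.0 | — | full standing-stock consumption |
| age cap | 50 | yr | curves evaluated at min(age, 50) |

Curves are age-capped at 50 years because the underlying surveys span
stand ages 2–50; the cap is numerically inert for Gompertz curves
(already at their asymptote) and prevents unbounded extrapolation of
Howden's power laws.  A_max = 200 with an absorbing top class makes
truncation error negligible, since biomass is constant above age 50.

**Baseline CC choice.**  The wildfire-only baseline applies the
prescribed-fire CC means to the age-50 stocks rather than 100%
consumption: that accounting reproduces the published per-site baseline
integers to within ±1, whereas the literal 100% reading overshoots all
sites by ~30–80%.  The literal reading remains available
(`wildfire_cc="literal"`).  Within the 200-year transient runs,
superimposed wildfires do consume 100% of standing stock, which is the
combination that reproduces the published Moor House totals.

## Uncertainty

Uncertainty propagates by a parametric bootstrap (default 10,000
replicates, 95% percentile limits).  Each replicate independently
redraws every curve parameter from Normal(estimate, SE) restricted to
its feasible domain (a > 0, b ≥ 0, 0 < c < 1) by rejection sampling —
i.e. a truncated normal — plus carbon fractions and CC from their means
and sds (clipped to [0, 1]); draws are made once per replicate and
shared across age classes.  Covariances between parameters are not
reported for the built-in fits and are ignored.  Predicted biomass is
truncated at zero.

Two of the built-in litter fits (Moor House, Dorset) have
near-uninformative shape parameters (t values 0.16 and 1.42).  Because
the Gompertz map is nonlinear, the bootstrap mean then sits visibly off
the plug-in value at short rotations (up to ~25%), even though the
percentile interval brackets it.  This is a property of
parameter-resampling under weak identification, not a numerical defect;
all headline point estimates use mean parameters and are unaffected.

Combustion-completeness scenarios (20–100%) replace both fractions' CC
with the level; their bootstrap perturbs the level with a
Normal(level, 0.05) draw truncated to [0, 1].

## Fitting and model selection

The Gompertz form is fitted by bounded nonlinear least squares
(`scipy.optimize.curve_fit`), starting from `a` = max observed biomass,
`c` = 0.85 and `b` solved from the earliest observation, with restarts
over a rate grid 0.6–0.95 on non-convergence; SEs come from the
estimated covariance.  The log-linear form is ordinary least squares of
`ln y` on `ln(age+1)` (statsmodels).  The original study used
nonlinear mixed-effects models with treatment-within-block random
effects; this package fits fixed effects only, since the block
structure is not part of the published parameter set and the
fixed-effect estimates are what the downstream model consumes.

Form selection uses small-sample-corrected AIC on a common response
scale: the log-form Gaussian likelihood is mapped to the biomass scale
by the Jacobian of the log transform (`ll_orig = ll_log − Σ ln yᵢ`).
Ties select the Gompertz form.  The exact selection statistic used in
the original analysis is unstated; AICc is the standard choice at these
sample sizes.

## Synthetic surveys

`generate_survey` emulates a space-for-time survey: integer stand ages
drawn uniformly on 2–50 (or a user design), per-fraction means from the
site's true curves, additive Gaussian noise (sd 2 t ha⁻¹, truncated at
zero) for Gompertz fractions and multiplicative log-normal noise
(log-sd 0.1) for log-linear fractions, matching the scale on which each
form is fitted.  The default noise levels give fitted t statistics of
the same order as the published fits at n ≈ 200 per fraction.  The
generator omits spatial blocks, grazing treatments and measurement
error structure, so recovery tests demonstrate estimator correctness
under clean sampling rather than robustness to field-survey artefacts.

Zero additive noise at young Kerloch-like stands can produce exact-zero
biomass after truncation, which the log-scale fit correctly rejects;
model-comparison workflows on additive-noise data should either use
noise scales that keep biomass positive or drop zero observations.

## Numerical choices and edge cases

- Stationary-distribution residual tolerances: area sums to 1 within
  1e-9; the closed form matches the dominant eigenvector of the
  explicit transition matrix and is a fixed point of the annual step to
  1e-10.
- A wildfire year evaluates the stock at the pre-step ages (a stand
  born after the previous fire is age W at the next one), so a 50-year
  interval consumes age-50 stocks, consistent with the baseline recipe.
- `optimal_rotation` reports all rotations within 1.5% of the grid
  minimum (published optima are sometimes dual, e.g. shortest and
  longest); the grid of totals is returned alongside.
- Horizons that are not multiples of W are allowed with a warning;
  wildfires then occur at multiples of W up to the horizon.
- Total C loss is not perfectly monotone in wildfire frequency: at
  short rotations a wildfire reset suppresses 7 years of prescribed
  burning, which can slightly outweigh the young-stand wildfire pulse
  (largest inversion on the default grid ≈ 1.8%, Dorset R=8).

## Problem sizes

The analysis scripts and default test configuration use the full
rotation grid (4 sites × 43 rotations), 200-year transients, synthetic
surveys of 200 observations per fraction, 100-replicate coverage
experiments and bootstraps of 2,000–10,000 replicates; all complete in
seconds on one core.

## Known limitations

- Above-ground carbon only; peat and soil carbon are out of scope (the
  underlying management question treats winter prescribed burning as
  peat-neutral).
- Deterministic area-proportion dynamics: no spatially explicit
  patches, stochastic fire spread or partial wildfires.
- Deterministic wildfire timing; stochastic arrival processes are not
  modelled.
- Growth curves are stationary: no climate- or deposition-driven change
  in accumulation over the 200-year horizon.
- The Howden/Dorset 200-year totals are sensitive to the litter unit
  convention and transient phasing; the Moor House and Kerloch rows are
  the reliable quantitative anchors, and Howden/Dorset results should
  be read qualitatively (optima locations, monotone trends).
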