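# Methods

## Kinetic model

The package models a single-substrate batch fermentation with a
growth-associated product. Three coupled assumptions define it:

1. **Logistic biomass growth.** `dX/dt = μmax·X·(1 − X/Xmax)` with
   initial biomass X0. The explicit solution is evaluated in the
   overflow-safe form `X(t) = Xmax / (1 + ((Xmax−X0)/X0)·e^(−μmax t))`.
   The degenerate case X0 = Xmax is rejected rather than treated as a
   constant culture: a parameter set that cannot grow is almost always a
   data-entry error, and silently returning a flat curve would hide it.
2. **Luedeking–Piret product formation.** `dP/dt = α·dX/dt + β·X`.
   The closed-form layer assumes the growth-associated regime (β = 0),
   which integrates to `P = α·X + K`; the estimator layer fits the full
   two-term model and *tests* whether β = 0 is tenable (Gaden class,
   below), instead of assuming it.
3. **Substrate balance with maintenance.**
   `−dS/dt = (1/Yx/s)·dX/dt + (1/Yp/s)·dP/dt + Ke·X`. Substituting the
   logistic solution and integrating gives

   ```
   S(t) = S0 − (1/Yx/s + α/Yp/s)·(X(t) − X0)
             − Ke·(Xmax/μmax)·ln((Xmax − X0 + X0·e^(μmax t))/Xmax)
   ```

   The log term is computed with `logaddexp` so large μmax·t cannot
   overflow. Sign convention: S(t) decreases; consumption is reported as
   S0 − S(t). When parameters imply S < 0 before the requested time, the
   function warns with the exhaustion time (found by root bracketing)
   rather than clipping — only the simulator clips, because a simulated
   observation cannot be negative.

The growth-associated structure links the yields: Yp/s = α·Yx/s.
`yps_from_alpha` exposes this as a consistency check. The packaged
reference parameter set fails it (reported Yp/s 1.8736 vs α·Yx/s
1.8137); both printed values are retained and nothing is forced, since
choosing either silently would misrepresent the source data.

### Parameters (units, defaults)

| symbol | meaning | unit |
|---|---|---|
| X0, Xmax | initial / maximum biomass | g/l |
| μmax | maximum specific growth rate | 1/h |
| α, β | growth- / non-growth-associated product coefficients | g/g, g/(g·h) |
| K | integration constant of the product line | g/l |
| Yx/s, Yp/s | biomass / product yield on substrate | g/g |
| Ke | maintenance coefficient | g substrate/(g dry wt·h) |
| S0, P0 | initial substrate / product | g/l |

Time is hours everywhere inside the library; readers convert day columns
(`time_d`) at ingest (1 d = 24 h). Incubation time as a *design factor*
stays in days — coding is affine, so the unit cancels.

P0 and K are stored separately: the fitted product line need not pass
through (X0, P0), and conflating the two would bias simulated initial
conditions.

### Derived rate conventions

The source field reports peak-based summaries without formulas. The
conventions implemented are: volumetric rate Q = peak concentration ÷
time of that peak; specific rate q = Q ÷ peak biomass; Yp/x = peak
product ÷ peak biomass. On the reference validation series these
reproduce the reported Qp (0.0477 vs printed 0.0478), qp (0.0149), Qx
(0.019) and qs (0.0822). They do **not** reproduce the reported specific
biomass rate qx = 0.007 (the convention gives ≈ 0.006); no stated
convention we could find does, and the value is left unmatched rather
than reverse-engineered.

## Estimation

* `fit_logistic` — default is nonlinear least squares on concentrations
  (Levenberg–Marquardt via `scipy.optimize.curve_fit`; start values:
  first observation for X0, 1.05·max(X) for Xmax, the log-ratio slope
  for μmax). The alternative `linearized` method minimizes squared error
  of `ln(X/(Xmax−X))` against t, profiling Xmax on a 200-point grid
  between max(X) and 3·max(X) and polishing the best grid point with a
  bounded scalar search. Nonlinear SEs come from the curve_fit
  covariance; seeded simulations in the test suite confirm ±2 SE covers
  the generating μmax ≥ 90% of the time at 5% multiplicative noise.
* `fit_product_line` — OLS of P on X (slope α, intercept K).
* `fit_luedeking_piret` — central finite differences on interior points
  give dX/dt and dP/dt (no smoothing; deliberately simple and
  replaceable), then a no-intercept two-predictor OLS. Gaden class by a
  2·SE rule: class I if β is within 2 SE of zero while α is not, class
  III for the reverse, class II otherwise. The 2·SE threshold is this
  package's choice; the source literature asserts class I without a
  test.
* `fit_substrate` — holds growth and product parameters fixed, ties
  Yp/s = α·Yx/s, and fits (Yx/s, Ke) by bounded nonlinear least squares
  on the closed-form S(t). S0 is taken from the supplied parameter set
  (the balance is anchored at t = 0, which the data may not include).
* `percentage_error` / `compare_time_courses` — signed error
  `(experimental − calculated)/experimental × 100` per time point. Rows
  with experimental = 0 are dropped with a warning (the ratio is
  undefined there). Both the signed mean and the mean absolute error are
  reported, neither privileged: on the packaged five-row validation
  table they are 4.01%/7.21% (biomass) and 1.32%/2.94% (product), and
  the source's own printed averages (2.68%, 3.39%) match neither —
  presumably computed over unprinted time points. Display rounding is
  half-up to two decimals, matching how such tables are printed.

## Response surface

Factors code affinely: low → −1, center → 0, high → +1 (the convention
implied by "(low,high)" term labels in JMP-style reports). `fit_ols`
implements the closed-form normal equations with unbiased residual
variance, so SEs, t ratios, 95% CIs (estimate ± t(0.975, n−p)·SE),
whole-model F, and Type-III drop-one effect SS all follow from first
principles — and statsmodels serves as an *independent* cross-check in
the tests rather than the implementation. Exact fits (SSE = 0) floor
p-values at 1e-300 before the log/FDR transforms.

LogWorth is −log10(p). The FDR adjustment is Benjamini–Hochberg step-up
(via `statsmodels.stats.multitest`), chosen because the source names
only "FDR"; the published LogWorth values are −log10 of the published
raw p-values, so the tests anchor on the transform, not the adjustment.

`select_terms` is backward elimination: drop the highest-p non-intercept
term until all remaining p ≤ alpha_stay (default 0.05), ties broken by
term order, falling back to intercept + main effects when the starting
model is not estimable. Under a pure-noise response this keeps on
average ≲ 0.5 spurious terms; with three active terms at low noise it
recovers all three in > 95% of seeded replicates.

`optimize_surface` is an exhaustive grid search over the coded cube
(default 11 points per factor), deterministic with first-index
tie-breaking. For five factors at 21 points that is 4·10⁶ predictions —
still well under a second — so no gradient method is needed and
multimodal quadrics cannot trap it.

### The reference-design reproduction

The packaged design table holds the 22 runs its source printed; the
design called for 23, and one run is absent. The source is also
internally inconsistent about which interaction terms survived model
selection (its narrative and ANOVA say temperature×agitation; its
estimate table says agitation×time), so both term sets ship as named
variants and every reproduction runs under both. Neither reproduces the
published intercept (5.0552) or RMSE (0.852): the printed runs give
intercept 5.3884 and RMSE 1.328/1.307, with a whole-model p ≈ 0.31–0.36.
The linear-term estimates land close to the published ones (X1 −0.435
vs −0.454; X2 0.601 vs 0.521) while interactions and quadratics do not —
the signature of a missing/typo-damaged run rather than a different
model. The package therefore reports what the printed data support and
flags the discrepancy instead of asserting the published values; the
fit's internal identities (F = t², CI arithmetic, SS decomposition) are
enforced unconditionally.

## Synthetic-data generators

`simulate_time_course` evaluates the closed forms on an hour grid
(default: the study's sampling days 3, 5, 7, 9, 11, 13 × 24 h), with the
product series anchored at P0 (P = P0 + α·(X − X0)) and the substrate
series clipped at zero with a truncation warning. Concentration noise is
multiplicative lognormal, `v·exp(σz − σ²/2)` with z ~ N(0,1) — strictly
positive and mean-preserving — at a default relative scale of 5%,
a typical replicate CV for dry-weight and gravimetric product assays.
`simulate_design` evaluates a coded quadratic surface on the reference
22-run layout (or any user layout) and adds N(0, σ) response noise,
default σ = 0.852 g/l, the residual scale the reference analysis
reports; the true replicate error of that study is unknown, so this
default is explicitly a plausibility choice, not an estimate. All
randomness flows through one `numpy.random.default_rng(seed)` per call;
identical seeds give byte-identical output, and writers stamp the seed
into file headers.

What the generators deliberately do **not** emulate: death/decline
phases (the logistic curve is monotone, while real biomass drops after
the peak — visible in the reference validation series), lag phases,
autocorrelated within-run errors, heteroscedastic assay floors, and any
wet-lab surface-activity measurement. Passing the round-trip tests
therefore shows the estimators are correct *under the model's own
assumptions*; it does not certify them against decline-phase data, where
the logistic fit will systematically overshoot late biomass.

## Numerical choices and test problem sizes

* Closed forms are verified against a vectorized classical RK4
  integration of the ODE system (step 0.01 h over [0, 264] h) to 1e-6
  relative on hourly grids, across 100 random parameter sets.
* Simulation studies use 200 seeded replicates on 20-point grids —
  enough for median/coverage statistics with Monte-Carlo error well
  inside the asserted margins, and small enough that the whole suite
  runs in well under a minute of simulation time.
* Substrate-fit bias is asserted as median bias (≤ 10%) because the
  maintenance coefficient of the reference set is small relative to
  realistic noise; individual estimates can hit the non-negativity
  bound, but the estimator is median-unbiased.
* Rounding for display is half-up (`decimal`), not banker's; numbers are
  rounded only at presentation.

## Known limitations

* Single substrate, batch only: no fed-batch, Monod, Gompertz, or
  temperature/pH dependence inside the kinetic model (environmental
  factors live exclusively in the response surface).
* Kinetic uncertainties are asymptotic (curve-fit covariance); no
  bootstrap or Bayesian intervals.
* The finite-difference Luedeking–Piret fit is noise-sensitive on
  sparse grids; with fewer than ~10 points the Gaden classification
  should be read as indicative.
* The reference fixtures carry their source's internal inconsistencies
  verbatim (see `src/fermkin/data/README.md`); analyses on them report,
  rather than resolve, those conflicts.
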