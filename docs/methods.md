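# Methods

## The experimental setting

A batch shake-flask fermentation of a marine actinomycete produces a
bioactive metabolite whose concentration is not measured directly; its
activity is read as the diameter (mm) of the inhibition zone it clears
against an indicator organism in an agar-diffusion assay.  Two questions are
addressed statistically: *which culture conditions maximize the zone*
(design-of-experiments / response-surface half) and *how do biomass,
substrate and product evolve in time* (unstructured-kinetics half).

## Face-centered central composite design

For n factors the design is the 2ⁿ factorial cube at coded ±1, 2n axial
points on the face centers (axial distance fixed at 1), and n_c replicated
center points: N = 2ⁿ + 2n + n_c runs.  With the study's five factors and
eight center replicates, N = 50.  The face-centered variant is used because
every factor is run at exactly three levels, which is what the published
level tables contain; rotatable axial distances are out of scope.  Coding is
the standard linear map `coded = (actual − center)/half-range`; with three
equispaced levels this is the only affine map sending low/center/high to
−1/0/+1.  Center points are appended after the factorial and axial blocks in
canonical order; run-order randomization is opt-in and seeded so that every
design is reproducible.

The packaged factor set carries one wrinkle of the source study: the level
table gives temperature levels 25/30/35 °C while the narrative uses
20/25/30 °C.  Both variants are packaged (`factors`, `factors_narrative`);
the design code takes whatever `FactorSpec` the user supplies and does not
arbitrate.

## Second-order response-surface model

Each response is fitted on coded factors with the full quadratic polynomial
(21 terms for five factors), by ordinary least squares through statsmodels.
Fitting on coded rather than actual units keeps the published coefficient
sets directly usable and the model matrix well-conditioned.  Reported
diagnostics:

* **Sequential model comparison** over nested tiers mean → linear → 2FI →
  quadratic → cubic.  Incremental F = (ΔSS/Δdf) / MS_residual of the larger
  model.  On a three-level design the pure cubic columns satisfy x³ = x
  pointwise and are aliased with the linear terms; the cubic tier therefore
  keeps only the estimable linear×quadratic cross terms, pruned by a greedy
  left-to-right rank scan (tolerance 1e-9 relative).
* **ANOVA** in the layout response-surface software prints: a model row,
  one row per term with partial (type III) sums of squares SS_j = t_j²·MS_res,
  the residual row, and the lack-of-fit/pure-error split.  Pure error comes
  from groups of runs with exactly equal coded coordinates (the eight center
  replicates, in the canonical design); with no replicates the lack-of-fit
  rows are reported as not computable, and with zero pure error the F ratio
  is flagged undefined rather than infinite.
* **Fit summary**: R², adjusted R², predicted R² from PRESS via the
  hat-matrix shortcut PRESS = Σ(eᵢ/(1−hᵢ))² (a brute-force leave-one-out loop
  is used only as a test oracle), standard deviation √MS_res, CV% =
  100·√MS_res/ȳ, RMSE = √(SS_res/n), and AAD% defined as the mean absolute
  relative deviation in percent (the abbreviation is used without a formula
  in the field; this is the standard reading).  A response containing zeros
  makes AAD% undefined and it is reported as missing.
* **Degenerate inputs**: a constant response collapses to an intercept-only
  model with R² reported as 0 and a warning; fewer runs than terms is an
  error; exactly collinear model columns raise an error naming the dependent
  columns.

**Optimization over the cube.**  The stationary point solves ∇Y = 0; if the
Hessian is negative definite and the point lies in [−1,1]ⁿ it is returned as
an interior maximum.  Otherwise the quadratic is maximized by multi-start
L-BFGS-B (32 deterministic seeded starts, analytic gradient) and classified
as a boundary maximum or saddle-adjusted solution; ties within 1e-9 of the
best value break to the lexicographically smallest point.

**p-values** come from the F distribution with the row's degrees of freedom;
no multiplicity adjustment is applied (none is conventional in this layout).

## Unstructured kinetics

Time is in days throughout (growth rates in day⁻¹, 11-day fermentations).
The model family, with X biomass (g/L), S substrate (g/L), P the
inhibition-zone proxy (mm):

* logistic growth dX/dt = µₘₐₓX(1 − X/Xₘ), closed form
  X(t) = X₀e^{µt}/(1 − (X₀/Xₘ)(1 − e^{µt}));
* Luedeking–Piret product formation dP/dt = α·dX/dt + βX, closed form
  P(t) = P₀ + α(X(t) − X₀) + (βXₘ/µₘₐₓ)·ln[1 − (X₀/Xₘ)(1 − e^{µt})];
* modified Luedeking–Piret substrate consumption −dS/dt = γ·dX/dt + ηX,
  closed form S(t) = S₀ − γ(X(t) − X₀) − (ηXₘ/µₘₐₓ)·ln[…].

The logarithm's argument equals 1 at t = 0 and grows with t, so the log term
is non-negative: the **minus** sign in S(t) is required for substrate to
decrease and is what integrating the rate equation gives (closed forms are
verified against adaptive ODE integration to 1e-6 relative in the tests).
All three forms are evaluated in an overflow-safe parameterisation
(sigmoid form for X; ln-term as µt + ln(X₀/Xₘ) + ln1p(·)), valid to
arbitrarily large µt.

Defaults: P₀ = 0 mm (no inhibition zone at inoculation), S₀ = 20 g/L (2%
w/v sucrose, the optimal medium), evaluation/harvest time 11 days (the end
of the stationary phase, when the maximum zone is recorded), stationary-phase
window days 5–11 (user-overridable) for slope-based estimates of the
non-growth-associated constants η = −(dS/dt)ₛₜₐₜ/Xₘₐₓ and
β = (dP/dt)ₛₜₐₜ/Xₘₐₓ.

**Estimation** is sequential, mirroring the equations' structure: the
logistic parameters are fitted first by nonlinear least squares in log-space
over (µₘₐₓ, X₀, Xₘ−X₀) — which enforces positivity and X₀ < Xₘ without
explicit constraints — with a deterministic 5-start multi-start and
parameter tolerance 1e-10.  Conditional on the growth fit, the product and
substrate models are *linear* in (α, β) and (γ, η); their non-negative
least-squares optima are therefore computed exactly by NNLS rather than by
iterative search, with the intercept fixed at the first observation of the
series (or at a user-supplied known value such as the medium recipe).  A
joint simultaneous refinement over all series, scaled by each series'
dispersion, is available as an option but is not the default.  A constant
biomass series makes the logistic parameters unidentifiable and raises a
convergence error with diagnostics.

## Synthetic data and what the tests show

`gen_ccd_responses` adds i.i.d. homoscedastic Gaussian noise to a known
quadratic surface — exactly the error structure OLS assumes — and
`gen_timecourses` adds per-series Gaussian noise (absolute, or proportional
to the instantaneous signal) to the closed-form trajectories, clipping
biomass at zero.  All randomness flows from one seed through spawned
`SeedSequence` children.

Study conditions frozen in the test suite:

* surface recovery: the packaged five-factor, 50-run design with noise
  SD 0.1 mm (the order of the published replicate scatter); each coefficient
  is recovered within 3 estimated standard errors in ≥95% of 200 replicates;
* kinetic recovery: 13 daily samples with 2% noise — proportional per point
  for biomass (a relative instrument error keeps small early readings
  positive, as the fitter requires), and 2% of each series' dynamic range for
  substrate and product.  The substrate baseline (20 g/L, of which only
  ≈5 g/L is consumed) is deliberately excluded from the noise scale: an
  information analysis shows that with noise proportional to the full
  baseline the growth-associated coefficient γ is not recoverable to 15% by
  any estimator, so that regime would test nothing about the code.  With
  intercepts fixed at the known medium values, all seven parameters are
  recovered with median relative error below 15% over 50 seeds (γ ≈ 10%,
  β ≈ 12%, the rest ≤ 5%).

What passing these studies does **not** show: real assay noise is not
Gaussian or homoscedastic (zone diameters are read to the half-millimeter),
real replicate runs drift between days, biomass is not exactly logistic, and
the per-organism product fits share one growth curve by construction.  The
synthetic studies validate the estimators against their own assumptions,
not the biology.

## Known limitations

* Only face-centered composite designs are generated (no rotatable or
  inscribed variants, Box–Behnken, fractional cores, or blocking).
* Multi-response (desirability) optimization and Box–Cox transforms are not
  implemented; optima are per-response.
* The kinetic family excludes substrate/product inhibition terms and
  structured/segregated models; it targets batch mode only.
* Printed historical ANOVA/R² values from the source study are not
  recomputable because the underlying raw tables are not reliably available;
  the package instead verifies the self-consistent quantities (closed forms,
  worked-example predictions, stationary-phase identities) and validates the
  estimators on synthetic data.
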