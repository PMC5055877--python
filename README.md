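# fermopt

Statistical optimization and kinetic modelling of antimicrobial-metabolite
fermentation.

A marine actinomycete strain produces a bioactive metabolite whose potency is
read out as the zone of inhibition (mm) it clears against indicator
organisms (*S. aureus*, *B. subtilis*, *X. campestris*, *P. aeruginosa*,
*C. albicans*).  `fermopt` implements the two statistical halves of such a
culture-optimization study:

1. **Response-surface optimization.**  Five culture variables — incubation
   time (days), pH, temperature (°C), sucrose (% w/v) and soya peptone
   (% w/v) — are screened with a face-centered central composite design
   (N = 2⁵ + 2·5 + 8 = 50 runs) and each organism's inhibition zone is
   modelled by the second-order polynomial on coded factors

   Y = β₀ + Σᵢ βᵢXᵢ + Σᵢ<ⱼ βᵢⱼXᵢXⱼ + Σᵢ βᵢᵢXᵢ²,

   fitted by OLS with the full diagnostic suite (sequential model comparison,
   per-term ANOVA with the lack-of-fit/pure-error split, R², adjusted R²,
   predicted R² via PRESS, CV%, RMSE, AAD%) and maximized over the coded cube.

2. **Unstructured batch kinetics.**  Biomass follows the logistic law
   dX/dt = µₘₐₓX(1 − X/Xₘ); the product proxy follows Luedeking–Piret
   dP/dt = α·dX/dt + βX (α growth-associated, β non-growth-associated), and
   the limiting substrate the modified form −dS/dt = γ·dX/dt + ηX.
   Substituting the logistic solution gives closed forms for X(t), S(t), P(t),
   which the package both simulates and fits (bounded nonlinear least squares
   for growth; exact non-negative least squares for the conditional α/β and
   γ/η subproblems).

The package is organized as sklearn-style estimators
(`ResponseSurfaceRegressor`, `LogisticGrowthModel`, `LuedekingPiretProduct`,
`LuedekingPiretSubstrate`) with functional wrappers, plus a synthetic-data
module that carries the published study's ground-truth fixtures (factor
levels, the five fitted coefficient sets, the kinetic parameter table) and a
`fermopt` command-line tool (`design`, `simulate`, `fit-rsm`, `fit-kinetics`,
`report`).

## Worked example

```python
import numpy as np
import fermopt as f

fx = f.study_fixtures()

# --- response surface: simulate a noisy 50-run experiment and refit it
design = f.generate_ccfd(fx["design_spec"])
truth = f.SurfaceTruth(model=fx["models"]["saureus"], noise_sd=0.1, seed=7)
y = f.gen_ccd_responses(design, truth)
est = f.ResponseSurfaceRegressor().fit(design, y)
s = est.summary_
print(f"R2 = {s.r_squared:.4f}  adj R2 = {s.adj_r_squared:.4f}  "
      f"pred R2 = {s.pred_r_squared:.4f}  CV% = {s.cv_percent:.2f}")
opt = est.optimum()
print("optimum:", opt.classification, opt.point.round(3), "->", round(opt.value, 3), "mm")

# --- kinetics: simulate a 13-day fermentation and refit the model family
p = fx["kinetics"]["xcampestris"]
t = np.arange(0.0, 13.0)
tc = f.gen_timecourses(f.KineticTruth(params=p, times=t, proportional=True,
                                      noise_sd_x=0.02, noise_sd_s=0.005,
                                      noise_sd_p=0.02, seed=7))
fit = f.fit_kinetics(tc)
print(f"mu_max = {fit.params.mu_max:.4f}/day  Xm = {fit.params.xm:.4f} g/L  "
      f"alpha = {fit.params.alpha:.2f} mm/g  beta = {fit.params.beta:.3f} mm/(g d)")
print("P(11 d) =", round(f.lilp_product(11.0, fit.params), 2), "mm")
```

prints

```
R2 = 0.9979  adj R2 = 0.9965  pred R2 = 0.9951  CV% = 0.44
optimum: interior stationary max [ 0.04  -0.707  0.165  0.087  0.059] -> 21.018 mm
mu_max = 0.7298/day  Xm = 0.2256 g/L  alpha = 123.37 mm/g  beta = 4.872 mm/(g d)
P(11 d) = 33.29 mm
```

The surface fit recovers the generating model almost perfectly (R² ≈ 0.998
against 0.1 mm of measurement noise) and places the optimum just inside the
cube — slightly below the center pH, at mid-range of everything else —
predicting a ~21 mm zone.  The kinetic refit recovers the generating growth
rate (0.7431 day⁻¹ truth) and Luedeking–Piret coefficients (α = 124.62,
β = 4.4248 truth) from 2% measurement noise, and the model-fitted zone at the
day-11 harvest, 33.3 mm, sits next to the noise-free closed-form value of
33.08 mm.

The same pipeline is available from the shell:

```sh
fermopt report --seed 1 --out-dir out/   # simulate -> fit-rsm -> fit-kinetics
```

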