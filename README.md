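# phenoloop

Closed-loop analysis of dose–stress plant phenotyping experiments.

Automated phenotyping platforms grow small model plants (e.g.
*Brachypodium distachyon*) in sterile chambers, image roots and shoots every
other day, and record harvest fresh weights. `phenoloop` implements the
analysis half of such a platform's experiment loop for a copper-stress style
study design:

1. **Simulate** virtual experiments with the statistical structure the
   analysis assumes — logistic latent growth whose rate is inhibited
   dose-dependently after an amendment day, per-day root/shoot pixel counts
   with multiplicative noise, a saturating shoot-health decline, harvest
   fresh weights, and optional two-endmember hyperspectral cubes.
2. **Model** phenotype endpoints vs dose with a Gaussian process
   (stationary ARD kernel, constant fitted noise, seeded stochastic
   hyperparameter search + local refinement), reporting posterior mean and
   standard deviations (with and without noise) on a 0–500 µM grid.
3. **Design** the next round by variance-acquisition Bayesian optimization:
   greedily pick the doses of maximal posterior epistemic variance, with a
   minimum separation.
4. **Evaluate** models by 5 × 6-fold dose-stratified cross-validation with
   range-normalized RMSE (NRMSE) and Gaussian CRPS, percentile-bootstrap
   confidence intervals, and scrambled-target null ratios; compare variants
   by t-test / ANOVA + Tukey HSD with percent improvements computed from
   unrounded means.
5. **Analyze time series**: Savitzky–Golay smoothing + spline interpolation
   to daily series (days 4–25), per-day dose correlations with bootstrap
   CIs, per-day ANOVA/Tukey screens vs the 0 µM control with
   Benjamini–Hochberg correction, and UMAP + HDBSCAN trajectory clustering
   of the days 11–25 feature block.

The key quantities, in the field's notation:

- vegetation index per pixel: `NDVI = (m750 − m550) / (m750 + m550 + 2·mmin)`
  with `m750`, `m550` mean reflectances over 740–750 / 540–560 nm and `mmin`
  the per-pixel minimum over the retained 430–800 nm range;
- shoot size: `√(top² + side² + front²)` over the three view pixel counts;
- health fraction: share of pixels whose nonnegative projection onto the
  "green" atom of a two-atom spectral dictionary dominates;
- `NRMSE = RMSE / range(test targets)`;
  `CRPS(µ,σ;y) = σ[z(2Φ(z)−1) + 2φ(z) − 1/√π]`, `z=(y−µ)/σ`;
- null ratio: `NRMSE(real) / NRMSE(y-scrambled)` on the full dataset.

## Worked example

```python
import numpy as np
from phenoloop import (DoseDesign, GPConfig, AcquisitionRequest,
                       simulate_experiment, fit_gp, propose_doses)
from phenoloop.loop import harvest_table

study = simulate_experiment(DoseDesign.round1(), seed=1)   # 7 doses x 6 reps
h = harvest_table(study)
model = fit_gp(h.dose_uM.to_numpy(), h.fw_root.to_numpy(),
               GPConfig(max_iterations=2000, seed=3))
print(propose_doses(model, AcquisitionRequest()))
ps = model.posterior_summary()
print(float(ps.grid[np.argmax(ps.mean <= 0.5 * ps.mean[0])]))
```

prints

```
[360.0, 380.0, 400.0, 420.0, 440.0]
43.0
```

The five proposals are the doses of maximal posterior variance (at least
20 µM apart) — here the sparsely sampled high-dose region; `43.0` is the
dose at which the fitted posterior mean crosses 50 % of the 0 µM
prediction, close to the generator's size-level EC50 of 38.7 µM for roots.

The full two-round loop (simulate → fit → propose → simulate → evaluate →
compare → trajectory analytics) is one call or one command:

```bash
phenoloop loop --seed 7 --out runs/demo
```

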