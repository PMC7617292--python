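# medgrowth

**Latent-profile moderated mediation of depressive-symptom trajectories in
two-arm longitudinal trials.**

Maintenance antidepressants (m-ADM) and mindfulness-based cognitive therapy
with tapering support (MBCT-TS) are both used to manage recurrent
depression, but they plausibly work through different mechanisms and for
different people. A standing question is whether gains in mindfulness
skills are the mechanism through which MBCT-TS changes the course of
residual depressive symptoms — and whether that mechanism is stronger for
people with a more severe clinical history. `medgrowth` implements the
full analysis chain needed to ask that question of a two-arm trial with
repeated Beck Depression Inventory-II (BDI-II) assessments:

1. **Latent profile analysis (LPA)** — a finite mixture over a mixed
   continuous/binary battery of baseline severity indicators (residual
   symptoms, clinical history, rumination, affect, social factors),
   estimated by EM with casewise handling of missing entries, with
   AIC/BIC/entropy model selection and distal-variable validation.
2. **Latent growth curve models (LGCM)** — intercept/linear/quadratic
   trajectory shapes for BDI-II at months 0, 3, 9, 12, 18, 24, with
   homoscedastic, heteroscedastic, or heteroscedastic lag-correlated
   (AR-type) residuals, fitted by full-information maximum likelihood
   (FIML) under missingness at random, and compared by information
   criteria and likelihood-ratio tests.
3. **Moderated mediation** — per latent profile *g*:

   ```
   ΔFFMQ  =  a0_g + a_g·arm + e_M                     (a-path)
   η₁     =  β0_g + b·ΔFFMQ + c′·arm + ζ₁             (b-, c′-paths)
   BDI_t  =  η₀ + η₁·λ_t + η₂·λ_t² + ε_t
   ```

   where ΔFFMQ is the pre→post change in the Five Facet Mindfulness
   Questionnaire total and η₁ is the latent linear slope of symptom
   change (points/month). Conditional indirect effects are the products
   IE_g = a_g·b; the **index of moderated mediation** is IE₂ − IE₁.
   Inference for products uses the nonparametric percentile bootstrap
   (case resampling stratified by arm), and a sensitivity refit adjusts
   both equations for home-practice level and antidepressant
   discontinuation.

Because individual-level data from such trials are typically not
deposited, the package ships a calibrated synthetic-trial generator
(`medgrowth.simulate`) that reproduces the statistical structure the
chain assumes — two latent severity profiles, profile-dependent a-paths,
a quadratic latent trajectory with heteroscedastic correlated residuals,
and per-wave missingness at realistic retention rates — so every stage is
testable end to end.

## Worked example

```python
import medgrowth as mg

data = mg.generate_dataset(mg.default_config(seed=1))   # n = 424

ind = mg.indicator_frame(data)
selection = mg.select_profiles(ind, K_max=3, seed=1)
print(selection[["K", "loglik", "bic", "entropy_rel", "best_bic"]]
      .round(1).to_string(index=False))

lpa = mg.fit_lpa(ind, K=2, seed=1)
labels = mg.modal_assignment(lpa.posteriors)

spec = mg.MedModSpec(bootstrap_draws=400, bootstrap_seed=1)
fit = mg.fit_medmod(data, labels, spec, seed=1)
boot = mg.bootstrap_ci(data, labels, spec)
print(f"a-paths by profile: {fit.a_g.round(2)}")
print(f"conditional indirect effects: {fit.ie_g.round(2)}")
print(f"index of moderated mediation: {fit.index:.2f}  "
      f"95% CI ({boot.ci['index'][0]:.2f}, {boot.ci['index'][1]:.2f})")
```

prints

```
 K   loglik     bic  entropy_rel  best_bic
 1 -21228.7 42681.2          1.0     False
 2 -21026.6 42398.0          0.8      True
 3 -21002.1 42470.0          0.8     False
a-paths by profile: [ 6.07 12.88]
conditional indirect effects: [-0.19 -0.4 ]
index of moderated mediation: -0.21  95% CI (-0.29, -0.15)
```

Reading the output: BIC selects two baseline severity profiles. The
trial-arm effect on mindfulness-skill change is about twice as large in
the higher-severity profile (12.9 vs 6.1 FFMQ points). Multiplying each
a-path by the shared b-path gives the conditional indirect effects in
BDI-II points/month; their difference, the index of moderated mediation,
is negative with a bootstrap CI excluding zero — the mediated benefit of
the mindfulness arm on the symptom slope is credibly larger for the
higher-severity profile. Over 24 months the severe-profile indirect
effect projects to `mg.projected_change(fit.ie_g[1], 24) ≈ −9.6` BDI-II
points.

The same chain is available from a shell:

```bash
medgrowth pipeline --seed 1 --boot-draws 1000 --out run1/
medgrowth simulate --seed 2 --n 424 --out trial.csv
medgrowth mediate trial.csv --boot-draws 1000 --seed 2 --out table.csv
```

`pipeline` writes the selection table, profile z-score figure, growth
model comparison, a Table-2-style mediation summary (point estimates,
bootstrap CIs, R² per equation), the covariate-adjusted sensitivity
rerun, and a JSON manifest recording seeds, draw counts, timings and
convergence codes.

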