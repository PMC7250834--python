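# borealdeer

Dynamic occupancy and multi-scale persistence modelling for camera-trap
surveys, built around the spatiotemporal distribution dynamics of invasive
white-tailed deer (*Odocoileus virginianus*) in the western boreal forest.

Camera-trap grids produce serial detection/non-detection records at fixed
sites. Two complementary questions arise from such data:

1. **Time** — how does the occupied fraction of the landscape change from
   season to season, and how strongly do severe winters contract it?
2. **Space** — which landscape features, and measured at what radius
   around a site (the *scale of effect*), best explain how persistently a
   site is used?

`borealdeer` implements both analyses as a tested, reusable pipeline,
together with a synthetic-data generator that emulates the study design
they were developed for: 62 cameras on a stratified grid with a minimum
2-km spacing, surveyed monthly for 12 three-month seasons (36 surveys per
site), spanning one mild, one severe and one moderately severe winter.

## Models

**Dynamic occupancy.** Each site follows a two-state hidden Markov chain.
With ψ₁ the initial occupancy probability, an occupied site goes locally
extinct between seasons *t* and *t*+1 with probability ε_t, an empty site
is colonized with probability γ_t, and given occupancy each monthly survey
*j* of season *t* detects the species with probability p_t,j. The
likelihood of a site's detection history is computed by the forward
algorithm over the latent chain; missing surveys drop their Bernoulli
factor. Parameters are estimated by maximum likelihood on the logit scale,
competing structures (ε, γ, p constant or time-varying) are ranked by AIC
weights, and the fit yields derived seasonal quantities:

- occupancy ψ_{t+1} = ψ_t (1 − ε_t) + (1 − ψ_t) γ_t,
- spatial growth rate λ_t = ψ_{t+1} / ψ_t (1 = stable distribution),
- probability of false absence PFA_t = Π_j (1 − p_t,j),

with delta-method standard errors propagated through the recursion.

**Persistence SDM.** The per-site count of survey months with a detection
(0–36 annually, 0–9 for the January–March winters) is modelled as a
binomial GLM (logit link) on landscape covariates: percent cover of
landcover classes and densities (km/km²) of linear disturbance features,
summarised in circular buffers. Covariates are extracted at 20 radii from
250 m to 5000 m; per radius, sparse classes are combined, correlated
variables (|r| > 0.7) pruned, survivors standardized, the full model
reduced by backward stepwise-AIC, and the scale of effect chosen by AIC
weight across radii. The winning model is pruned post hoc by Wald p-value
and checked with deviance explained, overdispersion, seeded 10-fold
cross-validation and Moran's I of residuals (inverse-distance weights,
null expectation −1/(n−1)).

## Worked example

```python
from borealdeer import (SimulationConfig, simulate_study,
                        DynamicOccupancyModel, OccupancyModelSpec)

cfg = SimulationConfig()           # 62 sites, 12 seasons x 3 surveys
study = simulate_study(cfg, seed=3)
model = DynamicOccupancyModel(
    study["history"], cfg.design,
    OccupancyModelSpec(epsilon="by-season", gamma="by-season", p="constant"),
)
fit = model.fit(n_starts=2, seed=0)
print(fit.trajectory().to_frame().round(3).head(6).to_string())
```

```
   season              label    psi  se_psi  lambda  se_lambda    pfa
0       1                rut  0.939   0.031   0.948      0.055  0.005
1       2           post-rut  0.891   0.040   1.091      0.057  0.005
2       3  pre/early-fawning  0.972   0.023   1.000      0.033  0.005
3       4       post-fawning  0.972   0.023   0.983      0.037  0.005
4       5                rut  0.956   0.027   0.593      0.069  0.005
5       6           post-rut  0.567   0.063   1.600      0.187  0.005
```

Season 6 is the synthetic severe winter: occupancy collapses from 0.96 to
0.57 (λ = 0.59, a ~40% contraction) and rebounds the following spring
(λ = 1.60) — the dynamic the model is designed to measure. `fit.summary()`
prints per-parameter estimates with SEs, flagging boundary estimates
(e.g. colonization pinned at 1.0, SE printed as 0.00).

The same machinery runs from the shell:

```sh
borealdeer simulate      --config cfg.yaml --out-dir out   # synthetic study
borealdeer fit-occupancy --config cfg.yaml --out-dir out   # AIC table + trajectory
borealdeer scan-scales   --config cfg.yaml --out-dir out   # scale-of-effect scan
borealdeer fit-sdm       --config cfg.yaml --out-dir out   # coefficients + diagnostics
```

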