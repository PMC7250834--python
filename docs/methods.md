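# Methods

## The temporal model

The dynamic occupancy model treats each camera site as an independent
two-state hidden Markov chain observed through imperfect detection. The
latent state z_{i,t} ∈ {unoccupied, occupied} evolves across primary
seasons with initial distribution (1 − ψ₁, ψ₁) and transition matrix

```
            to empty      to occupied
occupied    ε_t           1 − ε_t
empty       1 − γ_t       γ_t
```

Within season *t*, survey *j* is a Bernoulli trial with success
probability p_{t,j} given occupancy, and a structural zero otherwise. The
site likelihood is a forward recursion over seasons; the emission for an
unoccupied season is 1 when all non-missing surveys are 0 and 0 otherwise,
and a fully missing season contributes emission 1 for both states (the
chain simply propagates). Missing surveys drop their Bernoulli factor
exactly — no imputation.

Because deer range widely within a three-month season, seasonal occupancy
is interpreted as site *use*: within-season zeros at a used site reflect
movement through the camera's detection zone and are absorbed by p. This
is an interpretive relaxation of the closure assumption, not a change to
the likelihood. ψ, ε and γ are spatially homogeneous (no site covariates
in this stage), so ψ_t estimates the landscape-average proportion of area
used in season *t*.

### Estimation and numerics

All probabilities are optimized on the logit scale with L-BFGS-B
(finite-difference gradients, objective tolerance 1e−8 by default, 1e−10
in the recovery studies). Logits are clamped to |x| ≤ 15, which allows the
optimizer to express genuine boundary solutions (colonization saturating
at 1 after a winter crash) without overflow; an estimate with |logit| > 10
is flagged as a boundary estimate, reported at its probability-scale value
with SE printed as 0.00 and excluded from the Hessian inversion. This
reproduces, rather than avoids, the border-condition behaviour that
seasonal colonization estimates show when nearly every empty site is
recolonized.

Each fit uses one start at empirical detection/occupancy frequencies plus
`n_starts` random N(0, 1.5²) logit draws (default 10; the likelihood
surface is mildly multimodal only in small, sparse data sets). Standard
errors come from the inverse numerical Hessian at the optimum;
probability-scale SEs and the SEs of the derived ψ_t and λ_t trajectory
use the delta method with central finite differences through the
recursion. λ_t is reported as missing when ψ_t = 0. Site histories are
deduplicated to unique rows with multiplicities before evaluation, which
makes large simulated fits cheap.

Exactness of the forward recursion is guarded by an independent oracle:
exhaustive enumeration over all 2^T latent state sequences (refused for
T > 12), compared to 1e−10 in the tests, plus the law-of-total-probability
check that site likelihoods over all possible histories sum to 1.

### Model ranking

Competing structures — ε and γ constant or seasonal, p constant, seasonal
or per-survey — are compared by AIC = −2 logL + 2K, normalised Akaike
weights w_i = exp(−Δ_i/2)/Σ exp(−Δ_j/2), and pairwise evidence ratios
w_i/w_j. Ranking requires all fits to share a data fingerprint (hash of
the detection matrix), so accidental cross-data comparisons fail loudly.

## The spatial model

Per-site persistence is the count of survey months with ≥ 1 detection out
of the non-missing months (at most 36 annually; at most 9 for the three
January–March winters), modelled as binomial with a logit link via IRLS
(statsmodels GLM). Per-term inference is the Wald statistic β/SE referred
to the standard normal — the figure GLM software prints in its t-value
column for binomial families.

Covariate preparation at each radius, in order: (1) percent-cover classes
whose landscape-wide mean cover is below 2% (configurable; the natural
range is 1–2%) are summed into one combination variable; (2) while any
pair of retained variables has |r| > 0.7, the member of the worst pair
with the larger mean |r| to all other variables is dropped (a
deterministic greedy rule; the tie-break had to be chosen and this one is
reproducible); (3) survivors are standardized to mean 0, sd 1 so β
magnitudes are comparable effect sizes. Zero-variance variables are
dropped with a warning.

The scale of effect is found by fitting the full model at each of 20
radii (250–5000 m in even 250-m steps — the range and count are fixed,
the even spacing is our choice), reducing each by backward stepwise-AIC
(drop the single term whose removal most lowers AIC until no removal
does; backward-only because the procedure starts from a full model and is
reproducible), and normalising AIC weights across radii from the reduced
models. Named candidate model sets (term subsets) can be ranked at the
chosen radius with the same AIC-weight machinery. Post-hoc parsimony
pruning drops the worst term with Wald p > α (default α = 0.2,
configurable per analysis) and refits until all terms pass.

Diagnostics: deviance explained 1 − D_res/D_null (defined as 0 for a
degenerate constant response); overdispersion as Pearson χ²/df; k-fold
cross-validation (default k = 10, seeded fold assignment) scored as mean
squared error between held-out observed proportions and predicted
probabilities; and Moran's I of response-scale residuals with
inverse-distance weights w_ij = 1/d_ij, not row-standardized, null
expectation −1/(n−1) and the normality-assumption variance, two-sided
normal p, with an optional permutation p-value. Note the normal
approximation is only trustworthy when no two sites are nearly
coincident; with a minimum inter-site spacing (2 km here) permutation and
normal p agree closely, but heavy-tailed weight matrices inflate the
kurtosis of the permutation distribution. Coincident sites are an error.

## Covariate extraction

The landscape enters as a classified integer raster (ESRI ASCII grid, a
projected metric CRS) plus polyline features (GeoJSON). Percent cover
uses the cell-centre rule — a cell belongs to a buffer when its centre is
within the radius — which makes a direct cell-counting oracle exact. Line
density is clipped polyline length per buffer area (km/km²) via shapely.
Buffers that leave the raster are computed on the available cells against
the within-raster cell count, with a warning; the full-circle area is
still used for line densities. The raster pathway approximates a
vector-inventory GIS workflow; its legend (conifer, muskeg, upland
deciduous, cutblock, well site, industrial block) is illustrative of
boreal disturbance classes and fully configurable.

## The synthetic generator

`SimulationConfig` defaults are the study conditions: 62 sites, 12
quarterly seasons from October 2011 with 3 monthly (30.4-day) surveys
each, stratified placement by dominant landcover of 1-km cells with ≥ 2-km
spacing, and three winters ordered mild, severe, moderately severe.

- **Landscape**: Gaussian-smoothed noise (patch scale 400 m) cut at the
  class mixture's quantiles over a 40 × 40 km extent (≈ the study's
  3000-km² landscape once the 5-km edge buffer is removed) at 50-m
  resolution; random 2–5-km line segments per class to target densities
  (0.3/0.5/1.5 km/km² for roads/OHV trails/seismic lines — seismic-heavy,
  as in boreal Alberta).
- **Snow**: per winter, a 166-day sinusoid (November–mid-April) with peak
  depth by severity (15/45/65 cm) plus AR(1) noise (φ = 0.9, σ = 2.5 cm),
  clipped at 0. Winters are classified by days with snow-on-ground above
  the 30-cm threshold: ≤ 10 days mild, ≤ 100 moderate, else severe. The
  cutpoints reproduce the observed labels for exceedance counts of 0, 73
  and 125 days; the mild/moderate and moderate/severe boundaries are
  otherwise conventions, not estimates.
- **Dynamics**: ψ₁ = 0.95; extinction into a winter season set by its
  severity class (0.15 mild / 0.30 moderate / 0.40 severe), 0.05
  otherwise; colonization 0.95 out of winters (the spring rebound), 0.60
  otherwise. The severity→ε defaults echo the seasonal point estimates
  the model family produces on the real system, made monotone in
  severity; explicit ε/γ vectors can override them. Detection is monthly
  Bernoulli given occupancy, with per-season base rates (rut 0.90,
  post-rut 0.80, spring 0.75, summer 0.92) and within-season survey
  offsets (−0.05, 0, +0.05), so the generating detection structure is
  per-survey and lowest in late winter/spring.
- **Spatial coupling**: persistence counts are drawn as
  Binomial(36, expit(β₀ + xβ)) on standardized covariates at the 1000-m
  effect radius, with a default β echoing the annual coefficient table
  (deciduous 0.03, cutblocks 0.07, well sites 0.24, trails −0.88, block
  features 0.41; intercept −0.16). The occupancy and persistence modes
  are separate generators — the analyses share data in the field, but no
  joint generative model is specified, so the temporal mode keeps spatial
  homogeneity while the spatial mode carries the covariate signal.

One global seed is expanded into independent substreams (landscape, snow,
dynamics, detection, persistence), so components regenerate independently
and all outputs are bit-reproducible from (config, seed).

What the generator does *not* emulate: animal movement and home ranges
(detections are conditionally independent given occupancy), spatial
autocorrelation in the occupancy dynamics, observer/camera failure
patterns beyond independent missingness, and real vector GIS inventories.
Passing recovery tests therefore demonstrate correctness of the
estimators under the models' own assumptions at realistic scale — not
robustness to the violations real camera data exhibit.

## Problem sizes in the test and acceptance runs

Recovery studies use 50 replicates of 500 sites (4 seasons × 3 surveys)
for parameter coverage, 300-site replicates for AIC model identification,
the full 62-site 12-season layout for the winter-contrast and
trajectory checks, and 5–7 landscape replicates for the 20-radius scale
scan; these sizes give stable rates while keeping a full run to a few
minutes on one core.

## Known limitations

- Wald 2-SE intervals on the logit scale undercover slightly for
  transition probabilities near 0/1 at moderate sample sizes (the usual
  boundary skew); profile-likelihood intervals are not implemented.
- The stepwise and p-value pruning procedures inherit the usual
  selection-inference caveats; reported SEs are conditional on the
  selected model.
- The survey calendar is an arithmetic 30.4-day grid, not calendar
  months; labels drift by up to ~1 day/season against the civil calendar
  over three years.
- CV mean-squared error on the proportion scale is one of several
  reasonable GLM cross-validation costs; absolute values are not
  comparable across costs.
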