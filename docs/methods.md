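# Methods

This note documents the models, parameter choices and numerical decisions
behind `reburn`, and what the synthetic-data tests do and do not demonstrate
about real field data.

## Sampling hierarchy and data model

All computation respects the field design: fires contain 5–7 sites, each
site three 10 m × 2 m plots, each plot 2–3 evenly spaced measurement points
with paired 1 m² seedling quadrats, one residual-SOL monolith per plot, a
10 m CWD line-intercept transect and a 10 m² shrub subplot. Class summaries
therefore average plots within sites before averaging sites within FRI
classes, mirroring analyses that treat site as a random intercept.

Sites carry both a fire-history FRI class and a final class after tree-ring
corroboration. History is kept when `|ring age − history interval| ≤
max(5 y, 10 %)`; otherwise the ring age's band (> 70 y long, 30–70 y mid,
< 30 y short) wins and triple status is dropped. The tolerance is a package
choice (corroboration criteria are rarely printed); it is exposed as an
argument of `reclassify_fri`.

## Aboveground pools

Biomass is power-law allometry `m = a·d^b` (kg dry matter, diameter cm) per
species and component (stem, bark, coarse/fine branches, foliage, cones for
trees; stem, branches, foliage for shrubs). Combusted biomass is the
component-wise product with the discrete combustion class assessed in the
field, so pre-fire = post-fire + combusted holds *exactly* by arithmetic.
Carbon is 50 % of dry biomass throughout.

The shipped coefficient defaults (`data/allometry_default.yaml`) are
placeholders with realistic Interior-Alaska magnitudes, tagged
`source: literature-to-be-filled`: users analysing real data should install
the species-specific published coefficients they intend to cite. Every test
uses synthetic truth tables, so correctness is coefficient-independent.

Standing dead trees (snags) route to a separate pool under the same
allometry; no snag-specific correction (e.g. absent foliage) is applied —
if snags lack a component, that belongs in the input combustion/record, not
in code. CWD volume uses the Van Wagner line-intercept estimator
`V = π²·Σd²/(8L)` with decay-class wood densities; the field protocol
defines what is tallied, the estimator is the standard one for it.

The deciduous fraction index uses pre-fire *live* stems only and the literal
thresholds 33.33 / 66.66 (boundary semantics: ≤ 33.33 spruce, ≥ 66.66
deciduous). A treeless plot is open regardless of DI.

## Burn depth

Where black spruce with adventitious roots grew (mature spruce plots), burn
depth is the mean measured root height above the residual SOL plus a 3.2 cm
offset — the calibrated depth of adventitious roots within an intact SOL.
With the mean aggregate, applying the offset per root or after averaging is
algebraically identical; under the optional median aggregate it is not, and
the offset is applied after aggregation. Elsewhere a registered predictor
supplies expected pre-fire depth and `burn = max(0, predicted − residual)`;
the zero-clamp means `pre-fire = max(residual, predicted)`. The predictor is
an interface (lookup table by composition × drainage, or the synthetic truth
in simulations); training a pre-fire depth model from inventory data is out
of scope.

## Soil carbon

Increment C pools are `thickness × bulk density × %C × 10⁴` g C m⁻², with
bulk density from fine dry mass over rock-corrected volume. Pools are
modelled per composition class and data regime (residual profiles from
burned sites; unburned reference profiles) as a gamma GLMM with log link:

```
log E[y] = β₀ + β₁·depth + β₂·I(10–20) + β₃·I(>20)
         + β₄·depth·I(10–20) + β₅·depth·I(>20) + b_site + log(t/5)
```

where depth is the increment midpoint (the unbiased covariate for an
increment aggregate), depth classes are half-open with ties at 10/20 cm
going deeper, and the `log(t/5)` offset puts partial bottom increments on
the nominal 5-cm footing. The marginal likelihood over the Gaussian site
intercepts is maximised by a Laplace approximation: inner vectorized Newton
for all site modes (the penalized likelihood is strictly concave in each
intercept for this family), outer L-BFGS-B over (β, log σ, log shape) with
gradient tolerance 1e-8 and at most 500 iterations; standard errors come
from the numerical Hessian at the optimum. The fit agrees with glmmTMB to
roughly three decimals on shared data (a cross-check in the test suite —
glmmTMB is an oracle there, never the implementation). With a single depth
class present the model falls back to intercept + depth with a warning.

Cumulative C over `[a, b)` sums population-level increment predictions
(random intercept 0) on a 5-cm grid with the final partial segment scaled by
`t/5`; it is additive across grid-aligned split points and monotone in `b`.
Residual SOL C uses the burned-site residual model over
`[0, residual depth)`, replaced by the measured monolith sum at monolithed
points; combusted SOL C prices `[0, burn depth)` with the unburned-reference
model, because combustion removes the *top* of the pre-fire profile.
Pre-fire SOL C is their sum, so belowground conservation holds by
construction at every point and plot. Predictions target unmonolithed
points whose site effect is unknown, so the random intercept is set to zero;
the lognormal mean adjustment `exp(σ²/2)` is *not* applied — a documented
limitation that biases population-mean pools low by ~σ²/2 (≈ 4–5 % at
σ = 0.3).

## Legacy accounting

Per class and component: `A = P_pre − P_ref`, `G = L − A`,
`%G = 100·G/L`, annual rate `A/τ`. The reference map is long → itself
(hence `A = L`, `G = 0` identically), mid/short → long's post-fire mean,
triple → mid's post-fire mean. Totals sum the component inputs; in replay
mode each printed row is computed independently from its own printed inputs
(published totals are not always exact component sums at printed
precision). `G` is reported signed, positive = legacy C combusted. τ
defaults to the class-mean stand age at fire; the replay inputs carry the
intervals implied by the published annual rates (102, 45, 16, 39, 21 y).
Zero loss makes `%G` undefined and is emitted as NA with a warning.

## Regeneration and contingency inference

Quadrats are pooled per site (6–9 m²); density = count/area, per-species
biomass = density × mean individual allometric biomass over the measured
basal diameters (falling back to a nominal 0.2 cm diameter for counted but
unmeasured species). Sites sampled < 2 years post-fire are excluded.
Trajectory is open exactly when the total seedling count is zero — the
conservative reading of regeneration failure; a density threshold is not
applied (the sampled-area pooling already guards against sparse-recruitment
misclassification). Extra search quadrats contribute both their counts and
their area to the site totals (config-switchable).

Independence of trajectory (or pre-fire composition) and FRI uses
`X² = Σ(O−E)²/E` with a Monte-Carlo null: tables drawn with fixed margins by
Patefield's algorithm (`scipy.stats.random_table`), 10 000 replicates by
default, `p = (1 + #{X²* ≥ X²})/(B + 1)`. Post hoc cells use standardized
Pearson residuals `z = (O−E)/√(E(1−p_row)(1−p_col))` with two-sided normal
p-values, Benjamini–Hochberg adjusted jointly over all cells.

## Synthetic campaigns

The generator's defaults emulate the published study conditions: 31 fires,
5–7 sites each (~185 sites), class mix 68/47/44/13/13 across
long/mid/short/triple-mid/triple-short, stand ages and pre-fire SOL depths
centred on the published class means, composition mixes per class matching
the reported site counts (spruce-dominated long/mid, deciduous-heavy short),
snag and CWD loads elevated in short FRIs, and an unburned reference network
of ~111 sites dominated by spruce. Aboveground combustion severity is a
latent plot-level beta variable, shifted per component (foliage burns first)
and discretized to the nearest field class. Adventitious-root heights are
generated as (true burn depth − 3.2 cm) with root-to-root spread that
preserves the mean, so the AR method recovers truth exactly; mature-spruce
burn depths are floored at the 3.2 cm offset (roots at the surface). SOL
truth curves put ~1200–2400 g C m⁻² in each 5-cm increment with gamma shape
2 and site SD 0.3; increment lab measurements are back-computed from the
drawn pools so the loader reproduces them exactly.

Truth belowground pools are defined on the *population* curve (site effect
excluded), making pipeline predictions at random-intercept zero unbiased
against truth and conservation exact by construction. `calibrated_config`
solves per-class depth medians and burn fractions so expected class pools
land on specified magnitudes (by default the published class-level
accounting inputs); it exists for end-to-end recovery experiments and is a
calibration device, not field truth.

What passing synthetic tests shows: the estimators are consistent and the
plumbing exact under the generative assumptions (correct allometry, gamma
increment noise, exchangeable site effects, known pre-fire depths for
non-spruce plots). What they do not show: robustness to allometric model
error, non-gamma soil heterogeneity, spatially structured severity, or
pre-fire-depth predictor bias — all of which affect real campaigns.

## Problem sizes and runtime choices

Test and example problem sizes are chosen to exercise the estimators at
meaningful precision while keeping the suite quick: conservation and
end-to-end recovery run on ~200-site campaigns (about the published study's
185), depth-model recovery uses 50 replicates of 200 sites (~1200
increments, the scale of the study's spruce model), and Monte-Carlo
calibration uses 1000 null tables at B = 2000. The full suite runs in a few
minutes on one CPU.

## Known limitations

- No uncertainty propagation from the soil GLMM into the legacy table; the
  accounting is a point computation (a site-clustered bootstrap could be
  layered on top).
- FRI contrasts via mixed Tweedie models and marginal-means machinery are
  out of scope; class means with between-site SEs are reported instead.
- The gamma-GLMM retransformation bias noted above.
- Thaw depth is carried descriptively, never modelled.
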