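# Methods

This note documents the models, the synthetic world, the numerical choices
and the known limitations of the package. Nothing here states an empirical
result that the tests or `scripts/acceptance.py` do not themselves compute.

## Geodesy and solar timing

Distances are haversine great-circles on a sphere of mean radius
6371.0088 km. At Mediterranean migration scales (≤ 1000 km) this is within
0.5% of an ellipsoidal geodesic, and unlike planar "Euclidean" distances it
is reproducible without a projection choice. Initial bearings are standard
great-circle forward azimuths in [0°, 360°).

Sunrise/sunset use the NOAA solar-position equations with zenith 90.833°
(refraction plus solar radius). Polar day/night is flagged, never raised.
`hours_after_sunset` is 0 at sunset and positive after; timestamps whose
local civil time falls before noon are referenced to the *previous*
evening's sunset, so the covariate is continuous across midnight for
nocturnal fixes. Local civil time is Italian: UTC+2 until the last Sunday
of October, UTC+1 after; the offset is configurable per dataset.

One naming caveat carried through from the source material: the departure
model's covariate is labelled "hours before sunset" in one table but
defined as "hours after sunset" in the text; the sign convention here
follows the text (after sunset = positive).

## Weather fields and wind support

Atmospheric variables live on dense regular (time, lat, lon) grids at
0.25°/1 h; the three cloud layers at 0.75°/6 h. Interpolation is bilinear
in space at the two bracketing time slices, then linear in time — exact on
fields linear in lat/lon/t and always inside the envelope of the eight
bracketing nodes. Queries outside the hull raise rather than clamp.
Cloud grids use the same scheme (no nearest-neighbour fallback).

Wind direction is stored as the blowing-TOWARD bearing; origin-convention
input is converted at ingest (+180°). Tailwind = 3.6·v·cos Δ (signed),
crosswind = |3.6·v·sin Δ|, both in km/h with v in m/s; Δ is the circular
difference between the flight direction and the wind direction. Tailwind²
+ crosswind² = (3.6 v)² identically. Wind is treated as a single 2-D field;
no pressure-level selection is attempted.

## Segmentation rules and their free parameters

The migration definition (100-km radius, arrival before 1 November of the
hatch year, ≥ 12-h stopovers, ≥ 20-day non-breeding site, > 100 km/day
directed approach) is applied verbatim. Three operational constants the
source never specifies are exposed as configurable arguments:

* **in-flight**: segment speed to the next fix ≥ 20 km/h while moving away
  from the colony (flamingo cruising speed is ≥ ~45 km/h; foraging moves are
  far slower);
* **colony residence radius**: 5 km;
* **dwell radius**: 15 km around the running dwell centroid.

The directed-approach test takes the maximum displacement between any two
fixes ≤ 24 h apart in the window from 24 h before the dwell entry to 12 h
after it, because the greedy dwell clustering can absorb the final flight
fix. Gaps > 12 h inside a candidate dwell raise a data-quality warning
rather than silently certifying the dwell duration. "> 100/km day" in the
source is read as the obvious typo for "> 100 km/day".

With 2-h fixes and ~50–70 km/h flight, the detected departure fix can
already lie tens of km along the route; detected event distances are
therefore mildly truncated relative to the colony→destination distance
(occasionally below 100 km for the shortest routes). This is a property of
the fix cadence, not of the generator.

## Estimation machinery

* Continuous predictors are centred and scaled by the sample SD; quadratic
  terms are squares of the standardized base and are tested as their own
  term block. Categoricals are reference-coded; aliased columns (rank
  checks) are dropped and reported, never fatal.
* VIF screening is iterative: drop the largest VIF ≥ 3, recompute, repeat.
* LM/GLM (Gaussian, binomial, Poisson) delegate to statsmodels. Poisson
  fits attach the Pearson χ²/df dispersion statistic.
* The **Gaussian random-intercept LMM** is fitted by profiled REML: the
  variance ratio λ = τ²/σ² is optimised on the log scale with per-group
  Woodbury identities; λ → 0 is reported as zero group variance with a
  boundary flag. Per-coefficient F tests use **Satterthwaite** denominator
  df via the delta method on the inverse observed REML information.
  Kenward–Roger (used by the source for the speed model) is not
  implemented: at this data scale the difference is immaterial and the
  acceptance surface is coefficient recovery, not df. The implementation
  matches R `lme4::lmer` (REML) to ~4 decimals in the test suite.
* The **binomial random-intercept GLMM** maximises a Laplace-approximated
  marginal likelihood over (β, log σ): per-group modes by damped Newton
  (steps clamped to ±2 — the objective is concave but undamped steps can
  oscillate from a warm start), BFGS outer optimisation, SEs from a
  central-difference observed information. Matches `lme4::glmer` to ~2
  decimals. Complete separation (|β| > 30 at the optimum) and
  non-convergence raise explicit diagnostics; a wild *starting* fit only
  triggers a neutral restart. σ → 0 is a flagged boundary; `fix_sigma_zero`
  collapses to the plain logistic fit.
* Convergence: relative tolerance ~1e-8 in the inner solves, ≤ 500 outer
  iterations.
* Diagnostics: Wald type-III χ² per term block (invariant to term order);
  McFadden R² = 1 − ℓ/ℓ₀; marginal R² by variance partition
  var(Xβ̂)/(var(Xβ̂) + τ² + residual), with residual σ² for Gaussian and
  π²/3 on the latent scale for binomial-logit; semi-partial R² is the
  leave-one-term-out marginal-R² difference (the source cites a
  partitioning method without formulas; this declared definition is
  deterministic and testable).

## Circular statistics

Rayleigh test: r̄ = |Σe^{iθ}|/n, Z = n r̄², p by the standard series
approximation. The "t" quoted alongside published Rayleigh results is
interpretable only as r̄ (its printed value of 1 is attainable by no other
quantity); both r̄ and Z are reported. Directions are binned into six
half-open 60° classes [0,60), …, [300,360): the printed class edges in the
source are internally inconsistent (one 80° class), while its stated intent
is "six classes of 60° each". The per-colony Poisson GLM of departure-bin
counts on wind-bin frequencies has n = 6 observations; results are reported
exactly and this small-n fragility is a caveat the analysis inherits from
its design, not something the package corrects.

## The synthetic world

The generator's defaults are the study's stated conditions, fixed a priori:

* three colonies at the published coordinates; 16/11/13 birds (40 total,
  ≈ 80% migrants as published); sex ratio 11 F : 29 M; 2-h fixes,
  August–November season, one cohort year (2015) per dataset — year terms
  in the models are aliased on default data and reported as such.
* biometrics: sex-specific tarsus means equal to the published reference
  values (275/247 mm); masses/wings at field-realistic juvenile values with
  a colony offset (Comacchio larger, as reported qualitatively).
* propensity: migrate ~ Bernoulli(logit⁻¹(1.4 + 0.9·z_SMI)) — mean ≈ 80%
  migrants, better condition → more migratory.
* departure hazard: at every eligible 2-h step (local 16:00–24:00 ∪
  00:00–02:00, inclusive endpoints) a ready migrant departs with
  probability logit⁻¹(−4.97 + 1.41·z_tailwind + 4.37·z_h − 2.52·z_h²) — the
  published standardized estimates applied to covariates standardized
  within the simulation (colony-season moments). The hazard step *is* the
  first in-flight fix, so the case-control design's label-1 covariates
  coincide with the generative inputs. Colony "readiness" offsets (5/20/40
  days, females +10) reproduce the published phenology ordering
  (Molentargius < Comacchio < Margherita; males earlier). A migrant whose
  hazard never fires by 20 October is forced out at the next eligible step
  so its event can finish before the 1 November deadline.
* flight speed per segment: 72.05 (the published standardized-scale
  intercept) − 10.73·male + 8.52·z_tailwind + 8.2·z_d − 8.79·z_d², plus a
  bird intercept (SD 5) and residual (SD 8), floored at 25 km/h. z_d uses
  fixed standardization constants (mean 300 km, SD 214.3 km) chosen a
  priori so the concave profile peaks at ≈ 400 km, the decline point the
  study reports. Realized mean speeds land near the published ~45 km/h.
  (The source itself prints two different mean speeds, 54.6 and
  45.2 km/h, in different sections; the package reports its own mean.)
* winds: per-colony regime mixtures (blowing-toward convention) with
  Markov switching (~36-h dwell), diurnal modulation and AR(1) noise,
  blended spatially by colony-centred kernels. Molentargius's dominant
  Mistral-like regime aligns with its Tunisia-bound routes; Margherita's
  dominant Mistral-like regime opposes its northward routes (with a
  secondary Scirocco-like regime supplying the favourable windows the
  wait-for-wind mechanism needs), so the direction-vs-wind analysis
  exercises both the positive and the negative published signs.
* destinations per colony follow the published map qualitatively
  (Molentargius→Tunisia, Comacchio→Venice lagoon, Margherita→Po delta,
  plus minority routes), with distances set so the realized mean
  (~380 km) and range match the published 388 km (103–813).
* precipitation includes a small everywhere-positive drizzle floor, as in
  reanalysis total-precipitation fields; without it exact zeros make rain a
  quasi-separating predictor in the sparse case-control design.
* all randomness flows from one seed through numpy `SeedSequence` spawning;
  identical seeds give byte-identical fixture bundles and result tables.

**What a green test does and does not establish.** The generator emulates
the *statistical structure* the analyses assume — not real meteorology
(no fronts, orography or pressure-level structure), no social behaviour
(mixed-age flocks guiding juveniles, which the study discusses but never
models), no GPS error, no device failure, and regular 2-h fixes without the
timing jitter real tags show (the study's 676 control rows for 30 birds
imply such jitter; the builder makes no attempt to reproduce that count).
Green recovery tests establish that the estimators and builders are
correct on data satisfying their assumptions, not that the published
biological findings are true.

## Reproducibility

Pipeline stages communicate only through files in a run directory
(`data/`, `tables/`, `manifest.json`); the manifest stores SHA-256 hashes
of the config, inputs and every result table, so identical seeds are
verifiable byte-for-byte. Weather bundles are NetCDF3 (scipy backend;
netCDF4 is not required) plus a long-format CSV dialect for desk-scale
fixtures; both round-trip losslessly.

## Known limitations

* Random intercepts only (as in the study's models); no random slopes.
* Laplace (not adaptive quadrature) is the default GLMM integral; with
  ~20 observations per bird its bias is small but nonzero for extreme
  variance components.
* The departure-model variance of the bird intercept is not printed in the
  source; simulations use SD 1 on the logit scale.
* Segment speeds are chord/Δt over 2-h intervals: true instantaneous speed
  variation within an interval is unobservable at this cadence.
* The direction-vs-wind GLM inherits its n = 6 design from the analysis it
  reproduces; its p-values should be read accordingly.
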