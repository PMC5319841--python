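# Methods

## The mapping problem

Dominant African malaria vectors (the *Anopheles gambiae* complex and the
*An. funestus* subgroup) are sibling species: morphologically identical and
separable only by molecular assay, yet different in range, behaviour and
insecticide resistance. Mapping one sibling species from survey data poses
two coupled problems:

1. **No true absences.** A survey that did not report the focal species is
   only an absence if its identification method *could have* detected it.
2. **Sampling bias.** Surveys cluster around roads, towns and study sites;
   a naive model learns the survey process, not the habitat.

The procedure implemented here addresses both with presence/background
modelling in which the background carries the *same* spatial bias as the
presences: the full anopheline survey record is the background set, split
into class 1 (methods that would have detected the focal species — genuine
soft absences, given **twice** the weight) and class 2 (everything else).
Deserts host no surveys but the species are known absent there, so 210
pseudo-absence points sampled uniformly from the desert biome mask anchor
the low end of the suitability scale. Pseudo-absences join the model as
class-2 background: they originate from no survey, so the capable-method
upweighting cannot apply to them.

### Weights

Class-1 : class-2 background weight is exactly 2 : 1 for any dataset. On
top of that ratio the default (`balanced`) mode rescales background weights
so the total background weight equals the total presence weight
(presences keep weight 1); `plain` mode keeps raw (1, 2, 1) weights. The
2 : 1 ratio is the fixed contract; the presence/background balance is a
package default that is configurable and recorded in every frozen config.

## Boosted regression trees

The suitability model is a from-scratch weighted BRT for Bernoulli
response, additive on the log-odds scale:

    F(x) = F0 + nu * sum_m T_m(x),    p(x) = expit(F(x))

with `F0 = logit(sum(w y) / sum(w))`. Each stage fits a small least-squares
regression tree to the pseudo-residuals `r = y − p` over a bag of
observations (weight-proportional sampling without replacement, fraction
0.75 by default), growing best-first by the split that maximises the
weighted SSE reduction, to at most `tree_complexity` leaves (default 5,
i.e. ≤ 4 splits). Leaves take the Newton step for the Bernoulli loss,
`sum(w r) / sum(w p (1−p))`, with the denominator floored at 1e-12 for
pure leaves. The additive score is updated with shrinkage `nu` (default
0.005) and the weighted mean deviance is traced per stage.

Determinism choices: split candidates are midpoints between consecutive
distinct sorted values; ties in gain break to the lowest feature index,
then the lowest threshold; points on a threshold go left (`<=`). Bagging,
the internal early-stopping holdout, bootstraps and pseudo-absence draws
all use seeded PCG64 generators, so a model is a pure function of
(data, config, seed) and serialises to byte-stable JSON.

Weight semantics are exact rather than approximate: rescaling all weights
by a constant leaves the fit unchanged, and (at bag fraction 1 and
`min_obs_leaf` 1) an observation of weight 2 is equivalent to duplicating
it — both are asserted by tests.

The default 1000 trees at shrinkage 0.005 follow the slow-learning
convention of BRT species-distribution modelling. The recovery experiments
and the worked examples in this repository use 200 trees at shrinkage 0.05
per submodel (the same total learning, ~10 at larger steps) so a full
20-submodel ensemble on the standard world fits in seconds; the choice is
recorded in each run's frozen config. Optional early stopping monitors a
20% internal holdout and trims to the best stage after 50 stagnant stages.

## Ensemble and uncertainty maps

The mapped quantity is the relative probability of occurrence per pixel.
200 submodels (default) are fitted, each to an independent bootstrap of
the presence/background dataset; per pixel the submodel predictions form a
distribution summarised by its mean, median and 0.025/0.975 quantiles.
Quantiles use linear interpolation of order statistics (type 7, the numpy
default). Bootstraps are stratified by label with class sizes preserved —
the pooled alternative is available by flag, but stratification guarantees
every resample contains both classes. Submodel seeds derive from
(master seed, submodel index), so results are independent of execution
order and worker count.

A caveat verified empirically and asserted as a property test: with few
submodels the interpolated extreme quantiles sit inside the sample range
and *under-cover*, so the average (q_high − q_low) grows toward its
asymptote as the ensemble grows, with contracting increments. Small
ensembles understate uncertainty; they do not overstate it.

Maps are masked to the species range plus a 300 km buffer (pixel-centre
membership), reflecting uncertainty in the expert range limits. Ranges are
extended before buffering so every molecularly confirmed presence is
covered: each outside point is unioned in as a 25 km disc — enough to
encompass the location without inflating the range; the radius is
configurable because no principled value exists. Planar (synthetic) worlds
buffer with Euclidean distance; geographic ranges are buffered through a
per-geometry spherical azimuthal-equidistant projection so "300 km" holds
at any latitude.

## Record curation

- **Validation** rejects (as data, with reason codes, never exceptions)
  records outside the study extent, with inverted year ranges, or with no
  dating information. This is the automated surrogate for the manual
  checks that coordinates matched the sampling design and fell in the
  right country.
- **Collection year**: records without dates are assumed collected two
  years before publication; multi-year collections take the floor of the
  midpoint (a package decision — one representative year is needed for
  covariate matching). Years are clamped to the covariate span
  (2001–2012 in the synthetic default): earlier records use the first
  year's layers, later records the last year's.
- **"An. gambiae (old)"** (pre-split *gambiae s.l.* identifications):
  outside the buffered *An. coluzzii* range the record can only be
  *An. gambiae* and is relabelled; anywhere inside the buffered coluzzii
  range — overlap or coluzzii-only — the old label cannot be resolved and
  the record is discarded and counted. Unknown identification-method codes
  never upgrade a record (treated as non-molecular, class 2).
- **Locations**, not records, are the unit of the validation split:
  co-located records share a location id (coordinates rounded to six
  decimals) and move to the same side. 10% of presence locations and 10%
  of background locations (rounded half-up, minimum one) are withheld;
  the mean map is scored by rank-based AUC (Mann–Whitney, ties counted
  half) of withheld presences against withheld background.

## Bioassay summarisation

A record is one mortality value for one mosquito population at one time
and place from one study. Records without molecular identification are
discarded; records where the majority species strictly exceeds 95% of the
sample are attributed to that species; the remainder form a separately
tallied "mixed" stratum (reported, not deleted). The strict reading of
">95%" (a sample at exactly 95% is rejected) is implemented with the
threshold configurable. Summaries per species × insecticide class ×
period give n, min, max and the unweighted arithmetic mean (records, not
mosquito counts, are the unit), with the sorted unique country list.
Periods are "≤2000" then five-year bins; a species × class group with
fewer than 10 records is aggregated into one all-years bin. Protocol
deviations are carried as annotations and never used as filters.

## The synthetic world

The generator emulates the statistical structure of the real exercise on
an abstract planar grid (1 pixel = 5 km):

- **Covariates**: per band, Gaussian-filtered white noise (filter width =
  grid_width/8) standardised to mean 0, sd 1 — smooth fields with
  realistic spatial autocorrelation; an optional band-correlation
  parameter mixes in a shared field (default 0: independent). Annual
  layers drift by cumulative smooth increments of sd 0.02/year — enough
  to make year-matching observable, small enough that the
  most-contemporary map remains a faithful summary of all years.
- **Truth**: suitability = expit(intercept + Σ coef·band) over a small
  set of active bands; every generated record stores the uniform draw and
  the suitability value that decided its label, so labels regenerate
  exactly from stored ground truth.
- **Surveys**: clustered around random centres (sampling bias), never in
  the desert strip; each survey carries a method code — a capable
  molecular assay (85%), a molecular assay blind to the focal species, or
  morphology only. A capable survey yields a presence with probability
  equal to the local suitability, otherwise a background record.
- **Default conditions** (the standard study world): 64×64 grid, 8 bands
  of which 2 active with |coefficient| 5 and intercept −1.5, 900 survey
  locations in 20 clusters of spread 45 km, desert fraction 0.15. These
  values were fixed against the analytic ceiling of the presence/
  background AUC — the AUC the *true* suitability map attains, which no
  model can exceed. Background contains capable surveys at suitable
  pixels where the species was absent by chance, so the ceiling is well
  below 1; under these conditions it is 0.91–0.95 across seeds
  (~350 presences, ~630 background), i.e. a world in which recovering
  held-out AUC > 0.85 is demanding but attainable. With weaker effects or
  a half-suitable landscape the ceiling drops below 0.85 for any model.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: real African geography and country borders,
covariate semantics and their strong collinearity, gazetteer/geocoding
error, imperfect assay sensitivity, overdispersed within-site repeat
surveys, and reporting bias in the bioassay literature. Tests demonstrate
that the machinery is correct and recovers known truth under the stated
conditions, not that the real maps are right.

## Problem sizes used in tests and examples

Unit tests run on 32×32 worlds with ~250 surveys and 3–4 submodels; the
recovery experiments use the standard 64×64 world with a 20-submodel
ensemble of 200-tree BRTs and ten replicate single fits for the influence
ranking. The worked example in the README is the same 20-submodel run.
Full-scale settings (200 submodels, 1000 trees) remain the defaults of
`EnsembleConfig`/`BRTConfig` and are what the CLI uses unless told
otherwise.

## Known limitations

- The BRT is exact but plain numpy: fine for 10³–10⁴ points and 10³
  trees, not tuned for continental 10⁶-pixel prediction grids.
- Geographic buffering assumes a spherical earth (error ≲ 0.5% versus the
  ellipsoid — negligible against a deliberately round 300 km buffer).
- `mask_to_range` uses pixel-centre membership; boundary pixels whose
  centre falls just outside are dropped whole.
- The resistance module summarises; it deliberately does not model trends
  (the sampling bias across time and space in bioassay data makes naive
  trend-fitting misleading).
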