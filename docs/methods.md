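# Methods

This note documents the model behind `forest-adapt`, its assumptions,
the tunable parameters, the synthetic cohort the tests run on, and the
design choices made where the rules left room.

## Analysis unit and inputs

The unit is the *centroid*: a permanent survey site whose up to four
subplots are aggregated — species shares, stand volume and coordinates
by the arithmetic mean, altitude and slope by the median (midpoint of
the two central values for an even count; a standard convention).
Sites where none of the fifteen registered taxa occurs are excluded and
counted. Each centroid carries an environmental-zone label
(Alpine South, Continental, Pannonian, Mediterranean Mountains) as an
*input* column rather than a polygon overlay, which keeps the pipeline
testable without external GIS data and sidesteps ambiguous
zone-boundary cases.

Climatic suitability enters as occurrence probabilities (percent) per
plot × species × period, either as long-format tables or sampled from
GeoTIFF rasters. Raster sampling is nearest-cell — SDM ensemble outputs
are effectively categorical surfaces and interpolation would blur the
cut-off decision — and auto-detects a [0, 1] probability scale (raster
maximum ≤ 1.5 triggers a ×100 rescale, logged). The sampler reads the
GeoTIFF georeferencing tags directly and applies no reprojection; plot
coordinates must already be in the raster CRS. Plots outside a raster
get a missing value, treated downstream as probability 0 (conservative:
absent evidence is "unsuitable"), with a logged warning.

## Species registry

The registry fixes, per taxon: the mean model cut-off (percent), the
mean annual volume increment (m³ over bark ha⁻¹ yr⁻¹), the standardized
increment, and trait flags (native, conifer, evergreen). The two white
oaks are merged into *Quercus* spp. at the registry level because
inventory composition and growth data do not separate them; the oak
split exists only on the suitability side, where the more probable of
*Q. petraea*/*Q. robur* is kept and judged against the merged-oak
cut-off (48.3 %).

The *printed* standardized increments are canonical for scoring. The
column is not exactly increment/mean-of-15 for every species (largest
gap ≈ 0.034 for *A. grandis*), so recomputing it would silently shift
production categories; `standardize_increments` exists for
user-supplied increment sets and is tested for scale invariance and
mean-1 output. Increments are static species constants — no
growth-and-yield modelling, no site or age effects.

Evergreen ("wintergreen") flags drive the avalanche rules. Only three
natives are evergreen (*P. abies*, *A. alba*, *P. sylvestris*;
*L. decidua* is the lone deciduous conifer). For the nine NNT the
registry freezes standard botany: all NNT conifers evergreen, all NNT
broadleaves deciduous; the flags are per-species fields, so a stricter
natives-only wintergreen definition is a registry override away.

## Suitability and local failure

Binary suitability is `probability >= cutoff`: the rules define
*below*-threshold as unsuitable, so equality counts as suitable.
Relative suitability is the ratio `probability / cutoff` (≥ 1 ⇔
suitable), the ranking key for replacements. A difference-based variant
(`1 + (p − c)/100`) is available behind the `mode` argument since
"relative to the cut-off" admits both readings; ratio is the default
because it weights a 10-point surplus more for low-cut-off species,
matching the intuition that such species are easier to establish.
A species occurring today (share > 0) whose future-period suitability
is false is *locally failing*: assumed unable to regenerate and lost by
the end of the century.

## Scenario engine

One-step replacement, no temporal dynamics, no competition: the future
stand is the current stand with every failing species' share
reallocated.

* **No adaptation.** The failing share is redistributed over surviving
  suitable residents proportionally to their current shares (the
  minimal-assumption recolonization rule); if none survive the plot is
  unstocked. The failing species' *stock volume* is lost either way —
  volume is multiplied by the surviving share fraction. This coupling
  (composition persists, volume drops) reconciles two observations the
  rule set must reproduce: resident species keep their frequency, yet
  volume-based protection deteriorates only in this scenario. A config
  switch (`no_adaptation_redistribution="drop"`) leaves the space
  vacant instead.
* **MSS.** Each failing species is replaced by the single most suitable
  candidate (argmax of relative suitability) from the pool — natives
  only or all fifteen. One receiver per failing species; the receiver
  may already be present (shares merge). A species never replaces
  itself.
* **CC/BB.** As MSS but restricted to the failing species' growth form
  first; when no same-form candidate is suitable, the overall argmax is
  used (strict form-first, no suitability margin).
* Adaptation scenarios transfer share *and* volume to the receiver;
  only a receiver-less failing share loses its volume. This is what
  makes volume-based rockfall categories invariant under successful
  adaptation.
* **Tie-break:** higher standardized increment, then lexicographically
  smaller code — deterministic and reproducible; any rule would do, a
  productivity preference is at least defensible silviculturally.

The engine is verified against an independently written brute-force
oracle (hardcoded trait sets, explicit enumeration of candidates) on
randomized plots, plus invariant suites: identity when nothing fails,
share sums never increase, combi NNT share ≥ native NNT share, no
species additions under no-adaptation, volume conservation when every
failure finds a receiver.

## Ecosystem services

* **Production**: unweighted mean standardized increment over species
  present — the averaging rule names no weights, so presence, not
  share, is the default (share-weighted mode behind a flag). Bands:
  high > 0.78, moderate 0.63–0.78 (both edges inclusive), low < 0.63.
* **Richness**: count of taxa with share > 0 (merged oaks count once).
* **NNT share**: non-native share over total stocked share, so a
  partially stocked plot normalizes to its stocked part; 0 if unstocked.
* **Avalanche** (altitude > 800 m, slope 25–60° inclusive): high if
  volume ≤ 100 m³ ha⁻¹ (not fully stocked — the volume clause takes
  precedence, it is an "or" within the high-risk cell) or wintergreen
  share ≤ 40 %; low if wintergreen ≥ 70 %; moderate otherwise. The
  published bands leave gaps (69–70 %); they are closed by making the
  low-risk bound inclusive, per the prose "equal or above 70 %".
  Wintergreen proportion is share-based (volume-based would need
  per-species volumes, which the data model does not carry).
* **Rockfall** (hazard-zone plots only): volume ≥ 360 low, ≤ 180 high,
  else moderate; same gap-closure convention.
* **Unstocked plots** score production 0/low, richness 0, NNT share 0,
  and high risk for both protective services — a bare slope protects
  nothing, and the convention keeps the category partitions total.
* **Change vs current** is the sign (−1/0/+1) on the numeric or ordinal
  scale, plus a percent change for volume-backed quantities (undefined
  when the current value is 0 and flagged as such).

Zone reports give unweighted per-plot means with sample SDs (SD 0 for a
single plot) and category counts; production counts run over all plots,
protection counts only over service-eligible plots, so each service's
counts sum to its eligible-plot total.

## Synthetic cohort

Defaults define the study conditions: 1423 / 1448 / 150 sites in
Alpine South / Continental / Pannonian (the three excluded
Mediterranean-Mountain sites are not emulated), four subplots each.

* **Terrain**: site-level normals — altitude 1300 ± 400 m and slope
  30 ± 12° (Alpine South), 650 ± 300 m and 15 ± 10° (Continental),
  250 ± 80 m and 4 ± 3° (Pannonian) — with small subplot jitter (5 m,
  0.5°). These means/SDs were chosen so the avalanche-eligibility rule
  selects roughly 30 % of sites, essentially all outside the Pannonian,
  and an analytic helper (`expected_avalanche_fraction`) gives the
  closed-form expectation the tests compare against.
* **Rockfall zones**: Bernoulli per site (0.26 / 0.107 / 0), about 17 %
  of sites overall.
* **Composition**: per zone, a mixture weight vector over the 15 taxa
  (spruce-dominated in the mountains; oak/pine with ~16 % total NNT
  weight in the Pannonian, ~1 % elsewhere). A site draws its mixture
  from a Dirichlet centred on the zone weights (concentration 2, so
  stands are species-poor), and each subplot tallies 10 stems
  multinomially — shares are exact simplex points and the expected NNT
  share equals the configured weight, which the parameter-recovery test
  exploits (3 SE at cohort size).
* **Volume**: lognormal with zone means 360/370/280 m³ ha⁻¹ and shape
  0.55, clipped to the observed 0–1700 range.
* **Suitability**: per species, an altitude-logistic probability with
  amplitude, midpoint, scale, an uphill midpoint shift per climate-impact
  unit, and an amplitude decline knob. Periods map to impact 0 / 1 / 2
  (historical / RCP 4.5 / RCP 8.5). Montane species (spruce, firs,
  larch, beech) shift uphill and lose the lowlands; thermophilous
  species (oaks, Douglas fir, black walnut, Monterey pine) expand;
  four NNT have amplitudes below their cut-offs and are never suitable,
  mirroring their marginal role. Plot-level Gaussian noise (SD 4) is
  drawn once per plot × species and shared across periods, so impact 0
  reproduces the historical table exactly and the decline knob is
  provably monotone.

What the generator does **not** emulate: spatial autocorrelation, real
climate fields, stand age/structure, management history, and any
correlation between composition and suitability at a site. Passing
cohort tests therefore demonstrates that the *rules* behave as
specified under realistic marginal distributions — not that the
pipeline reproduces any particular national statistic.

## Numerical choices and degenerate inputs

* Shares are plain floats; a share sum may be < 1 (partial stocking)
  and outcome share sums never exceed the input sum.
* Unstocked ⇔ outcome share sum is exactly 0; volume is then forced to 0.
* Oak merge ties go to *Q. petraea* (code order).
* Probability tables may not mix split oak rows with pre-merged
  `que` rows for the same plot/period (rejected).
* Empty zones yield n = 0 summaries; empty result sets yield
  header-only output files.

## Problem sizes

The default test suite runs the full 3021-site cohort once per future
period (a few seconds) plus ~1000-plot randomized oracle comparisons;
the reproduction script runs the same cohort under both periods. These
sizes were chosen to keep a complete run comfortably interactive on a
single core.

## Known limitations

* No growth dynamics: increments are species constants and volumes
  static apart from the replacement bookkeeping.
* Protection scoring uses volume as a density proxy; stem counts and
  diameters, which matter mechanically for rockfall, are not modelled.
* Invasion risk of NNT is out of scope; the scenarios treat every
  registered NNT as plantable wherever suitable.
* The raster sampler handles north-up, affine, single-band GeoTIFFs in
  the plot CRS only.
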