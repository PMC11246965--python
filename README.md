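# forest-adapt

Climate-adaptation scenario analysis for forest inventory plots.

Warming climate is pushing major Central European stand-forming tree
species out of their suitable range. Forest managers must decide how to
replant the growing space that failing species vacate: do nothing, use
only native species, or include non-native tree species (NNT) — and
replace by climatic suitability alone or preserve the stand's growth
form (conifer vs broadleaf). `forest-adapt` turns these choices into a
reproducible pipeline: from per-species climatic suitability and
plot-level stand composition it applies five species-change scenarios
and scores every plot for timber productivity, tree-species richness,
non-native share, and protection against avalanches and rockfall, with
zone-stratified reporting. It is aimed at forest scientists and
silviculture planners who have (or can model) occurrence probabilities
for candidate species and want plot-level scenario outcomes.

## Model

Fifteen taxa are tracked: six natives — *Picea abies*, *Abies alba*,
*Pinus sylvestris*, *Larix decidua*, *Fagus sylvatica* and merged
*Quercus* spp. (*Q. petraea*/*Q. robur*) — and nine NNT, including
*Pseudotsuga menziesii*, *Abies grandis* and *Pinus radiata*. Each
species *s* carries an occurrence-probability cut-off *c\_s* (percent)
and a standardized annual volume increment.

For a plot with probability *p* (from an ensemble species distribution
model, consumed not fitted):

* **binary suitability**: suitable iff *p ≥ c\_s*;
* **relative suitability**: *r = p / c\_s*, the ranking key for
  replacements (*r ≥ 1* ⇔ suitable);
* a species present today but unsuitable in the future period is
  considered unable to regenerate and **locally failing**.

Five scenarios reallocate each failing species' share:

| scenario | pool | rule |
|---|---|---|
| `no_adaptation` | residents only | share redistributed over surviving suitable residents; the failing stock volume is lost; unstocked if none survive |
| `native_mss` / `combi_mss` | natives / all 15 | most suitable species: argmax *r* among suitable candidates |
| `native_ccbb` / `combi_ccbb` | natives / all 15 | conifer-for-conifer, broadleaf-for-broadleaf; falls back to the overall argmax when no same-form candidate is suitable |

Adaptation scenarios transfer share *and* volume to the receiver; ties
break by higher standardized increment, then species code.

Services per plot: mean standardized increment (high > 0.78, moderate
0.63–0.78, low < 0.63); species richness; NNT share; avalanche risk
(eligible above 800 m at 25–60° slope; low when the wintergreen canopy
share is ≥ 70 %, high when ≤ 40 % or stand volume ≤ 100 m³ ha⁻¹) and
rockfall risk (inside mapped hazard zones; low ≥ 360, high ≤ 180
m³ ha⁻¹).

Because real national inventory coordinates are confidential, the
package includes a seeded synthetic-cohort generator
(`forest_adapt.synthetic`) emulating the zone structure (Alpine South /
Continental / Pannonian), terrain, compositional shares, lognormal
volumes and altitude-logistic suitability surfaces for a historical
period and two future scenarios (RCP 4.5 / 8.5, 2081–2100).

## Worked example

A pure Norway-spruce plot in the Pannonian lowland where, under
RCP 8.5, only the non-native Douglas fir remains suitable:

```python
from forest_adapt import load_registry, build_suitability_table, run_all, scenario_fixture
from forest_adapt.services import scores_frame

registry = load_registry()
plots, raw = scenario_fixture("pannonian_spruce")
table = build_suitability_table(raw, registry)
results = run_all(plots, table, "rcp85_2081_2100", registry)
for label, (outcome,) in results.items():
    print(f"{label:>14}: shares={outcome.shares}  volume={outcome.volume:.0f}  unstocked={outcome.unstocked}")
```

```
 no_adaptation: shares={}  volume=0  unstocked=True
    native_mss: shares={}  volume=0  unstocked=True
     combi_mss: shares={'pme': 1.0}  volume=300  unstocked=False
   native_ccbb: shares={}  volume=0  unstocked=True
    combi_ccbb: shares={'pme': 1.0}  volume=300  unstocked=False
```

Without NNT the plot is left unstocked — spruce fails and no native is
suitable — while the combi scenarios replant it with Douglas fir
(`pme`), preserving the 300 m³ ha⁻¹ stock. Scoring the same run:

```
     scenario  production_value production_category  richness  nnt_share
      current              0.95                high         1        0.0
no_adaptation              0.00                 low         0        0.0
    combi_mss              1.54                high         1        1.0
```

The production value is the mean standardized increment of the species
present (spruce 0.95, Douglas fir 1.54); losing the stand drops the
plot to the low-production class, replanting with Douglas fir raises it.

A full synthetic run from the shell:

```bash
forest-adapt pipeline --seed 3 --rcp 8.5 --out out/
# -> plots.csv, suitability.csv, plot_scores.csv, zone_summary.csv,
#    change_{production,avalanche,rockfall}.geojson
```

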