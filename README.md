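# ecosens

Eco-environmental sensitivity evaluation for land-use planning: a fuzzy
matter-element (FME) model with entropy-derived indicator weights,
hierarchical weighted overlay to a five-class sensitivity surface, and
vector-polygon area tabulation.

## The problem

Land-use planners need to know which parts of a region are ecologically
fragile before zoning it.  A standard quantitative route scores every
evaluation unit (e.g. an administrative village polygon) on a hierarchy of
indicators — soil conditions, water conditions, atmospheric conditions and
biodiversity, each broken into measurable factors such as slope, soil pH,
BOD, SO₂ or vegetation cover — and aggregates the scores into a composite
sensitivity index used to classify the region into *insensitive*,
*slightly*, *moderately*, *highly* and *extremely sensitive* zones.

`ecosens` implements that pipeline end-to-end:

1. **Grading** — each raw indicator value is binned into a discrete grade
   index g ∈ {1, 3, 5, 7, 9} by a per-indicator grade table (numeric
   intervals or categorical maps; shared bin edges resolve to the more
   sensitive class).
2. **Fuzzy matter-element scoring** — the units × indicators matrix R_mn is
   normalized to excellent dependent degrees (u = x/max x for characters
   where larger means more sensitive, u = min x/x otherwise), squared
   differences Δ = (u₀ − u)² against the ideal standard element are formed,
   and each unit's *Euclid approach degree* PH = 1 − √(Σᵢ wᵢ Δᵢ)
   (or the Hamming form 1 − Σ wᵢ Δᵢ; both rank identically) measures its
   closeness to the ideal.  Units are ranked by PH.
3. **Entropy weighting** — objective weights from data dispersion:
   b = (r − r_min)/(r_max − r_min), corrected frequencies
   f = (1 + b)/Σ(1 + b), normalized entropy H = −Σ f ln f / ln m, and
   w = (1 − H)/(n − ΣH).  Indicators that do not discriminate between
   units get weight exactly 0.  Fixed expert weights (a shipped hierarchy)
   can be used instead.
4. **Synthesis** — the composite index G = Σ wⱼ·gⱼ, applied recursively up
   the A/B/C/D indicator hierarchy (a weighted mean at every node), then
   classified by the intervals [1,3), [3,5), [5,7), [7,9), [9,10].
5. **GIS overlay** — factor polygon layers are intersected so every output
   polygon carries one grade per layer, same-class polygons are dissolved
   (area-conserving), and per-class areas are tabulated in hectares with
   proportions of the evaluated total.

A synthetic-data module generates gridded polygon units whose raw values
land in chosen grade bins, with configurable class mixture, within-bin
noise and bin-leak probability, so the whole pipeline is testable without
any external data.  Fixtures transcribe the published grade system, weight
hierarchy and per-class area tables of a city-scale case study (defects in
the printed source are kept as printed and flagged).

## Worked example

```python
import ecosens as es

scheme = es.load_fixture("table1")   # 40-indicator grade system
tree   = es.load_fixture("table5")   # expert weight hierarchy

cfg = es.SimulationConfig(rows=10, cols=10, cell_size=1000.0,
                          mixture=(0.2, 0.2, 0.2, 0.2, 0.2),
                          sigma=0.05, eps=0.05, seed=42)
sim = es.generate_units(cfg, scheme)

areas = es.compute_areas(sim.layer)          # 1 km x 1 km cells = 100 hm²
areas.index = sim.layer.frame["unit_id"]

res = es.SensitivityModel(sim.raw, scheme, tree=tree, areas=areas).fit()
print(res.summary())
```

prints

```
Eco-environmental sensitivity evaluation
========================================================
units: 100    indicators: 40
weights: fixed    approach-degree variant: euclid
composite index G: min 1.000  mean 4.865  max 9.000

class distribution:
  1  insensitive                32  (32.00%)
  3  slightly sensitive         18  (18.00%)
  5  moderately sensitive       24  (24.00%)
  7  highly sensitive           24  (24.00%)
  9  extremely sensitive         2  (2.00%)

area summary (hm², % of evaluated total):
  1  insensitive                3,200.00   32.00%
  3  slightly sensitive         1,800.00   18.00%
  5  moderately sensitive       2,400.00   24.00%
  7  highly sensitive           2,400.00   24.00%
  9  extremely sensitive          200.00    2.00%
```

One hundred 1 km² units were simulated with a uniform class mixture and
mild noise (5% of a bin width, 5% bin-leak), graded on all 40 indicators,
aggregated under the fixed expert weights and classified; the class shares
track the generating mixture up to noise.  `res.rank()` orders units by
their approach degree toward the ideal, `res.G` holds the per-unit
composite index, and `res.weight_tree` the weights actually used
(`weights="entropy"` derives them from the data instead).

The same steps are available from a shell:

```bash
ecosens simulate --rows 10 --cols 10 --seed 42 --out sim/
ecosens evaluate --raw sim/raw.csv --units sim/units.geojson --out result.csv
ecosens overlay --layers a.geojson b.geojson --dissolve-by class_index --out merged.geojson
```

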