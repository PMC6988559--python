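# scalescan

**Scale-dependent temporal beta diversity for river networks.**

When a drainage is resurveyed decades after an original survey, the answer
to "how much did the fish assemblage change?" depends on the spatial grain
of the question. Individual stream reaches can turn over almost completely
while the pooled drainage keeps nearly the same species at nearly the same
relative abundances — local extirpations are balanced by colonization from
connected sites. scalescan is for community ecologists (and anyone doing
compositional resurvey analysis — the machinery transfers directly to
microbiome beta diversity) who want to measure that scale dependence
explicitly instead of picking one grain by convention, and to ask where on
the scaling axis change stops behaving like local noise: a *domain of
scale* boundary.

## What it computes

Given site × species abundance tables for two periods, site coordinates
and Strahler orders, and a fluvial (river-km) distance matrix:

1. **Taxon harmonization** (merge/rename map, totals conserved), then
   **site pairing**: each resurvey site matched to its fluvially nearest
   historical site, retained when straight-line distance < 8 km and stream
   order matches; one-to-one by default.
2. **Temporal dissimilarity** per pair: Morisita–Horn
   `d(x, y) = 1 − 2Σxᵢyᵢ / ((dx + dy) X Y)` with `X = Σxᵢ`,
   `dx = Σxᵢ²/X²` (scale-invariant, abundance-based), or Jaccard
   `1 − a/(a+b+c)` on presence/absence.
3. **The scale scan**: a Ward hierarchy on fluvial distance, cut at every
   K from N pairs (local) to 1 (global); pairs pooled per cluster and the
   temporal dissimilarity recomputed, giving K values per grain K.
4. **Discontinuity test** for a nominated grain: B = 100,000 bootstrap
   means of K draws from the N local values; p = fraction of means ≤ the
   observed mean at K.
5. **Diversity bookkeeping**: Hill-number partition with equal site
   weights, γ = α × β (default q = 0: mean site richness, pooled richness),
   site-resampling bootstrap SEs, Simpson's reciprocal, and species
   persistence counts that close exactly against γ.

A seeded generator of dendritic riverscape metacommunities (lognormal
regional pool, distance-decay occupancy, identity turnover with persistent
local dominance, optional planted tributary-scale domain) makes every
stage runnable and testable offline.

## Worked example

Find the planted domain of scale in a synthetic riverscape
(`examples/03_scale_scan_and_domain_test.py`):

```text
 K  n  mean    q1  median    q3   min   max
 1  1 0.082 0.082   0.082 0.082 0.082 0.082
 5  5 0.050 0.014   0.022 0.053 0.014 0.144
10 10 0.037 0.008   0.017 0.052 0.001 0.153
15 15 0.015 0.001   0.001 0.016 0.000 0.113
20 20 0.272 0.004   0.109 0.450 0.000 0.990
33 33 0.703 0.484   0.831 0.949 0.161 1.000

median change is minimized at K = 15 (planted tributary count: 15)
bootstrap test at K = 15: observed mean 0.015, p = 0.0000
```

Reading it: at the local grain (K = 33) the median 40-year change is 0.83
— reaches are individually unstable. Change collapses at K = 15, exactly
the number of tributaries in which the generator homogenized turnover, and
rises again for coarser pooling as tributaries with drifted abundance
weights are mixed. The bootstrap p-value says a mean this low at K = 15
essentially never arises from resampling the local values: a genuine
domain boundary, not sampling noise. The same pipeline on default
(unplanted) data shows the plain local-vs-global contrast
(`examples/02_local_vs_global_change.py`):

```text
33 retained pairs, 33 exact matches
local MH dissimilarity: mean 0.37, range 0.01-0.98
global MH dissimilarity (drainage pooled): 0.06
```

The other examples cover the generator itself (`01`) and the diversity
partition with bootstrap SEs (`04`). The same workflow is scriptable from
a shell:

```bash
scalescan simulate --seed 7 --out synth/
scalescan run --abundance synth/abundance.csv --sites synth/sites.csv \
              --fluvial synth/fluvial_km.csv --k-test 15 --out results/
```

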