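# Methods

## The question the package answers

A drainage is resurveyed decades after an original fish survey. At any one
stream reach the assemblage may have turned over almost completely, yet the
species list of the whole drainage can be nearly unchanged: local
instability need not propagate upward when sites are coupled by dispersal.
*At what spatial grain does compositional change stop looking like local
noise and start looking like regional change?*  scalescan answers this by
measuring temporal beta diversity at every grain between "one site pair"
and "the whole drainage", and testing candidate discontinuities — domains
of scale — against a resampling null.

## The procedure

1. **Harmonize taxa.** User-supplied merge/rename operations are applied
   before anything else (the default map carries the three operations needed
   for the 1974/2014 Oklahoma fish data this design follows: two
   *Campostoma* and two *Fundulus* species collapsed to genus groups, and
   *Notropis rubellus* reassigned to *N. suttkusi*). Merges conserve row
   totals exactly.

2. **Pair sites.** Each second-period site is matched to its fluvially
   nearest first-period site; a pair is kept only if the straight-line
   (haversine, R = 6371.0088 km) distance is < 8 km and both reaches have
   the same Strahler order. Default matching is one-to-one: candidates are
   consumed from a single globally ascending queue of fluvial distances
   (ties broken lexicographically by site id), so a contested historical
   site goes to the closer resurvey and the loser falls through to its next
   eligible option. This prevents pseudo-replication; a many-to-one mode
   preserving the literal per-site "nearest" reading is available. Nothing
   in the matcher is stochastic, and the result is invariant to input row
   order.

3. **Local change.** Morisita–Horn dissimilarity (Horn's relative-abundance
   form, `1 − 2Σxy/((dx+dy)XY)` with `dx = Σx²/X²`) between the two periods
   of every pair; Jaccard (`1 − a/(a+b+c)`) on presence/absence as the
   coarse-resolution check. Morisita–Horn is invariant to per-vector
   rescaling, so unequal sampling effort between surveys cancels; for this
   reason no abundance standardization is applied anywhere. The classic
   small-sample Morisita variant is available behind a flag. Empty
   assemblages raise errors rather than produce NaN — a silent NaN would
   flow through every downstream summary.

4. **Pool across grains.** A Ward hierarchy is built on the fluvial
   distance matrix of the pairs (Lance–Williams recurrence on squared
   dissimilarities; deterministic lexicographic tie-break). This is the
   spatially constrained ("Ward-like") clustering with the spatial mixing
   weight at its boundary value 1.0, where the compositional matrix is
   accepted and ignored and the method degenerates to plain Ward on space.
   Cutting the tree at every K from N down to 1 and pooling member pairs
   per period gives K pooled temporal dissimilarities per grain. Only
   memberships feed downstream, so any Ward-on-d² variant producing the
   same topology is equivalent; merge heights are reported on the distance
   scale merely for plotting. Fluvial matrices that violate the triangle
   inequality (possible when pairing approximates locations) are accepted
   with a logged warning — the recurrence does not require metricity.

5. **Test a discontinuity.** For a nominated grain K, draw K values with
   replacement from the N local (K = N) dissimilarities, record the mean,
   repeat B = 100,000 times; p is the exact count fraction of bootstrap
   means ≤ the observed mean at K (one-sided "≤", no continuity
   correction), with quartiles of the bootstrap distribution reported
   (linear-interpolation quantiles). Which K to test is the user's choice,
   as the candidate comes from inspecting the per-K summaries; testing many
   K invites multiplicity, which is logged but deliberately not corrected —
   matching the design this follows, which applied a single visual
   candidate at α = 0.05.

6. **Diversity bookkeeping.** Hill-number partition with equal site
   weights: gamma from the pooled assemblage, alpha the equal-weight Hill
   mean across sites (`(Σ_i Σ_s p_is^q / N)^(1/(1−q))`), beta = gamma/alpha
   — multiplicative by construction. Default order q = 0, where alpha is
   mean site richness and gamma pooled richness, and the species ledger
   closes integer-exactly: shared + period-unique species = gamma. SEs come
   from resampling sites with replacement (B = 10,000), implemented as one
   multinomial-weight matrix product; point estimates are plug-in values,
   not bootstrap means. Simpson's reciprocal (Hill q = 2) is reported for
   the pooled assemblage per period.

## The synthetic riverscape

The generator exists so every stage — file formats included — runs offline
with the statistical structure the analysis assumes. What it emulates:

- **Geometry.** A mainstem with `n_tributaries` junctions (spacing
  U(8, 20) km) carrying compact tributary subtrees (edges U(0.5, 4) km),
  one site per subtree node plus one at each tributary mouth, so site
  Strahler orders span the hierarchy. Headwater drainages being small
  relative to mainstem spacing is what makes "the tributary" a well-posed
  spatial grain; with a single edge-length distribution everywhere, no
  scale separates and no clustering level is privileged. The planar
  embedding steps each edge at full length with bounded turning, so
  straight-line distance is a contraction of fluvial distance; pseudo
  lat/lon scale the embedding near (34.2°N, 96.3°W) with a 3% shrink so the
  great-circle approximation preserves the contraction.
- **Regional pool.** `n_species = 50` lognormal(2.0, 1.2) regional
  abundances; each species occupies a contiguous river neighborhood around
  a focal reach, occupancy probability `exp(−0.03 · river-km)`.
- **Local assemblages.** Multinomial samples of 150 individuals weighted by
  regional abundance × a persistent site-level lognormal(0, 1.2) dominance
  factor (local lottery/filtering). Without the dominance factors every
  site tracks the regional ranking and abundance-based dissimilarity barely
  registers identity turnover; with them, site compositions are individual
  and their changes are visible to Morisita–Horn. Defaults give mean site
  richness ≈ 10, pooled richness ≈ 46–50 with near-singleton species, and
  (at τ = 0.5) mean local MH ≈ 0.35 against global MH ≈ 0.1.
- **Turnover (default mode).** Per site each occupied species is dropped
  with probability τ (default 0.5) and replaced by a
  propagule-pressure-weighted draw from the locally available,
  not-currently-present species; abundances of changed sites are redrawn
  with dominance factors refreshed only for incoming species. Unchanged
  sites keep counts bit-for-bit, so τ = 0 reproduces the period exactly. A
  third period (8 resurveyed sites, τ₂ = 0.15) exercises the one-year
  comparison path.
- **Planted domain (for parameter-recovery testing).** Three ingredients
  homogenize turnover at the tributary scale: (i) second-period
  assemblages within a tributary are a cyclic permutation of its
  first-period assemblages — every site changes, no subset of a tributary
  is invariant, but the pooled tributary is; (ii) tributary totals drift by
  lognormal(0, 1.0) factors, carried by deterministic rescaled copies of
  the permuted compositions, so pooling *across* tributaries mixes stable
  but distinct compositions with shifted weights and measured change rises
  again below the tributary grain; (iii) residual site-level weight jitter
  scales with each tributary's isolation *excess* over the best-connected
  tributary (lognormal sd 0.25 × excess), a rescue-effect gradient that
  leaves the first-merged (least isolated) tributaries quietest. The result
  is a sharp interior minimum of per-K median change at K = n_tributaries,
  recovered in ≈95% of seeded runs by `recovered_domain` (argmin of the
  per-K median; ties resolve to the smallest K).

What the generator does **not** emulate — and therefore what passing tests
cannot show about real data: detection error and effort variation between
surveys; mechanistic population dynamics or environmental covariates;
correlated (directional) regional change such as homogenization by
invaders; and a realistic colonization tail — because replacement draws are
propagule-weighted and the 50-species pool is nearly saturated in period 1,
species unique to period 2 are rarer than the converse (the field data this
emulates had a roughly symmetric 9/7 split). The planted mode additionally
drops sampling noise from second-period counts (deterministic rescaled
copies); it is an engineered testbed for the scan, not an ecological
forecast.

## Numerical choices

- Dissimilarities clamped to [0, 1]; symmetry enforced by averaging with
  the transpose (fp noise only); 1e-12 tolerances on exactness assertions.
- Bootstrap p-values are exact count fractions (multiples of 1/B); all
  quantiles are linear-interpolation (type-7).
- Ward ties: lexicographically smallest node-index pair; under exact ties a
  dendrogram is not unique and no particular published tree is claimed.
- Cluster ids at a cut are 1..K ordered by smallest member label; the K-cut
  always refines the (K−1)-cut.
- Seeds: every stochastic component takes an explicit seed; composite runs
  derive independent streams with `SeedSequence.spawn`. Degenerate inputs
  (empty assemblages, K out of range, orphan sites, chained taxon maps) are
  hard errors naming the offender.

## Problem sizes in the shipped checks

The test suite and the acceptance script use the default study conditions:
33 pairs, 50 species, 150 individuals per visit; B = 100,000 for the
discontinuity bootstrap and B_div = 10,000 for the diversity bootstrap;
50 seeded runs for planted-domain recovery and 100 for the local-vs-global
contrast. Everything runs in a few minutes on one CPU.

## Known limitations

- The one-to-one pairing rule is a design choice; the original study
  reduced 65 candidate resurveys to 33 pairs without stating its conflict
  resolution, so neither matching mode claims to replicate that selection.
- The diversity partition assumes equal site weights and defaults to q = 0;
  other orders are exposed but the bootstrap resamples whole sites only (no
  within-site rarefaction).
- No automatic changepoint detection: the scan reports boxplot-ready per-K
  summaries and tests user-nominated grains, matching a visual-inspection
  workflow.
- Fluvial distances are an input (or synthetic); routing real hydrography
  into a distance matrix is out of scope.
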