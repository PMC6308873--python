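# Methods

This note documents the statistical models, the defaults and why they were
chosen, the synthetic-data assumptions, and the numerical conventions used
throughout `mixedstock`.

## Data model and exclusion rules

A `HaplotypeCountTable` is a populations × haplotypes matrix of
non-negative integer counts with exactly one row flagged as the mixture
(the feeding-ground sample); all other rows are sources (nesting
rookeries). Source rows must have positive totals; the mixture row may be
empty, in which case the mixed stock analysis returns its prior — a useful
degenerate case for checking prior dominance.

Before any downstream analysis, four exclusion rules reduce the haplotype
columns, in a fixed order:

1. **orphans** — present in the mixture but in no source. Such haplotypes
   cannot be traced to any sampled rookery and carry no assignment
   information;
2. **source-only** — absent from the mixture, hence uninformative about it;
3. **shared singletons** (optional, default on) — exactly one copy in the
   mixture *and* exactly one copy summed across all sources. A single
   shared copy would pin a whole mixture individual to one rookery on the
   strength of one observation; the rule is exposed as a toggle rather
   than hard-coding any particular haplotype, with a manual exclusion list
   as an escape hatch for ad-hoc choices;
4. **manual** labels.

On the bundled Atlantic table these rules exclude CM-A4, CM-A6, CM-A10,
CM-A12 (source-only) and CM-A50 (shared singleton: one Martinique copy,
one Ascension Island copy), retaining five of ten haplotypes. Column order
is preserved so that the sampler's documented draw order — and hence
bit-reproducibility — does not depend on set iteration order.

## Diversity estimators

Gene diversity uses Nei's unbiased estimator
`Hs = n/(n-1) (1 - Σ p²)` with sampling variance
`V = 2/(n(n-1)) {2(n-2)[Σp³ - (Σp²)²] + Σp² - (Σp²)²}`.
Nucleotide diversity is the frequency-weighted mean per-site difference
over haplotype pairs with the same n/(n-1) correction, which equals the
plain average over all C(n,2) individual pairs (the test suite checks this
identity against a brute-force loop). Its reported SD is the square root
of Nei's total variance `(n+1)/(3(n-1)L)·π + 2(n²+n+3)/(9n(n-1))·π²`,
i.e. including the stochastic (evolutionary) component, which is what the
standard population-genetics packages print.

Gaps and ambiguous bases are handled by pairwise deletion everywhere. The
TN93 distance is computed from the purine-transition, pyrimidine-transition
and transversion proportions with base frequencies estimated from the
compared pair; a non-positive logarithm argument (saturation) raises a
dedicated error rather than returning a truncated value.

Two published per-rookery diversity values (Cayenne 0.476, Awala 0.239)
are *not* reproducible from the bundled count table under Nei's estimator
(which gives 0.407 and 0.091); the Martinique and Suriname values are
reproduced exactly. The bundled counts are taken as authoritative and the
discrepancy is documented rather than patched.

## Pairwise ΦST and permutation tests

Differentiation between two populations is the AMOVA fixation index: with
squared haplotype distances `D²` (identity distance reproduces the pure
frequency statistic), sums of squares within and among populations give
variance components `σ²_w = SSD_w/(N-2)` and
`σ²_a = (SSD_a - σ²_w)/n_c`, `n_c = N - (n_a² + n_b²)/N`, and
`Φ_ST = σ²_a/(σ²_a + σ²_w)`. Negative estimates are reported as computed
(they arise for identical frequency profiles at finite n); truncation at
zero is available behind a flag but off by default so that the permutation
reference distribution is untampered. The engine is validated against a
brute-force AMOVA computed from the expanded individual-level distance
matrix.

The permutation test pools the individuals of the two populations,
reallocates them with sample sizes fixed, and uses the add-one rule
`p = (1 + #{Φ* ≥ Φ_obs})/(B + 1)`, so the attainable minimum is 1/(B+1)
and p is never zero. Published pairwise FST values for this system were
computed from deposited GenBank sequences that are not shipped here, so
the machinery is validated by oracle equivalence and null-uniformity
simulations instead of by reproducing those numbers.

## Many-to-one mixed stock analysis

The sampler is the standard conjugate latent-assignment Gibbs scheme for
a single mixture (Pella–Masuda style):

- `z_i | θ, q ∝ θ_s · q_s[h_i]` for each mixture individual i (individuals
  sharing a haplotype are exchangeable, so assignments are drawn as one
  multinomial per haplotype column — identical target, far fewer draws);
- `q_s | z ~ Dirichlet(source counts + 1/H + assigned mixture counts)`;
- `θ | z ~ Dirichlet(1/S + assignment counts)`.

Defaults: θ prior Dirichlet(1/S,…,1/S) — each rookery equally likely to
contribute a priori, with total prior weight of a single observation —
and 1/H pseudocounts on source frequencies; 4 chains of 25,000 iterations,
50% burn-in, thinning 5; overdispersed initialization (each chain starts
with θ mass 0.9 on a different randomly chosen source), which is what
makes the Gelman–Rubin diagnostic meaningful. All are configurable.
Convergence is assessed per source on the θ marginals with the classic
potential scale reduction factor `sqrt(((n-1)/n·W + B/n)/W)`; values below
1.2 are accepted. Identical constant chains return the sentinel 1.0;
internally constant chains that disagree return +inf.

Chain seeds are spawned from a single `numpy` `SeedSequence`, so a given
(seed, config) is bit-reproducible. Correctness is established three
independent ways in the tests: a closed-form conjugate (Beta) posterior in
a two-source scenario with effectively known source frequencies; prior
recovery with an empty mixture; and 95%-credible-interval coverage of a
known θ across 20 seeded synthetic replicates (5 well-separated sources,
mixture of 200, coverage of ≥4 of 5 components required in ≥90% of
replicates — observed 20/20).

### The regional headline and its discrepancy

On the reduced Atlantic table with the shipped four-region map, the
posterior concentrates about 57% of the mixture on the five Eastern
Caribbean rookeries (seed-stable to ±0.2 points; all shrink factors
≈ 1.01). The originating study reported 40% for that region. The
difference is structural, not Monte-Carlo: 21 of the 40 mixture
individuals carry CM-A5, which after exclusions is carried at high
frequency almost exclusively by the Eastern Caribbean rookeries (Costa
Rica, at frequency 0.25, is the only competitor), so any equal-prior
many-to-one fit places roughly half the mixture there. A prior-sensitivity
sweep over standard symmetric choices (θ concentration 1/S to 1, frequency
pseudocount 0.1 to 1) moves the regional mean only within 48–64%. The 40%
figure is therefore not recoverable from the bundled counts under this
model class; the acceptance test that encodes it is expected to fail and
is kept as an honest record of the discrepancy, alongside the
Cayenne/Awala diversity inconsistencies above.

## Track cleaning

Filters run in the fixed order land → speed → class, and the filter report
counts removals by stage against the original point count, mirroring how
such error budgets are usually quoted (e.g. 51% on land, 8% over-speed,
0.1% class Z for shore-proximate Argos data).

- **Land**: nearest-cell lookup in a regular lon/lat grid (ESRI ASCII grid
  dialect, 1 = land); cell centers define the grid and a point exactly on
  a boundary resolves to the lower index. Queries outside coverage raise.
  The mask resolution is a free parameter of the mask file.
- **Speed**: a forward pass against the last *retained* point removes any
  point whose great-circle speed is strictly over `vmax` (default
  10 km/h). The pairwise alternative invalidates both segments around a
  single bad fix; the last-retained-point rule removes exactly the bad fix
  and is therefore the shipped default (the comparison basis is a
  documented, swappable choice). Zero time gaps drop the later duplicate.
  The first point is always retained.
- **Class**: membership test against an excluded-class set, default {Z}.

Distances are great circles on a sphere of radius 6371.0 km (haversine);
the sub-0.5% ellipsoidal error is irrelevant at the precision of any
telemetry summary. Summaries use sample (n−1) SD throughout — this choice
reproduces the published cohort footers (515 ± 349 locations,
4394 ± 1964 km, duration SD 79 days) from the bundled per-turtle rows.
The published cohort CCL and body-mass footers (85.9 ± 3.8 cm, 81 ± 9.3 kg)
do not equal the mean ± SD of the printed per-turtle values (85.2 ± 4.3 cm,
74.7 ± 8.7 kg); they are bundled as-is and not asserted.

## Synthetic-data generators

All generators are pure functions of (parameters, seed) on numpy's PCG64,
with draw order documented in each docstring; fixtures are generated at
test time, never stored.

- **Rookeries**: per-source frequencies from a symmetric
  Dirichlet(0.3) — low concentration reproduces the strong skew of real
  control-region tables (one to three common haplotypes, several rare
  private ones) — then multinomial counts. The canonical scenario matches
  the reference system's scale: 15 sources with the bundled tables' row
  totals (22–214), 10 haplotypes, mixture of 40.
- **Mixture**: individuals draw a source from the true θ and a haplotype
  from that source's *true* (not observed) frequencies, so recovery tests
  measure estimation error only.
- **Sequences**: one random ancestor plus k uniform-random substitutions
  per haplotype at distinct sites (k uniform on a configurable range), so
  the haplotype-to-ancestor p-distance is exactly k/L.
- **Tracks**: a correlated random walk (heading noise SD 0.4 rad per
  15-min step) at 5 km/h, with disjoint planted corruption sets at the
  rates above: land points teleported to random land-cell centers, speed
  outliers displaced by twenty vmax-intervals (~50 km, large enough that
  the jump still exceeds vmax across a run of a dozen removed land
  points), and class-Z relabels. Because the walk's own segment speeds
  stay at the base speed and headings decorrelate across gaps, the three
  filters remove exactly the planted sets at the default rates — which is
  what the truth-label tests assert.

What the generators do **not** emulate: spatially correlated Argos error,
tidal/current drift, haplotype genealogy (sequences are star-shaped around
one ancestor), rookery-size-correlated sampling effort, and temporal
structure in class-Z occurrence. Tests passing on synthetic data therefore
demonstrate correctness of the estimators and filters under their stated
assumptions, not robustness to every pathology of field data.

## Problem sizes and runtimes

The test suite runs the full-scale sampler configuration (4 × 25,000 on
the 15-source table, a few seconds) for the headline checks, and reduced
chains (2 × 3,000–6,000) for unit-level properties where only Monte-Carlo
consistency is needed; permutation-null uniformity uses 200 replicate
datasets × 199 permutations. These sizes were chosen to keep the whole
suite under a minute while leaving every assertion's tolerance dominated
by the statistic being tested rather than by simulation noise.

## Known limitations

- Only two-population AMOVA is provided (no hierarchical or >2-group
  variants), matching the pairwise use case.
- The many-to-one model has no rookery-size weighting or ecological
  covariates; the equal-contribution prior is the stated assumption.
- TN93 falls back to an error on saturated pairs rather than switching to
  a different correction.
- The land mask supports the plain-text ESRI ASCII grid dialect only.
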