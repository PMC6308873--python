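# mixedstock

Tools for locating the natal origins of a mixed feeding-ground aggregation
from mtDNA haplotype frequencies, and for cleaning the satellite tracks that
document where those animals go next. The package was built around a
juvenile green turtle (*Chelonia mydas*) system — a Caribbean feeding
ground sampled for D-loop control-region haplotypes, with 15 Atlantic
nesting rookeries as candidate sources, plus Argos/Fastloc-GPS tracks of
the juveniles that eventually migrate away — but every component is generic
over any rookery-and-mixture marker dataset and any point telemetry.

## What it computes

**Population genetics.** For each population with haplotype counts
$c_1,\dots,c_H$ ($n=\sum_h c_h$, $p_h=c_h/n$):

- Nei's unbiased gene diversity
  $H_s = \frac{n}{n-1}\bigl(1-\sum_h p_h^2\bigr)$ with its sampling
  variance, and nucleotide diversity
  $\pi = \frac{n}{n-1}\sum_{i<j} 2 p_i p_j d_{ij}$ per site from an aligned
  haplotype set (pairwise deletion of gaps/N);
- Tamura–Nei (TN93) corrected distances between aligned haplotypes;
- pairwise $\Phi_{ST}$ from a two-group AMOVA with a pluggable haplotype
  distance matrix, and permutation tests that reallocate individuals
  between the two populations ($p = (1+\#\{\Phi^*\ge\Phi\})/(B+1)$).

**Bayesian many-to-one mixed stock analysis.** A Pella–Masuda-style Gibbs
sampler for the contribution vector $\theta$ of $S$ sources to one mixture:
each mixture individual carries a latent origin $z_i$ drawn
$\propto \theta_s\, q_s[h_i]$, source haplotype frequencies
$q_s \sim \mathrm{Dirichlet}(\text{counts} + 1/H)$, and
$\theta \sim \mathrm{Dirichlet}(1/S + \text{assignment counts})$ — every
rookery equally likely to contribute a priori. Multiple overdispersed
chains, per-source Gelman–Rubin shrink factors (convergence accepted below
1.2), 95% credible intervals, and draw-wise aggregation of contributions
into regions.

**Telemetry cleaning.** The standard three-stage filter for shore-proximate
Argos data — points on land (against a raster land mask), great-circle
travel speed strictly over 10 km/h from the last retained point, and
unresolved location class Z — followed by per-track summaries (locations,
duration, path length, segment speeds) and cohort means ± sample SD.

**Synthetic data.** Seeded generators for rookery count tables
(Dirichlet-multinomial), mixtures drawn from known contributions, aligned
haplotype sequences with planted substitutions, and Argos-like tracks with
planted land/speed/class-Z errors — each returning the ground truth that
recovery tests assert against.

## Worked example

```python
>>> from mixedstock import datasets, apply_exclusion_rules, gene_diversity
>>> table = datasets.load_reference_counts()   # 16 populations x 10 haplotypes
>>> gene_diversity(table.row("MT"))            # the feeding-ground sample, n=40
(0.6743589743589743, 0.06346984696971447)
```

So the mixed aggregation is genetically diverse ($H_s = 0.674 \pm 0.063$),
as expected for a feeding ground drawing from many rookeries. Reduce the
table and fit the mixed stock analysis:

```python
>>> reduced, report = apply_exclusion_rules(table)
>>> sorted(report.all_excluded)
['CM-A10', 'CM-A12', 'CM-A4', 'CM-A50', 'CM-A6']
>>> from mixedstock.msa import MsaConfig, fit_msa
>>> fit = fit_msa(reduced, MsaConfig(seed=1))  # 4 chains x 25,000 iterations
>>> float(fit.shrink.max())
1.0061229527746665
>>> {r: round(100 * s["mean"], 1) for r, s in fit.region_contributions.items()}
{'Eastern Caribbean': 57.4, 'Northern Western Caribbean': 22.3,
 'Southwest Atlantic': 8.2, 'Southeast Atlantic': 12.0}
```

All shrink factors are below 1.2, so the four chains agree. The posterior
puts about 57% of the mixture on the five Eastern Caribbean rookeries
(Aves, Guadeloupe, Suriname, and the two French Guiana beaches) — the
mixture's dominant haplotype CM-A5 is carried at high frequency almost
exclusively there — with most of the rest on the northwestern Caribbean.
Individual rookeries within a region are only weakly separable (wide,
zero-touching credible intervals), which is why contributions are reported
regionally.

The same CLI is available from a shell: `mixedstock genetics`,
`mixedstock msa`, `mixedstock tracks`, `mixedstock simulate ...`
(`--help` on each).

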