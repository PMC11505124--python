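# ffgassess

Functional-feeding-group (FFG) bioassessment of river macroinvertebrate
communities, built for surveys like the upper Yellow River programme it
emulates: benthic macroinvertebrates collected at fixed sites in a
dam-regulated gorge reach and a downstream alluvial plain reach across
several months, identified to genus/species, counted, weighed, and
converted to areal density (ind./m²) and biomass (g/m²).

From three delimited-text tables — a long-format sample table, a
taxon-attribute table (FFG membership + pollution-tolerance value), and a
site-by-environmental-factor table — the package computes:

- **FFG composition and dominance.** Relative abundance of the five FFGs
  (collector-gatherers CG, predators PR, scrapers SC, collector-filterers
  CF, shredders SH) per river section and month, and the species
  dominance index *Y* = (*n*ᵢ/*N*) · *f*ᵢ, where *n*ᵢ is a taxon's mean
  density, *N* the total density of its FFG, and *f*ᵢ its occurrence
  frequency; *Y* > 0.02 flags a dominant species.
- **Biotic indices with water-quality classes.** The Hilsenhoff
  Biological Index HBI = Σ *n*ᵢ*X*ᵢ / *N* (abundance-weighted mean
  pollution tolerance) and the Shannon–Wiener index
  *H*′ = −Σ *P*ᵢ log₂ *P*ᵢ, each mapped to five classes
  (Excellent … Very bad).
- **Eleven FFG ecosystem-attribute parameters** (F1–F11): densities and
  density ratios summarizing primary/secondary production,
  decomposition, longitudinal transport, lateral input, CPOM/FPOM input,
  top-down control and habitat stability.
- **Permutation statistics, written from first principles:** Bray–Curtis
  dissimilarity, crossed two-factor PERMANOVA (sequential sums of squares
  on the Gower-centered distance matrix), Mantel tests of FFG–environment
  association per month, and the Mann–Whitney U test with tie-corrected
  normal approximation and exact small-sample enumeration.
- **A synthetic survey generator** reproducing the study design
  (18 gorge + 15 plain sites × 4 months, 65 taxa, overdispersed counts,
  planted factor–FFG associations) for testing and power analysis.

## Worked example

```python
from ffgassess import (build_matrix, default_scenario, generate,
                       ffg_relative_abundance, index_report)

dataset = generate(default_scenario(), seed=1)
matrix = build_matrix(dataset.records)
print(ffg_relative_abundance(matrix, dataset.attributes).round(2))
```

```text
                  CG     PR     SC     CF     SH
gorge/March    81.93   5.95   8.62   3.49   0.00
gorge/May      64.09   8.87  13.75   6.99   6.31
gorge/July     85.89   1.26   8.97   3.14   0.74
gorge/October  65.78   6.73  13.74   9.67   4.08
plain/March    48.81  13.11  17.57  15.62   4.88
plain/May      24.78  21.13  18.46  11.45  24.19
plain/July     49.98   6.59  19.68  17.20   6.55
plain/October  15.05  17.45  30.90  29.14   7.45
```

Collector-gatherers dominate everywhere but decline from the gorge to the
plain, shredders are missing from the gorge in March, and scrapers and
collector-filterers peak in the plain in October — the spatial structure
the generator plants and the composition module recovers from one
simulated survey (sampling noise moves individual cells a few points off
their targets).

```python
per_sample, means = index_report(matrix, dataset.attributes)
print(means.head(2).to_string(index=False))
```

```text
    stratum  n_samples  hbi_mean  shannon_mean hbi_class shannon_class
gorge/March         18      4.30        2.7944      Good          Good
  gorge/May         18      4.67        3.3005      Good     Excellent
```

Each stratum row is the arithmetic mean of its per-sample index values
(HBI to 2 decimals, *H*′ to 4, half-away-from-zero) with the class of the
rounded mean. Synthetic tolerance values are drawn uniformly on [0, 10],
so simulated HBI means hover near 5 ("Good"); with a real tolerance table
the same report reproduces survey-style water-quality classifications.

The full pipeline (composition, PERMANOVA, dominance table, gorge-plain
density contrasts, Mantel screen, attribute table, index report) runs
from the shell:

```sh
ffgassess simulate --seed 3 --out data/
ffgassess run --samples data/samples.csv --taxa data/taxa.csv \
              --env data/environment.csv --out report/ --seed 7
```

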