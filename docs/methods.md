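# Methods

## Data model and conversion

The unit of observation is one taxon in one site-month collection event.
Replicate grabs/sweeps are assumed pooled upstream (one record set per
site and month sharing a single `sampled_area`), so density and biomass
conversion is a plain division: density = count / area (ind./m²),
biomass = wet weight / area (g/m²). Duplicate (sample, taxon) rows are
summed before division and logged; conflicting areas within one sample
are an error, not a warning. Taxa absent from a sample are materialized
as explicit zeros so that distance computations are defined on a
rectangular matrix. The sample identifier is the (site, month) pair; a
33-site × 4-month survey yields the 132-row layout whose PERMANOVA total
has 131 degrees of freedom.

## Dominance index

*Y*ᵢ = (*n*ᵢ/*N*) · *f*ᵢ with *N* the summed mean density of the taxa in
taxon *i*'s own FFG — not the whole community. This within-group reading
matters: it makes Σᵢ (*n*ᵢ/*N*) = 1 inside each FFG, so *Y* compares a
taxon only against its guild. *f*ᵢ is the fraction of the stratum's
samples in which the taxon occurs. *Y* is invariant to uniform rescaling
of densities, so mean densities, summed densities and raw counts give
identical values (tested); the implementation uses stratum-mean density.
Taxa whose whole FFG is absent from a stratum get an undefined (NaN) *Y*
and are never flagged dominant. Rendered dominance tables show only
*Y* > 0.02 entries, ordered by FFG then lexicographic taxon name.

## Biotic indices and classification

HBI is the abundance-weighted mean of per-taxon pollution-tolerance
values; *H*′ = −Σ *P*ᵢ log₂ *P*ᵢ in bits. The sign convention is the
conventional one: diversity formulas are sometimes printed without the
leading minus even where all reported values are positive, so the
implementation fixes *H*′ ≥ 0 explicitly.

The five-level class bands are published with overlapping endpoints
(HBI 3.9–5.4 "Good" and 5.4–7.0 "Moderate"), so the half-open
orientation is a package policy: HBI bands are lower-inclusive
([3.9, 5.4) is Good, hence HBI = 3.9 is Good), *H*′ bands are
upper-inclusive ((1, 2] is Moderate) with exactly 0 mapped to Very bad.
Alternative breakpoints can be passed to `classify`.

Display rounding follows survey-table convention: HBI to 2 decimals,
*H*′ to 4, half away from zero. Stratum means are computed in decimal
arithmetic before rounding so that a mean like 104.31/18 = 5.795 rounds
on its exact value (→ 5.80) rather than on its binary float neighbour.
Classes of stratum means are assigned to the rounded mean, matching how
published summary tables are read.

## Ecosystem attributes F1–F11

All densities entering F1–F11 are stratum-mean densities over the
stratum's samples; F2 is the stratum-mean total wet biomass. Ratios with
zero denominators are undefined (NaN, rendered "NA"), never coerced to
zero — a reach without shredders and collector-gatherers has no defined
habitat-stability ratio rather than a perfectly unstable one. "Total
SHs and CGs" in the habitat-stability denominator is read as
D(SH) + D(CG), consistent with the decomposition parameter F4; the
autotrophy/heterotrophy denominator is D(CF) + D(CG) only, following the
published attribute definitions literally. The default table reports the
six strata gorge, plain (pooling months) and March, May, July, October
(pooling sections).

## Permutation statistics

**Distance.** Bray–Curtis d = Σ|x−y| / Σ(x+y) is the default community
dissimilarity (Euclidean available); a pair of all-zero samples is
assigned d = 0 by convention and logged.

**PERMANOVA.** The squared distance matrix is Gower-centered
(G = −½ J D² J); sums of squares of the crossed design
section + month + section×month are sequential (Type I) in that order,
each term's SS being tr((H_k − H_{k−1}) G) for the nested hat matrices
H_k (computed by SVD, which is robust to the deliberate rank deficiency
of full dummy blocks). Pseudo-F tests each term against the residual
mean square; p-values come from free permutation of sample labels with
the add-one convention p = (1 + #{F* ≥ F}) / (n_perm + 1). 999
permutations by default, giving the 0.001 floor typical of published
tables; tiny designs can enumerate all n! relabelings exactly. On
Euclidean distances of univariate data the pseudo-F reduces to the
classical one-way ANOVA F (tested to 1e-9), and the one-factor case
matches scikit-bio's implementation exactly.

**Mantel.** Pearson (default) or Spearman correlation over the
n(n−1)/2 upper-triangle entries, one-tailed (greater), null distribution
by simultaneous row/column permutation of the second matrix. The
per-month screen pairs Bray–Curtis on each FFG's taxon sub-matrix with
Euclidean distance on each z-standardized environmental factor
(5 FFGs × 12 factors × months); cells with an absent FFG or a constant
factor are NA. No multiple-testing correction is applied to the grid.

**Mann–Whitney U.** U from midranks, tie-corrected variance, 0.5
continuity correction; Z < 0 when the first sample (gorge) tends below
the second (plain). For pooled sizes ≤ 10 the exact two-sided p is
computed by enumerating every split of the pooled values; the exact path
agrees with brute-force enumeration for all layouts with n ≤ 8 and the
asymptotic path with scipy's tie-corrected implementation.

All stochastic routines take a single integer seed that fans out to
independent substreams via `numpy.random.SeedSequence.spawn`; fixed
seeds make every result bit-reproducible.

## Synthetic survey generator

The generator emulates the target survey design: 18 gorge and 15 plain
sites visited in March, May, July and October; 65 taxa split
16 CG / 23 PR / 13 SC / 4 CF / 9 SH. Expected FFG relative abundances
per section × month are anchored at the survey's published extremes
(CG 89.7% in the gorge in March and 24.35% in the plain in October,
SC 28.34% and CF 25.86% in the plain in October, shredders absent from
the gorge in March); the remaining cells are interpolated fixture values
chosen to preserve the published gradients (CG declining gorge → plain,
SC/CF/PR/SH higher in the plain). Expected total densities
(110–500 ind./m² by section and month, gorge densest, July peak, March
minimum) put the section-pooled FFG means in the magnitude range of
published attribute tables.

Counts are negative binomial (dispersion k = 2 — field macroinvertebrate
counts are overdispersed) around per-taxon means obtained by splitting
each FFG's expected mass over its taxa with a geometric rank-abundance
series (decay 0.6), so every FFG has a Gammarus-like dominant taxon.
Wet weights are count × a fixed lognormal per-taxon body mass
(median 10 mg) × lognormal noise. Environmental factors are Gaussian
with section-specific means chosen as plausible large-river values.

Planted factor–FFG associations work through one standard-normal latent
per planted FFG per sample: the factor is drawn with correlation 0.7 to
the latent, and the FFG's expected density is multiplied by a mean-one
lognormal response exp(1.2 z − 0.72). Mean-one centering keeps planted
FFGs on their composition targets; the response scale 1.2 corresponds to
roughly ten-fold density swings across ±2 s.d. sites, a realistic
magnitude for benthic communities along environmental gradients. Planted
factors carry no contradictory section offset (conductivity means are
section-homogeneous): a factor whose between-section contrast opposes
the planted FFG's own section gradient would cancel the association in
pooled distances, which is a property of the design, not of the test.
Default plants: DO↔CG, Cond↔CG, PO4↔SH.

What the generator does **not** emulate: spatial autocorrelation along
the river, taxon-level environmental niches (the response acts on whole
FFGs), seasonal turnover in taxon identity, and a real tolerance table
(synthetic tolerances are uniform on [0, 10], fixed per taxon by seed).
Passing recovery tests therefore demonstrate correctness of the
estimators under the assumed sampling model, not field performance.

## Parameter recovery and problem sizes

A planted association acts on all samples, so recovery is assessed with
one pooled Mantel per plant (all 132 samples); the per-month screen
remains the analysis view, where detection of the sparse shredder link
is naturally weaker in months with few shredders. The recovery check
runs 100 generator seeds with 199 permutations per test (p resolution
0.005, ample for a 0.05 detection threshold) and completes in well under
a minute on one CPU; analysis-facing defaults stay at 999 permutations.
At the default effect sizes the PERMANOVA section effect and all three
planted links are detected in every run.

## Bundled reference values

`ffgassess/data/site_indices_reference.csv` holds published per-site
HBI and *H*′ values for the 33-site survey the default scenario
emulates. They are inputs for recomputing per-section monthly averages
and their classes. Fourteen of the sixteen recomputed averages equal the
published ones exactly; two (gorge May HBI 6.31 vs 6.30; gorge March
*H*′ 1.2850 vs 1.2849) differ by one unit in the last printed digit
because the original averages were evidently taken over unrounded
per-site values. The recomputed values are the ones asserted.

## Known limitations

- One FFG per taxon; no trait-based fuzzy membership.
- No kick-net effort correction and no taxonomic synonymy resolution;
  `sampled_area` must be supplied, never inferred.
- PERMANOVA permutes freely (no restriction within months); restricted
  permutation schemes are out of scope.
- The Mantel grid is reported uncorrected for multiple testing.
- No normative scoring of F1–F11; the package computes the parameters,
  interpretation is the analyst's.
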