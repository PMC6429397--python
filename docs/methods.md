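# Methods

This note documents the statistical procedures implemented in `microprot`,
the defaults they ship with, and what the synthetic-data tests do and do not
establish.

## Quantification

**NSAF.** Spectral counts are a length-biased proxy for abundance: longer
proteins expose more tryptic peptides. NSAF divides each count by the
protein's length in amino acids and renormalizes within each sample so
abundances sum to 1. Zeros are preserved exactly (an NSAF value is 0 iff the
count is 0), and a sample with no counts at all is an error, not a silent
column of NaNs.

**Size factors.** Between-sample depth is corrected by the median-of-ratios
estimator standard for overdispersed count data: for proteins detected in
*every* sample, compute each sample's ratios to the protein-wise geometric
mean and take the per-sample median, then rescale the factors to geometric
mean 1 (the declared reference convention, so the normalization is
scale-free). If no protein is detected everywhere the estimator refuses to
run and suggests a pseudo-count or a common-subset restriction rather than
guessing. Note that because NSAF columns already sum to 1, size factors on
NSAF capture *compositional* shifts, not raw sequencing-style depth; the
recovery guarantee (planted factors within 5% at ≥ 500 proteins, verified in
the tests) applies to any positive matrix whose columns differ by
multiplicative factors.

**Johnson transformation.** NSAF values are strongly right-skewed, so
Pearson correlation is computed after mapping to approximate normality
through the Johnson system. The fit uses the classical four-percentile
quantile-ratio method: data quantiles at the normal deviates ±z and ±3z give
spacings m, n, p, and the ratio mn/p² selects the family (S_U above 1, S_B
below, S_L on the boundary, tolerance 0.05). z is scanned over
0.25–1.25 in steps of 0.05 and the candidate whose transformed sample
maximizes the Shapiro–Wilk p-value wins. The candidate set always includes a
numerically-linear S_U standardization, which guarantees the transformation
never degrades the Shapiro–Wilk statistic (W is affine-invariant), including
on already-normal input. Fits require ≥ 20 finite, non-constant values;
every accepted fit is strictly increasing on the data range (δ > 0, λ > 0,
domain checked for the bounded families).

**Correlation support and zeros.** For a pair of samples the comparison
support is, by default, proteins detected in at least one member ("union";
"intersection" is available). The Johnson transform is fitted per pair on
the pooled positive values; zeros are passed through the fitted transform at
a half-minimum pseudo-abundance. When the fitted family is bounded below and
the half-minimum falls outside its support, the pseudo-abundance is placed
halfway between the lower bound and the smallest fitted value — undetected
proteins then map just below every detected one without the unbounded
leverage a boundary evaluation would produce (with raw boundary clamping,
union-support replicate correlations were dominated by a few ±20σ points and
even changed sign). Pairs with support < 3 are skipped with a warning and
excluded from averages; distinct isoforms are kept separate for correlation
and combined (counts summed, longest isoform's length kept) for everything
else.

## Exact multi-set intersection statistics

If m sets of sizes n₁..n_m are drawn independently and uniformly without
replacement from a background of N items, the running intersection is a
Markov chain: conditional on |X_{t−1}| = j, the next set covers
Hypergeom(N, j, n_t) of it. The implementation propagates this chain as a
dynamic program in log space (log-sum-exp), giving the exact pmf over
0..min(n), the product-form mean N·Π(nᵢ/N), and upper-tail p-values with no
Monte-Carlo error. For m = 2 this reduces to the one-sided
Fisher/hypergeometric test, which the suite asserts exactly; for m ≤ 4 the
pmf is cross-checked against an independent oracle that literally samples
random sets (10⁶ draws) and counts overlaps.

Design choices: the background N is configurable with two presets — the
searched-database size (16,972 reviewed mouse entries) as the default, or
the union of the supplied sets — and is always recorded in reports, since
the choice materially changes fold enrichments. p-values below the smallest
representable double are displayed as "< 1.0e-307" while the exact natural
log is kept; family summaries (e.g. "found in at least two replicates")
report the arithmetic mean FE over the combination family and a combined
p-value by Fisher's method computed from the exact log p-values, with the
method name always emitted beside the number.

## Candidate selection

Presence means spectral count ≥ 1 after filtering; upstream FDR control is
assumed already applied to the input table. Contaminant rows (flagged or
listed) and proteins detected in ≥ 2 negative-control replicates are dropped
under the default `exclude` policy; the alternative `baseline_subtract`
policy instead subtracts the negative-control mean abundance per protein at
the NSAF stage (floored at 0) — the choice is recorded in every report
because the source procedure is ambiguous between the two readings.
Subtractive lists are computed against the union of every *other* group's
total (not their additive lists), which makes subtractive lists of different
groups disjoint by construction. additive_k is monotone decreasing in k;
k defaults to 2, and the pipeline clamps k to the replicate count for
single-replicate groups (recording the effective k) rather than failing the
whole run.

With per-replicate detection probability p and r replicates, planted
group-exclusive proteins are recovered by the additive rule with probability
P(Bin(r, p) ≥ k) and by the subtractive rule with probability
P(Bin(r, p) ≥ 1) (cross-group false positives cannot occur for true
exclusives). At p = 0.7, r = k = 2 this is 0.49 vs 0.91 — the quantitative
core of the additive-vs-subtractive argument, asserted within 3 binomial
standard errors in the acceptance suite.

## Contingency enrichment

Fold enrichment is the proportion ratio FE = (a/n_s)/(b/N_b). In the default
inclusive mode (sample ⊂ background) the chi-square tests and the odds ratio
are computed on the sample-vs-whole-background table
[[a, n_s−a], [b, N_b−b]]; this is the layout under which the published
protrusion-localization significances (5.54 × 10⁻²⁸ and 6.05 × 10⁻¹⁴) are
reproduced exactly, so it is the package's definition rather than the
remove-the-sample complement layout. Both Pearson and Yates
continuity-corrected chi-square are emitted (df = 1, upper-tail p;
Yates ≤ Pearson always). Term-enrichment tables rank by raw Pearson p
ascending with ties broken by FE descending then term id, and carry
Benjamini–Hochberg adjusted p-values in an extra column that never replaces
the raw values. The "top-k protrusion-term percentage" comparison considers
over-represented terms only (FE > 1): core-dominated lists produce strongly
*depleted* protrusion terms whose small p-values would otherwise flood the
top of the ranking and invert the comparison's meaning. Annotations are flat
term → member sets keyed by gene symbol; no ontology-graph propagation is
performed.

## Synthetic experiments

The generator emulates the structure the analysis assumes, with full ground
truth: a shared abundant core (50% of proteins), per-group exclusive
complements (4% per group) in a low-abundance regime (abundance scaled by
0.15), scattered proteins present in random subsets of groups (35%
per group), contaminant rows, and negative controls that see a thin sliver
(5%) of the core at very low depth. The default topology is eight groups /
18 samples: three whole-cell controls (2–3 replicates, ~25,000 expected
spectra each), three protrusion groups (2–3 replicates, ~4,000 spectra), one
single-replicate fragile-protrusion group (~2,500 spectra), and duplicate
negative controls — mirroring the depth asymmetry that motivates the
subtractive approach. Counts are negative binomial (variance μ + μ²/k,
dispersion k = 10) around μ = depth × size-factor × length-weighted relative
abundance, so expected per-sample totals equal the configured depth and
scale linearly with it. Detection dropout is a separate Bernoulli draw,
logistic in log expected count (slope 1.4, midpoint at an expected count
of 1) or a fixed probability when configured — a zero can therefore arise
from either the count draw or non-detection, which is what produces
realistic replicate presence/absence variation. Protrusion-related
annotation terms (40 of 250) each center on one protrusion group's
exclusives (80% of members) because annotation profiles differ between
protrusion subtypes; the remaining terms are drawn uniformly. Exclusive
complements and term focus were set so the generated world reproduces the
reported qualitative structure of such experiments (large exclusive
fractions in protrusion samples; tens of percent protrusion-related top
terms under subtraction), not tuned to any test threshold.

What a green synthetic test establishes: the pipeline's set logic,
normalization, ranking and statistics behave as specified under a known
world with realistic count noise and dropout. What it does not establish:
anything about peptide-level identification, FDR filtering, chromatography
or instrument effects (not modeled — the unit is the protein-level spectral
count), nor the numeric enrichment folds of any particular real experiment.

## Numerical choices and degenerate inputs

- Probability arithmetic for intersections in natural-log space with
  log-sum-exp; display floor 1.0 × 10⁻³⁰⁷, exact logs retained.
- NSAF column sums asserted to 1 ± 1e-9; size factors to geometric mean
  1 ± 1e-9.
- Fold enrichments are kept at full precision internally; report-style
  rounding (integers ≥ 10, one decimal below) exists only in display
  helpers.
- Degenerate inputs fail loudly: all-zero sample columns, constant vectors,
  n < 20 for Johnson fitting, k above the replicate count, empty sample
  sets, sets larger than their background.
- Reports round floats to 10 significant decimals before JSON
  serialization, making identical-seed runs byte-identical across
  platforms with IEEE-754 doubles.

## Known limitations

- The Johnson fit optimizes Shapiro–Wilk p over a fixed z grid; it is not a
  maximum-likelihood fit and the selected family can differ between nearby
  samples. Only the transformed values' normality matters downstream.
- Size factors on NSAF matrices measure compositional shifts, not depth
  (NSAF already normalizes depth away).
- The exact intersection model assumes uniformly random sets; real replicate
  lists are abundance-biased, so the test is anti-conservative as a
  biological null and should be read as a descriptive enrichment measure —
  as is standard for this statistic.
- Combined p-values over overlapping combination families use Fisher's
  method, which assumes independence the combinations do not have; the
  method label travels with every combined value.
- The protrusion-term percentage depends on the annotation source's term
  granularity; only within-run comparisons between selection approaches are
  meaningful.
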