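# Methods

## Scope and data model

`beandiv` analyzes germplasm collections characterized with the standard
29-descriptor set for common bean: 13 quantitative traits with units and
16 qualitative traits whose states are small integer codes. The trait
catalog (codes, organs, kinds, level sets, units) is fixed in
`beandiv.catalog.default_catalog()`; collections are CSV files with an
`id,region,county` header plus trait-code columns, empty cells meaning
missing. Missing values are allowed in storage but are dropped per trait
by the diversity analysis (with a logged count) and drop the whole row
in clustering/PCA, where a distance with absent coordinates would be
undefined.

## Diversity indices

Quantitative traits are discretized into ten classes around the trait
mean X̄ using half-standard-deviation widths. The nine cut points are
b_k = X̄ − 2s + (k − 1)·0.5 s for k = 1..9. Class 1 is the open lower
tail x < X̄ − 2s and class 10 the open upper tail x > X̄ + 2s; interior
class j covers [b_{j−1}, b_j). Two edge conventions needed fixing:

- a value exactly equal to X̄ + 2s stays in class 9, because the upper
  tail is defined by a strict inequality;
- when s = 0 every observation is placed in class 6, the continuous
  limit of the class whose lower bound is the mean, giving H′ = 0.

The Shannon–Weaver index H′ = −Σ pᵢ ln pᵢ uses the natural logarithm
and runs over non-empty classes only (a 0·ln 0 term is defined as 0).
For qualitative traits the classes are the raw recorded state codes; the
ten-class scheme is never applied to coded states. The coefficient of
variation is CV = s/X̄; both s and the binning use the sample (n − 1)
standard deviation, the usual convention in trait statistics.

Organ-level diversity is the arithmetic mean of the member traits' H′,
split by trait kind (qualitative/quantitative); the collection-wide
index is the arithmetic mean over all 29 traits, and per-region indices
recompute the whole per-trait analysis on each region's accession
subset. The arithmetic mean is adopted as the aggregation rule because
it reproduces every published organ-level value from the corresponding
published per-trait values to within one unit in the last printed digit.
Internal computation is full precision; displayed values round half-up
to 3 decimals.

## Clustering

All included traits — qualitative codes treated as numbers — are column
z-scored (sample sd; constant columns become zero with a warning).
Treating ordinal/nominal codes as numeric is statistically debatable but
is the established procedure for this analysis, and the package is
faithful to it. Distances are Euclidean. UPGMA merges, at each step, the
pair of clusters with the smallest average inter-cluster distance; the
recorded merge height is that average distance itself (not halved), and
after a merge the distance to any third cluster is the size-weighted
average of the merged members' distances. The implementation delegates
to `scipy.cluster.hierarchy.linkage(method="average")`, which realizes
exactly this definition; the test suite checks it against a naive O(n³)
re-implementation that recomputes every average over original leaf
pairs. Ties between equal-minimum pairs are resolved by scipy's
deterministic scan order; tie order cannot change merge heights, only
labels. Cutting k groups removes the k − 1 highest merges (scipy
`fcluster`, `maxclust`), which is well defined because UPGMA heights are
monotone; group labels are assigned by size, descending. The dendrogram
exports as Newick with branch lengths derived from merge-height
differences, and as a merge-table CSV.

## Correlation PCA

PCA eigendecomposes the trait correlation matrix, not the covariance
matrix — the convention under which the contribution rate of component
j is λⱼ/p × 100 with p the number of traits, so contributions sum to
100 %. Eigenvector signs are arbitrary; for determinism each loading
column is flipped so its largest-magnitude entry is positive. Scores are
the z-scored data times the loadings, so the sample variance of the
j-th score column equals λⱼ. Constant traits make the correlation
undefined and are rejected by name. Published contribution rows carry
the rounding of their unprinted eigenvalue digits, so checks against
them use a ±0.001 tolerance rather than exact 4-dp equality.

## Gene-pool rules

Four diagnostic signals per pool, each firing one rule on a cluster
group's profile (HSW mean; modal GH, PHA, SSC, SCC, CS):

| Andean | Mesoamerican |
|---|---|
| HSW ≥ 35 g (large/medium-large seed) | HSW < 25 g (small seed) |
| speckled seed coat (SSC ≠ free) | speckle-free coat (SSC = free) |
| erect GH **or** determinate PHA | prostrate GH **and** indeterminate PHA |
| white/pinkish flower (CS 1–3) | plain black/yellow/white coat (SCC 4/2/3) |

A pool is called only with a two-rule margin over the rival score;
anything closer is introgressed — this operationalizes "combined
characteristics of both pools" without a tunable continuous threshold.
Seed market classes use the standard HSW cut-offs small < 25 g ≤ medium
≤ 40 g < large. The same rules apply to single accessions (raw values
instead of modes) for the region × pool composition, whose percentages
are computed over the full collection and rounded to 1 dp. Missing
profile fields simply leave rules unfired; with no fields at all the
call degenerates to introgressed with an explanatory evidence entry.

## Synthetic collections

The generator emulates a regional landrace collection structured by the
two domesticated gene pools. Each pool is an archetype: per-trait
Gaussians (truncated at zero by resampling for positive-unit traits)
and categorical state distributions, shipped in a human-editable
parameter file (`beandiv/data/archetypes.yaml`). The means follow
published group-level summaries (Andean-like HSW ≈ 42 ± 5 g, mostly
erect/determinate, speckled coats, white-pink flowers; Mesoamerican-like
HSW ≈ 22 ± 4 g, prostrate/indeterminate, speckle-free black/yellow/white
coats); the dispersions and the remaining state probabilities are
invented, plausibility-chosen defaults and are labeled as such in the
file. The seed length/width ratio is recomputed from the drawn length
and width rather than sampled, keeping the derived trait consistent.

Introgressed accessions are trait-wise mosaics: each trait comes from
the Andean archetype with probability λ (default 0.5), else the
Mesoamerican one. A mosaic keeps categorical traits well defined and
mirrors how introgressed material shows some characters from each pool;
it does not model linkage, pedigree or heritability. The default
configuration draws 52 Andean, 40 Mesoamerican and 23 introgressed
accessions (115 total, a 45.2/34.8/20 % split) with region frequencies
skewed so Mesoamerican types dominate region I and Andean types regions
II–IV. All outputs are pure functions of (config, catalog, archetypes)
through one `numpy` Generator.

What passing recovery tests show — and do not show: with the default
archetype separation, cluster cuts and the rule classifier recover the
generating pools essentially perfectly, so the pipeline's plumbing is
correct; real collections have weaker separation, trait correlations and
measurement structure the generator does not emulate, so recovery rates
here say nothing about classification accuracy on real accessions.
Recovery experiments in the tests use 46-accession collections (23 per
pool) across 50 seeds, small enough to keep the full suite under a
minute while leaving the binomial pass-criteria meaningful.

## Numerical choices and limitations

- Natural logarithms throughout H′; half-up rounding to 3 decimals for
  display only.
- Binning boundary membership is resolved by exact floating comparison;
  the brute-force oracle in the tests enumerates boundaries
  independently to guard against off-by-one-ulp drift.
- Exact published group memberships, group trait means and per-region
  index values for the original 115-accession collection are not
  reproducible because the accession-level data are not deposited; the
  package reproduces the published quantities whose inputs are printed
  (two-level frequencies, per-trait index aggregation, eigenvalue
  bookkeeping, count arithmetic) and covers the rest with
  oracle-equivalence and simulation-recovery properties.
- No rarefaction or bootstrap uncertainty for H′; no alternative
  linkages; no rotation of PCA loadings; no molecular-marker or
  race-level classification.
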