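# Methods

## Size/shape decomposition

Every analysis operates on natural logs of the raw µm measurements. The
isometric size axis (*isosize*) of a specimen is the mean of its
log-measurements — equivalently the log of the geometric mean — and its
shape coordinates are the log-measurements centred by isosize. Shape rows
therefore sum to zero exactly, shape space has dimension p − 1, and
multiplying a specimen's raw measurements by any common factor moves only
its isosize: shape, and everything built on shape, is size-free by
construction. Logs are natural throughout; `exp(isosize)` recovers the
geometric mean in µm.

## Shape PCA

The shape PCA eigendecomposes the covariance (not correlation) matrix of
the shape coordinates — all variables share log-units, so no per-variable
rescaling is wanted. The all-ones direction is the exact null space of the
shape covariance; the implementation drops it and returns p − 1 components,
each orthogonal to the ones vector. Signs are fixed so each loading's
largest-magnitude entry is positive. The number of components a user
retains is their choice (scree inspection is informational); the pipeline
reports the PC1+PC2 variance fraction.

## Ratio spectra and bootstrap

A ratio spectrum orders the variables by their coefficient on an axis — a
shape-PC loading or the allometry vector (the slope of each shape
coordinate on isosize, which sums to zero). Confidence intervals come from
resampling specimens with replacement, stratified by group when group
labels exist, recomputing the axis, aligning its sign with the point
estimate (the dot product decides), and taking the central interval.
Defaults are 1000 replicates at 68% coverage. Degenerate resamples (a
constant shape column) are redrawn and counted. Stratification keeps each
group's sample size fixed; whether to stratify was an open choice and is
recorded in the spectrum's metadata.

## Standard distance and δ

For two groups, the standard distance of a projection direction v is
|v·(m₁ − m₂)| / sqrt(vᵀ S_pooled v), with the pooled within-group
covariance using the n₁ + n₂ − 2 denominator. The LDA ratio extractor scans
all p(p−1)/2 unordered character pairs for the log-ratio direction
e_a − e_b with maximal D; the second ratio maximizes the joint 2-D
Mahalanobis standard distance together with the first (a complementarity
criterion — the second ratio adds discrimination rather than repeating the
first), and the greedy scheme extends to further ratios. Whether the
original extractor ranks ratio 1 by marginal D or by correlation with the
full LDA axis is not decidable from the material at hand; marginal D was
chosen, and on every tested fixture it agrees with an independently coded
exhaustive scan. Ties break lexicographically by abbreviation pair, and the
numerator/denominator are oriented so the pooled geometric-mean ratio is
≥ 1 (reports print ratios ≥ 1).

δ is operationalized as D_size / D_ratio, where D_size is the standard
distance of isosize. Small δ means shape discriminates far better than
size. The operationalization is validated two ways: on synthetic ground
truth δ·D_ratio reproduces D_size identically and the Monte-Carlo mean of δ
matches the generator's analytic value; and within published best-ratio
tables the product δ·D is near-constant across the two extracted ratios of
a comparison, exactly what δ = D_size/D_ratio implies.

Observed ratio ranges in reports are computed from raw values of
non-imputed specimens only, because imputed values can generate outlying
ratios; imputed specimens still participate in fitting D. A ratio is
starred as key-worthy when the two group ranges overlap by at most 5% of
their union length — the operationalization chosen here for "very little or
no overlap".

## Measurement QC

Body measurements of related taxa correlate strongly and positively on the
log scale; a damaged character (e.g. a collapsed gaster) loses that
correlation. The QC computes pairwise-complete Pearson correlations of
log-measurements and flags a variable whose *median* off-diagonal
correlation falls below a threshold, default 0.5. The scale (log) and the
flag rule are this package's operationalization of what is usually done by
inspecting matrix scatterplots; the default threshold cleanly separates a
variable whose correlations straddle zero from healthy variables
correlating above 0.9. A zero-variance variable is flagged with reason
"constant". Flagging is monotone in the threshold.

## Imputation

Missing cells are filled by deterministic iterated ridge regression on the
log scale: initial fill with column medians plus a small seeded jitter,
then column-by-column regression of each incomplete character on all
others (ridge penalty λ = 1e−3 times the mean diagonal of the centred
predictor cross-product), sweeping until the largest absolute change of an
imputed log-value is below 1e−6 or 50 sweeps. Chained-equations tools with
stochastic defaults would not give the reproducibility contract wanted
here: identical seed, identical table, bit-identical imputations.
Imputation never touches observed cells, and the imputed mask flows through
the pipeline so range calculations can exclude imputed specimens.

## Identification key

The key is data, not code: couplets, ratio thresholds, qualitative-trait
requirements and per-species diagnosis ranges ship in
`src/mra/data/anisopteromalus_key.yaml`. Quantitative conditions decide
each couplet; when neither branch's conditions hold (a specimen in the gap
between two printed ranges) or both hold, supplied qualitative traits
(booleans such as `gena_carinate`) may resolve the branch — traits
supporting both branches raise an error, and with no deciding evidence the
classification is "indeterminate" with the ambiguous thresholds listed.
The single-specimen point thresholds of *A. ceylonensis* are encoded as
±0.05 bands around the printed values; values between a band and the
alternative branch's range are indeterminate. Couplet 4's two thresholds
must agree, else indeterminate. Because published range limits can touch
(e.g. mesosoma:OOL 8.11–11.87 against a couplet bound of 8.14), a specimen
at the extreme edge of one species' ranges can in principle key toward its
sibling; the shipped consistency checks therefore use range midpoints.

## K2P distances

The Kimura 2-parameter distance is computed per sequence pair after
pairwise deletion: any site where either sequence has a gap or an
ambiguity code (anything outside A/C/G/T) is excluded for that pair, which
matches the stated gap handling and extends it to ambiguities. With
transition proportion P and transversion proportion Q over retained sites,
d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q); non-positive log arguments mean
saturation and yield NaN rather than a number. Summaries report min / mean
/ max per species (intra) and per species pair (inter); single-record
species get a not-applicable intraspecific row. Alignment and tree
inference are out of scope — the deliverable is the divergence summary
that supports or undermines a species split.

## Synthetic generator

The generator mirrors the decomposition the analysis assumes:
ln x_ik = base + μ_g(i),k + (1 + a_k)·s_i + offset_g(i) + ε_ik, with
sum-zero group mean shapes μ_g, log-size s ~ N(0, σ_size²), sum-zero
allometry a, group size offsets, and i.i.d. log noise ε ~ N(0, σ_noise²).
Allometry enters multiplicatively on log-size so that a_k is *exactly* the
allometry-coefficient estimand — recovery tests have sharp truth. The base
log of 6.0 puts measurements near 400 µm. Closed forms follow for the
standard distance of any log-ratio ((a_j−a_k)²σ_size² + 2σ_noise² within-
group variance) and of isosize (σ_size² + σ_noise²/p), hence for δ.

Two canned scenarios ship. The *planted-contrast* scenario has two groups
of 60 specimens, 19 characters, one log-ratio contrast solved at run time
to hit a requested population D (default 5), σ_size 0.10, σ_noise 0.02 and
a smooth sum-zero allometry vector of amplitude 0.15. The *demo* scenario
has six groups of sizes 25/90/15/3/6/110 (two dominant cosmopolitan
species, one near-singleton — the sampling balance typical of the
motivating revision, chosen once as a realistic design), 20 characters,
group mean shapes of log-SD 0.08 drawn from a fixed internal seed,
σ_size 0.12, σ_noise 0.03, small size offsets, and a silent artifact on
gaster breadth (40% of values replaced by group mean × exp N(0, 0.5)) plus
2% MCAR missingness. MCAR injection never blanks a whole row or column.

What the generator does *not* emulate: correlated measurement error,
non-normal size distributions, within-group substructure (strains beyond a
label), allometry that differs between groups, and missingness that
depends on specimen condition (real name-bearing types lose body parts for
non-random reasons). Passing recovery tests therefore show the estimators
are correct under the stated model, not that real measurement tables meet
its assumptions.

## Numerical choices and problem sizes

Eigendecomposition uses symmetric `eigh` with eigenvalues clipped at zero;
near-machine degeneracies in the isosize standard distance (constant
isosize up to round-off) return 0 instead of noise ratios. Bootstrap CIs in
the heavier recovery studies use 200 replicates (the default elsewhere is
1000); the planted-contrast recovery and QC power studies use 100 seeded
replicates each, and the δ consistency study 50 — sizes chosen to give
stable rates while keeping the whole suite and the acceptance script in the
seconds range. Determinism is part of the contract everywhere: every
stochastic step takes a seed, and the pipeline's outputs are byte-identical
across reruns with identical inputs.

## Known limitations

- Two-group comparisons only (unions of labels are allowed per side);
  no multi-group discriminant extraction.
- The key engine models qualitative characters as observer-supplied
  booleans; it does not score them from measurements or images.
- K2P summaries assume an existing alignment; no alignment, model
  selection, or phylogeny inference.
- Ratio-range reports depend on having non-imputed specimens for the pair
  of characters; a group measured incompletely everywhere yields no range.
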