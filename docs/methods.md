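# Methods

## The model

`nullvec` summarizes a biological sequence of length *N* by three
standardized parameters per residue type *X*, each of the form
(measure − null mean) / √(null variance):

- **Type I (composition).** Measure: the proportion p_X = n_X/N.
  Null: n_X ~ Binomial(N, π_X), so mean π_X and variance π_X(1−π_X)/N.
- **Type II (centroid).** Measure: the mean m_X of X's 1-based positions.
  Null: positions uniform on 1..N, so mean (N+1)/2.
- **Type III (dispersion).** Measure: the unbiased variance v_X of X's
  positions, against its expectation under uniform placement.

Concatenating the (I, II, III) triplet for each symbol in the fixed
alphabet order (A R N D C E Q G H I L K M F P S T W Y V for protein;
A C G T / A C G U for nucleotides) gives a 60-component protein vector or
a 12-component nucleotide vector. Any fixed order would preserve the
Euclidean geometry; the order is recorded in the vector-table header.
Collections of vectors are compared by Euclidean distance, visualized by
PCA, and grouped by complete-linkage agglomerative clustering.

## Null conventions

Two positional nulls are offered, differing in the second and fourth
moments:

- `iid_uniform` (default): the n positions are independent uniform draws.
  Closed forms: Var(m) = (N²−1)/(12n); E(v) = σ² = (N²−1)/12;
  Var(v) = μ₄/n − σ⁴(n−3)/(n(n−1)) with μ₄ = (N²−1)(3N²−7)/240 (central
  fourth moment of a discrete uniform variable on 1..N).
- `srswor`: the n positions are a simple random sample without
  replacement from 1..N — what actually happens inside a sequence, where
  a residue cannot occupy a site twice. Then Var(m) = (N+1)(N−n)/(12n)
  and E(v) = N(N+1)/12 (the finite-population correction makes the
  unbiased sample variance estimate the population variance of 1..N with
  denominator N). Var(v) has no convenient closed form here and is
  calibrated by Monte Carlo (200,000 replicates, fixed internal seed),
  cached per (N, n) so vectors are reproducible run to run.

All closed forms were verified against the Monte Carlo calibrator before
being frozen into the test suite; the calibrator draws positions directly
and never calls the analytic code.

The Type III null mean defaults to the value implied by the positional
model. A verbal rule placing it at (N²−1)/2 is also exposed
(`type3_mean_rule="paper_literal"`) for fidelity checks only: it sits six
standard-deviation-scales above the sampling distribution of v, so every
Type III parameter becomes a large negative constant that dominates the
vector and destroys the mean-0/variance-1 calibration. The `calibrate`
subcommand flags exactly this when asked to use the literal rule.

## Priors

The composition null probability π_X defaults to the codon multiplicity
of X in the standard genetic code divided by 64 (`codons_over_64`,
e.g. π_G = 4/64 = 0.0625; probabilities sum to 61/64). Alternatives:
`codons_over_61` divides by the 61 coding codons (sums to 1);
`dataset_frequency` uses pooled frequencies of the input collection, with
unobserved residues floored at 10⁻⁶ and renormalized; `uniform` (the
DNA/RNA default, 0.25 per base). Note that renormalizing `codons_over_64`
to a sampling distribution yields exactly `codons_over_61`; statistical
calibration checks therefore use the sum-to-one form so that the
simulation and the standardization describe the same process.

## Degenerate cases

Parameters whose measure or null variance is undefined are set to 0,
read as "no evidence of deviation from the null": Type II/III when the
residue is absent, Type III when it occurs once, and Type II under
`srswor` with n = N (all sites occupied, zero null variance). This keeps
every vector finite and distances well-defined. The cost is shrinkage:
for a residue with expected count λ = Nπ_X, a fraction P(n < 2) of null
sequences contribute an exact 0 to Type III, so its unconditional
variance is about P(n ≥ 2) rather than 1 (≈ 0.83 for Met/Trp at N = 200
under the codon prior). Calibration checks of the variance-1 property
are therefore made on residues with λ ≥ 10; the means are unaffected.

## Calibration of the parameters

On simulated null sequences the parameters should be approximately
standard normal. Because a simulated (or real) sequence places each
residue's positions without replacement, the calibration is run under
the matching `srswor` convention; under `iid_uniform` the Type III
parameters carry a small systematic offset of (N+1)/12 in the measure
(≈ 0.03 standard units at N = 200), which is invisible per sequence but
detectable as a mean shift over 10⁴ replicates. At 10,000 sequences of
length 200 under the codon prior, every one of the 60 parameter means
lies within 4 standard errors of 0 and the Type I variances are within
10% of 1 (the acceptance suite recomputes this from scratch).

## PCA and clustering

PCA is an SVD of the centered score matrix — centering only, no
unit-variance scaling, because the parameters are already standardized
against the null, which is the method's point (column standardization is
available as an option). Sign convention: the largest-magnitude entry of
each loading is made positive, so output is reproducible across runs and
BLAS implementations. Explained variances are the squared singular
values over (m − 1).

Complete-linkage clustering is implemented in-package (Lance–Williams
maximum update) because determinism requires a fixed tie-break: among
equally distant cluster pairs, the pair whose lexicographically smallest
member identifiers come first is merged. Merge heights are monotone and
agree with any correct complete-linkage implementation; the test suite
checks them against both an exhaustive brute-force agglomerator (all
trees on ≤ 7 leaves) and scipy's implementation. Dendrograms serialize
to Newick with ultrametric heights (leaf at 0, branch length = parent
height − child height).

## Synthetic benchmark

The generator emulates families of related sequences: one i.i.d.
ancestor per family drawn from the prior, then per-member mutation —
each site substituted with the given probability (replacement drawn from
the prior excluding the current residue, so a substitution always
changes the site), then per-site indel events (insertion or deletion
with equal odds, length uniform on 1..max), applied left to right.
Defaults: ancestor length 300, 3 families × 20 members, substitution
rate 0.05, indel rate 0.01, max indel length 3, seed 42 — within-family
identity around 95%, so families are separable but not trivially so.
Under these defaults, cutting the complete-linkage tree into 3 clusters
recovers the family labels exactly (adjusted Rand index 1.0).

What the generator does *not* emulate: substitution-matrix structure
(PAM/BLOSUM), site-rate heterogeneity, domain architecture, or
compositional drift between families. Passing the benchmark therefore
shows that the pipeline resolves groups differing by accumulated random
point changes without alignment; it does not certify performance on real
protein families, whose differences are structured.

## Problem sizes and numerical choices

Statistical tests use 10⁴ null sequences (calibration), 2×10⁵ Monte
Carlo replicates (moment oracles), and 50 random matrices (clustering
oracle); these give standard errors comfortably below the tested
tolerances while keeping the default suite fast. Distance symmetry is
enforced to 1e-9; PCA oracle agreement to 1e-8; vector tables are
written with 17 significant digits so round-trips are exact. All
randomness flows through numpy `default_rng` with explicit seeds.

## Known limitations

- The parameters are only asymptotically Gaussian; for short sequences
  or rare residues the discreteness of counts and the zero-imputation
  rule are visible in the tails.
- `codons_over_64` is not a probability distribution (sum 61/64); it is
  supported as a standardization convention, but simulation and
  calibration use its renormalized (sum-to-one) form.
- Complete linkage is O(n³) time, O(n²) memory — fine for thousands of
  sequences, not for databases.
- The method ignores residue order beyond mean and dispersion of each
  residue type's positions; sequences agreeing in those summaries are
  indistinguishable by construction.
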