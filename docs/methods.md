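# Methods

## Model and procedure

The unit of observation is a feature table of non-negative counts
(features × samples) with per-sample system / population / ecotype
labels. One analysis covers one *study system*: all of its samples enter
a single Bray–Curtis dissimilarity matrix

BC(i,j) = Σₖ |xₖᵢ − xₖⱼ| / Σₖ (xₖᵢ + xₖⱼ) ∈ [0,1],

and a single PCoA. Mixing coordinates from different ordinations is a
hard error — angles across incompatible bases are meaningless.

PCoA is the Gower double-centering eigendecomposition: with D the
distance matrix and J = I − 11ᵀ/n, B = −½ J D² J; coordinates are
eigenvectors scaled by √eigenvalue. Because Bray–Curtis is non-Euclidean,
B generally has negative eigenvalues; these axes are dropped without
Lingoes/Cailliez correction — matching the default behaviour of the
QIIME2-era ordination stack this package interoperates with — and their
absolute mass is logged and stored on the `Ordination`. Axes whose
eigenvalue falls below 1e-8 of the leading eigenvalue are treated as
numerical noise. By default all positive axes are retained; `n_axes`
truncates. Axis sign is arbitrary in PCoA; it is fixed deterministically
by making the largest-|loading| entry of each axis positive, so repeated
runs and independently computed ordinations of the same matrix agree.
Angles are invariant to any sign convention as long as it is applied
uniformly within one ordination, which this guarantees.

Change vectors are differences of group centroids (arithmetic means of
member coordinates on all retained axes), with direction taken verbatim
from the comparison design — never auto-flipped, because a consistent
direction convention (e.g. benthic → limnetic everywhere) is what makes
angles across population pairs comparable. Two designs are supported:
*pair* (one vector per population pair) and *outgroup* (all vectors share
one ancestral/outgroup origin). Vectors shorter than 1e-12 are rejected:
their direction is undefined. Angles use the clamped arccos of the
normalized dot product (clamping to [−1,1] protects exactly parallel or
anti-parallel pairs from floating-point overshoot). Every unordered pair
of vectors contributes one row: θ in degrees, both lengths, and meanL —
the unweighted mean of the two lengths, the per-comparison magnitude
covariate used in angle–magnitude correlations.

## Statistical tests

*t-test vs 90°* — t = (mean − 90)/(s/√n), sample s (n−1 denominator),
one-sided lower-tail p = P(T₍ₙ₋₁₎ ≤ t). One-sidedness is deliberate:
parallelism is the alternative θ < 90°, and with it a mean angle above
90° yields p > 0.5.

*Wilcoxon signed-rank vs 90°* — zero differences dropped, average ranks
on ties. For n ≤ 25 the null distribution of the positive-rank sum W⁺ is
computed exactly by dynamic programming over sign patterns (doubling the
tie-averaged ranks makes them integers, so the DP is exact even with
ties); beyond that, normal approximation with continuity correction and
tie-corrected variance. p = P(W⁺ ≤ observed), the standard lower-tail
convention; for a tied pair straddling 90° symmetrically this gives 0.75
rather than the mid-p value 0.5 — we keep the standard convention.

A Shapiro–Wilk gate at α = 0.05 selects between the two in `auto` mode;
explicit method flags override.

*Monte-Carlo* — each iteration draws k independent uniformly-random unit
directions in d dimensions (normalized standard normals) and records the
mean of all C(k,2) pairwise angles; p = (1 + #{null mean ≤ observed
mean})/(iterations + 1). Simulating whole vector *sets* rather than
pooling independent single angles preserves the dependence among angles
that share a vector, and the add-one correction keeps p strictly
positive. Default 10⁵ iterations; below 10³ a warning is logged. The
null is centered at 90° and tightens as d grows; in d = 2 the single-pair
angle is exactly uniform on [0°, 180°].

*Rayleigh* — unit directions uᵢ = vᵢ/‖vᵢ‖, mean resultant length
R̄ = ‖mean(uᵢ)‖, S = k·d·R̄², p = upper tail of χ²(d). This is the basic
(uncorrected) Rayleigh statistic with d equal to the retained ordination
dimensionality; vector lengths never enter.

*Spearman* — average-rank ties; exact two-sided p by full enumeration of
rank permutations for n ≤ 10 (chunked so memory stays flat), t-
approximation above.

*Paired set comparison* — two matched angle sets (e.g. taxonomic
composition vs inferred function over identical comparisons) are compared
by a two-sided paired t-test; `restrict_below_90` first keeps only
comparisons where both members show parallelism (< 90°). Pairing is used
because the designs index identical comparisons.

No multiple-testing correction is applied by default (raw p-values are
reported); `benjamini_hochberg` is available for across-system FDR
control.

Determinism: every stochastic operation (rarefaction, Monte-Carlo,
simulators) is driven by one integer seed; per-sample rarefaction
substreams are spawned deterministically from it, so results do not
depend on sample order or on dropped samples.

## Preprocessing

Rarefaction draws a multivariate-hypergeometric subsample (without
replacement) of each sample down to the requested depth; samples below
depth are dropped and logged, samples exactly at depth pass through
unchanged, and every retained column sums exactly to depth. Taxonomy
collapse truncates lineages at the requested rank (phylum … species),
sums features sharing the truncated lineage, pools rank-less features
into `unclassified_<rank>`, and conserves per-sample totals exactly.
Missing taxonomy entries are an error by default (`missing="pool"` opts
into pooling). Missing values anywhere are errors, never imputed.

## Synthetic data

The generators define the conditions under which the method is validated:

* `make_vector_fan` constructs vector sets with *exact* target pairwise
  angles by solving fan positions in a plane (sign search against the
  full target table) and embedding in d dimensions. Unrotated by default
  so the targets are reproduced to ≤ 1e-9°; an optional seeded rotation
  preserves them only to floating-point precision.
* `simulate_ordination_groups` places pair centroids with shift
  directions realizing a parallelism mode — parallel (all angles 0°),
  orthogonal (mutually orthogonal shifts, needs d ≥ pairs), antiparallel
  (alternating ± along one axis; with k > 2 not every pairwise angle can
  be 180°, so alternation is the natural extension and preserves the
  parallel < orthogonal < antiparallel rank ordering), or random —
  and adds spherical Gaussian within-group noise.
* `simulate_count_tables` draws Dirichlet-multinomial counts: a shared
  base composition, a mild per-pair lognormal baseline wobble (pairs
  occupy distinct regions of community space, as real population pairs
  do), and log-fold shifts of the "to" group on a subset of features
  whose sharing across pairs encodes the mode (`overlap` controls partial
  sharing in parallel mode). The taxonomy is a deterministic 7-rank
  nested hierarchy with doubling widths (12 phyla … 192 genera), wide
  enough that phylum-level collapse retains usable structure, as in real
  16S data sets.

Defaults — 6 pairs, 50 samples/group, latent d = 10, 200 features, depth
10,000, per-feature Dirichlet concentration 0.5, shift 5 (latent sd units
/ log-fold), dispersion 1, 10% of features shifted — were chosen once as
a well-powered but ordinary 16S-style design; they are fixtures of the
validation suite, not claims about any particular host system.

What the simulations do **not** emulate: phylogenetic correlation among
features (so UniFrac-specific behaviour is untested beyond matrix
ingestion), sequencing-run batch effects, sample-depth heterogeneity
(all samples share one depth unless rarefaction is exercised), and
zero-inflation beyond what the Dirichlet-multinomial induces. Passing
tests therefore demonstrate correctness of the geometry and calibration
of the tests under a clean compositional model, not robustness to every
artefact of real amplicon data. Bray–Curtis + PCoA distort latent
centroid geometry; end-to-end checks accordingly assert rank-order
recovery of parallelism modes and monotonicity of meanL in the shift
magnitude, not exact angle values.

## Validation problem sizes

The shipped suite validates at desk scale, chosen so the full run stays
in seconds-to-minutes: null calibration uses 500 replicates (k = 6,
d = 20, 2,000-iteration Monte-Carlo p-values) for the uniformity check
and 300 replicates of the orthogonal scenario at 50 samples/group for
type-I error; null centering uses 10,000 simulated sets (k = 10, d = 20)
and 100,000 single pairs (d = 50); end-to-end recovery runs the
Dirichlet-multinomial scenarios at 4–6 pairs × 50 samples/group with the
Monte-Carlo test at its full 10⁵ iterations.

## Known limitations

* Convergence/divergence classification relative to ancestral states is
  out of scope — only direction-consistent parallelism is quantified;
  interpreting outgroup designs as ancestral requires external evidence.
* With very few vectors the Wilcoxon test cannot reach p < 0.05 (its
  minimal exact p is 2⁻ⁿ), and with k = 2 the Monte-Carlo and t-test
  degenerate to a single angle; small designs should lean on the
  Monte-Carlo test.
* Negative-eigenvalue mass is discarded, so retained coordinates
  under-represent highly non-Euclidean distance structure; the discarded
  mass is reported for diagnosis.
* The Rayleigh χ²(d) reference is asymptotic in k; with k much smaller
  than d it is conservative-to-approximate, which is one reason three
  test families are reported side by side.
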