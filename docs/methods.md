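# Methods

This note documents the models and procedures implemented in `ambin`, their
assumptions, the defaults and why they were chosen, and what the synthetic
communities do and do not establish about behavior on real data.

## Annotation-binned OTU construction

OTUs are annotation bins, not similarity clusters: every rarefied read that
resolves to the same taxonomic call (taxonomy node + cleaned display label)
is counted together, and no consensus sequence is ever built.

Hit retention and resolution proceed as:

1. **E-value cut** — hits with e-value < 10⁻¹⁰ are retained.  The cut is
   strict (`<`, not `≤`): the threshold phrasing "below" is read literally.
   Identity and coverage cuts, by contrast, are inclusive (`≥`).
2. **Round 1** — hits at ≥ 99% identity and ≥ 99% query coverage compete by
   bit score.  Bit scores are compared after rounding to one decimal, the
   precision of tabular alignment output, so genuine ties are not split by
   floating-point noise.  A unique maximum annotates the read at that hit's
   species; tied maxima pool their accessions and the read is annotated at
   the lowest common taxon of the tied species.  Accessions mapping to the
   same species tie at species level without lifting.
3. **Label cleaning** — among tied labels, any candidate free of the
   case-insensitive tokens *unknown / uncharacterized / uncultured* is
   preferred (fewest words, then lexicographic); when every candidate
   carries such a token the least-decorated one is kept unchanged.
4. **Round 2** — reads with no round-1 annotation are reconsidered at
   ≥ 98% identity/coverage, but may only join an OTU that already registers
   the accession of a qualifying hit; the highest-scoring such hit decides,
   with ties going to the OTU with the larger current total and then the
   lexicographically smallest id.  No OTU is created in this round, which
   captures sequencing-error variants of already-established amplicons
   without minting low-confidence bins.

Rarefaction (uniform subsampling without replacement to a common depth,
seeded) is applied once, before annotation, treating it as read-level
preprocessing alongside quality filtering.

**Query coverage** is taken from a `qcovs` column when the hit table has
one; for plain 12-column tables it is derived as
100·(qend − qstart + 1)/query length from a supplied length map, and
parsing fails loudly when neither is available rather than guessing.

## Sparsity and abundance filters

An OTU is flagged and removed when present in fewer than
`min_replicates = 4` samples ("replicates"; a count of zero everywhere is
reported as "absent"), or when its maximum single-sample count reaches
`max_concentration = 0.75` of its total ("concentration").  Retention under
the concentration rule therefore requires max/total **strictly below**
0.75 — a ratio of exactly 0.75 is treated as concentrated.  Replicates are
samples; the block structure of the design is not consulted.  Flags are
reported for audit even though flagged OTUs leave all downstream analysis.
After normalization, testing is restricted to OTUs whose normalized total
is strictly greater than `min_total_normalized = 10`.

## Normalization

Median-of-ratios size factors: s_j = median over reference OTUs of
count_ij / geometric mean of OTU i, where the reference set is the OTUs
positive in every sample.  When no all-positive row exists the geometric
means fall back to positive entries only, with a logged warning.  Factors
are not rescaled afterward, so only their ratios are meaningful — the
scale-equivariance property (tripling one sample's counts triples its
factor) holds for factor ratios.

## Diversity and ordination

The six alpha indices use the ecology conventions of the standard R
toolkit: Shannon with natural log, Simpson as 1 − Σp², inverse Simpson as
1/Σp², Chao1 = S + F₁(F₁−1)/(2(F₂+1)), and Fisher's α as the root of
S = α ln(1 + N/α) found by Brent's method to 10⁻¹²  (undefined and
reported as NaN when every individual is a singleton).  Group comparisons
use Welch's unequal-variance t-test — with four replicates per group,
variance homogeneity is unverifiable, so the safer test is the default.
Degenerate inputs are handled explicitly: equal means give (t=0, p=1);
unequal means with zero variance in both groups give the (±∞, p→0) limit
and are flagged.

Bray–Curtis distances feed PCoA (Gower double-centering, eigendecomposition,
axes scaled by √eigenvalue).  Negative eigenvalues are reported but their
axes dropped; no Lingoes/Cailliez correction is applied, which is
acceptable because only the leading positive axes are consumed downstream.
CAP projects the PCoA scores onto the treatment-indicator span and
eigendecomposes the fitted scores, yielding at most (groups − 1)
constrained axes and a constrained-inertia fraction.  PERMANOVA partitions
squared distances into between/within sums of squares,
F = (SSB/(g−1))/(SSW/(n−g)), with p = (1 + #{F* ≥ F})/(1 + n_perm) over
seeded free label permutations (999 by default, the conventional choice of
the R ecosystem); a `strata` argument permutes within blocks for
split-plot designs.

## Negative-binomial differential abundance

Counts follow NB with variance μ + αμ².  The dispersion pipeline is a
deliberately simple moments + trend + shrinkage scheme:

- **raw**: per group, α̂ = (s² − m)/m² on normalized counts, pooled across
  groups weighted by degrees of freedom, clamped at 0;
- **trend**: α(μ) = a₀ + a₁/μ fitted by Huber robust regression to the
  positive raw values against 1/μ (a flat median fallback below 10 usable
  points), coefficients clamped nonnegative;
- **final**: the geometric mean of raw and trend (weight 0.5), floored at
  10⁻⁸.

This replaces the Cox–Reid adjusted-profile-likelihood machinery of the
transcriptomics tools; the fidelity target is *calibration* — the null
rejection rate and power under the study's n = 4 design — not numerical
identity with any particular implementation.  The acceptance suite checks
raw-p rejection in [0.03, 0.08] at nominal 0.05 on a 2,000-OTU null and
≥ 70% sensitivity with median |LFC error| ≤ 0.5 at true LFC 2.

Group means are fit per OTU by Newton iteration on ln q with the dispersion
fixed (score Σ(k − μ)/(1 + αμ), information Σμ/(1 + αμ), steps clipped to
±5); the Wald statistic is log₂FC over its expected-information standard
error with a two-sided normal reference.  An OTU with counts in exactly one
condition is reported as status `infinite_fc` (encoded `+INF`/`-INF` in
tables) while its p-value comes from the same fit with the zero group's
normalized mean floored at 0.5 — presence/absence calls therefore still
carry a significance statement rather than a bare ±∞.

Benjamini–Hochberg adjustment runs **within each contrast** (ten separate
families for the five-treatment design); untested OTUs are excluded from
the family size.  A differential-abundance call requires both raw p < 0.05
and adjusted p < 0.05.  Because the families are separate, the FDR of the
*union* of DA OTUs across contrasts is not controlled at 0.05 — the
end-to-end test scores FDR at the (OTU, contrast)-instance level, where BH
does control it.  Independent filtering and posterior LFC shrinkage are
intentionally omitted.  The shifted-log transform log₂(k/s + 1) is provided
for diagnostics only and never feeds a test.

## Sub-OTUs and phylogenetics

Two distinct amplicon sequences in one OTU belong to the same sub-OTU when
their supporting-accession sets intersect, and the sub-OTU relation is the
**transitive closure** of that pairwise criterion (connected components).
Closure is required for sub-OTUs to partition the OTU; it also guarantees
pairwise-disjoint accession sets, the defining property.  Sub-OTUs are
numbered `seq1, seq2, …` by descending read count, and each is represented
by its most frequent exact sequence.

Jukes–Cantor distances use pairwise deletion of gapped columns (tolerant of
ragged fragment alignments; complete deletion would discard whole columns
for a single short sequence) and raise at p ≥ 0.75, the model's saturation
bound.  Neighbor joining is the standard Saitou–Nei agglomeration with the
rate-corrected Q criterion; Q-ties within 10⁻¹² join the pair whose subtree
leaf labels sort lexicographically smallest, making topologies
deterministic, and negative branch lengths are clamped to zero.  Bootstrap
support resamples alignment columns with replacement, rebuilds the JC/NJ
tree per replicate (saturated replicate pairs are capped just below the
bound rather than discarded), and scores the recurrence of each original
internal bipartition; supports at or below the display threshold (50% by
default) are suppressed.  Multiple sequence alignment is an input contract:
sub-OTU representatives and spike sequences must arrive pre-aligned to one
length.  Bootstrap distances use JC (not raw p-distances) for consistency
with the main tree.

## The synthetic communities

The generator emulates exactly the structure the analysis consumes,
mirroring the motivating field design — five treatments (control, Pb, Zn,
Cu, three-metal) × four blocks = 20 samples:

- a seven-rank taxonomy grouped by a factor of two per rank, with one
  reference fragment (400 bp, roughly the V4–V5 amplicon length) per
  species; congeneric fragments diverge at ≈ divergence × length positions,
  and a configurable number of genera share identical fragments to exercise
  tie resolution;
- reads as fragment copies with i.i.d. substitutions (default 0.4%, which
  leaves ~2.4% of 400-bp reads below the 99% round-1 identity cut yet above
  the 98% round-2 cut — precisely the population the rescue round exists
  for); provenance recorded per read;
- full-length alignment hits to the nearest references by Hamming distance,
  with the documented surrogate score 2·(matches − 3·mismatches) and
  e-value 10^(−score/10) — strictly monotone in mismatches and
  tie-preserving, which is all the binning logic reads; real
  alignment-search statistics are out of scope;
- count matrices drawn NB(μ·2^lfc, α) per cell, Poisson at α = 0.

It deliberately omits indels, chimeras, homopolymer errors, primer bias,
and partial-coverage alignments (the tests construct partial-coverage hits
directly to exercise the coverage filter).  Passing tests therefore demonstrate the
pipeline's logic and calibration under its own model assumptions; they do
not certify behavior under structured real-world error profiles.

## Problem sizes and reproducibility

The test suite and acceptance script run the binning oracle at 10 species ×
20 samples × 1,000 reads, calibration at 2,000 null / 1,500 spiked OTUs,
tree recovery over 100 random additive 5-leaf matrices against an
exhaustive least-squares search of all 15 topologies, and PERMANOVA
calibration over 500 null datasets — sizes chosen so every oracle has
enough resolution to detect miscalibration while the whole suite stays
comfortably interactive.  Every stochastic stage takes an explicit seed;
the pipeline manifest records config hash and per-output checksums, and
reruns are byte-identical.

## Known limitations

- The NB fit covers two-group contrasts only; multi-factor designs,
  continuous covariates, and outlier handling (Cook's distance) are out of
  scope.
- Ordination reports no dispersion ellipses or figures; outputs are tables
  meant for external plotting.
- The LCA lift assumes a single rooted taxonomy; conflicting taxonomies or
  ranks below species are not modeled.
- `fisher_alpha` diverges when observed richness equals the read count and
  is reported as NaN rather than extrapolated.
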