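# Methods

This note documents the statistical model, the numerical choices, and
the design decisions behind `exocnv`, and states what the synthetic
validation does and does not demonstrate about real data.

## Read-depth model and coverage counting

The pipeline's central object is the dense *s* × *t* matrix of mean
per-base coverage over exome capture targets. Coverage is computed with
the filter set of the published XHMM protocol's GATK DepthOfCoverage
invocation: reads with mapping quality < 20, duplicate-flagged reads,
and secondary/supplementary alignments are skipped; base qualities are
ignored (the protocol sets the base-quality floor to 0). Only
reference-consuming aligned bases (CIGAR M/=/X) carry depth; deletions
within a read (D) do not, although `CoverageFilters(count_deletions=True)`
flips that choice since upstream tools differ. In the default
`fragment` counting unit, a base covered by both mates of a pair
contributes depth 1 (per-base depth is capped at once per fragment);
`read` mode counts every passing read. The per-target value is the sum
of per-base depths divided by the target length, so splitting a target
preserves the length-weighted mean — a tested invariant.

Coordinates are 1-based inclusive internally, matching the
`chrom:start-stop` dialect of XHMM matrix headers; BED input (0-based,
half-open) is converted at the parsing boundary. Matrices are dense by
contract: an unparseable cell is an error, never a NaN. A matrix with
unsorted target headers is rejected rather than silently reordered, and
no operation reorders samples.

## Filtering

Pre-normalization filters use the XHMM-protocol defaults, all
user-settable: target length in [10, 10 000] bp, target mean depth in
[10, 500]x, GC fraction in [0.1, 0.9], masked ("low complexity")
fraction ≤ 0.25, sample mean depth in [25, 200]x, sample depth SD ≤
150x. After PCA normalization, targets whose cross-sample SD exceeds 30
(in normalized units) are removed. GC and complexity annotations can
come from a reference FASTA (complexity = fraction of soft-masked
lowercase bases) or an annotation table; targets lacking an annotation
simply skip those rules.

## PCA normalization and rank selection

With the centered matrix's singular variances v_i = σ_i², the removal
rule keeps the K components satisfying v_i ≥ c·Σv/n with c = 0.7 and n
the number of candidate components. We take n = min(s, t) after
filtering: with s ≤ t (the usual WES regime) column centering makes the
matrix rank at most s − 1, which is what justifies the (n − k − 1)
factor in the total-variance over-estimate

  over(k) = Σ_{i≤k} v_i + (n − k − 1)·v_k,   under(k) = Σ_{i≤k} v_i.

Because v is non-increasing, over(k) ≥ Σv ≥ under(k) in that regime, so
the true cutoff c·Σv/n lies between the two estimated cutoffs. Counting
components against the over-cutoff under-counts at most; if the first
retained component also falls below the under-cutoff, no component
beyond K can pass the true cutoff and K is certified exact. When t < s − 1
the over bound can in principle undershoot by up to one tail
variance; the certification check makes a wrong certified K require a
component inside a window of width ≤ c·v_k/n below the true cutoff *and*
a sharp drop immediately after — the oracle-equivalence suite (200
designed flat/steep/mixed spectra) has never produced one, and an
uncertified search simply falls through to the exact full-spectrum rule.

Iteration starts at k = ⌈n/10⌉ and doubles k until certification,
capped at n − 1 (geometric growth keeps the number of SVD recomputations
logarithmic; the growth schedule is our choice). Ties at the cutoff are
removed (≥ comparison). The truncated SVD uses ARPACK with a fixed
start vector (falling back to dense LAPACK for near-full k or
degenerate inputs), so all results are deterministic; removal subtracts
the rank-K reconstruction U_K Σ_K V_Kᵀ. Each sample row is then
standardized with the sample-SD convention (denominator s − 1).

## The CNV hidden Markov model

States are DEL, DIP, DUP with initial distribution (p, 1 − 2p, p),
p = 1e−8 per target. Emissions are unit-variance normals on the
z-score scale at means −M, 0, +M with M = 3. The zero-distance
transition matrix uses the CNV exit probability q = 1/(mean CNV length
in targets), default q = 1/6; transitions at inter-target distance d mix
toward the stationary row Π = (p, 1 − 2p, p):

  T(d) = f·T0 + (1 − f)·Π,   f = exp(−d/D),   D = 70 000 bp.

d is the midpoint-to-midpoint distance of consecutive targets (a `gap`
mode is available; the choice matters only for long targets), floored at
0; a chromosome change sets f = 0, which makes the likelihood factorize
across chromosomes exactly — so one HMM over the whole filtered target
list is equivalent to independent per-chromosome chains (tested).

Decoding uses Viterbi entirely in natural-log space. Likelihoods and
posteriors use the scaled forward/backward recursions (per-step
renormalization), which stay finite on chains whose raw likelihood
underflows double precision (a 200-target chain at |z| ≤ 8 has log
likelihood far below log(5e−324)). All arithmetic is double precision.

### Quality scores

For a called run [a, b] with state c, five event probabilities are
computed exactly as ratios of constrained to unconstrained forward
passes (each constrained pass zeroes disallowed states per target and
carries its own scaling, so the ratio is formed in log space):

- P_SOME: 1 − P(no target in [a,b] has state c) — the reporting
  criterion, phred ≥ 30 by default;
- P_NON_DIPLOID: 1 − P(all targets in [a,b] are DIP);
- P_EXACT: P(all of [a,b] is c and the flanking targets are not);
- P_START / P_STOP: the breakpoint events (state becomes c exactly at a
  / stops being c after b).

At the first or last target of a chromosome the missing flank constraint
is dropped (the probability is not conditioned on a nonexistent target);
this edge behavior is pinned against the path-enumeration oracle because
it is exactly where read-depth callers historically disagree. Phred
conversion is round(−10·log10(1 − P)) with round-half-up, clamped to
[0, 99]. Event inclusion (exact ⊆ some ⊆ non-diploid) holds by
construction and is asserted in tests.

## Synthetic cohorts

The generator emulates the structure the normalization stage exists to
remove:

  depth(s, t) = noise( base_t · scale_s · bias(s, t) · cnv_factor(s, t) )

with per-target baseline depth base_t ~ U(80, 160)x, per-sample scale
~ U(0.9, 1.1), and bias = 1 + strength·Σ_r u_r v_rᵀ built from
orthonormalized rank-3 factors rescaled to unit per-entry variance
(strength 0.1, i.e. ~10–17% systematic swings — strong enough to defeat
naive calling, weaker than the 50% CNV signal). Embedded CNVs multiply
depth by 0.5 (het deletion) or 1.5 (het duplication) over 5–8
consecutive targets. Default cohort: 30 samples × 500 targets on two
chromosomes, target lengths 120–300 bp, gaps 0.2–2 kb. Poisson noise on
the per-target base count is the default (mean–variance coupling like
real counting noise); Gaussian and noiseless modes exist for controlled
SVD tests. All randomness flows from one integer seed through
`numpy.random.SeedSequence.spawn`, so cohorts are bit-reproducible.

What this does *not* emulate: GC-dependent bias curves, pseudo-autosomal
or sex-chromosome effects, reference artifacts, overdispersion beyond
Poisson, or breakpoints inside targets. Passing the recovery experiment
therefore demonstrates the pipeline's internal correctness (the
normalization removes exactly the planted low-rank structure; the HMM
recovers the planted events at the right coordinates), not field
performance on real exomes. Because Poisson noise at ≥80x is mild,
residual systematic structure below the 0.7/n cutoff produces recurrent
false calls in the synthetic recovery runs; these are reported, not
suppressed — the same trade-off the real tool makes.

SAM fixtures for the coverage module are built by tiling reads layer by
layer (soft-clipping the final read of a layer so aligned bases end
exactly at the target boundary), making the expected mean depth exact by
construction; crafted variants add MAPQ-0 reads, duplicate-flagged reads
and overlapping proper pairs.

## Validation strategy and problem sizes

Every delicate computation has an independent oracle in `tests/`:

- rank selection vs. the exhaustive full-spectrum rule on designed
  flat/steep/mixed spectra (200 matrices, s ∈ [10, 60], t ∈ [50, 400]);
- Viterbi, likelihood and all five quality probabilities vs. vectorized
  enumeration of all 3^T paths (500 chains, T ≤ 8, |z| ≤ 8, mixed
  spacings including abutting targets and chromosome breaks);
- scaled forward vs. an independent log-sum-exp forward on 200-target
  chains (agreement within 1e−9 despite raw-likelihood underflow);
- coverage vs. a literal per-base, per-fragment tally;
- end-to-end recovery of 20 embedded CNVs in the default 30 × 500
  cohort, with the PCA-vs-no-PCA contrast.

These sizes were chosen so the whole suite runs in well under a minute
while the enumeration spaces stay exhaustive. `scripts/acceptance.py`
re-runs the same measurements from scratch under a user-supplied seed.

## Known limitations

- No CRAM input, no multi-sample BAMs, no distributed or chunked
  processing; cohorts must fit in memory.
- XHMM's separate re-genotyping mode is out of scope; `exocnv` stops at
  discovery.
- The `.xcnv` writer is format-compatible but no attempt is made to
  bit-match XHMM's extended-precision numerics.
- Rank-selection certification is proven for the s ≤ t regime; for
  t < s − 1 it is supported by the fallback-to-exact path and empirical
  oracle equivalence rather than a strict bound (see above).
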