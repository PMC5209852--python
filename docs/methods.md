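# Methods

This note records the models, conventions, and design choices behind
`somabench`, in the order the pipeline runs them.

## Clonal model and ground truth

A tumor is `K` diploid clones (default 8) related by a rooted ancestry
tree over nodes 1..K, plus contaminating normal cells. When no topology is
supplied, the tree is a seeded random recursive tree: node 1 is the root
and node `i > 1` attaches to a uniform node in `1..i−1`. An explicit
parent vector may be passed instead; the semantics downstream depend only
on the ancestor/descendant relation, not on the particular topology.

Clone proportions are one draw from a symmetric Dirichlet(α, …, α) with
α = 1/8 by default. This small concentration yields sparse mixtures — a
couple of dominant clones and several near-vanishing ones — which is what
makes the simulated VAF spectrum span essentially all of (0, 1].

Somatic variants are assigned to a uniformly random tree node and
inherited by all of its descendants; one zygosity draw per variant makes
every carrier heterozygous or homozygous with probability 1/2 each (the
draw is shared across carriers — zygosity is a property of the mutation
event, and a single draw is the simplest model consistent with diploid
clones). Germline variants are heterozygous or homozygous in the normal
genome with probability 1/2 each and are inherited by all clones at the
same copy number.

The expected allele fraction in a mixture with normal-read fraction κ is

    VAF = [ (1−κ) · Σ_{c ∈ carriers} w_c · copies_c + κ · copies_normal ] / 2 .

This is forced by diploidy and the mixing proportions. Useful corollaries:
somatic VAF ≤ 1 − κ, and homozygous germline VAF = 1 at every κ. κ enters
the read mixing and this formula identically; purity is 1 − κ.

## Variant generation and haplotype construction

Random variants are placed uniformly over the capture-target bases,
pairwise non-overlapping on the reference (overlap is *rejected*, not
resolved — user-supplied overlapping variants are an error, because no
well-defined merge semantics exists for them). SNV alternates are uniform
over the three non-reference bases. A fraction of 0.67% of variants are
indels — the share observed in SNV-focused exome studies — split evenly
between insertions and deletions with geometric lengths (mean 2, capped at
10; the true indel-length distribution of any particular tumor is unknown,
and this stand-in only needs to exercise the coordinate machinery).

Variants use VCF conventions: 1-based positions, and indels left-anchored
on a shared first base. Internally all arithmetic is 0-based half-open,
and BED targets are 0-based half-open.

Applying phased variants yields a `HaplotypeGenome` with a piecewise
liftover map: match blocks advance reference and haplotype coordinates in
lockstep, insertion blocks map every inserted base to the last preceding
reference base (the anchor), and deletions appear as gaps between match
blocks. Heterozygous variants go to one haplotype chosen once per variant
and inherited consistently by all carriers; homozygous variants go to
both. The liftover is monotone, and comparing a haplotype to the
reference through it recovers exactly the applied SNV set (a property the
test suite checks).

## Read simulation

Reads (default 100 bp, single-end) are sampled uniformly over the capture
targets padded by 100 bp on each side — a crude stand-in for capture
shoulders. The read count is `mean_depth · target_bases / read_len`
(unpadded target bases), so realized coverage inside targets sits slightly
below nominal at the padded edges. Per-cycle substitution errors follow a
linear ramp e(i) = e0 + slope·i, by default from 0.1% at the first cycle
to 1% at the last, with base qualities round(−10·log10 e(i)). This
replaces empirically trained capture/error models on purpose: it is
dependency-free, transparent, and sufficient for every statistical
component tested here. It does **not** model PCR duplicates, GC bias,
indel sequencing errors, or quality miscalibration — conclusions about
those error modes cannot be drawn from this simulator, and passing tests
say nothing about them.

Tumor samples are mixed multinomially: read counts per source follow
Multinomial(total, ((1−κ)·w_1, …, (1−κ)·w_K, κ)), drawn without
replacement from per-clone pools that are deliberately oversampled (35%
plus a constant) so allocation never exhausts a pool. Every read name
encodes `sample|clone|hap|refstart|strand|serial`, which is what allows
truth alignments (MAPQ 60, CIGARs derived from the liftover blocks) and
truth-aware error attribution without any external aligner. The study
grid from the emulated experiment — coverage levels 12/25/50/75/100% of a
full run, contamination varied at the 50% level — is exposed as
`COVERAGE_GRID` / `CONTAMINATION_GRID`.

## The naive caller and germline removal

The built-in caller exists so the downstream machinery is testable without
external tools, and doubles as a sane baseline: per site and non-reference
base with at least `min_alt = 2` supporting reads, it computes the
one-sided binomial tail P(X ≥ k | n, e = 0.005) and reports sites with
p < 0.05, scored by −log10 p. It knows nothing about the normal sample,
so germline variants are (correctly, from its point of view) called — and
removed afterwards by one of two procedures:

- **Binomial germline filter**: a call is removed iff the alt count in
  the matched normal satisfies P(X ≥ k_N | n_N, e) < 0.05 — more alt
  evidence than sequencing error at rate e = 0.5% explains. The 0.5% is a
  worst-case bound used as the test value; both this filter and the
  caller use one-sided (greater) alternatives, since only an *excess* of
  alt reads is evidence of a variant or of germline origin.
- **Normal-call subtraction**: remove tumor calls whose (chrom, pos, alt)
  was also called in the normal alone.

Both filters preserve the surviving order, recompute ranks, are idempotent
and only shrink call sets.

## Evaluation

Evaluation is SNV-level against the simulated truth. Multi-nucleotide
substitutions (on either side) are split into per-base SNVs, dropping
positions where ref equals alt; a predicted MNV's pieces share its score.
Any truth record containing an indel defines an exclusion zone over its
reference footprint, and predictions overlapping a zone are labelled
`excluded` and participate in no metric — such sites are ambiguous to
score when truth and prediction can legitimately represent the same event
differently. A prediction is TP iff its (chrom, pos, alt) matches a
somatic truth SNV, each truth SNV matchable once; everything else
(non-excluded) is FP. Ranks are always the deterministic total order:
score descending, ties broken by ascending (chrom, pos, alt).

Metrics over the effective (non-excluded) ranking:

- `fdr_prefix(α)`: the largest prefix length j with FP(j)/j ≤ α.
- PR curve: precision(j) = TP(j)/j, recall(j) = TP(j)/n_truth.
- `auPRC_t`: precision integrated over recall by right-continuous step
  interpolation, restricted to prefixes with precision ≥ t,
  un-normalized. Each qualifying prefix contributes its precision times
  the recall it newly covers. The definition was fixed here (the measure
  is only loosely pinned down by its name): it lies in [0, 1], approaches
  the full step-interpolated auPRC as t → 0, and satisfies
  auPRC_95 ≤ auPRC_90.
- VAF-binned sensitivity: bins (0, 0.05), [0.05, 0.10), …, [0.95, 1.0] —
  the last bin closed so homozygous clonal variants are binnable.

All metrics depend on ranks only; any strictly monotone transform of a
tool's scores changes nothing.

## Error attribution

Candidates are the two high-signal error sets: false calls inside the longest
prefix with precision ≥ 0.95 (high-confidence FPs) and somatic truth SNVs
absent from the full call set with true VAF ≥ 0.25 (high-frequency FNs,
boundary inclusive). Each candidate site is classified against tumor and
normal pileup columns into every applicable category:

| category | rule (defaults) |
|---|---|
| low_coverage | tumor depth < 25 |
| low_quality | max MAPQ among alt-supporting tumor reads < 31 |
| variable_region | ≥ 1 truth indel or > 4 truth SNVs within 10 bp (site itself excluded) |
| low_support | depth ≥ 25, no aligned alt read, but carrier reads exist in the pool |
| seq_error_in_normal | site not germline, yet ≥ 1 alt read in the normal pileup |
| low_quality_in_normal | normal raw depth ≥ 25 but MAPQ ≥ 31 depth < 25 |
| low_coverage_in_normal | normal depth < 25 |
| in_normal | truth germline at the site |
| alignment_location | ≥ 1 read whose true origin covers the site aligned elsewhere / discarded |
| high_coverage | tumor depth > 200 |
| other | iff nothing above applies |

Categories may overlap (profiles can sum above 100%), with three
structural exclusions: `other` is always a singleton; `low_support`
presupposes adequate coverage and so excludes `low_coverage`;
`low_quality_in_normal` presupposes adequate raw normal depth and so
excludes `low_coverage_in_normal`. Interpretation choices made here:
"reads supporting the variant" means alt-supporting reads at the column
(if none exist, `low_quality` cannot fire); the variable-region context
counts ground-truth variants of both origins; one alt read in the normal
suffices for `seq_error_in_normal` (minimal-evidence reading,
configurable); "ambiguous alignments in the normal" is operationalized as
the MAPQ < 31 proxy. `low_support` and `alignment_location` require
truth-origin read metadata, which only simulated data (or the read-name
grammar, when external aligners are inserted) can provide. Per-tool
profiles are category percentages over the candidate set; tool–tool
similarity is the Pearson correlation of the full 11-component percentage
vectors (undefined — reported as NaN — for empty candidate sets or
zero-variance profiles).

## Rank combination

Given K ≥ 2 ranked call sets, the union universe U is formed; each tool
ranks its own calls 1..n_k and all its uncalled variants share the single
worst rank |U| (rather than n_k + 1, keeping rank scales comparable
between tools with very different call counts). Ranks map to scores
Φ⁻¹(1 − rank/(|U|+1)). The score columns are standardized, their
correlation matrix Σ estimated, and the combined score is the
precision-weighted sum `z · Σ⁺ 1` — equivalently, scores are whitened by
the symmetric pseudo-inverse of Σ (eigenvalues below 1e−10 are null
directions; a zero-variance column contributes nothing and is logged) and
row-summed against the whitened all-ones direction. The pseudo-*inverse*
(not its square root) is the deliberate choice: it is the GLS weighting
and it makes the desired invariances exact — identical call sets are a
fixed point, an exact duplicate of a tool never changes the combined
ranking (both reduce to (a+b)/(1+ρ) in the two- and three-tool algebra),
and two exactly reversed rankings cancel to a complete tie because the
all-ones vector is orthogonal to the range of Σ. An inverse-square-root
whitening would weight a duplicated tool by √2 and break duplicate
invariance. Tier-ranked tools (callers that emit stringency lists instead
of scores) are adapted by ranking tier first — most stringent list on
top — and coordinate within tier.

The intersection baseline keeps variants present in every tool's
α-FDR-restricted prefix (or full call sets when no labels are given); its
recall is bounded by the weakest tool's.

## Problem sizes and numerical choices

Fixture experiments use synthetic references of 100–200 kb with 10–20 kb
of capture targets, a few hundred somatic and twice as many germline
variants, and depths of 25–200×; these are the package's chosen
desk-scale study conditions (the code accepts genome-scale inputs, but
fixtures do not ship them). All randomness flows through
`numpy.random.default_rng` with child seeds derived by SHA-256 from a
single base seed and a stage tag, so every artifact is bit-reproducible
per seed — two runs with equal configuration produce byte-identical
outputs, which the manifest checksums in the pipeline verify. Binomial
tails are computed by `scipy.stats.binom` (log-survival-function scores
avoid underflow at extreme counts); the test suite checks them against a
direct tail-summation oracle. Dirichlet components are clipped away from
exact zero (at 1e−300) only to preserve the strict-positivity invariant.

## Known limitations

- No copy-number variation or aneuploidy: VAFs are purely
  tree-and-mixture driven.
- The error model is substitution-only with a linear ramp; capture bias,
  duplicates, and indel sequencing errors are absent, so error-source
  frequencies observed here need not match any real capture's.
- Truth alignments sidestep the aligner: alignment-induced error modes
  (`low_support`, `alignment_location`) occur only when users insert real
  aligners between stages; the classifier supports them through the
  read-name grammar but the built-in pipeline rarely produces them.
- The built-in caller is intentionally naive; it is a harness for the
  measurement machinery, not a competitive caller.
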