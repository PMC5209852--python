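# somabench

Somatic single-nucleotide variant (SNV) calling in tumors is hard for
reasons that are easy to state and awkward to measure: tumors are mixtures
of genetically distinct subclones diluted by normal tissue, so true
variants appear at any allele fraction in (0, 1]; germline variants leak
into somatic call sets; and coverage, mapping quality, and local variant
density each produce their own flavor of false call. Benchmarking callers
on real data founders on the absence of ground truth.

`somabench` builds that ground truth synthetically, end to end, and ships
the measurement machinery to go with it. It is aimed at people who develop
or tune somatic-calling pipelines and want a controlled, fully specified
tumor-normal experiment: every variant's true origin, carrier clones,
zygosity, and expected allele fraction are known, and every simulated read
records where it came from.

## The model

A tumor sample is a mixture of `K` diploid cancer clones (default `K = 8`)
plus contaminating normal cells. Clones are related by a rooted clonal
ancestry tree; a somatic variant is acquired at one node and inherited by
all descendants, while germline variants sit in the normal genome and in
every clone. Clone proportions `w` are one draw from a symmetric
Dirichlet(α, …, α) with α = 1/8. With normal-read fraction κ
(purity 1 − κ) and `c_i` mutated copies per carrier clone, the expected
variant allele frequency is

    VAF = [ (1 − κ) · Σ_{i ∈ carriers} w_i · c_i  +  κ · c_normal ] / 2 .

Reads are sampled uniformly over padded capture targets with a linear
per-cycle error ramp (0.1% → 1% by default), mixed multinomially by
`((1 − κ)·w, κ)`, and emitted with truth alignments (SAM, MAPQ 60) so that
no external aligner is needed.

On top of the simulator:

- **Evaluation** — MNV splitting, indel exclusion zones, FDR-restricted
  top sets, precision–recall curves, and `auPRC_t`: the area under the PR
  curve restricted to ranked prefixes with precision ≥ t (t = 0.90, 0.95),
  plus sensitivity per 0.05-wide VAF bin.
- **Germline removal** — a one-sided binomial test on the alt-read count
  in the matched normal (error rate e = 0.005, remove when the tail
  probability < 0.05), and plain subtraction of normal-sample calls.
- **Error attribution** — eleven pileup-based error-source categories
  (low coverage < 25×, low mapping quality < 31, variable region, low
  support, sequencing error in normal, low quality in normal, low coverage
  in normal, in normal, alignment location, high coverage > 200×, other)
  with per-tool profiles and their Pearson correlations.
- **Combination** — decorrelated rank fusion of K ≥ 2 call sets: union
  ranks are mapped to standard-normal scores, the score columns are
  whitened by the pseudo-inverse of their correlation matrix, and the
  weighted sum is re-ranked. The intersection of FDR-restricted call sets
  is provided as the baseline.

## Worked example

`examples/combine_callers.py` fabricates five callers that each find ~60%
of 400 simulated somatic SNVs (independently) and add 60 false calls, then
fuses them:

```
caller0: 304 calls, auPRC_90 = 0.535
caller1: 300 calls, auPRC_90 = 0.513
caller2: 302 calls, auPRC_90 = 0.485
caller3: 301 calls, auPRC_90 = 0.520
caller4: 308 calls, auPRC_90 = 0.582

rank combination: auPRC_90 = 0.960
intersection: 36 calls, auPRC_90 = 0.090
```

Each caller alone tops out near auPRC_90 ≈ 0.5: it can rank at most 60% of
the truth above its false calls. The rank combination reaches 0.96 because
the callers' misses are complementary while their false calls rarely
coincide, so fusion recovers nearly the union of their sensitivities at
high precision. The intersection is precise but keeps only variants all
five agree on — recall, and with it the area, collapses.

The other examples follow the same pattern: `simulate_tumor.py` (clonal
tree, weights, VAF spectrum, read mixing), `evaluate_caller.py` (the
built-in naive binomial caller before/after germline filtering — the
unfiltered auPRC_90 is 0.0 because germline leaks crowd the top of the
ranking, the filtered one ≈ 0.5), and `attribute_errors.py` (error-source
profiles of the naive caller's mistakes).

A thin CLI mirrors the pipeline stages
(`somabench run`, `simulate-truth` … `attribute-errors`,
`combine-rank`, `combine-intersect`); see `somabench --help`.

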