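"""Shared builders for tests: hand-constructed pileups, truth sets, and the
one-category attribution cases, plus independent brute-force oracles."""

from __future__ import annotations

import math

import numpy as np

from somabench.attribution import ErrorCategory, PoolEvidence
from somabench.calling import CallSet
from somabench.core import Origin, TruthVariant, Variant
from somabench.evaluation import LabeledCallSet
from somabench.pileup import PileupColumn, PileupRead


def make_column(
    chrom: str,
    pos: int,
    ref_base: str = "A",
    n_ref: int = 30,
    alt: str = "T",
    n_alt: int = 0,
    mapq: int = 60,
    alt_mapq: int | None = None,
    low_mapq_ref: int = 0,
    low_mapq_value: int = 10,
) -> PileupColumn:
    """A pileup column with controllable depth, alt support, and MAPQs."""
    reads = []
    for _ in range(n_ref - low_mapq_ref):
        reads.append(PileupRead(base=ref_base, baseq=30, mapq=mapq))
    for _ in range(low_mapq_ref):
        reads.append(PileupRead(base=ref_base, baseq=30, mapq=low_mapq_value))
    for _ in range(n_alt):
        reads.append(
            PileupRead(base=alt, baseq=30,
                       mapq=mapq if alt_mapq is None else alt_mapq)
        )
    return PileupColumn(chrom=chrom, pos=pos, reads=reads)


def somatic_truth(
    chrom: str, pos: int, ref: str, alt: str, vaf: float, node: int = 1,
    carriers=(1,), copies: int = 1,
) -> TruthVariant:
    return TruthVariant(
        variant=Variant(chrom, pos, ref, alt),
        origin=Origin.SOMATIC,
        carriers=frozenset(carriers),
        copies=copies,
        normal_copies=0,
        assigned_node=node,
        true_vaf=vaf,
    )


def germline_truth(
    chrom: str, pos: int, ref: str, alt: str, copies: int = 1, vaf: float = 0.5,
    n_clones: int = 8,
) -> TruthVariant:
    return TruthVariant(
        variant=Variant(chrom, pos, ref, alt),
        origin=Origin.GERMLINE,
        carriers=frozenset(range(1, n_clones + 1)),
        copies=copies,
        normal_copies=copies,
        true_vaf=vaf,
    )


def synthetic_truth_set(
    n: int, seed: int = 0, chrom: str = "chr1", vaf_range=(0.02, 1.0)
) -> list[TruthVariant]:
    """n somatic truth SNVs at distinct positions with spread-out VAFs."""
    rng = np.random.default_rng(seed)
    positions = rng.choice(np.arange(1, 40 * n), size=n, replace=False)
    pairs = [("A", "T"), ("C", "G"), ("G", "A"), ("T", "C")]
    out = []
    for pos in sorted(int(p) for p in positions):
        ref, alt = pairs[int(rng.integers(0, 4))]
        vaf = float(rng.uniform(*vaf_range))
        out.append(somatic_truth(chrom, pos, ref, alt, vaf))
    return out


def labeled_from_pattern(labels: list[str], n_truth: int) -> LabeledCallSet:
    """A LabeledCallSet whose effective labels follow the given TP/FP pattern."""
    n = len(labels)
    scored = [(Variant("c1", i + 1, "A", "T"), float(n - i)) for i in range(n)]
    callset = CallSet.from_scores("fixture", scored)
    return LabeledCallSet(callset=callset, labels=list(labels), n_truth=n_truth)


# ---------------------------------------------------------------------------
# independent oracles

def binomial_tail_oracle(k: int, n: int, e: float) -> float:
    """P(X >= k | n, e) by direct summation of the complement."""
    if k <= 0:
        return 1.0
    acc = 0.0
    for j in range(k):
        acc += math.comb(n, j) * (e ** j) * ((1.0 - e) ** (n - j))
    return max(0.0, 1.0 - acc)


def brute_force_metrics(is_tp: list[bool], n_truth: int, alpha: float, t: float):
    """Prefix-enumeration oracle for fdr_prefix, the PR curve, and the
    precision-limited area, independent of the package implementation."""
    best_j = 0
    tp = 0
    precisions, recalls = [], []
    area = 0.0
    prev_recall = 0.0
    for j, lab in enumerate(is_tp, start=1):
        tp += int(lab)
        fdr = (j - tp) / j
        if fdr <= alpha:
            best_j = j
        prec, rec = tp / j, tp / n_truth
        precisions.append(prec)
        recalls.append(rec)
        if prec >= t and rec > prev_recall:
            area += prec * (rec - prev_recall)
            prev_recall = rec
    return best_j, precisions, recalls, area


# ---------------------------------------------------------------------------
# the eleven single-category attribution cases

def attribution_cases():
    """(name, site, tumor col, normal col, truth context, pool evidence,
    expected category set) — each constructed to fire exactly one rule."""
    site = ("chr1", 5000, "T")
    clean_t = make_column("chr1", 5000, n_ref=40, n_alt=8)
    clean_n = make_column("chr1", 5000, n_ref=40, n_alt=0)
    none = PoolEvidence()
    cases = []

    cases.append((
        "low_coverage",
        site, make_column("chr1", 5000, n_ref=8, n_alt=2), clean_n, [], none,
        {ErrorCategory.LOW_COVERAGE},
    ))
    cases.append((
        "low_quality",
        site, make_column("chr1", 5000, n_ref=40, n_alt=6, alt_mapq=20),
        clean_n, [], none,
        {ErrorCategory.LOW_QUALITY},
    ))
    context = [somatic_truth("chr1", 5000 + d, "A", "G", 0.4)
               for d in (-9, -5, 2, 6, 9)]
    cases.append((
        "variable_region", site, clean_t, clean_n, context, none,
        {ErrorCategory.VARIABLE_REGION},
    ))
    cases.append((
        "low_support",
        site, make_column("chr1", 5000, n_ref=40, n_alt=0), clean_n, [],
        PoolEvidence(carrier_reads_in_pool=12),
        {ErrorCategory.LOW_SUPPORT},
    ))
    cases.append((
        "seq_error_in_normal",
        site, clean_t, make_column("chr1", 5000, n_ref=39, n_alt=1), [], none,
        {ErrorCategory.SEQ_ERROR_IN_NORMAL},
    ))
    cases.append((
        "low_quality_in_normal",
        site, clean_t,
        make_column("chr1", 5000, n_ref=40, n_alt=0, low_mapq_ref=22), [], none,
        {ErrorCategory.LOW_QUALITY_IN_NORMAL},
    ))
    cases.append((
        "low_coverage_in_normal",
        site, clean_t, make_column("chr1", 5000, n_ref=10, n_alt=0), [], none,
        {ErrorCategory.LOW_COVERAGE_IN_NORMAL},
    ))
    cases.append((
        "in_normal",
        site, clean_t, clean_n,
        [germline_truth("chr1", 5000, "A", "T")], none,
        {ErrorCategory.IN_NORMAL},
    ))
    cases.append((
        "alignment_location",
        site, clean_t, clean_n, [],
        PoolEvidence(reads_aligned_elsewhere=3),
        {ErrorCategory.ALIGNMENT_LOCATION},
    ))
    cases.append((
        "high_coverage",
        site, make_column("chr1", 5000, n_ref=230, n_alt=10), clean_n, [], none,
        {ErrorCategory.HIGH_COVERAGE},
    ))
    cases.append((
        "other", site, clean_t, clean_n, [], none,
        {ErrorCategory.OTHER},
    ))
    return cases


def random_attribution_inputs(rng):
    """One random classification input for exclusivity-rule fuzzing."""
    site = ("chr1", int(rng.integers(100, 10_000)), "T")
    t_col = make_column(
        "chr1", site[1],
        n_ref=int(rng.integers(0, 260)),
        n_alt=int(rng.integers(0, 30)),
        alt_mapq=int(rng.choice([10, 25, 31, 60])),
    )
    n_col = make_column(
        "chr1", site[1],
        n_ref=int(rng.integers(0, 60)),
        n_alt=int(rng.integers(0, 3)),
        low_mapq_ref=int(rng.integers(0, 30)),
    )
    truth = []
    for d in range(-12, 13):
        if d != 0 and rng.random() < 0.15:
            if rng.random() < 0.2:
                truth.append(
                    TruthVariant(
                        variant=Variant("chr1", site[1] + d, "AC", "A"),
                        origin=Origin.SOMATIC,
                        carriers=frozenset({1}),
                        copies=1,
                        normal_copies=0,
                        assigned_node=1,
                        true_vaf=0.3,
                    )
                )
            else:
                truth.append(somatic_truth("chr1", site[1] + d, "A", "G", 0.3))
    if rng.random() < 0.3:
        truth.append(germline_truth("chr1", site[1], "A", "T"))
    ev = PoolEvidence(
        carrier_reads_in_pool=int(rng.integers(0, 3)),
        reads_aligned_elsewhere=int(rng.integers(0, 2)),
    )
    return site, t_col, n_col, truth, ev
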