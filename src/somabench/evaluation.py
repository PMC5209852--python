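"""Matching predictions to ground truth and performance measures.

Evaluation is SNV-level: multi-nucleotide substitutions are split into
per-base SNVs, and predictions overlapping a ground-truth record that
contains an indel (a length-changing substitution such as ACGG->GCGGG, or
an anchored insertion/deletion) are labelled *excluded* — such sites are
ambiguous to score and participate in no metric.

Callers are compared on FDR-restricted top sets: the largest prefix of the
confidence ranking whose false discovery rate stays within a bound alpha.
The headline metric is the area under the precision-recall curve
restricted to prefixes with precision >= t (auPRC_90 / auPRC_95), and
sensitivity is reported per VAF bin of width 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calling import CallRecord, CallSet
from .core import Origin, TruthVariant, Variant

__all__ = [
    "normalize_variants",
    "LabeledCallSet",
    "label_calls",
    "fdr_prefix",
    "PRCurve",
    "precision_recall_curve",
    "auprc_at_precision",
    "sensitivity_by_vaf",
    "VAF_BIN_WIDTH",
]

VAF_BIN_WIDTH = 0.05


def split_mnv(v: Variant) -> list[Variant]:
    """Decompose an equal-length substitution into per-base SNVs.

    Positions where ref and alt agree are dropped, so e.g. ACG->AGG
    yields the single SNV C->G at pos+1.
    """
    if len(v.ref) != len(v.alt):
        raise ValueError("split_mnv requires an equal-length substitution")
    return [
        Variant(v.chrom, v.pos + i, r, a)
        for i, (r, a) in enumerate(zip(v.ref, v.alt))
        if r != a
    ]


def normalize_variants(
    variants: list[Variant],
) -> tuple[list[Variant], list[tuple[str, int, int]]]:
    """Reduce a variant list to SNVs plus indel exclusion zones.

    Returns (snvs, exclusions) where exclusions are 0-based half-open
    reference intervals covered by length-changing records.  SNVs pass
    through; MNVs are split per base; anything containing an indel
    contributes its reference footprint to the exclusion zones.
    """
    snvs: list[Variant] = []
    exclusions: list[tuple[str, int, int]] = []
    for v in variants:
        if len(v.ref) == len(v.alt):
            snvs.extend(split_mnv(v) if len(v.ref) > 1 else [v])
        else:
            s, e = v.ref_span
            exclusions.append((v.chrom, s, max(e, s + len(v.alt))))
    return snvs, exclusions


def _in_exclusion(v: Variant, zones: dict[str, list[tuple[int, int]]]) -> bool:
    s, e = v.ref_span
    for zs, ze in zones.get(v.chrom, ()):
        if s < ze and zs < e:
            return True
    return False


@dataclass
class LabeledCallSet:
    """A normalized call set with per-record TP/FP/excluded labels.

    ``n_truth`` is the number of scoreable ground-truth somatic SNVs;
    excluded records participate in no metric.
    """

    callset: CallSet
    labels: list[str]
    n_truth: int

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.callset.records):
            raise ValueError("one label per record required")
        bad = set(self.labels) - {"TP", "FP", "excluded"}
        if bad:
            raise ValueError(f"unknown labels {bad}")
        if self.labels.count("TP") > self.n_truth:
            raise ValueError("more TPs than truth variants")

    def effective(self) -> tuple[np.ndarray, list[CallRecord]]:
        """(is_tp array, records) with excluded entries removed."""
        recs = [r for r, l in zip(self.callset.records, self.labels)
                if l != "excluded"]
        is_tp = np.array(
            [l == "TP" for l in self.labels if l != "excluded"], dtype=bool
        )
        return is_tp, recs


def label_calls(calls: CallSet, truth: list[TruthVariant]) -> LabeledCallSet:
    """Label each prediction TP, FP, or excluded against the ground truth.

    Both sides are normalized first: truth MNVs are split into SNVs (each
    inheriting the parent's VAF) and truth records containing indels
    define exclusion zones; predicted MNVs are split into per-base SNV
    calls sharing the parent's score, and length-changing predictions are
    excluded outright.  A prediction is TP iff its (chrom, pos, alt)
    matches a somatic truth SNV, each truth SNV matchable at most once.
    """
    truth_snv_keys: set = set()
    zones: dict[str, list[tuple[int, int]]] = {}
    for tv in truth:
        v = tv.variant
        if len(v.ref) == len(v.alt):
            if tv.origin is Origin.SOMATIC:
                for s in (split_mnv(v) if len(v.ref) > 1 else [v]):
                    truth_snv_keys.add(s.key)
        else:
            s, e = v.ref_span
            zones.setdefault(v.chrom, []).append((s, max(e, s + len(v.alt))))

    expanded: list[tuple[Variant, float, bool]] = []  # (snv, score, is_indel)
    for rec in calls:
        v = rec.variant
        if len(v.ref) == len(v.alt):
            for s in (split_mnv(v) if len(v.ref) > 1 else [v]):
                expanded.append((s, rec.score, False))
        else:
            expanded.append((v, rec.score, True))
    seen = set()
    for v, _, _ in expanded:
        if v.key in seen:
            raise ValueError(f"duplicate call coordinates after splitting: {v.key}")
        seen.add(v.key)

    ordered = sorted(expanded, key=lambda t: (-t[1], t[0].chrom, t[0].pos, t[0].alt))
    records = [
        CallRecord(variant=v, score=s, rank=i)
        for i, (v, s, _) in enumerate(ordered, start=1)
    ]
    normalized = CallSet(tool_id=calls.tool_id, records=records,
                         rank_basis=calls.rank_basis, latents=calls.latents)

    labels: list[str] = []
    matched: set = set()
    for (v, _, is_indel) in ordered:
        if is_indel or _in_exclusion(v, zones):
            labels.append("excluded")
        elif v.key in truth_snv_keys and v.key not in matched:
            matched.add(v.key)
            labels.append("TP")
        else:
            labels.append("FP")
    return LabeledCallSet(callset=normalized, labels=labels,
                          n_truth=len(truth_snv_keys))


def fdr_prefix(labeled: LabeledCallSet, alpha: float) -> int:
    """Length of the largest ranked prefix with FDR <= alpha.

    The prefix is taken over the effective (non-excluded) ranking; 0 is
    returned when no prefix satisfies the bound.  By construction no
    longer prefix satisfies it.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    is_tp, _ = labeled.effective()
    if is_tp.size == 0:
        return 0
    fp_cum = np.cumsum(~is_tp)
    j = np.arange(1, is_tp.size + 1)
    ok = np.flatnonzero(fp_cum / j <= alpha)
    return int(ok[-1] + 1) if ok.size else 0


def prefix_keys(labeled: LabeledCallSet, j: int) -> set:
    """Variant keys of the first j effective records."""
    _, recs = labeled.effective()
    return {r.key for r in recs[:j]}


@dataclass
class PRCurve:
    """Precision/recall per ranked-prefix length j = 1..n (effective)."""

    precision: np.ndarray
    recall: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.recall) < 0):
            raise ValueError("recall must be non-decreasing")


def precision_recall_curve(labeled: LabeledCallSet) -> PRCurve:
    """precision(j) = TP(j)/j and recall(j) = TP(j)/n_truth for every prefix."""
    if labeled.n_truth <= 0:
        raise ValueError("n_truth must be positive")
    is_tp, _ = labeled.effective()
    tp_cum = np.cumsum(is_tp)
    j = np.arange(1, is_tp.size + 1)
    return PRCurve(
        precision=tp_cum / j if is_tp.size else np.empty(0),
        recall=tp_cum / labeled.n_truth if is_tp.size else np.empty(0),
    )


def auprc_at_precision(curve: PRCurve, t: float) -> float:
    """Area under the PR curve restricted to prefixes with precision >= t.

    Precision is integrated over recall by right-continuous step
    interpolation from recall 0 up to the largest qualifying recall: each
    qualifying prefix (in rank order) contributes precision(j) times the
    recall it newly covers.  The result lies in [0, 1]; with t -> 0 this
    approaches the full step-interpolated auPRC, and auPRC_95 <= auPRC_90.
    """
    if not 0.0 < t <= 1.0:
        raise ValueError("t must be in (0, 1]")
    area = 0.0
    prev_recall = 0.0
    for p, r in zip(curve.precision, curve.recall):
        if p >= t and r > prev_recall:
            area += p * (r - prev_recall)
            prev_recall = r
    return float(area)


def sensitivity_by_vaf(
    truth: list[TruthVariant],
    detected: set,
    bin_width: float = VAF_BIN_WIDTH,
):
    """Per-VAF-bin sensitivity of a detected-key set against the truth.

    Bins are (0, w), [w, 2w), ..., [1-w, 1.0] — half-open except the last,
    which is closed at 1.0 so that homozygous clonal variants are
    binnable.  Truth MNVs are split into SNVs inheriting the parent VAF.
    Returns a list of dicts with bin bounds, counts, and sensitivity
    (None for empty bins).
    """
    n_bins = int(round(1.0 / bin_width))
    totals = np.zeros(n_bins, dtype=int)
    hits = np.zeros(n_bins, dtype=int)
    for tv in truth:
        if tv.origin is not Origin.SOMATIC:
            continue
        v = tv.variant
        if len(v.ref) != len(v.alt):
            continue
        if tv.true_vaf is None or not 0.0 < tv.true_vaf <= 1.0:
            raise ValueError(f"true_vaf must be in (0, 1] for {v.key}")
        idx = min(int(tv.true_vaf / bin_width), n_bins - 1)
        for s in (split_mnv(v) if len(v.ref) > 1 else [v]):
            totals[idx] += 1
            if s.key in detected:
                hits[idx] += 1
    out = []
    for i in range(n_bins):
        out.append(
            {
                "bin_low": round(i * bin_width, 10),
                "bin_high": round((i + 1) * bin_width, 10),
                "n_truth": int(totals[i]),
                "n_detected": int(hits[i]),
                "sensitivity": (hits[i] / totals[i]) if totals[i] else None,
            }
        )
    return out
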