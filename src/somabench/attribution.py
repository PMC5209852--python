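"""Classification of calling errors into pileup-based source categories.

High-confidence false positives (false calls inside a tool's
precision >= 95% prefix) and high-frequency false negatives (missed truth
SNVs with VAF >= 25%) are classified into eleven error-source categories
by inspecting the tumor and normal pileups at the site, the surrounding
ground-truth variants, and — where available — the true origins of the
reads in the pool.  A variant can fall into several categories at once
(the per-category percentages of a tool's error profile may sum above
100%), with three exceptions: `other` fires only when nothing else does,
`low_support` requires sufficient coverage and so excludes `low_coverage`,
and `low_quality_in_normal` likewise excludes `low_coverage_in_normal`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Origin, TruthVariant
from .evaluation import LabeledCallSet, split_mnv
from .pileup import PileupColumn

__all__ = [
    "ErrorCategory",
    "ClassifierThresholds",
    "PoolEvidence",
    "select_error_candidates",
    "classify_error_sources",
    "ErrorProfile",
    "error_profiles",
    "profile_correlation",
]


class ErrorCategory(str, enum.Enum):
    LOW_COVERAGE = "low_coverage"
    LOW_QUALITY = "low_quality"
    VARIABLE_REGION = "variable_region"
    LOW_SUPPORT = "low_support"
    SEQ_ERROR_IN_NORMAL = "seq_error_in_normal"
    LOW_QUALITY_IN_NORMAL = "low_quality_in_normal"
    LOW_COVERAGE_IN_NORMAL = "low_coverage_in_normal"
    IN_NORMAL = "in_normal"
    ALIGNMENT_LOCATION = "alignment_location"
    HIGH_COVERAGE = "high_coverage"
    OTHER = "other"


CATEGORY_ORDER = list(ErrorCategory)


@dataclass(frozen=True)
class ClassifierThresholds:
    """Cutoffs of the error taxonomy.

    min_depth: below this tumor (or normal) depth the site counts as low
    coverage (25x).  min_mapq: a variant whose best alt-supporting read
    maps below this quality counts as low quality (31, bowtie2's scale).
    context_window: +-bp window for the variable-region rule; more than
    ``max_context_snvs`` truth SNVs or any truth indel inside it fires.
    high_depth: tumor depth beyond which the site counts as high coverage
    (200x).  min_normal_alt: alt reads in the normal needed to call a
    normal-sample sequencing error (minimal-evidence reading: 1).
    """

    min_depth: int = 25
    min_mapq: int = 31
    context_window: int = 10
    max_context_snvs: int = 4
    high_depth: int = 200
    min_normal_alt: int = 1


@dataclass(frozen=True)
class PoolEvidence:
    """Truth-level read evidence that a pileup alone cannot show.

    carrier_reads_in_pool: reads in the sequenced pool that originate
    from a carrier haplotype bearing the variant and span the site.
    reads_aligned_elsewhere: reads whose true origin covers the site but
    whose primary alignment is elsewhere or absent (discarded
    multi-mappers).  Only simulated data can define these quantities.
    """

    carrier_reads_in_pool: int = 0
    reads_aligned_elsewhere: int = 0


def select_error_candidates(
    labeled: LabeledCallSet,
    truth: list[TruthVariant],
    min_precision: float = 0.95,
    min_fn_vaf: float = 0.25,
) -> tuple[list, list[TruthVariant]]:
    """High-confidence FPs and high-frequency FNs for attribution.

    FPs are the false calls inside the longest ranked prefix whose
    precision is at least ``min_precision``; FNs are somatic truth SNVs
    absent from the full call set with true VAF >= ``min_fn_vaf``
    (boundary inclusive).
    """
    is_tp, recs = labeled.effective()
    fp_keys: list = []
    if is_tp.size:
        tp_cum = np.cumsum(is_tp)
        j = np.arange(1, is_tp.size + 1)
        ok = np.flatnonzero(tp_cum / j >= min_precision)
        cut = int(ok[-1] + 1) if ok.size else 0
        fp_keys = [r.key for r, t in zip(recs[:cut], is_tp[:cut]) if not t]

    called_keys = {r.variant.key for r in labeled.callset.records}
    fns: list[TruthVariant] = []
    for tv in truth:
        if tv.origin is not Origin.SOMATIC:
            continue
        v = tv.variant
        if len(v.ref) != len(v.alt):
            continue
        if tv.true_vaf is None or tv.true_vaf < min_fn_vaf:
            continue
        pieces = split_mnv(v) if len(v.ref) > 1 else [v]
        if all(p.key not in called_keys for p in pieces):
            fns.append(tv)
    return fp_keys, fns


def classify_error_sources(
    site: tuple[str, int, str],
    tumor_col: PileupColumn,
    normal_col: PileupColumn,
    truth: list[TruthVariant],
    pool_evidence: PoolEvidence | None = None,
    thresholds: ClassifierThresholds = ClassifierThresholds(),
) -> set[ErrorCategory]:
    """Assign every applicable error-source category to one site.

    ``site`` is (chrom, 1-based pos, alt).  The rules, in order:
    low coverage (tumor depth < 25); low quality (best MAPQ among
    alt-supporting tumor reads < 31); variable region (>=1 truth indel or
    >4 truth SNVs within 10 bp, the site itself excluded); low support
    (depth >= 25 but no aligned alt read although carrier reads exist in
    the pool); seq error in normal (site not germline yet alt reads in
    the normal pileup); low quality in normal (raw depth >= 25 but
    MAPQ >= 31 depth < 25); low coverage in normal (depth < 25);
    in normal (truth germline at the site); alignment location (reads
    whose true origin covers the site aligned elsewhere or discarded);
    high coverage (tumor depth > 200); `other` iff nothing above applies.
    """
    chrom, pos, alt = site
    th = thresholds
    ev = pool_evidence or PoolEvidence()
    cats: set[ErrorCategory] = set()

    t_depth = tumor_col.depth
    if t_depth < th.min_depth:
        cats.add(ErrorCategory.LOW_COVERAGE)

    alt_mapq = tumor_col.max_mapq(alt)
    if alt_mapq is not None and alt_mapq < th.min_mapq:
        cats.add(ErrorCategory.LOW_QUALITY)

    n_snv = 0
    has_indel = False
    germline_here = False
    for tv in truth:
        v = tv.variant
        if v.chrom != chrom:
            continue
        if v.pos == pos and tv.origin is Origin.GERMLINE:
            germline_here = True
        if v.pos == pos:
            continue  # context excludes the site itself
        s, e = v.ref_span
        if s < pos + th.context_window and (pos - 1) < e + th.context_window:
            if len(v.ref) != len(v.alt):
                has_indel = True
            else:
                n_snv += len(split_mnv(v)) if len(v.ref) > 1 else 1
    if has_indel or n_snv > th.max_context_snvs:
        cats.add(ErrorCategory.VARIABLE_REGION)

    # low support requires enough coverage, so it never joins low_coverage
    if (
        t_depth >= th.min_depth
        and len(tumor_col.alt_reads(alt)) == 0
        and ev.carrier_reads_in_pool > 0
    ):
        cats.add(ErrorCategory.LOW_SUPPORT)

    if not germline_here and len(normal_col.alt_reads(alt)) >= th.min_normal_alt:
        cats.add(ErrorCategory.SEQ_ERROR_IN_NORMAL)

    n_depth = normal_col.depth
    if n_depth < th.min_depth:
        cats.add(ErrorCategory.LOW_COVERAGE_IN_NORMAL)
    elif normal_col.depth_at_mapq(th.min_mapq) < th.min_depth:
        cats.add(ErrorCategory.LOW_QUALITY_IN_NORMAL)

    if germline_here:
        cats.add(ErrorCategory.IN_NORMAL)

    if ev.reads_aligned_elsewhere > 0:
        cats.add(ErrorCategory.ALIGNMENT_LOCATION)

    if t_depth > th.high_depth:
        cats.add(ErrorCategory.HIGH_COVERAGE)

    if not cats:
        cats.add(ErrorCategory.OTHER)
    return cats


@dataclass
class ErrorProfile:
    """Per-tool category counts and percentages over one candidate set."""

    tool_id: str
    set_type: str  # "FP" or "FN"
    counts: dict[ErrorCategory, int]
    total: int

    @property
    def percentages(self) -> dict[ErrorCategory, float]:
        if self.total == 0:
            return {c: 0.0 for c in CATEGORY_ORDER}
        return {
            c: 100.0 * self.counts.get(c, 0) / self.total for c in CATEGORY_ORDER
        }

    def vector(self) -> np.ndarray:
        p = self.percentages
        return np.array([p[c] for c in CATEGORY_ORDER])


def error_profiles(
    classified: dict[str, list[set[ErrorCategory]]],
    set_type: str,
) -> dict[str, ErrorProfile]:
    """Aggregate per-variant category sets into per-tool profiles.

    Percentages are per-category shares of the tool's candidate total;
    since one variant may carry several categories they may sum above
    100%.  Aggregation is order-invariant in the input variants.
    """
    out = {}
    for tool, sets in classified.items():
        counts: dict[ErrorCategory, int] = {c: 0 for c in CATEGORY_ORDER}
        for cats in sets:
            for c in cats:
                counts[c] += 1
        out[tool] = ErrorProfile(
            tool_id=tool, set_type=set_type, counts=counts, total=len(sets)
        )
    return out


def profile_correlation(profiles: dict[str, ErrorProfile]) -> pd.DataFrame:
    """Pearson correlation between tools' category-percentage vectors.

    All eleven categories (including `other`) enter the vectors.  Tools
    with an empty candidate set have undefined correlations, reported as
    NaN.
    """
    tools = sorted(profiles)
    if len(tools) < 2:
        raise ValueError("need at least two tools for a correlation")
    mat = np.full((len(tools), len(tools)), np.nan)
    for i, a in enumerate(tools):
        for j, b in enumerate(tools):
            pa, pb = profiles[a], profiles[b]
            if pa.total == 0 or pb.total == 0:
                continue
            va, vb = pa.vector(), pb.vector()
            if va.std() == 0 or vb.std() == 0:
                continue
            mat[i, j] = float(np.corrcoef(va, vb)[0, 1])
    return pd.DataFrame(mat, index=tools, columns=tools)
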