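"""Call sets, a reference naive caller, and germline-removal filters.

A `CallSet` is one tool's ranked list of variant predictions.  The naive
binomial caller provides a self-contained reference caller so that the
evaluation, attribution, and combination machinery can be exercised end to
end without external tools; `perturb_truth_to_callset` fabricates callers
with controlled sensitivity and false-positive behaviour for combination
experiments.

Two germline-removal procedures are implemented: a binomial test on the
alt-read count in the matched normal (a call is removed when that count is
too high to be sequencing error at rate e), and plain subtraction of the
calls found in the normal sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import binom, norm

from .core import Origin, TruthVariant, Variant
from .genomes import ReferenceGenome
from .pileup import CountPileup

__all__ = [
    "CallRecord",
    "CallSet",
    "naive_somatic_caller",
    "normal_counts_for",
    "binomial_germline_filter",
    "subtract_normal_calls",
    "perturb_truth_to_callset",
]


@dataclass(frozen=True)
class CallRecord:
    variant: Variant
    score: float
    rank: int

    @property
    def key(self) -> tuple[str, int, str]:
        return self.variant.key


def _coord_key(v: Variant) -> tuple[str, int, str]:
    return (v.chrom, v.pos, v.alt)


@dataclass
class CallSet:
    """One tool's ranked predictions.

    Records are stored in rank order (rank 1 first); scores are
    non-increasing along the ranking and ties are broken by ascending
    (chrom, pos, alt) so that ranks are deterministic.
    """

    tool_id: str
    records: list[CallRecord]
    rank_basis: str = "score"
    latents: dict | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        seen: set = set()
        prev_score = None
        for i, rec in enumerate(self.records, start=1):
            if rec.rank != i:
                raise ValueError(f"ranks must be 1..n in order, got {rec.rank} at {i}")
            if prev_score is not None and rec.score > prev_score:
                raise ValueError("scores must be non-increasing along the ranking")
            prev_score = rec.score
            if rec.key in seen:
                raise ValueError(f"duplicate call {rec.key}")
            seen.add(rec.key)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def keys(self) -> set[tuple[str, int, str]]:
        return {r.key for r in self.records}

    def variants(self) -> list[Variant]:
        return [r.variant for r in self.records]

    @classmethod
    def from_scores(
        cls,
        tool_id: str,
        scored: list[tuple[Variant, float]],
        rank_basis: str = "score",
        latents: dict | None = None,
    ) -> "CallSet":
        """Rank by score descending with ascending coordinate tie-break."""
        ordered = sorted(scored, key=lambda vs: (-vs[1], _coord_key(vs[0])))
        records = [
            CallRecord(variant=v, score=float(s), rank=i)
            for i, (v, s) in enumerate(ordered, start=1)
        ]
        return cls(tool_id=tool_id, records=records, rank_basis=rank_basis,
                   latents=latents)

    def subset(self, keep: list[CallRecord], tool_id: str | None = None) -> "CallSet":
        """New CallSet from surviving records, order preserved, ranks redone."""
        records = [
            replace(rec, rank=i) for i, rec in enumerate(keep, start=1)
        ]
        return CallSet(
            tool_id=self.tool_id if tool_id is None else tool_id,
            records=records,
            rank_basis=self.rank_basis,
            latents=self.latents,
        )


def naive_somatic_caller(
    tumor_pileup: CountPileup,
    ref: ReferenceGenome,
    targets: list[tuple[str, int, int]],
    error_rate: float = 0.005,
    min_alt: int = 2,
    alpha: float = 0.05,
    tool_id: str = "naive",
) -> CallSet:
    """Binomial-tail caller over the tumor pileup.

    For every target site and non-reference base with at least ``min_alt``
    supporting reads, the one-sided tail P(X >= k | n, e) under a
    sequencing-error binomial is computed; sites with p < alpha are
    reported with score -log10 p, ranked by score descending.  Germline
    variants are *not* handled here: the caller flags any departure from
    the reference, and germline removal is delegated to
    `binomial_germline_filter` / `subtract_normal_calls`.
    """
    from .reads import seq_to_codes, CODE_BASES

    scored: list[tuple[Variant, float]] = []
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in targets:
        by_chrom.setdefault(chrom, []).append((start, end))
    for chrom, intervals in by_chrom.items():
        counts = tumor_pileup.counts[chrom]
        mask = np.zeros(len(counts), dtype=bool)
        for start, end in intervals:
            mask[start:end] = True
        ref_codes = seq_to_codes(ref.sequences[chrom])
        n = counts.sum(axis=1)
        for b in range(4):
            k = counts[:, b]
            cand = np.flatnonzero(
                mask & (ref_codes != b) & (k >= min_alt) & (n > 0)
            )
            if cand.size == 0:
                continue
            logp = binom.logsf(k[cand] - 1, n[cand], error_rate)
            pvals = np.exp(logp)
            called = pvals < alpha
            for pos0, lp in zip(cand[called], logp[called]):
                score = -lp / np.log(10)
                v = Variant(
                    chrom,
                    int(pos0) + 1,
                    ref.sequences[chrom][pos0],
                    str(CODE_BASES[b], "ascii"),
                )
                scored.append((v, float(score)))
    return CallSet.from_scores(tool_id, scored)


def normal_counts_for(
    calls: CallSet, normal_pileup: CountPileup
) -> dict[tuple[str, int, str], tuple[int, int]]:
    """Per-call (k_N, n_N): alt-read count and depth in the matched normal."""
    from .reads import BASE_CODES

    out = {}
    for rec in calls:
        v = rec.variant
        counts = normal_pileup.counts[v.chrom][v.pos - 1]
        n = int(counts.sum() + normal_pileup.del_depth[v.chrom][v.pos - 1])
        k = int(counts[BASE_CODES[v.alt]]) if v.alt in BASE_CODES else 0
        out[rec.key] = (k, n)
    return out


def binomial_germline_filter(
    calls: CallSet,
    normal_counts: dict[tuple[str, int, str], tuple[int, int]],
    error_rate: float = 0.005,
    alpha: float = 0.05,
) -> CallSet:
    """Remove calls whose normal-sample alt support exceeds sequencing error.

    A call with k_N alt reads out of n_N in the matched normal is removed
    iff the one-sided binomial tail P(X >= k_N | n_N, e) is below alpha:
    that much alt evidence in the normal points to a germline variant
    rather than sequencing error at rate e (default 0.5%, a worst-case
    Illumina error rate).  Survivors keep their order; ranks are
    recomputed.  The filter is idempotent and only ever shrinks the set.
    """
    keep = []
    for rec in calls:
        if rec.key not in normal_counts:
            raise KeyError(f"no normal counts for call {rec.key}")
        k, n = normal_counts[rec.key]
        if k > n:
            raise ValueError(f"k_N={k} exceeds n_N={n} at {rec.key}")
        p = float(binom.sf(k - 1, n, error_rate)) if k > 0 else 1.0
        if p >= alpha:
            keep.append(rec)
    return calls.subset(keep)


def subtract_normal_calls(tumor_calls: CallSet, normal_calls: CallSet) -> CallSet:
    """Drop tumor calls that were also called in the normal sample.

    This is the germline-removal strategy for callers that report both
    variant types: run the caller on the normal alone and subtract its
    calls by (chrom, pos, alt).
    """
    normal_keys = normal_calls.keys()
    keep = [rec for rec in tumor_calls if rec.key not in normal_keys]
    return tumor_calls.subset(keep)


def _sens_prob(sens_by_vaf, vaf: float) -> float:
    if callable(sens_by_vaf):
        return float(sens_by_vaf(vaf))
    if isinstance(sens_by_vaf, dict):
        # keyed by bin lower bound on a 0.05 grid; vaf=1.0 joins the last bin
        low = min(int(vaf / 0.05), 19) * 0.05
        low = round(low, 2)
        if low in sens_by_vaf:
            return float(sens_by_vaf[low])
        raise KeyError(f"no sensitivity given for VAF bin starting at {low}")
    return float(sens_by_vaf)


def perturb_truth_to_callset(
    truth: list[TruthVariant],
    sens_by_vaf,
    n_fp: int = 0,
    score_noise_sd: float = 0.5,
    rho: float | None = None,
    reference: CallSet | None = None,
    fp_targets: list[tuple[str, int, int]] | None = None,
    ref_genome: ReferenceGenome | None = None,
    seed: int = 0,
    tool_id: str = "perturbed",
) -> CallSet:
    """Fabricate a caller by degrading the truth set.

    Each somatic truth SNV is detected independently with the probability
    of its VAF bin (``sens_by_vaf`` may be a flat probability, a mapping
    from bin lower bound to probability, or a callable).  Detection runs
    through a latent standard normal z: the variant is detected iff
    z < Phi^{-1}(p).  With ``rho`` set, z is coupled to the latent of a
    ``reference`` call set built by this same function via a Gaussian
    copula, so rho=1 with matching sensitivities reproduces the reference
    detections exactly.  ``n_fp`` false calls are added at random
    non-truth positions; scores are a latent quality plus Gaussian noise,
    and the result is ranked deterministically.
    """
    rng = np.random.default_rng(seed)
    if rho is not None:
        if reference is None or reference.latents is None:
            raise ValueError(
                "coupling rho requires a reference CallSet produced by "
                "perturb_truth_to_callset (with stored latents)"
            )
        if not -1.0 <= rho <= 1.0:
            raise ValueError("rho must be in [-1, 1]")

    somatic = [tv for tv in truth if tv.origin is Origin.SOMATIC
               and tv.variant.is_snv()]
    scored: list[tuple[Variant, float]] = []
    latents: dict = {}
    for tv in somatic:
        if tv.true_vaf is None:
            raise ValueError("truth variants need true_vaf set")
        p = _sens_prob(sens_by_vaf, tv.true_vaf)
        eps = rng.standard_normal()
        if rho is not None:
            z_ref = reference.latents.get(tv.variant.key)
            if z_ref is None:
                z_ref = rng.standard_normal()
            z = rho * z_ref + np.sqrt(max(0.0, 1.0 - rho * rho)) * eps
        else:
            z = eps
        latents[tv.variant.key] = float(z)
        threshold = norm.ppf(np.clip(p, 1e-12, 1 - 1e-12))
        if p >= 1.0 or z < threshold:
            margin = max(threshold - z, 0.0)
            score = 1.0 + margin + rng.normal(0.0, score_noise_sd)
            scored.append((tv.variant, float(score)))

    taken = {tv.variant.key for tv in truth}
    taken |= {(v.chrom, v.pos, a) for v, _ in scored for a in "ACGT"}
    if n_fp > 0:
        if fp_targets is None:
            by_chrom: dict[str, list[int]] = {}
            for tv in truth:
                by_chrom.setdefault(tv.variant.chrom, []).append(tv.variant.pos)
            fp_targets = [
                (c, min(ps) - 1, max(ps)) for c, ps in by_chrom.items()
            ]
        spans = [(c, s, e) for c, s, e in fp_targets if e > s]
        lengths = np.array([e - s for _, s, e in spans])
        offsets = np.concatenate([[0], np.cumsum(lengths)])
        placed = 0
        tries = 0
        while placed < n_fp and tries < 1000 * n_fp:
            tries += 1
            flat = int(rng.integers(0, offsets[-1]))
            ti = int(np.searchsorted(offsets, flat, side="right")) - 1
            chrom, start, _ = spans[ti]
            pos = start + (flat - offsets[ti]) + 1
            if ref_genome is not None:
                refb = ref_genome.sequences[chrom][pos - 1]
                if refb == "N":
                    continue
            else:
                refb = "A"
            alt = "ACGT"[int(rng.integers(0, 4))]
            if alt == refb:
                continue
            key = (chrom, pos, alt)
            if key in taken or any((chrom, pos, a) in taken for a in "ACGT"):
                continue
            taken.add(key)
            score = rng.uniform(0.0, 1.5)
            scored.append((Variant(chrom, pos, refb, alt), float(score)))
            placed += 1
        if placed < n_fp:
            raise RuntimeError("could not place the requested false positives")
    return CallSet.from_scores(tool_id, scored, latents=latents)
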