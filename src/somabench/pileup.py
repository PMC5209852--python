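"""Pileup construction: per-site read evidence for calling and attribution.

Two representations are used.  `CountPileup` holds dense per-position base
counts over whole chromosomes and feeds the naive caller; it is built
vectorised from in-memory read pools.  `PileupColumn` carries full
per-read detail (base, base quality, MAPQ, truth origin) at selected sites
and feeds error-source classification; it can be built either from a read
pool with its source haplotypes or from a SAM/BAM file whose read names
follow the ``sample|clone|hap|refstart|strand|serial`` grammar.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genomes import HaplotypeGenome
from .reads import ReadPool, ReadRecord, CODE_BASES

__all__ = ["CountPileup", "PileupRead", "PileupColumn", "count_pileup",
           "pool_pileup", "build_pileup"]


@dataclass
class CountPileup:
    """Dense per-position base counts for one sample.

    ``counts[chrom]`` is an (L, 4) array over A/C/G/T; ``del_depth`` counts
    deletion-spanning reads, which contribute to total depth but no base.
    """

    counts: dict[str, np.ndarray]
    del_depth: dict[str, np.ndarray]

    def depth(self, chrom: str) -> np.ndarray:
        return self.counts[chrom].sum(axis=1) + self.del_depth[chrom]

    def site(self, chrom: str, pos: int) -> tuple[int, dict[str, int]]:
        """(total depth, per-base counts) at a 1-based position."""
        c = self.counts[chrom][pos - 1]
        bases = {str(CODE_BASES[i], "ascii"): int(c[i]) for i in range(4)}
        return int(c.sum() + self.del_depth[chrom][pos - 1]), bases


@dataclass(frozen=True)
class PileupRead:
    """One read's contribution to a pileup column.

    ``base`` is None for deletion-spanning reads.  ``origin`` is the parsed
    read-name tuple (sample, clone, hap, ref_start, strand, serial) when
    available, else None.
    """

    base: str | None
    baseq: int
    mapq: int
    origin: tuple[str, int, int, int, str, int] | None = None

    @property
    def clone(self) -> int | None:
        return self.origin[1] if self.origin else None


@dataclass
class PileupColumn:
    """All read evidence at one reference site for one sample."""

    chrom: str
    pos: int  # 1-based
    reads: list[PileupRead] = field(default_factory=list)

    @property
    def depth(self) -> int:
        return len(self.reads)

    @property
    def base_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in self.reads:
            if r.base is not None:
                out[r.base] = out.get(r.base, 0) + 1
        return out

    def alt_reads(self, alt: str) -> list[PileupRead]:
        return [r for r in self.reads if r.base == alt]

    def max_mapq(self, alt: str | None = None) -> int | None:
        reads = self.reads if alt is None else self.alt_reads(alt)
        return max((r.mapq for r in reads), default=None)

    def depth_at_mapq(self, min_mapq: int) -> int:
        return sum(1 for r in self.reads if r.mapq >= min_mapq)


def _block_arrays(genome: HaplotypeGenome, chrom: str):
    blocks = genome.blocks[chrom]
    starts = np.array([b.hap_start for b in blocks], dtype=np.int64)
    return blocks, starts


def count_pileup(
    pool: ReadPool,
    genomes: dict[tuple[int, int], HaplotypeGenome],
    ref_lengths: dict[str, int],
) -> CountPileup:
    """Accumulate base counts of a read pool at its true reference positions.

    Reads whose span lies within a single liftover match block (the vast
    majority) are accumulated vectorised; reads crossing indel breakpoints
    are walked segment by segment, with deletion gaps counted into
    ``del_depth``.
    """
    counts = {c: np.zeros((ln, 4), dtype=np.int32) for c, ln in ref_lengths.items()}
    deld = {c: np.zeros(ln, dtype=np.int32) for c, ln in ref_lengths.items()}
    fwd = pool.forward_seqs()
    L = pool.read_len

    group_key = (
        pool.chrom_idx.astype(np.int64) << 32
    ) | (pool.clone.astype(np.int64) << 8) | pool.hap.astype(np.int64)
    order = np.argsort(group_key, kind="stable")
    boundaries = np.flatnonzero(np.diff(group_key[order])) + 1
    for grp in np.split(order, boundaries):
        ci = int(pool.chrom_idx[grp[0]])
        chrom = pool.chroms[ci]
        if chrom not in ref_lengths:
            continue
        genome = genomes[(int(pool.clone[grp[0]]), int(pool.hap[grp[0]]))]
        blocks, starts = _block_arrays(genome, chrom)
        hs = pool.hap_start[grp]
        bi_first = np.searchsorted(starts, hs, side="right") - 1
        bi_last = np.searchsorted(starts, hs + L - 1, side="right") - 1
        simple = (bi_first == bi_last) & np.array(
            [not blocks[j].insertion for j in bi_first]
        )

        sg = grp[simple]
        if sg.size:
            offs = np.array(
                [blocks[j].ref_start - blocks[j].hap_start for j in bi_first[simple]],
                dtype=np.int64,
            )
            ref0 = pool.hap_start[sg] + offs
            positions = ref0[:, None] + np.arange(L)[None, :]
            codes = fwd[sg]
            valid = codes < 4
            flat = positions[valid] * 4 + codes[valid]
            np.add.at(counts[chrom].reshape(-1), flat, 1)

        for i in grp[~simple]:
            _accumulate_complex(
                counts[chrom], deld[chrom], genome, chrom,
                int(pool.hap_start[i]), fwd[i],
            )
    return CountPileup(counts=counts, del_depth=deld)


def _accumulate_complex(counts, deld, genome, chrom, hap_s, fwd_codes):
    hap_e = hap_s + len(fwd_codes)
    prev_ref_end = None
    for b in genome.blocks_in(chrom, hap_s, hap_e):
        lo, hi = max(hap_s, b.hap_start), min(hap_e, b.hap_end)
        if b.insertion:
            continue  # inserted bases have no reference position
        ref_lo = b.lift(lo)
        if prev_ref_end is not None and ref_lo > prev_ref_end:
            deld[prev_ref_end:ref_lo] += 1
        seg = fwd_codes[lo - hap_s : hi - hap_s]
        pos = np.arange(ref_lo, ref_lo + (hi - lo))
        valid = seg < 4
        np.add.at(counts.reshape(-1), pos[valid] * 4 + seg[valid], 1)
        prev_ref_end = ref_lo + (hi - lo)


def pool_pileup(
    pool: ReadPool,
    genomes: dict[tuple[int, int], HaplotypeGenome],
    sites: list[tuple[str, int]],
    mapq: int = 60,
) -> dict[tuple[str, int], PileupColumn]:
    """Detailed pileup columns at selected sites, straight from a read pool.

    Equivalent to emitting truth alignments and piling them up, but
    without the SAM round trip.  ``sites`` are (chrom, 1-based pos).
    """
    columns = {s: PileupColumn(chrom=s[0], pos=s[1]) for s in sites}
    by_chrom: dict[str, list[int]] = {}
    for chrom, pos in sites:
        by_chrom.setdefault(chrom, []).append(pos)
    fwd = pool.forward_seqs()
    L = pool.read_len
    max_span = L + 64  # reads never consume more reference than this

    order = np.argsort(pool.ref_start, kind="stable")
    ref_sorted = pool.ref_start[order]
    for chrom, positions in by_chrom.items():
        ci = pool.chroms.index(chrom)
        for pos1 in positions:
            p0 = pos1 - 1
            lo = np.searchsorted(ref_sorted, p0 - max_span, side="left")
            hi = np.searchsorted(ref_sorted, p0, side="right")
            for i in order[lo:hi]:
                if pool.chrom_idx[i] != ci:
                    continue
                genome = genomes[(int(pool.clone[i]), int(pool.hap[i]))]
                hap_s = int(pool.hap_start[i])
                entry = _base_at(genome, chrom, hap_s, hap_s + L, fwd[i], p0)
                if entry is None:
                    continue
                base_code, seq_idx = entry
                if base_code is None:
                    base, bq = None, 0
                else:
                    base = str(CODE_BASES[base_code], "ascii")
                    cycle = (L - 1 - seq_idx) if pool.minus[i] else seq_idx
                    bq = int(pool.quals[cycle])
                rec = pool.record(i)
                columns[(chrom, pos1)].reads.append(
                    PileupRead(
                        base=base,
                        baseq=bq,
                        mapq=mapq,
                        origin=(
                            rec.sample, rec.clone, rec.hap,
                            rec.ref_start, rec.strand, rec.serial,
                        ),
                    )
                )
    return columns


def _base_at(genome, chrom, hap_s, hap_e, fwd_codes, ref_pos):
    """Base carried by one read at a reference position, or None entries.

    Returns (base_code, seq_index), (None, None) for a deletion span, or
    None when the read does not cover the position.
    """
    prev_ref_end = None
    for b in genome.blocks_in(chrom, hap_s, hap_e):
        lo, hi = max(hap_s, b.hap_start), min(hap_e, b.hap_end)
        if b.insertion:
            continue
        ref_lo = b.lift(lo)
        if prev_ref_end is not None and prev_ref_end <= ref_pos < ref_lo:
            return (None, None)
        if ref_lo <= ref_pos < ref_lo + (hi - lo):
            hap_pos = lo + (ref_pos - ref_lo)
            idx = hap_pos - hap_s
            return (int(fwd_codes[idx]), idx)
        prev_ref_end = ref_lo + (hi - lo)
    return None


def build_pileup(
    alignments,
    sites: list[tuple[str, int]],
    min_baseq: int = 0,
) -> dict[tuple[str, int], PileupColumn]:
    """Pileup columns at selected sites from SAM/BAM alignments.

    ``alignments`` may be a path to a SAM/BAM file or an iterable of
    pysam.AlignedSegment.  Deletion-spanning reads count toward depth but
    contribute no base; bases below ``min_baseq`` are dropped entirely.
    Truth origins are parsed from read names where they follow the
    ``sample|clone|hap|refstart|strand|serial`` grammar.
    """
    import pysam

    if isinstance(alignments, (str,)) or hasattr(alignments, "__fspath__"):
        with pysam.AlignmentFile(str(alignments), "r", check_sq=True) as fh:
            if not fh.header.get("SQ"):
                raise ValueError("alignment file lacks @SQ header lines")
            return build_pileup(list(fh), sites, min_baseq=min_baseq)

    columns = {s: PileupColumn(chrom=s[0], pos=s[1]) for s in sites}
    wanted: dict[str, dict[int, tuple[str, int]]] = {}
    for chrom, pos1 in sites:
        wanted.setdefault(chrom, {})[pos1 - 1] = (chrom, pos1)
    for aln in alignments:
        if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
            continue
        chrom_sites = wanted.get(aln.reference_name)
        if not chrom_sites:
            continue
        if aln.reference_end is None:
            continue
        overlapping = [
            p for p in chrom_sites if aln.reference_start <= p < aln.reference_end
        ]
        if not overlapping:
            continue
        try:
            origin = ReadRecord.parse_name(aln.query_name)
        except (ValueError, AttributeError):
            origin = None
        seq = aln.query_sequence or ""
        quals = aln.query_qualities
        covered: dict[int, tuple[int | None, int]] = {}
        for qpos, rpos in aln.get_aligned_pairs(matches_only=False):
            if rpos is None or rpos not in chrom_sites:
                continue
            covered[rpos] = (qpos, 0)
        for rpos in overlapping:
            if rpos not in covered:
                continue  # site inside a skipped region
            qpos, _ = covered[rpos]
            if qpos is None:  # deletion spanning the site
                base, bq = None, 0
            else:
                base = seq[qpos].upper()
                bq = int(quals[qpos]) if quals is not None else 0
                if bq < min_baseq:
                    continue
            columns[chrom_sites[rpos]].reads.append(
                PileupRead(base=base, baseq=bq, mapq=aln.mapping_quality,
                           origin=origin)
            )
    return columns
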