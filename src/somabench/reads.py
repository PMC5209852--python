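"""Exome-capture-like read simulation with an Illumina-like error model.

Reads are sampled uniformly from padded capture-target intervals of each
haplotype genome (the padding emulates capture shoulders), with per-cycle
substitution errors following a linear ramp e(i) = e0 + slope * i and base
qualities Q(i) = round(-10 log10 e(i)).  Clone read pools are mixed into a
tumor sample by a multinomial allocation over ((1-kappa) * w_1, ...,
(1-kappa) * w_K, kappa), sampling without replacement within each pool.

Every read records its origin (sample, clone, haplotype, true reference
start, strand, serial) in its name, so that truth alignments can be
emitted without an external aligner and so that error attribution can
reason about where a read *should* have aligned.

Read pools are stored as column arrays (one row per read) rather than
per-read objects; at hundreds of thousands of reads this keeps mixing and
pileup construction vectorised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .genomes import HaplotypeGenome

__all__ = [
    "ErrorModel",
    "ReadRecord",
    "ReadPool",
    "simulate_reads",
    "mix_tumor_pool",
    "emit_truth_alignments",
]

BASE_CODES = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
CODE_BASES = np.frombuffer(b"ACGTN", dtype="S1")
_COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.uint8)

# lookup table: ASCII byte -> base code
_ASCII_TO_CODE = np.full(256, 4, dtype=np.uint8)
for _b, _c in BASE_CODES.items():
    _ASCII_TO_CODE[ord(_b)] = _c
    _ASCII_TO_CODE[ord(_b.lower())] = _c


def seq_to_codes(seq: str) -> np.ndarray:
    return _ASCII_TO_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def codes_to_seq(codes: np.ndarray) -> str:
    return CODE_BASES[codes].tobytes().decode("ascii")


@dataclass(frozen=True)
class ErrorModel:
    """Linear per-cycle substitution error ramp.

    e(i) = e0 + slope * i for cycle i in [0, read_len).  With the defaults
    the error rate rises from 0.1% at the first cycle to 1% at the last,
    a coarse stand-in for the quality decay of Illumina reads.  slope may
    be given explicitly; otherwise it is set so that e(read_len-1) = e_last.
    """

    e0: float = 0.001
    e_last: float = 0.01
    slope: float | None = None

    def rates(self, read_len: int) -> np.ndarray:
        if self.slope is not None:
            slope = self.slope
        elif read_len > 1:
            slope = (self.e_last - self.e0) / (read_len - 1)
        else:
            slope = 0.0
        e = self.e0 + slope * np.arange(read_len)
        if np.any(e < 0) or np.any(e >= 0.75):
            raise ValueError("per-cycle error rates must lie in [0, 0.75)")
        return e

    def qualities(self, read_len: int) -> np.ndarray:
        """Phred qualities consistent with the per-cycle error rates."""
        e = np.maximum(self.rates(read_len), 1e-9)
        return np.round(-10.0 * np.log10(e)).astype(np.uint8)

    @classmethod
    def error_free(cls) -> "ErrorModel":
        return cls(e0=0.0, e_last=0.0, slope=0.0)


@dataclass(frozen=True)
class ReadRecord:
    """One simulated read, with a name that losslessly encodes its origin."""

    sample: str
    clone: int  # 0 = normal genome
    hap: int  # haplotype index within the diploid genome (0 or 1)
    hap_start: int  # 0-based start on the source haplotype
    ref_start: int  # 0-based true reference start (lifted)
    strand: str  # '+' or '-'
    serial: int
    sequence: str  # as sequenced (reverse-complemented for '-' reads)
    qualities: np.ndarray  # phred scores, sequencing order

    @property
    def name(self) -> str:
        return (
            f"{self.sample}|{self.clone}|{self.hap}|{self.ref_start}|"
            f"{self.strand}|{self.serial}"
        )

    @staticmethod
    def parse_name(name: str) -> tuple[str, int, int, int, str, int]:
        sample, clone, hap, ref_start, strand, serial = name.split("|")
        if strand not in "+-":
            raise ValueError(f"bad strand in read name {name!r}")
        return sample, int(clone), int(hap), int(ref_start), strand, int(serial)


@dataclass
class ReadPool:
    """Column-oriented pool of simulated reads over one chromosome set.

    All reads share a length; sequences are stored in sequencing
    orientation as an (n, read_len) base-code matrix.  ``chrom_idx``
    indexes into ``chroms``.
    """

    sample: str
    chroms: list[str]
    read_len: int
    chrom_idx: np.ndarray  # (n,) int32
    clone: np.ndarray  # (n,) int16; 0 = normal
    hap: np.ndarray  # (n,) int8
    hap_start: np.ndarray  # (n,) int64, 0-based on source haplotype
    ref_start: np.ndarray  # (n,) int64, 0-based on reference
    minus: np.ndarray  # (n,) bool
    serial: np.ndarray  # (n,) int64
    seqs: np.ndarray  # (n, read_len) uint8 base codes, sequencing order
    quals: np.ndarray  # (read_len,) uint8 shared per-cycle qualities

    def __len__(self) -> int:
        return len(self.chrom_idx)

    def record(self, i: int) -> ReadRecord:
        return ReadRecord(
            sample=self.sample,
            clone=int(self.clone[i]),
            hap=int(self.hap[i]),
            hap_start=int(self.hap_start[i]),
            ref_start=int(self.ref_start[i]),
            strand="-" if self.minus[i] else "+",
            serial=int(self.serial[i]),
            sequence=codes_to_seq(self.seqs[i]),
            qualities=self.quals.copy(),
        )

    def forward_seqs(self) -> np.ndarray:
        """Sequences in reference (haplotype-forward) orientation."""
        out = self.seqs.copy()
        m = self.minus
        out[m] = _COMPLEMENT[out[m][:, ::-1]]
        return out

    def take(self, idx: np.ndarray, sample: str | None = None) -> "ReadPool":
        return ReadPool(
            sample=self.sample if sample is None else sample,
            chroms=self.chroms,
            read_len=self.read_len,
            chrom_idx=self.chrom_idx[idx],
            clone=self.clone[idx],
            hap=self.hap[idx],
            hap_start=self.hap_start[idx],
            ref_start=self.ref_start[idx],
            minus=self.minus[idx],
            serial=self.serial[idx],
            seqs=self.seqs[idx],
            quals=self.quals,
        )

    @staticmethod
    def concatenate(pools: list["ReadPool"], sample: str) -> "ReadPool":
        first = pools[0]
        if any(p.read_len != first.read_len for p in pools):
            raise ValueError("pools must share a read length")
        if any(p.chroms != first.chroms for p in pools):
            raise ValueError("pools must share a chromosome list")
        return ReadPool(
            sample=sample,
            chroms=first.chroms,
            read_len=first.read_len,
            chrom_idx=np.concatenate([p.chrom_idx for p in pools]),
            clone=np.concatenate([p.clone for p in pools]),
            hap=np.concatenate([p.hap for p in pools]),
            hap_start=np.concatenate([p.hap_start for p in pools]),
            ref_start=np.concatenate([p.ref_start for p in pools]),
            minus=np.concatenate([p.minus for p in pools]),
            serial=np.concatenate([p.serial for p in pools]),
            seqs=np.concatenate([p.seqs for p in pools]),
            quals=first.quals,
        )

    def to_fastq(self, path) -> None:
        qual_str = "".join(chr(q + 33) for q in self.quals)
        with open(path, "w") as fh:
            for i in range(len(self)):
                rec = self.record(i)
                fh.write(f"@{rec.name}\n{rec.sequence}\n+\n{qual_str}\n")


def _ref_to_hap(genome: HaplotypeGenome, chrom: str, ref_pos: int) -> int:
    """Smallest haplotype position whose lift is >= ref_pos."""
    for b in genome.blocks[chrom]:
        if b.insertion:
            continue
        ref_end = b.ref_start + (b.hap_end - b.hap_start)
        if ref_end > ref_pos:
            return b.hap_start + max(0, ref_pos - b.ref_start)
    return len(genome.sequences[chrom])


def simulate_reads(
    genome: HaplotypeGenome,
    targets: list[tuple[str, int, int]],
    mean_depth: float,
    read_len: int = 100,
    error_model: ErrorModel | None = None,
    padding: int = 100,
    sample: str = "pool",
    clone: int = 0,
    hap: int = 0,
    seed: int = 0,
    n_reads: int | None = None,
) -> ReadPool:
    """Sample single-end reads uniformly over padded capture targets.

    The read count is mean_depth * target_bases / read_len (rounded),
    where target_bases counts the unpadded target intervals; fragment
    starts are uniform over the padded intervals (default 100 bp padding,
    emulating capture shoulders).  Targets are given in reference
    coordinates and mapped onto the haplotype via its liftover.
    """
    if error_model is None:
        error_model = ErrorModel()
    if not targets:
        raise ValueError("no target intervals given")
    rng = np.random.default_rng(seed)
    chroms = sorted(genome.sequences)
    chrom_index = {c: i for i, c in enumerate(chroms)}

    # map padded ref targets to haplotype intervals, clamped for read_len
    intervals = []  # (chrom_idx, hap_lo, hap_hi)
    target_bases = 0
    for chrom, start, end in targets:
        if chrom not in genome.sequences:
            raise ValueError(f"target on unknown chromosome {chrom!r}")
        target_bases += end - start
        hap_len = len(genome.sequences[chrom])
        lo = _ref_to_hap(genome, chrom, max(0, start - padding))
        hi = _ref_to_hap(genome, chrom, end + padding)
        hi = min(hi, hap_len - read_len + 1)
        if hi > lo:
            intervals.append((chrom_index[chrom], lo, hi))
    if not intervals:
        raise ValueError("targets too small for the requested read length")

    if n_reads is None:
        n_reads = int(round(mean_depth * target_bases / read_len))
    lengths = np.array([hi - lo for _, lo, hi in intervals], dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    flat = rng.integers(0, offsets[-1], size=n_reads)
    which = np.searchsorted(offsets, flat, side="right") - 1

    chrom_idx = np.empty(n_reads, dtype=np.int32)
    hap_start = np.empty(n_reads, dtype=np.int64)
    for k, (ci, lo, _hi) in enumerate(intervals):
        m = which == k
        chrom_idx[m] = ci
        hap_start[m] = lo + (flat[m] - offsets[k])

    minus = rng.random(n_reads) < 0.5
    seqs = np.empty((n_reads, read_len), dtype=np.uint8)
    ref_start = np.empty(n_reads, dtype=np.int64)
    for ci, chrom in enumerate(chroms):
        m = np.flatnonzero(chrom_idx == ci)
        if m.size == 0:
            continue
        hap_codes = seq_to_codes(genome.sequences[chrom])
        idx = hap_start[m][:, None] + np.arange(read_len)[None, :]
        seqs[m] = hap_codes[idx]
        # true reference start = lift of the leftmost haplotype base
        blocks = genome.blocks[chrom]
        block_starts = np.array([b.hap_start for b in blocks])
        bi = np.searchsorted(block_starts, hap_start[m], side="right") - 1
        ref_start[m] = [blocks[j].lift(int(p)) for j, p in zip(bi, hap_start[m])]

    # orient minus-strand reads, then apply per-cycle sequencing errors
    seqs[minus] = _COMPLEMENT[seqs[minus][:, ::-1]]
    rates = error_model.rates(read_len)
    if np.any(rates > 0):
        err = rng.random((n_reads, read_len)) < rates[None, :]
        shift = rng.integers(1, 4, size=int(err.sum()), dtype=np.uint8)
        flat_seqs = seqs.reshape(-1)
        where = np.flatnonzero(err.reshape(-1))
        flat_seqs[where] = (flat_seqs[where] + shift) % 4

    return ReadPool(
        sample=sample,
        chroms=chroms,
        read_len=read_len,
        chrom_idx=chrom_idx,
        clone=np.full(n_reads, clone, dtype=np.int16),
        hap=np.full(n_reads, hap, dtype=np.int8),
        hap_start=hap_start,
        ref_start=ref_start,
        minus=minus,
        serial=np.arange(n_reads, dtype=np.int64),
        seqs=seqs,
        quals=error_model.qualities(read_len),
    )


def simulate_diploid_reads(
    hap0: HaplotypeGenome,
    hap1: HaplotypeGenome,
    targets,
    mean_depth: float,
    clone: int,
    sample: str,
    seed: int,
    **kwargs,
) -> ReadPool:
    """Split the requested depth evenly over the two haplotypes of a genome."""
    pools = []
    for h, genome in enumerate((hap0, hap1)):
        pools.append(
            simulate_reads(
                genome,
                targets,
                mean_depth / 2.0,
                sample=sample,
                clone=clone,
                hap=h,
                seed=seed + h,
                **kwargs,
            )
        )
    return ReadPool.concatenate(pools, sample=sample)


def mix_tumor_pool(
    clone_pools: dict[int, ReadPool],
    weights,
    normal_pool: ReadPool,
    kappa: float,
    total_reads: int,
    seed: int = 0,
) -> ReadPool:
    """Mix clone pools and normal contamination into one tumor read pool.

    Read counts per source are multinomial with probabilities
    ((1-kappa) * w_1, ..., (1-kappa) * w_K, kappa); reads are then drawn
    without replacement within each pool and the result is shuffled
    deterministically.
    """
    if not 0.0 <= kappa <= 1.0:
        raise ValueError("kappa must be in [0, 1]")
    rng = np.random.default_rng(seed)
    clones = sorted(clone_pools)
    probs = np.array([(1.0 - kappa) * weights.weights[c] for c in clones] + [kappa])
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("clone weights must sum to 1")
    counts = rng.multinomial(total_reads, probs)
    sources = [clone_pools[c] for c in clones] + [normal_pool]
    parts = []
    for pool, k in zip(sources, counts):
        if k > len(pool):
            raise ValueError(
                f"pool {pool.sample!r} has {len(pool)} reads, {k} requested"
            )
        idx = rng.choice(len(pool), size=k, replace=False)
        parts.append(pool.take(np.sort(idx)))
    mixed = ReadPool.concatenate(parts, sample="tumor")
    order = rng.permutation(len(mixed))
    return mixed.take(order, sample="tumor")


def _read_cigar(
    genome: HaplotypeGenome, chrom: str, hap_start: int, hap_end: int
) -> tuple[int, list[tuple[str, int]]]:
    """True alignment (0-based ref pos, CIGAR ops) for a haplotype interval.

    Match blocks become M, insertion blocks I, and gaps between consecutive
    match blocks D; inserted bases at either read edge are soft-clipped.
    """
    ops: list[tuple[str, int]] = []
    pos = None
    prev_ref_end = None
    for b in genome.blocks_in(chrom, hap_start, hap_end):
        lo, hi = max(hap_start, b.hap_start), min(hap_end, b.hap_end)
        if b.insertion:
            ops.append(("I", hi - lo))
            continue
        ref_lo = b.lift(lo)
        if pos is None:
            pos = ref_lo
        elif prev_ref_end is not None and ref_lo > prev_ref_end:
            ops.append(("D", ref_lo - prev_ref_end))
        ops.append(("M", hi - lo))
        prev_ref_end = ref_lo + (hi - lo)
    if pos is None:
        raise ValueError("read lies entirely within an insertion")
    while ops and ops[0][0] != "M":
        op, n = ops.pop(0)
        if op == "I":
            ops.insert(0, ("S", n))
            break
    while ops and ops[-1][0] in ("I", "D"):
        op, n = ops.pop()
        if op == "I":
            ops.append(("S", n))
            break
    merged: list[tuple[str, int]] = []
    for op, n in ops:
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + n)
        else:
            merged.append((op, n))
    return pos, merged


def emit_truth_alignments(
    pool: ReadPool,
    genomes: dict[tuple[int, int], HaplotypeGenome],
    ref_lengths: dict[str, int],
    path=None,
):
    """Write (or return) the true alignment of every read in the pool.

    One primary alignment per read at its true reference position with
    MAPQ 60; the CIGAR reflects the indel structure of the source
    haplotype segment.  Minus-strand reads carry the reverse flag with
    SEQ stored in reference orientation, per SAM convention.  Records are
    coordinate-sorted.  With ``path`` the records are written as SAM;
    otherwise a list of pysam.AlignedSegment is returned.
    """
    import pysam

    chrom_names = [c for c in pool.chroms if c in ref_lengths]
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": c, "LN": ref_lengths[c]} for c in chrom_names],
        }
    )
    fwd = pool.forward_seqs()
    records = []
    for i in range(len(pool)):
        chrom = pool.chroms[pool.chrom_idx[i]]
        key = (int(pool.clone[i]), int(pool.hap[i]))
        genome = genomes[key]
        hap_s = int(pool.hap_start[i])
        pos, cigar = _read_cigar(genome, chrom, hap_s, hap_s + pool.read_len)
        a = pysam.AlignedSegment(header)
        rec = pool.record(i)
        a.query_name = rec.name
        a.flag = 16 if pool.minus[i] else 0
        a.reference_id = chrom_names.index(chrom)
        a.reference_start = pos
        a.mapping_quality = 60
        a.cigarstring = "".join(f"{n}{op}" for op, n in cigar)
        a.query_sequence = codes_to_seq(fwd[i])
        q = pool.quals[::-1] if pool.minus[i] else pool.quals
        a.query_qualities = pysam.qualitystring_to_array(
            "".join(chr(v + 33) for v in q)
        )
        records.append(a)
    records.sort(key=lambda a: (a.reference_id, a.reference_start))
    if path is None:
        return records
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for a in records:
            out.write(a)
    return None
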