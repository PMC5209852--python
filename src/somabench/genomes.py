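"""Reference genomes, random variant generation, and haplotype construction.

Clone and normal genomes are built by applying phased variants to a
reference FASTA.  Because indels shift coordinates, every haplotype carries
a piecewise liftover map back to the reference, which downstream code uses
to place simulated reads at their true reference positions.

Coordinate conventions: VCF-style variants are 1-based and left-anchored;
all internal arithmetic and BED intervals are 0-based half-open.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np

from .core import Origin, Variant

__all__ = [
    "ReferenceGenome",
    "HaplotypeGenome",
    "generate_random_variants",
    "apply_variants",
    "lift_to_reference",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class ReferenceGenome:
    """In-memory reference: mapping of sequence name to uppercase string."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            bad = set(seq) - set("ACGTN")
            if bad:
                raise ValueError(f"{name}: unexpected characters {sorted(bad)}")

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    @classmethod
    def from_fasta(cls, path) -> "ReferenceGenome":
        import pyfaidx

        fa = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for name, seq in self.sequences.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")


@dataclass(frozen=True)
class _Block:
    """One liftover segment in haplotype coordinates (0-based half-open).

    Match blocks advance the reference in lockstep; insertion blocks hold
    haplotype-only bases that all map to ``ref_start``, the last reference
    base preceding the insertion (left-anchored VCF convention).
    """

    hap_start: int
    hap_end: int
    ref_start: int
    insertion: bool = False

    def lift(self, hap_pos: int) -> int:
        if self.insertion:
            return self.ref_start
        return self.ref_start + (hap_pos - self.hap_start)


@dataclass
class HaplotypeGenome:
    """A variant-bearing genome plus its liftover map to the reference."""

    sequences: dict[str, str]
    blocks: dict[str, list[_Block]] = field(default_factory=dict)

    def lift(self, chrom: str, hap_pos: int) -> int:
        """Map a 0-based haplotype position to its 0-based reference position."""
        blocks = self.blocks[chrom]
        seq_len = len(self.sequences[chrom])
        if not 0 <= hap_pos < seq_len:
            raise IndexError(f"{chrom}: haplotype position {hap_pos} out of range")
        idx = bisect_right(blocks, hap_pos, key=lambda b: b.hap_start) - 1
        return blocks[idx].lift(hap_pos)

    def blocks_in(self, chrom: str, hap_start: int, hap_end: int) -> list[_Block]:
        """Liftover blocks overlapping a haplotype interval, in order."""
        return [
            b
            for b in self.blocks[chrom]
            if b.hap_end > hap_start and b.hap_start < hap_end
        ]


def lift_to_reference(hap: HaplotypeGenome, chrom: str, hap_pos: int) -> int:
    """1-based haplotype position -> 1-based reference position.

    Positions inside an insertion map to the insertion's reference anchor
    base.  The map is monotone non-decreasing by construction.
    """
    return hap.lift(chrom, hap_pos - 1) + 1


def apply_variants(
    ref: ReferenceGenome, phased_variants: list[Variant]
) -> HaplotypeGenome:
    """Apply sorted, non-overlapping variants to the reference.

    Substitutions (SNV/MNV) replace bases in place; indels must be
    left-anchored (first ref base equals first alt base) and split the
    liftover map at their breakpoints.  An empty variant list yields the
    identity map.
    """
    per_chrom: dict[str, list[Variant]] = {}
    for v in phased_variants:
        if v.chrom not in ref.sequences:
            raise ValueError(f"unknown chromosome {v.chrom!r}")
        per_chrom.setdefault(v.chrom, []).append(v)

    sequences: dict[str, str] = {}
    blocks: dict[str, list[_Block]] = {}
    for chrom, refseq in ref.sequences.items():
        variants = sorted(per_chrom.get(chrom, []), key=lambda v: v.pos)
        prev_end = -1
        for v in variants:
            s, e = v.ref_span
            if s < prev_end:
                raise ValueError(f"overlapping variants at {chrom}:{v.pos}")
            if e > len(refseq):
                raise ValueError(f"variant at {chrom}:{v.pos} exceeds chromosome")
            if refseq[s:e] != v.ref:
                raise ValueError(
                    f"ref mismatch at {chrom}:{v.pos}: expected {v.ref!r}, "
                    f"reference has {refseq[s:e]!r}"
                )
            prev_end = e

        parts: list[str] = []
        chrom_blocks: list[_Block] = []
        ref_cursor = 0  # next unconsumed reference base
        hap_cursor = 0  # next haplotype base to emit
        block_hap = 0  # start of the open match block (haplotype coords)
        block_ref = 0  # start of the open match block (reference coords)

        def close_match_block(up_to_hap: int) -> None:
            nonlocal block_hap, block_ref
            if up_to_hap > block_hap:
                chrom_blocks.append(_Block(block_hap, up_to_hap, block_ref))

        for v in variants:
            s, e = v.ref_span
            if len(v.ref) == len(v.alt):
                # in-place substitution: the match block continues unbroken
                parts.append(refseq[ref_cursor:s])
                parts.append(v.alt)
                hap_cursor += (s - ref_cursor) + len(v.alt)
                ref_cursor = e
                continue
            if v.ref[0] != v.alt[0]:
                raise ValueError(
                    f"length-changing variant at {chrom}:{v.pos} must be "
                    "left-anchored (shared first base)"
                )
            # emit up to and including the anchor base
            parts.append(refseq[ref_cursor:s + 1])
            hap_cursor += s + 1 - ref_cursor
            close_match_block(hap_cursor)
            if len(v.alt) > len(v.ref):  # insertion after the anchor
                inserted = v.alt[1:]
                parts.append(inserted)
                chrom_blocks.append(
                    _Block(hap_cursor, hap_cursor + len(inserted), s, insertion=True)
                )
                hap_cursor += len(inserted)
                ref_cursor = e
            else:  # deletion of ref bases after the anchor
                ref_cursor = e
            block_hap = hap_cursor
            block_ref = ref_cursor
        parts.append(refseq[ref_cursor:])
        hap_cursor += len(refseq) - ref_cursor
        close_match_block(hap_cursor)
        seq = "".join(parts)
        if not chrom_blocks:  # zero-length chromosome edge case
            chrom_blocks = [_Block(0, 0, 0)]
        sequences[chrom] = seq
        blocks[chrom] = chrom_blocks
    return HaplotypeGenome(sequences=sequences, blocks=blocks)


def _target_arrays(targets):
    """Flatten (chrom, start, end) intervals for uniform position sampling."""
    chroms, starts, lengths = [], [], []
    for chrom, start, end in targets:
        if end <= start:
            raise ValueError(f"empty target interval {chrom}:{start}-{end}")
        chroms.append(chrom)
        starts.append(start)
        lengths.append(end - start)
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    return chroms, np.asarray(starts), offsets


def generate_random_variants(
    ref: ReferenceGenome,
    targets: list[tuple[str, int, int]],
    n_somatic: int,
    n_germline: int,
    indel_fraction: float = 0.0067,
    padding: int = 0,
    seed: int = 0,
    max_tries_per_variant: int = 1000,
) -> list[tuple[Variant, Origin]]:
    """Draw random non-overlapping variants over the capture targets.

    Positions are uniform over target bases (optionally padded); SNV alt
    alleles are uniform over the three non-reference bases.  A fraction
    ``indel_fraction`` (default 0.67%, the indel share typical of an
    SNV-focused exome study) become indels, split evenly between
    insertions and deletions with geometric lengths (mean 2, capped at
    10).  Variants never overlap on the reference.
    """
    if not 0.0 <= indel_fraction <= 1.0:
        raise ValueError("indel_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    padded = []
    for chrom, start, end in targets:
        length = len(ref.sequences[chrom])
        padded.append((chrom, max(0, start - padding), min(length, end + padding)))
    chroms, starts, offsets = _target_arrays(padded)
    total_bases = int(offsets[-1])

    n_total = n_somatic + n_germline
    occupied: dict[str, set[int]] = {c: set() for c in ref.sequences}
    out: list[tuple[Variant, Origin]] = []
    origins = [Origin.SOMATIC] * n_somatic + [Origin.GERMLINE] * n_germline
    budget = max_tries_per_variant * max(n_total, 1)

    for origin in origins:
        placed = False
        while budget > 0 and not placed:
            budget -= 1
            flat = int(rng.integers(0, total_bases))
            ti = int(np.searchsorted(offsets, flat, side="right")) - 1
            chrom = chroms[ti]
            pos0 = int(starts[ti] + (flat - offsets[ti]))
            seq = ref.sequences[chrom]
            is_indel = rng.random() < indel_fraction
            if is_indel:
                length = min(int(rng.geometric(0.5)), 10)
                if rng.random() < 0.5:  # insertion after anchor pos0
                    span = {pos0}
                    anchor = seq[pos0]
                    if anchor == "N":
                        continue
                    ins = "".join(
                        str(b, "ascii") for b in rng.choice(_BASES, size=length)
                    )
                    var = Variant(chrom, pos0 + 1, anchor, anchor + ins)
                else:  # deletion of `length` bases after anchor pos0
                    if pos0 + 1 + length > len(seq):
                        continue
                    span = set(range(pos0, pos0 + 1 + length))
                    refa = seq[pos0 : pos0 + 1 + length]
                    if "N" in refa:
                        continue
                    var = Variant(chrom, pos0 + 1, refa, refa[0])
            else:
                base = seq[pos0]
                if base == "N":
                    continue
                span = {pos0}
                alts = [b for b in "ACGT" if b != base]
                var = Variant(chrom, pos0 + 1, base, alts[int(rng.integers(0, 3))])
            if span & occupied[chrom]:
                continue
            occupied[chrom] |= span
            out.append((var, origin))
            placed = True
        if not placed:
            raise RuntimeError(
                "could not place all variants without overlap; "
                "reduce counts or enlarge targets"
            )
    out.sort(key=lambda vo: (vo[0].chrom, vo[0].pos))
    return out
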