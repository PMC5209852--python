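"""Readers and writers for the formats the pipeline exchanges.

Dialects are fixed: VCF v4.2, SAM v1.6, BED 0-based half-open, FASTQ
Phred+33, and TSV tables whose header lines start with '#'.  Truth sets
round-trip through VCF with INFO keys ORIGIN / NODE / COPIES / TRUE_VAF;
call sets round-trip with QUAL carrying the score.
"""

from __future__ import annotations

import csv
from dataclasses import replace

from .calling import CallRecord, CallSet
from .core import ClonalTree, Origin, TruthVariant, Variant

__all__ = [
    "write_truth_vcf",
    "read_truth_vcf",
    "write_callset_vcf",
    "parse_ranked_vcf",
    "ranks_from_tiers",
    "write_tree_tsv",
    "read_tree_tsv",
    "read_bed",
    "write_bed",
    "write_normal_counts",
    "read_normal_counts",
    "write_tsv",
]


def _vcf_header(contigs: dict[str, int], extra_info: list[str] = ()):
    import pysam

    header = pysam.VariantHeader()
    for line in extra_info:
        header.add_line(line)
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    return header


_TRUTH_INFO = [
    '##INFO=<ID=ORIGIN,Number=1,Type=String,Description="SOMATIC or GERMLINE">',
    '##INFO=<ID=NODE,Number=1,Type=Integer,Description="Clone node the variant was assigned to">',
    '##INFO=<ID=COPIES,Number=1,Type=Integer,Description="Mutated copies per carrier clone">',
    '##INFO=<ID=TRUE_VAF,Number=1,Type=Float,Description="Expected alt allele fraction in the mixture">',
    '##INFO=<ID=CARRIERS,Number=.,Type=Integer,Description="Carrier clone nodes">',
]


def write_truth_vcf(truth: list[TruthVariant], contigs: dict[str, int], path) -> None:
    import pysam

    header = _vcf_header(contigs, _TRUTH_INFO)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for tv in sorted(truth, key=lambda t: (t.variant.chrom, t.variant.pos)):
            v = tv.variant
            rec = out.new_record(
                contig=v.chrom, start=v.pos - 1, alleles=(v.ref, v.alt)
            )
            rec.info["ORIGIN"] = tv.origin.name
            if tv.assigned_node is not None:
                rec.info["NODE"] = tv.assigned_node
            rec.info["COPIES"] = tv.copies
            if tv.true_vaf is not None:
                rec.info["TRUE_VAF"] = tv.true_vaf
            rec.info["CARRIERS"] = tuple(sorted(tv.carriers))
            out.write(rec)


def read_truth_vcf(path) -> list[TruthVariant]:
    import pysam

    out = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if len(rec.alts or ()) != 1:
                raise ValueError(f"truth records must be bi-allelic: {rec}")
            v = Variant(rec.chrom, rec.pos, rec.ref, rec.alts[0])
            origin = Origin[rec.info["ORIGIN"]]
            vaf = rec.info.get("TRUE_VAF")
            out.append(
                TruthVariant(
                    variant=v,
                    origin=origin,
                    carriers=frozenset(rec.info.get("CARRIERS", ())),
                    copies=int(rec.info["COPIES"]),
                    normal_copies=(
                        0 if origin is Origin.SOMATIC else int(rec.info["COPIES"])
                    ),
                    assigned_node=rec.info.get("NODE"),
                    true_vaf=float(vaf) if vaf is not None else None,
                )
            )
    return out


def write_callset_vcf(callset: CallSet, contigs: dict[str, int], path) -> None:
    """Serialize a call set with QUAL = score and FILTER = PASS."""
    import pysam

    header = _vcf_header(
        contigs,
        ['##INFO=<ID=RANK,Number=1,Type=Integer,Description="Rank within the tool">'],
    )
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for rec in sorted(callset.records, key=lambda r: (r.variant.chrom, r.variant.pos)):
            v = rec.variant
            row = out.new_record(contig=v.chrom, start=v.pos - 1,
                                 alleles=(v.ref, v.alt))
            row.qual = rec.score
            row.filter.add("PASS")
            row.info["RANK"] = rec.rank
            out.write(row)


def parse_ranked_vcf(path, tool_id: str | None = None,
                     score_key: str | None = None) -> CallSet:
    """Read a VCF into a ranked CallSet.

    The score is QUAL, or INFO[``score_key``] when given.  Records are
    ordered by score descending with ascending coordinate tie-break;
    multi-allelic records are split into per-alt calls sharing the score.
    A record without a numeric score is a format error.
    """
    import pysam

    scored = []
    with pysam.VariantFile(str(path)) as vcf:
        name = tool_id or str(path)
        for rec in vcf:
            if score_key is not None:
                if score_key not in rec.info:
                    raise ValueError(
                        f"record {rec.chrom}:{rec.pos} lacks INFO/{score_key}"
                    )
                score = rec.info[score_key]
                if isinstance(score, tuple):
                    score = score[0]
            else:
                score = rec.qual
            if score is None:
                raise ValueError(
                    f"record {rec.chrom}:{rec.pos} has no usable score "
                    "(QUAL is missing and no score key was given)"
                )
            score = float(score)
            for alt in rec.alts or ():
                scored.append((Variant(rec.chrom, rec.pos, rec.ref, alt), score))
    return CallSet.from_scores(name, scored)


def ranks_from_tiers(tiers: list[list[Variant]], tool_id: str = "tiered") -> CallSet:
    """Build a CallSet from stringency tiers, most stringent last.

    A variant passing more filters lands in a later list and must rank
    above everything in earlier lists; within a tier, ascending
    coordinate order.  A variant present in several tiers keeps its
    highest (most stringent) tier.
    """
    best_tier: dict = {}
    variants: dict = {}
    for level, tier in enumerate(tiers):
        for v in tier:
            best_tier[v.key] = level
            variants[v.key] = v
    scored = [(variants[k], float(level)) for k, level in best_tier.items()]
    return CallSet.from_scores(tool_id, scored, rank_basis="tier")


def write_tree_tsv(tree: ClonalTree, path) -> None:
    with open(path, "w") as fh:
        fh.write("#node\tparent\n")
        for node in range(1, tree.n_clones + 1):
            fh.write(f"{node}\t{tree.parent.get(node, 0)}\n")


def read_tree_tsv(path) -> ClonalTree:
    parent = {}
    n = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            node, par = map(int, line.split())
            n = max(n, node)
            if par != 0:
                parent[node] = par
    return ClonalTree(n_clones=n, parent=parent)


def read_bed(path) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(("#", "track", "browser")) or not line.strip():
                continue
            fields = line.split()
            out.append((fields[0], int(fields[1]), int(fields[2])))
    return out


def write_bed(targets, path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in targets:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def write_normal_counts(counts: dict, path) -> None:
    """TSV of per-call normal evidence: chrom, pos, alt, k_N, n_N."""
    with open(path, "w") as fh:
        fh.write("#chrom\tpos\talt\tk_N\tn_N\n")
        for (chrom, pos, alt), (k, n) in sorted(counts.items()):
            fh.write(f"{chrom}\t{pos}\t{alt}\t{k}\t{n}\n")


def read_normal_counts(path) -> dict:
    out = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, pos, alt, k, n = line.split()
            out[(chrom, int(pos), alt)] = (int(k), int(n))
    return out


def write_tsv(rows: list[dict], path, columns: list[str] | None = None) -> None:
    """Write dict rows as TSV with a '#'-prefixed header line."""
    if not rows:
        with open(path, "w") as fh:
            fh.write("#\n")
        return
    columns = columns or list(rows[0])
    with open(path, "w", newline="") as fh:
        fh.write("#" + "\t".join(columns) + "\n")
        writer = csv.DictWriter(fh, fieldnames=columns, delimiter="\t")
        for row in rows:
            writer.writerow({c: row.get(c, "") for c in columns})
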