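"""End-to-end orchestration: simulate, call, filter, evaluate, attribute.

The pipeline mirrors a tumor-normal benchmarking workflow on fully
synthetic data: (1) draw a clonal tree, clone weights and a truth variant
set; (2) build per-haplotype clone and normal genomes; (3) simulate
capture reads per clone and mix them with normal contamination into a
tumor sample; (4) emit truth alignments; (5) run the naive caller; (6)
remove germline calls; (7) evaluate against the truth; (8) attribute
errors; (9) combine call sets.  Every stage is deterministic given the
configuration seed, writes its artifacts to the output directory, and is
recorded in a manifest with checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as sio
from .calling import (
    CallSet,
    binomial_germline_filter,
    naive_somatic_caller,
    normal_counts_for,
)
from .core import (
    ClonalTree,
    CloneWeights,
    MixtureSpec,
    Origin,
    TruthVariant,
    Variant,
    assign_variants,
    build_clonal_tree,
    draw_clone_weights,
    with_true_vaf,
)
from .evaluation import (
    auprc_at_precision,
    fdr_prefix,
    label_calls,
    precision_recall_curve,
    prefix_keys,
    sensitivity_by_vaf,
)
from .genomes import HaplotypeGenome, ReferenceGenome, apply_variants, generate_random_variants
from .pileup import count_pileup
from .reads import ErrorModel, ReadPool, mix_tumor_pool, simulate_reads

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "synthetic_reference",
    "tile_targets",
    "SimulatedTruth",
    "simulate_truth",
    "build_genomes",
    "simulate_sample",
    "call_and_filter",
    "evaluate_callset",
    "run_pipeline",
    "COVERAGE_GRID",
    "CONTAMINATION_GRID",
]

# the study's coverage grid: fractions of the full sequencing run, with the
# contamination series taken at the 50% coverage level
COVERAGE_GRID = {"12": 0.12, "25": 0.25, "50": 0.50, "75": 0.75, "100": 1.0}
CONTAMINATION_GRID = [0.0, 0.2, 0.4, 0.6]


@dataclass
class PipelineConfig:
    """Parameters of one simulated benchmarking run."""

    seed: int = 0
    outdir: str = "somabench-out"
    reference: str | None = None  # FASTA path; None = synthetic reference
    targets: str | None = None  # BED path; None = tiled over the reference
    genome_length: int = 200_000
    n_targets: int = 40
    target_length: int = 500
    n_clones: int = 8
    dirichlet_alpha: float = 1 / 8
    n_somatic: int = 400
    n_germline: int = 800
    indel_fraction: float = 0.0067
    kappa: float = 0.2
    depth: float = 50.0
    normal_depth: float = 50.0
    read_len: int = 100
    error_e0: float = 0.001
    error_e_last: float = 0.01
    caller_error_rate: float = 0.005
    caller_min_alt: int = 2
    fdr_alpha: float = 0.1

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _sub_seed(seed: int, *tags) -> int:
    """Stable child seed below 2**31 derived from a base seed and tags."""
    h = hashlib.sha256(("|".join(map(str, (seed, *tags)))).encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def synthetic_reference(
    length: int = 200_000, n_chroms: int = 1, seed: int = 0,
    name_prefix: str = "chr",
) -> ReferenceGenome:
    """Uniform-random ACGT reference for fixture-scale experiments."""
    rng = np.random.default_rng(_sub_seed(seed, "reference"))
    seqs = {}
    per = length // n_chroms
    for i in range(n_chroms):
        codes = rng.integers(0, 4, size=per)
        seqs[f"{name_prefix}{i + 1}"] = "".join("ACGT"[c] for c in codes)
    return ReferenceGenome(seqs)


def tile_targets(
    ref: ReferenceGenome, n_targets: int = 40, target_length: int = 500
) -> list[tuple[str, int, int]]:
    """Evenly spaced capture targets across the reference."""
    out = []
    chroms = sorted(ref.sequences)
    per_chrom = max(1, n_targets // len(chroms))
    for chrom in chroms:
        length = len(ref.sequences[chrom])
        spacing = length // per_chrom
        if spacing < target_length + 200:
            raise ValueError("reference too small for the requested targets")
        for i in range(per_chrom):
            start = i * spacing + (spacing - target_length) // 2
            out.append((chrom, start, start + target_length))
    return out


@dataclass
class SimulatedTruth:
    """Everything the simulator decided: the study's ground truth."""

    ref: ReferenceGenome
    targets: list[tuple[str, int, int]]
    tree: ClonalTree
    weights: CloneWeights
    truth: list[TruthVariant]  # true_vaf filled for the config kappa

    def truth_for_kappa(self, kappa: float) -> list[TruthVariant]:
        return [with_true_vaf(tv, self.weights, kappa) for tv in self.truth]


def simulate_truth(config: PipelineConfig,
                   ref: ReferenceGenome | None = None,
                   targets=None) -> SimulatedTruth:
    """Draw tree, weights, and the placed truth variant set."""
    if ref is None:
        if config.reference is not None:
            ref = ReferenceGenome.from_fasta(config.reference)
        else:
            ref = synthetic_reference(config.genome_length, seed=config.seed)
    if targets is None:
        if config.targets is not None:
            targets = sio.read_bed(config.targets)
        else:
            targets = tile_targets(ref, config.n_targets, config.target_length)
    tree = build_clonal_tree(config.n_clones, seed=_sub_seed(config.seed, "tree"))
    weights = draw_clone_weights(
        tree, alpha=config.dirichlet_alpha, seed=_sub_seed(config.seed, "weights")
    )
    variants = generate_random_variants(
        ref,
        targets,
        n_somatic=config.n_somatic,
        n_germline=config.n_germline,
        indel_fraction=config.indel_fraction,
        seed=_sub_seed(config.seed, "variants"),
    )
    truth = assign_variants(variants, tree, seed=_sub_seed(config.seed, "assign"))
    truth = [with_true_vaf(tv, weights, config.kappa) for tv in truth]
    return SimulatedTruth(ref=ref, targets=targets, tree=tree, weights=weights,
                          truth=truth)


def build_genomes(
    sim: SimulatedTruth, seed: int = 0
) -> dict[tuple[int, int], HaplotypeGenome]:
    """Per-haplotype genomes for the normal (clone 0) and every clone.

    Heterozygous variants go onto one haplotype, chosen once per variant
    and inherited consistently by every carrier; homozygous variants go
    onto both.
    """
    rng = np.random.default_rng(_sub_seed(seed, "phase"))
    hap_choice = {tv.variant.key: int(rng.integers(0, 2)) for tv in sim.truth}
    genomes: dict[tuple[int, int], HaplotypeGenome] = {}
    n_clones = sim.tree.n_clones
    for clone in range(0, n_clones + 1):
        for hap in (0, 1):
            phased = []
            for tv in sim.truth:
                if clone == 0:
                    carried = tv.origin is Origin.GERMLINE
                    copies = tv.normal_copies
                else:
                    carried = clone in tv.carriers
                    copies = tv.copies
                if not carried:
                    continue
                if copies == 2 or hap_choice[tv.variant.key] == hap:
                    phased.append(tv.variant)
            genomes[(clone, hap)] = apply_variants(sim.ref, phased)
    return genomes


def simulate_sample(
    sim: SimulatedTruth,
    genomes: dict[tuple[int, int], HaplotypeGenome],
    mixture: MixtureSpec,
    config: PipelineConfig,
    pool_slack: float = 1.35,
) -> tuple[ReadPool, ReadPool]:
    """Simulate one (tumor, matched normal) read-pool pair.

    Clone pools are oversampled by ``pool_slack`` so the multinomial
    allocation never exhausts them; the matched normal is an independent
    pool at ``config.normal_depth``.
    """
    error_model = ErrorModel(e0=config.error_e0, e_last=config.error_e_last)
    target_bases = sum(e - s for _, s, e in sim.targets)
    total_reads = int(round(mixture.coverage_level * target_bases / config.read_len))

    def diploid_pool(clone: int, depth: float, tag: str) -> ReadPool:
        pools = []
        for hap in (0, 1):
            pools.append(
                simulate_reads(
                    genomes[(clone, hap)],
                    sim.targets,
                    depth / 2.0,
                    read_len=config.read_len,
                    error_model=error_model,
                    sample=tag,
                    clone=clone,
                    hap=hap,
                    seed=_sub_seed(mixture.seed, tag, clone, hap),
                )
            )
        return ReadPool.concatenate(pools, sample=tag)

    clone_pools = {}
    for clone in range(1, sim.tree.n_clones + 1):
        share = (1.0 - mixture.kappa) * sim.weights.weights[clone]
        need = total_reads * share
        depth = (need * pool_slack + 400) * config.read_len / target_bases
        clone_pools[clone] = diploid_pool(clone, depth, f"clone{clone}")
    contam_depth = (
        (total_reads * mixture.kappa * pool_slack + 400)
        * config.read_len
        / target_bases
    )
    contam_pool = diploid_pool(0, contam_depth, "contam")
    tumor = mix_tumor_pool(
        clone_pools,
        sim.weights,
        contam_pool,
        mixture.kappa,
        total_reads,
        seed=_sub_seed(mixture.seed, "mix"),
    )
    normal = diploid_pool(0, config.normal_depth, "normal")
    return tumor, normal


def call_and_filter(
    sim: SimulatedTruth,
    genomes,
    tumor: ReadPool,
    normal: ReadPool,
    config: PipelineConfig,
    apply_germline_filter: bool = True,
) -> tuple[CallSet, CallSet, dict]:
    """Naive caller on the tumor pileup, then binomial germline filtering.

    Returns (raw calls, filtered calls, normal counts per call).
    """
    ref_lengths = sim.ref.lengths
    tumor_pileup = count_pileup(tumor, genomes, ref_lengths)
    normal_pileup = count_pileup(normal, genomes, ref_lengths)
    calls = naive_somatic_caller(
        tumor_pileup,
        sim.ref,
        sim.targets,
        error_rate=config.caller_error_rate,
        min_alt=config.caller_min_alt,
    )
    counts = normal_counts_for(calls, normal_pileup)
    filtered = (
        binomial_germline_filter(calls, counts, error_rate=config.caller_error_rate)
        if apply_germline_filter
        else calls
    )
    return calls, filtered, counts


def evaluate_callset(
    calls: CallSet,
    truth: list[TruthVariant],
    fdr_alpha: float = 0.1,
    precisions=(0.90, 0.95),
) -> dict:
    """Standard evaluation bundle: auPRC at fixed precisions, FDR prefix,
    sensitivity per VAF bin at the FDR-restricted top set."""
    labeled = label_calls(calls, truth)
    curve = precision_recall_curve(labeled)
    j = fdr_prefix(labeled, fdr_alpha)
    detected = prefix_keys(labeled, j)
    bins = sensitivity_by_vaf(truth, detected)
    out = {
        "tool": calls.tool_id,
        "n_calls": len(calls),
        "n_truth": labeled.n_truth,
        "fdr_alpha": fdr_alpha,
        "fdr_prefix": j,
        "sensitivity_at_fdr": (
            sum(b["n_detected"] for b in bins) / labeled.n_truth
            if labeled.n_truth
            else 0.0
        ),
        "vaf_bins": bins,
    }
    for t in precisions:
        out[f"auprc_{int(round(t * 100))}"] = auprc_at_precision(curve, t)
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


STAGES = [
    "simulate-truth",
    "build-genomes",
    "simulate-reads",
    "truth-align",
    "call-naive",
    "filter-germline",
    "evaluate",
    "attribute-errors",
]


def run_pipeline(config: PipelineConfig, stages: list[str] | None = None) -> dict:
    """Run the requested stages in order, writing artifacts and a manifest.

    Stages run in their canonical order; each requires its predecessors
    within the same invocation (state is kept in memory) and fails with
    an actionable error otherwise.  Returns the manifest dictionary.
    """
    from .attribution import (
        classify_error_sources,
        error_profiles,
        select_error_candidates,
    )
    from .pileup import pool_pileup
    from .reads import emit_truth_alignments

    stages = list(STAGES) if stages is None else stages
    order = {s: i for i, s in enumerate(STAGES)}
    for s in stages:
        if s not in order:
            raise ValueError(f"unknown stage {s!r}")
    stages = sorted(set(stages), key=order.__getitem__)

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "stages": {},
    }
    state: dict = {}

    def require(key: str, needed_by: str, produced_by: str):
        if key not in state:
            raise RuntimeError(
                f"stage {needed_by!r} needs {key}; run {produced_by!r} first "
                "(in the same invocation)"
            )
        return state[key]

    def record(stage: str, paths: list[Path]):
        manifest["stages"][stage] = {
            str(p.relative_to(outdir)): _sha256(p) for p in paths
        }

    for stage in stages:
        logger.info("running stage %s", stage)
        if stage == "simulate-truth":
            sim = simulate_truth(config)
            state["sim"] = sim
            ref_fa = outdir / "reference.fa"
            sim.ref.to_fasta(ref_fa)
            bed = outdir / "targets.bed"
            sio.write_bed(sim.targets, bed)
            tree_tsv = outdir / "clone_tree.tsv"
            sio.write_tree_tsv(sim.tree, tree_tsv)
            wtsv = outdir / "clone_weights.tsv"
            sio.write_tsv(
                [
                    {"clone": c, "weight": f"{w:.10f}"}
                    for c, w in sorted(sim.weights.weights.items())
                ],
                wtsv,
            )
            truth_vcf = outdir / "truth.vcf"
            sio.write_truth_vcf(sim.truth, sim.ref.lengths, truth_vcf)
            record(stage, [ref_fa, bed, tree_tsv, wtsv, truth_vcf])
        elif stage == "build-genomes":
            sim = require("sim", stage, "simulate-truth")
            genomes = build_genomes(sim, seed=config.seed)
            state["genomes"] = genomes
            paths = []
            for (clone, hap), genome in sorted(genomes.items()):
                p = outdir / f"genome_clone{clone}_hap{hap}.fa"
                ReferenceGenome(genome.sequences).to_fasta(p)
                paths.append(p)
            record(stage, paths)
        elif stage == "simulate-reads":
            sim = require("sim", stage, "simulate-truth")
            genomes = require("genomes", stage, "build-genomes")
            mixture = MixtureSpec(
                kappa=config.kappa, coverage_level=config.depth, seed=config.seed
            )
            tumor, normal = simulate_sample(sim, genomes, mixture, config)
            state["tumor"], state["normal"] = tumor, normal
            tq = outdir / "tumor.fastq"
            nq = outdir / "normal.fastq"
            tumor.to_fastq(tq)
            normal.to_fastq(nq)
            record(stage, [tq, nq])
        elif stage == "truth-align":
            sim = require("sim", stage, "simulate-truth")
            genomes = require("genomes", stage, "build-genomes")
            tumor = require("tumor", stage, "simulate-reads")
            normal = require("normal", stage, "simulate-reads")
            ts = outdir / "tumor.truth.sam"
            ns = outdir / "normal.truth.sam"
            emit_truth_alignments(tumor, genomes, sim.ref.lengths, ts)
            emit_truth_alignments(normal, genomes, sim.ref.lengths, ns)
            record(stage, [ts, ns])
        elif stage == "call-naive":
            sim = require("sim", stage, "simulate-truth")
            genomes = require("genomes", stage, "build-genomes")
            tumor = require("tumor", stage, "simulate-reads")
            normal = require("normal", stage, "simulate-reads")
            calls, _, counts = call_and_filter(
                sim, genomes, tumor, normal, config, apply_germline_filter=False
            )
            state["calls"], state["normal_counts"] = calls, counts
            cv = outdir / "calls.naive.vcf"
            sio.write_callset_vcf(calls, sim.ref.lengths, cv)
            nc = outdir / "normal_counts.tsv"
            sio.write_normal_counts(counts, nc)
            record(stage, [cv, nc])
        elif stage == "filter-germline":
            sim = require("sim", stage, "simulate-truth")
            calls = require("calls", stage, "call-naive")
            counts = require("normal_counts", stage, "call-naive")
            filtered = binomial_germline_filter(
                calls, counts, error_rate=config.caller_error_rate
            )
            state["filtered"] = filtered
            fv = outdir / "calls.filtered.vcf"
            sio.write_callset_vcf(filtered, sim.ref.lengths, fv)
            record(stage, [fv])
        elif stage == "evaluate":
            sim = require("sim", stage, "simulate-truth")
            filtered = require("filtered", stage, "filter-germline")
            result = evaluate_callset(filtered, sim.truth, config.fdr_alpha)
            state["evaluation"] = result
            mj = outdir / "metrics.json"
            with open(mj, "w") as fh:
                json.dump(result, fh, indent=2)
            rows = [
                {
                    "tool": result["tool"],
                    "alpha": config.fdr_alpha,
                    "auPRC_90": f"{result['auprc_90']:.6f}",
                    "auPRC_95": f"{result['auprc_95']:.6f}",
                }
            ]
            mt = outdir / "metrics.tsv"
            sio.write_tsv(rows, mt)
            record(stage, [mj, mt])
        elif stage == "attribute-errors":
            sim = require("sim", stage, "simulate-truth")
            genomes = require("genomes", stage, "build-genomes")
            tumor = require("tumor", stage, "simulate-reads")
            normal = require("normal", stage, "simulate-reads")
            filtered = require("filtered", stage, "filter-germline")
            labeled = label_calls(filtered, sim.truth)
            fp_keys, fns = select_error_candidates(labeled, sim.truth)
            sites = [(k[0], k[1], k[2]) for k in fp_keys] + [
                (tv.variant.chrom, tv.variant.pos, tv.variant.alt) for tv in fns
            ]
            locs = [(c, p) for c, p, _ in sites]
            tcols = pool_pileup(tumor, genomes, locs)
            ncols = pool_pileup(normal, genomes, locs)
            classified_fp = [
                classify_error_sources(s, tcols[(s[0], s[1])], ncols[(s[0], s[1])],
                                       sim.truth)
                for s in sites[: len(fp_keys)]
            ]
            classified_fn = [
                classify_error_sources(s, tcols[(s[0], s[1])], ncols[(s[0], s[1])],
                                       sim.truth)
                for s in sites[len(fp_keys):]
            ]
            rows = []
            for set_type, classified in (("FP", classified_fp), ("FN", classified_fn)):
                profs = error_profiles({"naive": classified}, set_type)
                prof = profs["naive"]
                for cat, pct in prof.percentages.items():
                    rows.append(
                        {
                            "tool": "naive",
                            "set_type": set_type,
                            "category": cat.value,
                            "count": prof.counts.get(cat, 0),
                            "percentage": f"{pct:.4f}",
                            "total": prof.total,
                        }
                    )
            pt = outdir / "error_profiles.tsv"
            sio.write_tsv(rows, pt)
            record(stage, [pt])

    config.to_yaml(outdir / "config.yaml")
    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
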