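import numpy as np
import pytest

from somabench.core import CloneWeights, Variant
from somabench.genomes import ReferenceGenome, apply_variants
from somabench.pipeline import synthetic_reference
from somabench.reads import (
    ErrorModel,
    ReadPool,
    ReadRecord,
    emit_truth_alignments,
    mix_tumor_pool,
    simulate_reads,
)


@pytest.fixture(scope="module")
def flat_genome():
    """10 kb identity haplotype (no variants applied)."""
    ref = synthetic_reference(length=10_000, seed=1)
    return ref, apply_variants(ref, [])


class TestErrorModel:
    def test_default_ramp_endpoints(self):
        e = ErrorModel().rates(100)
        assert e[0] == pytest.approx(0.001)
        assert e[-1] == pytest.approx(0.01)
        assert np.all(np.diff(e) > 0)

    def test_qualities_match_rates(self):
        m = ErrorModel()
        e = m.rates(100)
        q = m.qualities(100)
        assert np.array_equal(q, np.round(-10 * np.log10(e)))

    def test_rates_must_stay_below_three_quarters(self):
        with pytest.raises(ValueError):
            ErrorModel(e0=0.5, slope=0.01).rates(100)


class TestReadName:
    def test_name_round_trips_origin(self):
        rec = ReadRecord(
            sample="tumor", clone=3, hap=1, hap_start=500, ref_start=498,
            strand="-", serial=42, sequence="ACGT",
            qualities=np.array([30, 30, 30, 30]),
        )
        assert ReadRecord.parse_name(rec.name) == ("tumor", 3, 1, 498, "-", 42)

    def test_bad_strand_rejected(self):
        with pytest.raises(ValueError):
            ReadRecord.parse_name("s|1|0|5|x|1")


class TestSimulateReads:
    def test_read_count_formula(self, flat_genome):
        _, hap = flat_genome
        pool = simulate_reads(hap, [("chr1", 0, 10_000)], mean_depth=50,
                              read_len=100, padding=0, seed=0)
        assert len(pool) == 5_000

    def test_error_free_reads_are_exact_substrings(self, flat_genome):
        ref, hap = flat_genome
        pool = simulate_reads(hap, [("chr1", 2000, 3000)], mean_depth=20,
                              read_len=100, error_model=ErrorModel.error_free(),
                              seed=1)
        seq = ref.sequences["chr1"]
        comp = str.maketrans("ACGT", "TGCA")
        for i in range(len(pool)):
            rec = pool.record(i)
            segment = seq[rec.hap_start : rec.hap_start + 100]
            if rec.strand == "-":
                segment = segment.translate(comp)[::-1]
            assert rec.sequence == segment

    def test_mid_target_depth_matches_sampling_model(self, flat_genome):
        """Mean depth at a mid-target base over replicates stays within
        3 sigma of the binomial sampling model's prediction."""
        _, hap = flat_genome
        target = [("chr1", 2000, 4000)]
        pos = 3000  # deep inside the target
        n_reps = 100
        depths = []
        for rep in range(n_reps):
            pool = simulate_reads(hap, target, mean_depth=50, read_len=100,
                                  padding=0, seed=100 + rep)
            covering = (pool.hap_start <= pos) & (pool.hap_start > pos - 100)
            depths.append(int(covering.sum()))
        # 1000 reads over 2000 start positions, 100 admissible starts
        n_reads, p = 1000, 100 / 2000
        expected = n_reads * p
        se = np.sqrt(n_reads * p * (1 - p) / n_reps)
        assert abs(np.mean(depths) - expected) < 3 * se

    def test_empty_targets_rejected(self, flat_genome):
        _, hap = flat_genome
        with pytest.raises(ValueError):
            simulate_reads(hap, [], mean_depth=10)

    def test_deterministic_per_seed(self, flat_genome):
        _, hap = flat_genome
        a = simulate_reads(hap, [("chr1", 0, 2000)], 10, seed=7)
        b = simulate_reads(hap, [("chr1", 0, 2000)], 10, seed=7)
        assert np.array_equal(a.seqs, b.seqs)
        assert np.array_equal(a.hap_start, b.hap_start)


class TestMixTumorPool:
    def _pools(self, hap, sizes, seed=0):
        pools = {}
        for clone, n in sizes.items():
            pools[clone] = simulate_reads(
                hap, [("chr1", 0, 10_000)], mean_depth=1, n_reads=n,
                clone=clone, sample=f"clone{clone}", seed=seed + clone,
            )
        return pools

    def test_single_clone_no_contamination(self, flat_genome):
        _, hap = flat_genome
        pools = self._pools(hap, {1: 2000})
        normal = self._pools(hap, {0: 2000})[0]
        w = CloneWeights(weights={1: 1.0}, alpha=1 / 8, seed=0)
        mixed = mix_tumor_pool(pools, w, normal, kappa=0.0, total_reads=1500)
        assert len(mixed) == 1500
        assert np.all(mixed.clone == 1)

    def test_full_contamination_is_all_normal(self, flat_genome):
        _, hap = flat_genome
        pools = self._pools(hap, {1: 2000})
        normal = self._pools(hap, {0: 2000})[0]
        w = CloneWeights(weights={1: 1.0}, alpha=1 / 8, seed=0)
        mixed = mix_tumor_pool(pools, w, normal, kappa=1.0, total_reads=1500)
        assert np.all(mixed.clone == 0)

    def test_contamination_share_in_multinomial_band(self, flat_genome):
        # kappa=0.2, 100k reads -> 3 sigma band [19620, 20380]
        _, hap = flat_genome
        pools = self._pools(hap, {1: 60_000, 2: 60_000})
        normal = self._pools(hap, {0: 30_000})[0]
        w = CloneWeights(weights={1: 0.5, 2: 0.5}, alpha=1 / 8, seed=0)
        mixed = mix_tumor_pool(pools, w, normal, kappa=0.2,
                               total_reads=100_000, seed=3)
        n_normal = int((mixed.clone == 0).sum())
        assert 19_620 <= n_normal <= 20_380
        assert len(mixed) == 100_000

    def test_pool_exhaustion_raises(self, flat_genome):
        _, hap = flat_genome
        pools = self._pools(hap, {1: 100})
        normal = self._pools(hap, {0: 100})[0]
        w = CloneWeights(weights={1: 1.0}, alpha=1 / 8, seed=0)
        with pytest.raises(ValueError, match="requested"):
            mix_tumor_pool(pools, w, normal, kappa=0.0, total_reads=500)


class TestTruthAlignments:
    def test_plus_strand_position_is_one_based(self, flat_genome):
        ref, hap = flat_genome
        pool = simulate_reads(hap, [("chr1", 100, 1000)], 5, padding=0,
                              error_model=ErrorModel.error_free(), seed=2)
        recs = emit_truth_alignments(pool, {(0, 0): hap}, ref.lengths)
        by_name = {a.query_name: a for a in recs}
        for i in range(len(pool)):
            r = pool.record(i)
            a = by_name[r.name]
            # identity haplotype: 0-based start equals hap start, so the
            # 1-based SAM POS is hap_start + 1
            assert a.reference_start == r.hap_start
            assert a.mapping_quality == 60

    def test_minus_strand_flag_and_orientation(self, flat_genome):
        ref, hap = flat_genome
        pool = simulate_reads(hap, [("chr1", 100, 1000)], 5, padding=0,
                              error_model=ErrorModel.error_free(), seed=3)
        recs = emit_truth_alignments(pool, {(0, 0): hap}, ref.lengths)
        by_name = {a.query_name: a for a in recs}
        seq = ref.sequences["chr1"]
        minus_seen = False
        for i in range(len(pool)):
            r = pool.record(i)
            a = by_name[r.name]
            if r.strand == "-":
                minus_seen = True
                assert a.is_reverse
                # SAM stores the forward-reference orientation
                assert a.query_sequence == seq[r.hap_start : r.hap_start + 100]
        assert minus_seen

    def test_deletion_read_cigar_and_position(self):
        ref = ReferenceGenome({"c1": "ACGTACGTACGTACGTACGTACGTACGTACGT"})
        hap = apply_variants(ref, [Variant("c1", 10, "CGT", "C")])
        pool = simulate_reads(hap, [("c1", 0, 32)], mean_depth=200, read_len=20,
                              padding=0, error_model=ErrorModel.error_free(),
                              seed=4)
        recs = emit_truth_alignments(pool, {(0, 0): hap}, ref.lengths)
        spanning = [a for a in recs
                    if a.reference_start < 9 and a.reference_end > 13]
        assert spanning, "no read spans the deletion"
        for a in spanning:
            assert "2D" in a.cigarstring
            _, _, _, ref_start, _, _ = ReadRecord.parse_name(a.query_name)
            assert a.reference_start == ref_start

    def test_sam_round_trip(self, tmp_path, flat_genome):
        ref, hap = flat_genome
        pool = simulate_reads(hap, [("chr1", 0, 2000)], 10, seed=5)
        path = tmp_path / "truth.sam"
        emit_truth_alignments(pool, {(0, 0): hap}, ref.lengths, path)
        import pysam

        with pysam.AlignmentFile(str(path)) as fh:
            names = [a.query_name for a in fh]
        assert len(names) == len(pool)
        assert all(ReadRecord.parse_name(n) for n in names)


class TestFastq:
    def test_fastq_is_phred33_and_names_parse(self, tmp_path, flat_genome):
        _, hap = flat_genome
        pool = simulate_reads(hap, [("chr1", 0, 2000)], 5, seed=6)
        path = tmp_path / "reads.fastq"
        pool.to_fastq(path)
        lines = path.read_text().splitlines()
        assert len(lines) == 4 * len(pool)
        assert lines[0].startswith("@")
        ReadRecord.parse_name(lines[0][1:])
        quals = [ord(c) - 33 for c in lines[3]]
        assert quals == list(pool.quals)
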