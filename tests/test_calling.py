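import numpy as np
import pytest

from somabench.calling import (
    CallRecord,
    CallSet,
    binomial_germline_filter,
    naive_somatic_caller,
    perturb_truth_to_callset,
    subtract_normal_calls,
)
from somabench.core import Variant
from somabench.evaluation import label_calls
from somabench.genomes import ReferenceGenome
from somabench.pileup import CountPileup
from helpers import binomial_tail_oracle, synthetic_truth_set


def make_count_pileup(length, entries):
    """CountPileup over one chromosome from {pos1: {base: count}}."""
    counts = np.zeros((length, 4), dtype=np.int32)
    code = {"A": 0, "C": 1, "G": 2, "T": 3}
    for pos1, bases in entries.items():
        for b, k in bases.items():
            counts[pos1 - 1, code[b]] = k
    return CountPileup(counts={"c1": counts},
                       del_depth={"c1": np.zeros(length, dtype=np.int32)})


class TestCallSet:
    def test_ranks_follow_scores_with_coordinate_tiebreak(self):
        scored = [
            (Variant("c1", 30, "A", "T"), 5.0),
            (Variant("c1", 10, "A", "T"), 9.0),
            (Variant("c1", 20, "A", "T"), 5.0),
        ]
        cs = CallSet.from_scores("t", scored)
        assert [(r.variant.pos, r.rank) for r in cs] == [(10, 1), (20, 2), (30, 3)]

    def test_duplicate_calls_rejected(self):
        v = Variant("c1", 10, "A", "T")
        with pytest.raises(ValueError, match="duplicate"):
            CallSet("t", [CallRecord(v, 2.0, 1), CallRecord(v, 1.0, 2)])

    def test_scores_must_be_non_increasing(self):
        with pytest.raises(ValueError):
            CallSet("t", [
                CallRecord(Variant("c1", 10, "A", "T"), 1.0, 1),
                CallRecord(Variant("c1", 20, "A", "T"), 2.0, 2),
            ])


class TestNaiveCaller:
    @pytest.fixture()
    def ref(self):
        return ReferenceGenome({"c1": "A" * 200})

    def test_no_alt_reads_no_call(self, ref):
        pileup = make_count_pileup(200, {50: {"A": 100}})
        cs = naive_somatic_caller(pileup, ref, [("c1", 0, 200)])
        assert len(cs) == 0

    def test_single_alt_read_is_not_significant(self, ref):
        # P(X>=1 | 100, 0.005) = 1 - 0.995^100 ~ 0.394
        pileup = make_count_pileup(200, {50: {"A": 99, "T": 1}})
        cs = naive_somatic_caller(pileup, ref, [("c1", 0, 200)], min_alt=1)
        assert len(cs) == 0
        assert binomial_tail_oracle(1, 100, 0.005) == pytest.approx(0.394, abs=5e-3)

    def test_overwhelming_evidence_scores_high(self, ref):
        pileup = make_count_pileup(200, {50: {"A": 70, "T": 30}})
        cs = naive_somatic_caller(pileup, ref, [("c1", 0, 200)])
        assert len(cs) == 1
        assert cs.records[0].variant.key == ("c1", 50, "T")
        assert cs.records[0].score > 30

    def test_min_alt_threshold_applies(self, ref):
        pileup = make_count_pileup(200, {50: {"A": 10, "T": 1}})
        cs = naive_somatic_caller(pileup, ref, [("c1", 0, 200)], min_alt=2)
        assert len(cs) == 0

    def test_sites_outside_targets_ignored(self, ref):
        pileup = make_count_pileup(200, {150: {"A": 70, "T": 30}})
        cs = naive_somatic_caller(pileup, ref, [("c1", 0, 100)])
        assert len(cs) == 0


class TestBinomialGermlineFilter:
    def _calls(self, n=3):
        scored = [(Variant("c1", 10 * (i + 1), "A", "T"), float(n - i))
                  for i in range(n)]
        return CallSet.from_scores("t", scored)

    def test_worked_decisions(self):
        calls = self._calls(3)
        counts = {
            ("c1", 10, "T"): (0, 100),  # p = 1, kept
            ("c1", 20, "T"): (3, 100),  # p ~ 0.0141 < 0.05, removed
            ("c1", 30, "T"): (2, 100),  # p ~ 0.0898, kept
        }
        out = binomial_germline_filter(calls, counts)
        assert {r.variant.pos for r in out} == {10, 30}
        assert [r.rank for r in out] == [1, 2]
        assert binomial_tail_oracle(3, 100, 0.005) == pytest.approx(0.0141, abs=1e-3)
        assert binomial_tail_oracle(2, 100, 0.005) == pytest.approx(0.0898, abs=1e-3)

    def test_agrees_with_tail_oracle_on_grid(self):
        # spot grid here; the full n<=500 sweep runs in the acceptance suite
        for n in (1, 10, 50, 200, 500):
            for k in range(0, min(n, 12) + 1):
                calls = self._calls(1)
                out = binomial_germline_filter(
                    calls, {("c1", 10, "T"): (k, n)}, error_rate=0.005
                )
                removed = len(out) == 0
                assert removed == (binomial_tail_oracle(k, n, 0.005) < 0.05), (n, k)

    def test_idempotent_and_shrinking(self):
        calls = self._calls(3)
        counts = {r.key: (3 if r.variant.pos == 20 else 0, 100) for r in calls}
        once = binomial_germline_filter(calls, counts)
        twice = binomial_germline_filter(once, counts)
        assert len(once) <= len(calls)
        assert [r.key for r in once] == [r.key for r in twice]

    def test_never_removes_zero_alt_calls(self):
        calls = self._calls(3)
        counts = {r.key: (0, 30) for r in calls}
        assert len(binomial_germline_filter(calls, counts)) == 3

    def test_invalid_counts_rejected(self):
        calls = self._calls(1)
        with pytest.raises(ValueError):
            binomial_germline_filter(calls, {("c1", 10, "T"): (5, 3)})
        with pytest.raises(KeyError):
            binomial_germline_filter(calls, {})


class TestSubtractNormalCalls:
    def test_disjoint_sets_unchanged(self):
        t = CallSet.from_scores("t", [(Variant("c1", 10, "A", "T"), 2.0)])
        n = CallSet.from_scores("n", [(Variant("c1", 20, "A", "T"), 2.0)])
        assert [r.key for r in subtract_normal_calls(t, n)] == [("c1", 10, "T")]

    def test_identical_sets_empty(self):
        t = CallSet.from_scores("t", [(Variant("c1", 10, "A", "T"), 2.0)])
        assert len(subtract_normal_calls(t, t)) == 0

    def test_partial_overlap_preserves_order(self):
        t = CallSet.from_scores("t", [
            (Variant("c1", 10, "A", "T"), 3.0),
            (Variant("c1", 20, "A", "T"), 2.0),
            (Variant("c1", 30, "A", "T"), 1.0),
        ])
        n = CallSet.from_scores("n", [(Variant("c1", 20, "A", "T"), 9.0)])
        out = subtract_normal_calls(t, n)
        assert [r.variant.pos for r in out] == [10, 30]
        assert [r.rank for r in out] == [1, 2]


class TestPerturbTruth:
    def test_perfect_sensitivity_reproduces_truth(self):
        truth = synthetic_truth_set(100, seed=1)
        cs = perturb_truth_to_callset(truth, 1.0, n_fp=0, seed=2)
        assert cs.keys() == {tv.variant.key for tv in truth}
        labeled = label_calls(cs, truth)
        assert labeled.labels.count("TP") == 100
        assert labeled.labels.count("FP") == 0

    def test_flat_half_sensitivity_band(self):
        # 2000 truths at sens 0.5 -> binomial 3 sigma band [933, 1067]
        truth = synthetic_truth_set(2000, seed=3)
        cs = perturb_truth_to_callset(truth, 0.5, n_fp=0, seed=4)
        assert 933 <= len(cs) <= 1067

    def test_full_coupling_reproduces_reference_detections(self):
        truth = synthetic_truth_set(400, seed=5)
        ref = perturb_truth_to_callset(truth, 0.6, n_fp=0, seed=6)
        coupled = perturb_truth_to_callset(truth, 0.6, n_fp=0, rho=1.0,
                                           reference=ref, seed=7)
        assert coupled.keys() == ref.keys()

    def test_coupling_without_reference_rejected(self):
        truth = synthetic_truth_set(10, seed=8)
        with pytest.raises(ValueError):
            perturb_truth_to_callset(truth, 0.5, rho=0.5, seed=9)

    def test_false_positives_never_hit_truth_sites(self):
        truth = synthetic_truth_set(200, seed=10)
        cs = perturb_truth_to_callset(truth, 0.5, n_fp=50, seed=11)
        truth_keys = {tv.variant.key for tv in truth}
        fp_keys = cs.keys() - truth_keys
        assert len(fp_keys) == 50
        truth_positions = {(k[0], k[1]) for k in truth_keys}
        assert all((k[0], k[1]) not in truth_positions for k in fp_keys)
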