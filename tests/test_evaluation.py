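import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from somabench.calling import CallSet
from somabench.core import Variant
from somabench.evaluation import (
    auprc_at_precision,
    fdr_prefix,
    label_calls,
    normalize_variants,
    precision_recall_curve,
    sensitivity_by_vaf,
    split_mnv,
)
from helpers import (
    brute_force_metrics,
    labeled_from_pattern,
    somatic_truth,
    synthetic_truth_set,
)


class TestNormalization:
    def test_mnv_splits_positionally(self):
        out = split_mnv(Variant("c1", 5, "AC", "GT"))
        assert [(v.pos, v.ref, v.alt) for v in out] == [(5, "A", "G"), (6, "C", "T")]

    def test_matching_bases_dropped(self):
        out = split_mnv(Variant("c1", 5, "ACG", "AGG"))
        assert [(v.pos, v.ref, v.alt) for v in out] == [(6, "C", "G")]

    def test_indels_become_exclusion_zones(self):
        snvs, zones = normalize_variants([
            Variant("c1", 3, "A", "T"),
            Variant("c1", 10, "ACGG", "GCGGG"),  # substitution containing an indel
            Variant("c1", 30, "AC", "A"),
        ])
        assert [v.pos for v in snvs] == [3]
        assert ("c1", 9, 14) in zones  # covers the longer of ref/alt
        assert ("c1", 29, 31) in zones


class TestLabelCalls:
    def _truth(self):
        return [
            somatic_truth("c1", 100, "A", "T", 0.4),
            somatic_truth("c1", 200, "C", "G", 0.3),
        ]

    def test_exact_match_is_tp(self):
        calls = CallSet.from_scores("t", [(Variant("c1", 100, "A", "T"), 5.0)])
        labeled = label_calls(calls, self._truth())
        assert labeled.labels == ["TP"]
        assert labeled.n_truth == 2

    def test_wrong_alt_at_truth_position_is_fp(self):
        calls = CallSet.from_scores("t", [(Variant("c1", 100, "A", "G"), 5.0)])
        assert label_calls(calls, self._truth()).labels == ["FP"]

    def test_call_inside_indel_zone_is_excluded(self):
        truth = self._truth() + [
            # truth substitution containing an indel spanning pos 300-303
            somatic_truth("c1", 300, "ACGG", "GCGGG", 0.5),
        ]
        calls = CallSet.from_scores("t", [(Variant("c1", 300, "A", "G"), 5.0)])
        assert label_calls(calls, truth).labels == ["excluded"]

    def test_predicted_mnv_split_shares_score(self):
        calls = CallSet.from_scores("t", [(Variant("c1", 100, "AC", "TG"), 5.0)])
        truth = [somatic_truth("c1", 100, "A", "T", 0.4)]
        labeled = label_calls(calls, truth)
        assert len(labeled.callset) == 2
        assert sorted(labeled.labels) == ["FP", "TP"]

    def test_duplicate_coordinates_after_splitting_rejected(self):
        # two MNV predictions that decompose to the same SNV key
        calls = CallSet.from_scores("t", [
            (Variant("c1", 100, "AC", "TC"), 5.0),  # -> A>T @100
            (Variant("c1", 99, "CA", "CT"), 4.0),  # -> A>T @100
        ])
        with pytest.raises(ValueError, match="duplicate"):
            label_calls(calls, self._truth())


class TestFdrPrefix:
    def test_all_tp_keeps_everything(self):
        labeled = labeled_from_pattern(["TP"] * 5, n_truth=5)
        assert fdr_prefix(labeled, 0.0) == 5

    def test_worked_pattern(self):
        labeled = labeled_from_pattern(["TP", "FP", "TP"], n_truth=2)
        # prefix FDRs are 0, 1/2, 1/3 -> largest prefix under 0.1 is 1
        assert fdr_prefix(labeled, 0.1) == 1
        assert fdr_prefix(labeled, 1 / 3) == 3

    def test_leading_fp_with_zero_alpha(self):
        labeled = labeled_from_pattern(["FP", "TP", "TP"], n_truth=2)
        assert fdr_prefix(labeled, 0.0) == 0

    def test_excluded_records_do_not_count(self):
        labeled = labeled_from_pattern(["TP", "excluded", "FP", "TP"], n_truth=2)
        # effective sequence is [TP, FP, TP]
        assert fdr_prefix(labeled, 0.1) == 1

    @given(st.lists(st.booleans(), min_size=1, max_size=120),
           st.floats(0, 1))
    @settings(max_examples=80, deadline=None)
    def test_matches_brute_force(self, flags, alpha):
        labels = ["TP" if f else "FP" for f in flags]
        n_truth = max(labels.count("TP"), 1)
        labeled = labeled_from_pattern(labels, n_truth=n_truth)
        expected, _, _, _ = brute_force_metrics(flags, n_truth, alpha, 0.9)
        assert fdr_prefix(labeled, alpha) == expected


class TestPRCurve:
    def test_perfect_caller_reaches_the_corner(self):
        labeled = labeled_from_pattern(["TP"] * 4, n_truth=4)
        curve = precision_recall_curve(labeled)
        assert curve.precision[-1] == pytest.approx(1.0)
        assert curve.recall[-1] == pytest.approx(1.0)

    def test_worked_points(self):
        labeled = labeled_from_pattern(["TP", "FP", "TP"], n_truth=2)
        curve = precision_recall_curve(labeled)
        assert curve.precision == pytest.approx([1.0, 0.5, 2 / 3])
        assert curve.recall == pytest.approx([0.5, 0.5, 1.0])

    @given(st.lists(st.booleans(), min_size=1, max_size=100))
    @settings(max_examples=60, deadline=None)
    def test_recall_non_decreasing(self, flags):
        labels = ["TP" if f else "FP" for f in flags]
        n_truth = max(labels.count("TP"), 1)
        curve = precision_recall_curve(labeled_from_pattern(labels, n_truth))
        assert np.all(np.diff(curve.recall) >= 0)


class TestAuPRC:
    def test_perfect_caller_is_one(self):
        labeled = labeled_from_pattern(["TP"] * 6, n_truth=6)
        curve = precision_recall_curve(labeled)
        for t in (0.9, 0.95, 1.0):
            assert auprc_at_precision(curve, t) == pytest.approx(1.0)

    def test_no_qualifying_prefix_is_zero(self):
        labeled = labeled_from_pattern(["FP", "TP"], n_truth=1)
        curve = precision_recall_curve(labeled)
        assert auprc_at_precision(curve, 0.9) == 0.0

    def test_worked_value(self):
        labeled = labeled_from_pattern(["TP", "FP", "TP"], n_truth=2)
        curve = precision_recall_curve(labeled)
        # only prefix 1 reaches precision 0.9: rectangle 1.0 x 0.5
        assert auprc_at_precision(curve, 0.9) == pytest.approx(0.5)

    def test_tighter_precision_never_gains_area(self, rng):
        for _ in range(30):
            flags = rng.random(rng.integers(5, 200)) < rng.random()
            labels = ["TP" if f else "FP" for f in flags]
            n_truth = max(labels.count("TP"), 1)
            curve = precision_recall_curve(labeled_from_pattern(labels, n_truth))
            a90 = auprc_at_precision(curve, 0.90)
            a95 = auprc_at_precision(curve, 0.95)
            assert a95 <= a90 + 1e-12

    def test_metrics_depend_on_ranks_only(self):
        truth = synthetic_truth_set(50, seed=1)
        cs = CallSet.from_scores(
            "t", [(tv.variant, 50.0 - i) for i, tv in enumerate(truth)]
        )
        squashed = CallSet.from_scores(
            "t", [(r.variant, float(np.log1p(r.score))) for r in cs]
        )
        c1 = precision_recall_curve(label_calls(cs, truth))
        c2 = precision_recall_curve(label_calls(squashed, truth))
        assert np.allclose(c1.precision, c2.precision)
        assert auprc_at_precision(c1, 0.9) == auprc_at_precision(c2, 0.9)


class TestSensitivityByVaf:
    def test_bin_boundaries(self):
        truth = [
            somatic_truth("c1", 10, "A", "T", 0.05),  # -> [0.05, 0.10)
            somatic_truth("c1", 20, "A", "T", 1.0),  # -> final bin
            somatic_truth("c1", 30, "A", "T", 0.049),  # -> (0, 0.05)
        ]
        bins = sensitivity_by_vaf(truth, {("c1", 10, "T"), ("c1", 20, "T")})
        by_low = {b["bin_low"]: b for b in bins}
        assert by_low[0.05]["n_truth"] == 1 and by_low[0.05]["n_detected"] == 1
        assert by_low[0.95]["n_truth"] == 1 and by_low[0.95]["n_detected"] == 1
        assert by_low[0.0]["n_truth"] == 1 and by_low[0.0]["n_detected"] == 0

    def test_ratio(self):
        truth = [somatic_truth("c1", 10 * i, "A", "T", 0.32)
                 for i in range(1, 11)]
        detected = {("c1", 10 * i, "T") for i in range(1, 5)}
        bins = sensitivity_by_vaf(truth, detected)
        (b,) = [b for b in bins if b["n_truth"]]
        assert b["sensitivity"] == pytest.approx(0.4)

    def test_invalid_vaf_rejected(self):
        truth = [somatic_truth("c1", 10, "A", "T", 0.4)]
        object.__setattr__(truth[0], "true_vaf", 1.5)
        with pytest.raises(ValueError):
            sensitivity_by_vaf(truth, set())
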