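"""Center-point matching, metric family, exact paired statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

from polypnet.evaluation import (
    ConfusionMatrix2x2,
    binomial_ci,
    compute_metrics,
    image_level_accuracy,
    match_by_center,
    mcnemar_exact,
    npv,
    paired_table,
    roc_auc,
    stratify_by_area,
)
from polypnet.imaging import AnnotatedImage, BBox

# the two clinical test-set confusion matrices (neoplastic positive)
CM_WL = ConfusionMatrix2x2(tp=110, fn=14, fp=36, tn=20)
CM_NBI = ConfusionMatrix2x2(tp=118, fn=6, fp=25, tn=31)


class TestMatchByCenter:
    def test_centered_hit(self):
        out = match_by_center([BBox(10, 10, 20, 20)], [BBox(5, 5, 40, 40)])
        assert (out.tp, out.fp, out.fn) == (1, 0, 0)

    def test_no_predictions_is_one_false_negative(self):
        out = match_by_center([], [BBox(5, 5, 40, 40)])
        assert (out.tp, out.fp, out.fn) == (0, 0, 1)

    def test_miss_is_false_positive_without_false_negative(self):
        """A prediction exists but misses: FP, and under the image-level
        rule no FN is charged (FN means no box appeared at all)."""
        out = match_by_center([BBox(100, 100, 10, 10)], [BBox(5, 5, 20, 20)])
        assert (out.tp, out.fp, out.fn) == (0, 1, 0)

    def test_per_gt_mode_counts_unhit_boxes(self):
        out = match_by_center(
            [BBox(6, 6, 4, 4)], [BBox(5, 5, 10, 10), BBox(50, 50, 10, 10)], fn_mode="per_gt"
        )
        assert (out.tp, out.fp, out.fn) == (1, 0, 1)

    def test_edge_center_counts_as_inside(self):
        # prediction center (10, 15) lies exactly on the GT's left edge
        out = match_by_center([BBox(5, 10, 10, 10)], [BBox(10, 5, 30, 30)])
        assert out.tp == 1

    def test_matches_brute_force_scan(self, rng):
        for _ in range(200):
            preds = [
                BBox(int(rng.integers(0, 600)), int(rng.integers(0, 440)), int(rng.integers(1, 40)), int(rng.integers(1, 40)))
                for _ in range(int(rng.integers(0, 4)))
            ]
            gts = [
                BBox(int(rng.integers(0, 600)), int(rng.integers(0, 440)), int(rng.integers(1, 40)), int(rng.integers(1, 40)))
                for _ in range(int(rng.integers(0, 3)))
            ]
            out = match_by_center(preds, gts)
            tp = sum(
                1
                for p in preds
                if any(
                    g.x_min <= p.x_min + p.width / 2 <= g.x_min + g.width
                    and g.y_min <= p.y_min + p.height / 2 <= g.y_min + g.height
                    for g in gts
                )
            )
            assert out.tp == tp
            assert out.fp == len(preds) - tp
            assert out.fn == (1 if gts and not preds else 0)


class TestImageLevelAccuracy:
    @pytest.mark.parametrize(
        "detected,total,expected",
        [(859, 900, 95.4), (1712, 1800, 95.1), (843, 900, 93.7), (850, 900, 94.4)],
    )
    def test_clinical_ratios_one_decimal(self, detected, total, expected):
        assert round(image_level_accuracy(detected, total), 1) == expected

    def test_normal_frame_ratio(self):
        # 870/900 clean normal frames = 96.67% (two-decimal reporting)
        assert round(image_level_accuracy(870, 900), 2) == 96.67

    def test_rejects_zero_total(self):
        with pytest.raises(ValueError):
            image_level_accuracy(0, 0)

    def test_boolean_sequence_form(self):
        assert image_level_accuracy([True, True, False, True]) == 75.0


class TestMetrics:
    def test_wl_confusion_matrix_row(self):
        assert compute_metrics(CM_WL).as_dict() == {
            "accuracy": 72.2,
            "precision": 75.3,
            "recall": 88.7,
            "f1": 81.5,
            "f2": 85.7,
        }

    def test_nbi_confusion_matrix_row(self):
        assert compute_metrics(CM_NBI).as_dict() == {
            "accuracy": 82.8,
            "precision": 82.5,
            "recall": 95.2,
            "f1": 88.4,
            "f2": 92.3,
        }

    def test_perfect_matrix_all_hundred(self):
        rep = compute_metrics(ConfusionMatrix2x2(tp=50, fn=0, fp=0, tn=0))
        assert set(rep.as_dict().values()) == {100.0}

    def test_f_measures_lie_between_precision_and_recall(self, rng):
        for _ in range(50):
            cm = ConfusionMatrix2x2(*(int(v) for v in rng.integers(1, 200, size=4)))
            rep = compute_metrics(cm)
            lo, hi = min(rep.precision, rep.recall), max(rep.precision, rep.recall)
            assert lo - 0.1 <= rep.f1 <= hi + 0.1
            assert lo - 0.1 <= rep.f2 <= hi + 0.1

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(ConfusionMatrix2x2(0, 0, 0, 0))


class TestNPV:
    def test_clinical_values(self):
        assert npv(CM_NBI) == 84  # 31/37
        assert npv(ConfusionMatrix2x2(tp=118, fn=3, fp=25, tn=31)) == 91  # 31/34

    def test_no_false_negatives_gives_hundred(self):
        assert npv(ConfusionMatrix2x2(tp=5, fn=0, fp=2, tn=9)) == 100

    def test_undefined_when_no_negative_calls(self):
        with pytest.raises(ValueError):
            npv(ConfusionMatrix2x2(tp=5, fn=0, fp=2, tn=0))


class TestMcNemar:
    def test_published_discordant_pairs(self):
        assert mcnemar_exact(0, 3) == pytest.approx(0.25)
        assert mcnemar_exact(0, 16) < 0.001
        assert mcnemar_exact(0, 19) < 0.001

    def test_no_discordance_gives_one(self):
        assert mcnemar_exact(0, 0) == 1.0

    @given(st.integers(0, 200), st.integers(0, 200))
    @settings(max_examples=100, derandomize=True)
    def test_symmetric_and_bounded(self, a, b):
        p = mcnemar_exact(a, b)
        assert p == mcnemar_exact(b, a)
        assert 0.0 < p <= 1.0

    @given(st.integers(0, 100), st.integers(1, 100))
    @settings(max_examples=60, derandomize=True)
    def test_more_balanced_discordance_is_less_significant(self, k, extra):
        """Moving the split toward balance at fixed total never lowers p."""
        n = 2 * k + extra
        assert mcnemar_exact(k, n - k) <= mcnemar_exact(k + extra // 2, n - k - extra // 2) + 1e-12

    def test_matches_reference_exact_test(self):
        """Cross-check against the independent exact McNemar implementation
        for every discordant split with a + b <= 20."""
        for n in range(1, 21):
            for a in range(n + 1):
                b = n - a
                table = [[0, a], [b, 0]]
                expected = float(sm_mcnemar(table, exact=True).pvalue)
                assert mcnemar_exact(a, b) == pytest.approx(expected, abs=1e-12)


class TestBinomialCI:
    def test_published_intervals(self):
        assert binomial_ci(859, 900) == (93.9, 96.7)
        assert binomial_ci(843, 900) == (91.9, 95.2)

    def test_zero_successes_lower_bound(self):
        for n in (5, 50, 900):
            assert binomial_ci(0, n)[0] == 0.0

    def test_wilson_differs_at_upper_endpoint(self):
        # Wilson gives 95.1 where the exact interval gives 95.2
        assert binomial_ci(843, 900, method="wilson") == (91.9, 95.1)

    def test_coverage_at_clinical_operating_point(self):
        """Empirical coverage of the exact interval over 2000 simulated
        binomial draws at n=900, p=0.95 stays at or above nominal."""
        rng = np.random.default_rng(2024)
        n, p = 900, 0.95
        draws = rng.binomial(n, p, size=2000)
        covered = 0
        for k in draws:
            lo, hi = binomial_ci(int(k), n)
            covered += lo <= 100 * p <= hi
        assert covered / 2000 >= 0.94


class TestPairedTable:
    def test_identical_outcomes_no_discordants(self):
        t = paired_table([True, False, True], [True, False, True])
        assert (t.only_a, t.only_b) == (0, 0)
        assert t.mcnemar_p == 1.0

    def test_disjoint_outcomes(self):
        t = paired_table([True] * 5, [False] * 5)
        assert t.only_a == 5 and t.both == 0

    def test_matches_brute_force_counts(self, rng):
        a = rng.random(200) < 0.7
        b = rng.random(200) < 0.6
        t = paired_table(a, b)
        assert t.both == int((a & b).sum())
        assert t.only_a == int((a & ~b).sum())
        assert t.only_b == int((~a & b).sum())
        assert t.neither == int((~a & ~b).sum())
        assert t.n == 200


class TestAUC:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_chance_level_on_independent_scores(self, rng):
        scores = rng.random(4000)
        labels = (rng.random(4000) < 0.5).astype(int)
        assert abs(roc_auc(scores, labels) - 0.5) < 0.03

    def test_matches_concordant_pair_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(6, 40))
            scores = np.round(rng.random(n), 2)  # induce ties
            labels = (rng.random(n) < 0.5).astype(int)
            if labels.min() == labels.max():
                continue
            num = den = 0.0
            for i in np.nonzero(labels == 1)[0]:
                for j in np.nonzero(labels == 0)[0]:
                    den += 1
                    if scores[i] > scores[j]:
                        num += 1
                    elif scores[i] == scores[j]:
                        num += 0.5
            assert roc_auc(scores, labels) == pytest.approx(num / den)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.5, 0.6], [1, 1])


class TestStratifyByArea:
    def _rec(self, w, h):
        return AnnotatedImage("x.tif", 640, 480, gt_boxes=[BBox(0, 0, w, h)])

    def test_boundary_is_inclusive_above(self):
        below, above = stratify_by_area([self._rec(40, 40)], 1600)
        assert not below and len(above) == 1  # 1600 px is not "less than 1600"

    def test_just_below_threshold(self):
        below, above = stratify_by_area([self._rec(39, 41)], 1600)  # 1599 px
        assert len(below) == 1 and not above

    def test_sub1800_exclusion_feeds_the_npv_reanalysis(self):
        """Dropping the three sub-1800 px false negatives from the NBI
        matrix moves NPV from 84% (31/37) to 91% (31/34)."""
        cm_after = ConfusionMatrix2x2(tp=CM_NBI.tp, fn=CM_NBI.fn - 3, fp=CM_NBI.fp, tn=CM_NBI.tn)
        assert npv(CM_NBI) == 84
        assert npv(cm_after) == 91

    def test_record_without_boxes_rejected(self):
        rec = AnnotatedImage("y.tif", 640, 480, gt_boxes=[])
        with pytest.raises(ValueError):
            stratify_by_area([rec], 1600)
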