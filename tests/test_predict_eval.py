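"""Predictor routing/thresholding and the evaluation/report machinery."""

import numpy as np
import pandas as pd
import pytest

from sorfclass.core_io import SorfRecord, SorfTable
from sorfclass.model import ModelError
from sorfclass.predict_eval import (
    CLASSIFIER_NAME,
    DEFAULT_CUTOFFS,
    MetricCutoff,
    MetricReport,
    PredictionError,
    PredictionRow,
    benchmark_confusion,
    class_positivity_report,
    confusion_metrics,
    evaluate_harness,
    metric_calls,
    overlap_counts,
    predict,
    roc_points,
)


def make_record(n_codons, rec_id="r", label=None):
    return SorfRecord(rec_id, "A" * 100, "ATG" + "GCA" * n_codons + "TAA",
                      label=label)


@pytest.fixture(scope="module")
def cp_models(study_suite):
    models, _, _ = study_suite
    return {m.window_size: m for name, m in models.items() if name.startswith("CP")}


class TestPredict:
    def test_longest_window_routing(self, cp_models, study_suite):
        _, splits, _ = study_suite
        rec = make_record(98)  # 300-nt ORF
        rows, excl = predict([rec], cp_models)
        assert excl == [] and rows[0].window_used == 180

    def test_short_record_routed_to_small_window(self, cp_models):
        rows, _ = predict([make_record(20)], cp_models)  # 66-nt ORF
        assert rows[0].window_used == 54

    def test_score_equal_to_threshold_is_noncoding(self):
        row = PredictionRow("x", 99, score=0.5, call=True, threshold_used=0.5)
        assert row.call is False  # strictly-greater-than rule

    def test_threshold_monotonicity(self, cp_models, study_suite):
        _, splits, _ = study_suite
        records = splits["test"][:100]
        low, _ = predict(records, cp_models, threshold=0.5)
        high, _ = predict(records, cp_models, threshold=0.9)
        assert sum(r.call for r in high) <= sum(r.call for r in low)

    def test_heldout_records_scored_on_correct_side(self, cp_models, study_suite):
        """Scores must reflect the model's feature scaling: held-out coding
        records score high, non-coding records low."""
        _, splits, _ = study_suite
        pos = [r for r in splits["test"] if r.label == "coding"][:100]
        neg = [r for r in splits["test"] if r.label == "noncoding"][:100]
        pos_rows, _ = predict(pos, cp_models)
        neg_rows, _ = predict(neg, cp_models)
        assert np.mean([r.call for r in pos_rows]) > 0.8
        assert np.mean([r.call for r in neg_rows]) < 0.2

    def test_too_short_record_excluded_with_report(self, cp_models):
        rows, excl = predict([make_record(10, "tiny")], cp_models)
        assert rows == [] and excl[0].id == "tiny"

    def test_longest_available_model_window_used(self, cp_models):
        partial = {54: cp_models[54]}
        rows, _ = predict([make_record(98)], partial)  # 300-nt ORF
        assert rows[0].window_used == 54

    def test_missing_fixed_window_model_reports_count(self, cp_models):
        from sorfclass.features import FeatureConfig

        partial = {54: cp_models[54]}
        config = FeatureConfig(feature_set="cp", cc_window=180,
                               frequency_normalized=False)
        with pytest.raises(PredictionError, match=r"180 nt \(1 record\(s\)\)"):
            predict([make_record(98)], partial, config)


class TestConfusionMetrics:
    def test_hand_computed_quadruple(self):
        report = MetricReport(TP=3, FP=1, TN=5, FN=1)
        assert report.precision == 0.75
        assert report.sensitivity == 0.75
        assert report.specificity == pytest.approx(5 / 6)
        assert report.accuracy == 0.8

    def test_all_correct(self):
        rows = [PredictionRow(f"r{i}", 54, s, s > 0.5, 0.5)
                for i, s in enumerate([0.9, 0.9, 0.1, 0.1])]
        truth = {"r0": "coding", "r1": "coding", "r2": "noncoding", "r3": "noncoding"}
        report = confusion_metrics(rows, truth)
        assert (report.precision, report.sensitivity,
                report.specificity, report.accuracy) == (1.0, 1.0, 1.0, 1.0)

    def test_zero_predicted_positive_precision_is_null(self):
        rows = [PredictionRow("a", 54, 0.1, False, 0.5)]
        report = confusion_metrics(rows, {"a": "coding"})
        assert report.precision is None

    def test_unlabeled_id_rejected(self):
        rows = [PredictionRow("a", 54, 0.9, True, 0.5)]
        with pytest.raises(ValueError, match="truth label"):
            confusion_metrics(rows, {})


class TestRoc:
    def test_perfect_separation(self):
        scores = [0.9, 0.8, 0.2, 0.1]
        _, auc = roc_points(scores, [1, 1, 0, 0])
        assert auc == 1.0

    def test_null_scores_auc_near_half(self, rng):
        scores = rng.random(10_000)
        labels = rng.integers(0, 2, 10_000)
        _, auc = roc_points(scores, labels)
        assert 0.48 <= auc <= 0.52

    def test_score_reversal_symmetry(self, rng):
        scores = rng.random(500)
        labels = rng.integers(0, 2, 500)
        _, auc = roc_points(scores, labels)
        _, auc_rev = roc_points(-scores, labels)
        assert auc_rev == pytest.approx(1.0 - auc)

    def test_endpoints(self, rng):
        points, _ = roc_points(rng.random(50), [0, 1] * 25)
        assert points[0] == (0.0, 0.0) and points[-1] == (1.0, 1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_points([0.1, 0.9], [1, 1])


class TestHarness:
    def test_empty_threshold_list_rejected(self, study_suite):
        models, splits, _ = study_suite
        with pytest.raises(ValueError, match="empty threshold"):
            evaluate_harness(models, splits["test"][:5], splits["test"][-5:],
                             thresholds=[])

    def test_training_overlap_rejected(self, study_suite):
        models, splits, _ = study_suite
        pos = [r for r in splits["train"] if r.label == "coding"][:20]
        neg = [r for r in splits["train"] if r.label == "noncoding"][:20]
        with pytest.raises(ModelError, match="overlaps training"):
            evaluate_harness(models, pos, neg)

    def test_report_rows_per_model_and_threshold(self, study_suite):
        models, splits, _ = study_suite
        pos = [r for r in splits["test"] if r.label == "coding"][:50]
        neg = [r for r in splits["test"] if r.label == "noncoding"][:50]
        table = evaluate_harness(models, pos, neg, thresholds=[0.5, 0.9])
        assert len(table) == len(models) * 2
        assert set(table["model"]) == set(models)


def toy_table():
    rows = []
    for i in range(4):
        rows.append({"id": f"e{i}", "sequence": "ATGGCATAA", "upstream": "ACGTACG",
                     "annotation_class": "ensembl_sORF",
                     "FLOSS": 0.1, "ORFscore": 8.0, "PhyloP": 2.0, "PhastCon": 0.9})
    for i in range(6):
        rows.append({"id": f"i{i}", "sequence": "ATGAAATAA", "upstream": "ACGTACG",
                     "annotation_class": "intronic",
                     "FLOSS": 0.9, "ORFscore": 1.0, "PhyloP": 0.1, "PhastCon": 0.1})
    return SorfTable(pd.DataFrame(rows))


class TestClassPositivity:
    def test_counts_and_percentages(self):
        table = toy_table()
        calls = {f"e{i}": i < 3 for i in range(4)}  # 3 of 4 positive
        calls.update({f"i{i}": False for i in range(6)})
        report = class_positivity_report(table, calls)
        cell = report[(report.annotation_class == "ensembl_sORF")
                      & (report.metric == CLASSIFIER_NAME)].iloc[0]
        assert cell.n_positive == 3 and cell.n_total == 4
        assert cell.percent_positive == 75.0

    def test_percentages_recompute_from_counts(self):
        report = class_positivity_report(toy_table(), {})
        for row in report.itertuples():
            if row.n_total:
                assert row.percent_positive == pytest.approx(
                    100.0 * row.n_positive / row.n_total
                )

    def test_all_null_metric_reported_na(self):
        table = toy_table()
        table.frame["FLOSS"] = np.nan
        report = class_positivity_report(table, {})
        floss = report[report.metric == "FLOSS"]
        assert (floss.n_total == 0).all()
        assert floss.percent_positive.isna().all()

    def test_unknown_metric_in_cutoffs_rejected(self):
        with pytest.raises(ValueError, match="unknown metric"):
            class_positivity_report(toy_table(), {}, {"BOGUS": MetricCutoff(1.0)})


class TestOverlapCounts:
    @staticmethod
    def calls_frame(calls_by_metric, ids):
        df = pd.DataFrame(index=range(len(ids)))
        for metric, positives in calls_by_metric.items():
            df[metric] = pd.array([i in positives for i in ids], dtype="boolean")
        return df

    def test_two_metric_hand_enumeration(self):
        table = toy_table()
        calls = self.calls_frame({"A_": {1, 2}, "B_": {2, 3}}, [1, 2, 3])
        calls.columns = ["FLOSS", "ORFscore"]
        regions = overlap_counts(table, calls, ["FLOSS", "ORFscore"])
        assert regions == {
            frozenset({"FLOSS"}): 1,
            frozenset({"ORFscore"}): 1,
            frozenset({"FLOSS", "ORFscore"}): 1,
        }

    def test_identical_call_sets_mass_in_full_intersection(self):
        table = toy_table()
        calls = self.calls_frame({"FLOSS": {1, 2}, "ORFscore": {1, 2}}, [1, 2, 3])
        regions = overlap_counts(table, calls, ["FLOSS", "ORFscore"])
        assert regions == {frozenset({"FLOSS", "ORFscore"}): 2}

    def test_disjoint_sets_no_intersection_region(self):
        table = toy_table()
        calls = self.calls_frame({"FLOSS": {1}, "ORFscore": {2}}, [1, 2])
        regions = overlap_counts(table, calls, ["FLOSS", "ORFscore"])
        assert frozenset({"FLOSS", "ORFscore"}) not in regions

    def test_regions_partition_positive_anywhere_set(self):
        table = toy_table()
        calls = metric_calls(table, DEFAULT_CUTOFFS)
        regions = overlap_counts(table, calls, ["FLOSS", "ORFscore", "PhyloP"])
        positive_anywhere = (
            calls[["FLOSS", "ORFscore", "PhyloP"]].fillna(False).any(axis=1).sum()
        )
        assert sum(regions.values()) == positive_anywhere

    def test_subset_size_bounds(self):
        table = toy_table()
        calls = metric_calls(table, DEFAULT_CUTOFFS)
        with pytest.raises(ValueError, match="between 2 and 5"):
            overlap_counts(table, calls, ["FLOSS"])


class TestBenchmarkConfusion:
    def test_toy_confusion_arithmetic(self):
        table = toy_table()
        ids = list(table.frame["id"])
        calls = pd.DataFrame(
            {"FLOSS": pd.array(
                [i in {"e0", "e1", "e2", "i0"} for i in ids], dtype="boolean"
            )}
        )
        reports = benchmark_confusion(table, calls)
        r = reports["FLOSS"]
        assert (r.TP, r.FP, r.TN, r.FN) == (3, 1, 5, 1)
        assert r.accuracy == 0.8 and r.precision == 0.75

    def test_call_everything_positive(self):
        table = toy_table()
        calls = pd.DataFrame({"PhyloP": pd.array([True] * 10, dtype="boolean")})
        r = benchmark_confusion(table, calls)["PhyloP"]
        assert r.sensitivity == 1.0 and r.specificity == 0.0

    def test_call_nothing_positive_precision_null(self):
        table = toy_table()
        calls = pd.DataFrame({"PhyloP": pd.array([False] * 10, dtype="boolean")})
        assert benchmark_confusion(table, calls)["PhyloP"].precision is None

    def test_missing_class_rejected(self):
        table = toy_table()
        table.frame.loc[:, "annotation_class"] = "intronic"
        calls = pd.DataFrame({"PhyloP": pd.array([True] * 10, dtype="boolean")})
        with pytest.raises(ValueError, match="ensembl_sORF"):
            benchmark_confusion(table, calls)
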