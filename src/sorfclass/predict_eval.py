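"""End-user prediction and the evaluation/reporting layer.

The predictor auto-selects the longest coding-composition window a
record supports (54, 99 or 180 nt), routes the record to the model
trained for that window, and thresholds the calibrated score — strictly
greater than the threshold counts as coding, so ties go to non-coding.

Reporting covers confusion metrics and ROC curves, a balanced/unbalanced
evaluation harness over the feature-configuration suite, per-annotation-
class positivity tables, multi-metric overlap (Venn region) counts, and
positive-vs-negative-class confusion benchmarking against external
metrics (FLOSS, ORFscore, PhyloP, PhastCon) consumed as pre-computed
columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _auc
from sklearn.metrics import roc_curve as _roc_curve

from .core_io import Rejection, SorfRecord, SorfTable, METRIC_NAMES
from .features import (
    AUTO,
    FeatureConfig,
    FeatureError,
    assemble_features,
    select_cc_window,
)
from .model import ModelError, TrainedModel, labels_of, record_hashes, score_matrix
from .features import feature_matrix

DEFAULT_THRESHOLD = 0.5
HIGH_PRECISION_THRESHOLD = 0.9


class PredictionError(RuntimeError):
    pass


@dataclass(frozen=True)
class PredictionRow:
    id: str
    window_used: int
    score: float
    call: bool
    threshold_used: float

    def __post_init__(self):
        object.__setattr__(self, "call", self.score > self.threshold_used)


@dataclass(frozen=True)
class MetricReport:
    """Confusion counts and the derived ratio metrics.

    Ratios with empty denominators are None (unknown), never zero.
    """

    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    @property
    def precision(self) -> Optional[float]:
        d = self.TP + self.FP
        return self.TP / d if d else None

    @property
    def sensitivity(self) -> Optional[float]:
        d = self.TP + self.FN
        return self.TP / d if d else None

    @property
    def specificity(self) -> Optional[float]:
        d = self.TN + self.FP
        return self.TN / d if d else None

    @property
    def accuracy(self) -> Optional[float]:
        return (self.TP + self.TN) / self.total if self.total else None

    def as_dict(self) -> dict:
        return {
            "TP": self.TP, "FP": self.FP, "TN": self.TN, "FN": self.FN,
            "precision": self.precision, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "accuracy": self.accuracy,
        }


def predict(
    records: Sequence[SorfRecord],
    models: Mapping[int, TrainedModel],
    config: Optional[FeatureConfig] = None,
    threshold: float = DEFAULT_THRESHOLD,
) -> tuple[list[PredictionRow], list[Rejection]]:
    """Score records with per-window models.

    Window selection is automatic (longest fitting) unless ``config``
    pins a size; the signal-peptide skip defaults off at prediction.
    Records failing feature extraction land in the exclusion report.  A
    missing model for a needed window raises, naming the affected record
    count.
    """
    import dataclasses

    config = config or FeatureConfig(feature_set="cp", cc_window=AUTO)
    skip = config.skip_signal_peptide
    # assembly always follows the model's own feature configuration
    # (feature set, count vs frequency scaling); the caller controls only
    # the window pinning and the signal-peptide skip
    assembly = {
        w: dataclasses.replace(
            m.feature_config, cc_window=w, skip_signal_peptide=skip
        )
        for w, m in models.items()
    }
    available_windows = sorted(models, reverse=True)
    by_window: dict[int, list[tuple[SorfRecord, object]]] = {}
    exclusions: list[Rejection] = []
    order: list[str] = []
    missing: dict[int, int] = {}
    for rec in records:
        if config.cc_window == AUTO:
            # longest window, among the models supplied, that the record fits
            window = None
            for w in available_windows:
                try:
                    select_cc_window(rec, assembly[w])
                except FeatureError:
                    continue
                window = w
                break
            if window is None:
                exclusions.append(Rejection(
                    rec.id,
                    "sORF too short for the smallest available model window",
                ))
                continue
        else:
            window = int(config.cc_window)
            if window not in models:
                missing[window] = missing.get(window, 0) + 1
                continue
        fv = assemble_features(rec, assembly[window])
        by_window.setdefault(window, []).append((rec, fv))
        order.append(rec.id)
    if missing:
        raise PredictionError(
            "no model for window size(s) "
            + ", ".join(f"{w} nt ({n} record(s))" for w, n in sorted(missing.items()))
        )
    rows: dict[str, PredictionRow] = {}
    for window, pairs in by_window.items():
        model = models[window]
        X = np.vstack(
            [fv.values(model.feature_config.feature_set) for _, fv in pairs]
        )
        scores = score_matrix(model, X)
        for (rec, _), s in zip(pairs, scores):
            rows[rec.id] = PredictionRow(
                id=rec.id, window_used=window, score=float(s),
                call=bool(s > threshold), threshold_used=threshold,
            )
    return [rows[i] for i in order], exclusions


def predictions_frame(rows: Sequence[PredictionRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"id": r.id, "window_used": r.window_used, "score": r.score,
          "call": r.call, "threshold_used": r.threshold_used} for r in rows],
        columns=["id", "window_used", "score", "call", "threshold_used"],
    )


def confusion_metrics(
    rows: Sequence[PredictionRow], truth: Mapping[str, str]
) -> MetricReport:
    """Exact confusion counts of calls against coding/noncoding truth."""
    missing = [r.id for r in rows if r.id not in truth]
    if missing:
        raise ValueError(f"no truth label for id(s): {missing[:5]}")
    tp = fp = tn = fn = 0
    for r in rows:
        positive = truth[r.id] == "coding"
        if r.call and positive:
            tp += 1
        elif r.call and not positive:
            fp += 1
        elif not r.call and not positive:
            tn += 1
        else:
            fn += 1
    return MetricReport(tp, fp, tn, fn)


def roc_points(
    scores: Sequence[float], labels: Sequence[int]
) -> tuple[list[tuple[float, float]], float]:
    """ROC curve points (FPR, TPR) at every distinct score threshold,
    plus the trapezoid-rule AUC."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, _ = _roc_curve(labels, np.asarray(scores), drop_intermediate=False)
    return list(zip(fpr.tolist(), tpr.tolist())), float(_auc(fpr, tpr))


def evaluate_harness(
    models: Mapping[str, TrainedModel],
    pos_records: Sequence[SorfRecord],
    neg_records: Sequence[SorfRecord],
    mode: str = "balanced",
    thresholds: Sequence[float] = (DEFAULT_THRESHOLD,),
) -> pd.DataFrame:
    """Evaluate each feature-configuration model on a labeled set.

    Emits one row per (model, threshold) with confusion metrics and AUC,
    mirroring a balanced or deliberately negative-over-represented
    evaluation.  Every evaluation set is fingerprint-checked to be
    disjoint from each model's training data.
    """
    if not list(thresholds):
        raise ValueError("empty threshold list")
    if mode not in ("balanced", "unbalanced"):
        raise ValueError(f"unknown mode {mode!r}")
    records = list(pos_records) + list(neg_records)
    y = labels_of(records)
    rows = []
    for name in models:
        model = models[name]
        X, ids, excl = feature_matrix(records, model.feature_config)
        overlap = record_hashes(records) & model.fingerprint.get(
            "row_hashes", frozenset()
        )
        if overlap:
            raise ModelError(
                f"evaluation set overlaps training data of model {name!r} "
                f"({len(overlap)} example(s))"
            )
        kept = {r.id for r in records} - {e.id for e in excl}
        y_kept = np.array(
            [yy for r, yy in zip(records, y) if r.id in kept]
        )
        scores = score_matrix(model, X)
        _, auc_value = roc_points(scores, y_kept)
        for t in thresholds:
            calls = scores > t
            tp = int(((calls == 1) & (y_kept == 1)).sum())
            fp = int(((calls == 1) & (y_kept == 0)).sum())
            tn = int(((calls == 0) & (y_kept == 0)).sum())
            fn = int(((calls == 0) & (y_kept == 1)).sum())
            report = MetricReport(tp, fp, tn, fn)
            rows.append({
                "model": name, "mode": mode, "threshold": t,
                "n_excluded": len(excl), "auc": auc_value,
                **report.as_dict(),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# external-metric benchmarking reports


@dataclass(frozen=True)
class MetricCutoff:
    """Positivity rule for one external metric: score `direction` cutoff."""

    value: float
    direction: str = "ge"  # "ge": score >= value is positive; "le": <=

    def __post_init__(self):
        if self.direction not in ("ge", "le"):
            raise ValueError("direction must be 'ge' or 'le'")

    def call(self, scores: pd.Series) -> pd.Series:
        if self.direction == "ge":
            return scores >= self.value
        return scores <= self.value


#: Shipping defaults for the external metrics.  These are configuration
#: (conventional reference-usage cut-offs), always user-overridable; a
#: low FLOSS indicates a footprint-length distribution resembling
#: annotated coding sequence, hence the "le" direction.
DEFAULT_CUTOFFS: dict[str, MetricCutoff] = {
    "FLOSS": MetricCutoff(0.28, "le"),
    "ORFscore": MetricCutoff(6.0, "ge"),
    "PhyloP": MetricCutoff(1.0, "ge"),
    "PhastCon": MetricCutoff(0.5, "ge"),
}

CLASSIFIER_NAME = "sorfclass"


def metric_calls(
    table: SorfTable, cutoffs: Mapping[str, MetricCutoff]
) -> pd.DataFrame:
    """Boolean positivity calls per external metric (NaN scores -> NA)."""
    unknown = set(cutoffs) - set(METRIC_NAMES)
    if unknown:
        raise ValueError(f"unknown metric(s) in cutoffs: {sorted(unknown)}")
    calls = pd.DataFrame(index=table.frame.index)
    for metric, cutoff in cutoffs.items():
        if metric not in table.frame.columns:
            continue
        scores = table.frame[metric]
        col = cutoff.call(scores).astype("boolean")
        col[scores.isna()] = pd.NA
        calls[metric] = col
    return calls


def class_positivity_report(
    table: SorfTable,
    classifier_calls: Mapping[str, bool],
    cutoffs: Mapping[str, MetricCutoff] = DEFAULT_CUTOFFS,
) -> pd.DataFrame:
    """Per annotation class x metric: positive count, total, percentage.

    Rows with a null value for a metric leave that metric's denominator;
    a metric with no values in a class reports NA.  Classes with zero
    rows are omitted.  Percentages always recompute exactly from the
    reported counts.
    """
    df = table.frame
    calls = metric_calls(table, cutoffs)
    calls[CLASSIFIER_NAME] = pd.array(
        [classifier_calls.get(i) for i in df["id"]], dtype="boolean"
    )
    out = []
    for cls, idx in df.groupby("annotation_class").groups.items():
        for metric in [CLASSIFIER_NAME, *[m for m in METRIC_NAMES if m in calls]]:
            col = calls.loc[idx, metric]
            n_total = int(col.notna().sum())
            n_pos = int((col == True).sum())  # noqa: E712 - boolean NA semantics
            out.append({
                "annotation_class": cls, "metric": metric,
                "n_positive": n_pos, "n_total": n_total,
                "percent_positive": 100.0 * n_pos / n_total if n_total else None,
            })
    return pd.DataFrame(out)


def overlap_counts(
    table: SorfTable,
    calls: pd.DataFrame,
    metrics: Sequence[str],
) -> dict[frozenset, int]:
    """Venn-region counts of positive calls over a metric subset.

    Rows lacking a value for any metric in the subset are excluded
    first; the remaining positive-anywhere rows are partitioned into the
    2^k - 1 intersection regions keyed by the exact set of metrics that
    called them positive.
    """
    metrics = list(metrics)
    if not 2 <= len(metrics) <= 5:
        raise ValueError("metric subset size must be between 2 and 5")
    missing = [m for m in metrics if m not in calls.columns]
    if missing:
        raise ValueError(f"no calls for metric(s): {missing}")
    sub = calls[metrics]
    complete = sub.dropna()
    regions: dict[frozenset, int] = {}
    for _, row in complete.iterrows():
        members = frozenset(m for m in metrics if bool(row[m]))
        if members:
            regions[members] = regions.get(members, 0) + 1
    return regions


def benchmark_confusion(
    table: SorfTable,
    calls: pd.DataFrame,
    pos_class: str = "ensembl_sORF",
    neg_class: str = "intronic",
) -> dict[str, MetricReport]:
    """Confusion metrics per external metric/classifier, treating one
    annotation class as truth-positive and another as truth-negative
    (all other classes ignored)."""
    df = table.frame
    for cls in (pos_class, neg_class):
        if cls not in set(df["annotation_class"]):
            raise ValueError(f"annotation class {cls!r} absent from table")
    mask = df["annotation_class"].isin([pos_class, neg_class])
    truth = (df.loc[mask, "annotation_class"] == pos_class).to_numpy()
    reports = {}
    for metric in calls.columns:
        col = calls.loc[mask, metric]
        valid = col.notna().to_numpy()
        c = col[valid].astype(bool).to_numpy()
        t = truth[valid]
        reports[metric] = MetricReport(
            TP=int((c & t).sum()), FP=int((c & ~t).sum()),
            TN=int((~c & ~t).sum()), FN=int((~c & t).sum()),
        )
    return reports
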