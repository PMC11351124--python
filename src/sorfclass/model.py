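"""Classifier selection, training, calibration and persistence.

One model is trained per coding-composition window size (54/99/180 nt)
from the same source records, so the predictor can route any sORF to the
model matching the longest window its length supports.  Hyper-parameters
are chosen by exhaustive grid search with stratified 10-fold
cross-validation; the winning configuration is retrained on the full
training split and its decision values are mapped to probabilities with
Platt's sigmoid, fitted on a validation split that is machine-checked
(via per-example fingerprints) to be disjoint from training.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from itertools import product
from typing import Optional, Sequence, Union

import joblib
import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.neighbors import KNeighborsClassifier
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC

from .core_io import SorfRecord
from .datasets import SplitSpec, split_dataset
from .features import FeatureConfig, FeatureVector, feature_matrix

FORMAT_VERSION = 1

LABEL_TO_INT = {"noncoding": 0, "coding": 1}


class ModelError(RuntimeError):
    pass


class RoutingError(ModelError):
    """A feature vector was offered to a model of a different window."""


class ModelFileError(ModelError):
    """Unreadable or version-incompatible model file."""


@dataclass(frozen=True)
class HyperGrid:
    """Exhaustive hyper-parameter grid for one algorithm.

    ``param_grid`` is a list of parameter-name -> candidate-list dicts
    (sklearn convention); the cross product of every dict is searched.
    """

    algorithm: str  # "svm" | "knn" | "rf"
    param_grid: tuple = ()

    def __post_init__(self):
        if self.algorithm not in ("svm", "knn", "rf"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if not self.param_grid or any(
            not block or any(not v for v in block.values())
            for block in self.param_grid
        ):
            raise ValueError("empty hyper-parameter grid")

    def combinations(self) -> list[dict]:
        """All parameter combinations, in a deterministic lexicographic
        order (the grid-search tie-break of last resort)."""
        combos = []
        for block in self.param_grid:
            keys = sorted(block)
            for values in product(*(block[k] for k in keys)):
                combos.append(dict(zip(keys, values)))
        combos.sort(key=_combo_key)
        return combos


def _combo_key(params: dict) -> str:
    return repr(sorted((k, repr(v)) for k, v in params.items()))


def default_grid(algorithm: str) -> HyperGrid:
    """Package-default grids covering kernel/C/gamma (SVM), neighbor
    count/weighting/search (k-NN) and forest size/split criterion/feature
    subsampling (RF)."""
    if algorithm == "svm":
        return HyperGrid("svm", (
            {"kernel": ["linear"], "C": [0.1, 1, 10, 100]},
            {"kernel": ["rbf"], "C": [0.1, 1, 10, 100],
             "gamma": ["scale", 0.01, 0.1, 1]},
        ))
    if algorithm == "knn":
        return HyperGrid("knn", (
            {"n_neighbors": [3, 5, 11, 21], "weights": ["uniform", "distance"],
             "algorithm": ["auto"]},
        ))
    if algorithm == "rf":
        return HyperGrid("rf", (
            {"n_estimators": [100, 300, 500], "criterion": ["gini", "entropy"],
             "max_features": ["sqrt", "log2"]},
        ))
    raise ValueError(f"unknown algorithm {algorithm!r}")


def compact_rbf_grid() -> HyperGrid:
    """Small RBF-SVM grid used by the end-to-end harness."""
    return HyperGrid("svm", (
        {"kernel": ["rbf"], "C": [1, 10], "gamma": ["scale", 0.1]},
    ))


def make_estimator(algorithm: str, params: dict, seed: int = 0):
    if algorithm == "svm":
        return SVC(**params, random_state=seed)
    if algorithm == "knn":
        return KNeighborsClassifier(**params)
    if algorithm == "rf":
        return RandomForestClassifier(**params, random_state=seed)
    raise ValueError(f"unknown algorithm {algorithm!r}")


def record_hash(record: SorfRecord) -> str:
    """Content fingerprint of one record (flank + ORF, id-independent)."""
    return hashlib.sha256(f"{record.flank}|{record.orf}".encode()).hexdigest()


def record_hashes(records: Sequence[SorfRecord]) -> frozenset[str]:
    return frozenset(record_hash(r) for r in records)


def _data_hash(hashes: frozenset[str]) -> str:
    return hashlib.sha256("".join(sorted(hashes)).encode()).hexdigest()


@dataclass
class TrainedModel:
    """A fitted, window-specific classifier plus its provenance.

    ``platt`` holds the sigmoid parameters (A, B) of
    P(coding | d) = 1 / (1 + exp(A*d + B)); None until calibration.
    ``fingerprint`` records the training-data hash, the per-example row
    hashes (used to enforce split disjointness), the seed, and the
    cross-validation score of the winning hyper-parameters.
    """

    algorithm: str
    hyperparams: dict
    window_size: int
    feature_config: FeatureConfig
    estimator: object
    platt: Optional[tuple[float, float]] = None
    fingerprint: dict = field(default_factory=dict)

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        if self.algorithm == "svm":
            return np.asarray(self.estimator.decision_function(X), dtype=np.float64)
        idx = int(np.flatnonzero(self.estimator.classes_ == 1)[0])
        return np.asarray(self.estimator.predict_proba(X)[:, idx], dtype=np.float64)


def grid_search(
    X: np.ndarray,
    y: np.ndarray,
    grid: HyperGrid,
    k_folds: int = 10,
    seed: int = 0,
) -> tuple[dict, pd.DataFrame]:
    """Exhaustive cross-validated search over ``grid``.

    Every combination is scored by mean accuracy over stratified
    ``k_folds``-fold CV; the winner maximizes mean accuracy, with ties
    broken by lower CV variance, then lexicographic parameter order.
    Returns (best_params, full CV table).
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("grid search requires both classes present")
    cv = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    rows = []
    for params in grid.combinations():
        est = make_estimator(grid.algorithm, params, seed=seed)
        scores = cross_val_score(est, X, y, cv=cv, scoring="accuracy")
        rows.append(
            {"params": params, "mean_cv_accuracy": scores.mean(),
             "cv_accuracy_std": scores.std()}
        )
    table = pd.DataFrame(rows)
    best_idx = min(
        range(len(rows)),
        key=lambda i: (
            -rows[i]["mean_cv_accuracy"],
            rows[i]["cv_accuracy_std"],
            _combo_key(rows[i]["params"]),
        ),
    )
    return dict(rows[best_idx]["params"]), table


def train_final(
    X: np.ndarray,
    y: np.ndarray,
    algorithm: str,
    hyperparams: dict,
    feature_config: FeatureConfig,
    window_size: int,
    seed: int = 0,
    cv_score: Optional[float] = None,
    training_hashes: frozenset[str] = frozenset(),
) -> TrainedModel:
    """Fit the final (uncalibrated) model and record its fingerprint.

    ``training_hashes`` are record-content fingerprints of the training
    examples; downstream calibration and evaluation use them to enforce
    split disjointness.
    """
    X = np.asarray(X, dtype=np.float64)
    if np.isnan(X).any():
        raise ValueError("feature matrix contains NaN (upstream feature bug)")
    est = make_estimator(algorithm, hyperparams, seed=seed)
    est.fit(X, np.asarray(y))
    rows = frozenset(training_hashes)
    return TrainedModel(
        algorithm=algorithm,
        hyperparams=dict(hyperparams),
        window_size=window_size,
        feature_config=feature_config,
        estimator=est,
        fingerprint={
            "data_hash": _data_hash(rows),
            "row_hashes": rows,
            "seed": seed,
            "cv_score": cv_score,
        },
    )


def calibrate_platt(
    model: TrainedModel,
    X_val: np.ndarray,
    y_val: np.ndarray,
    val_hashes: Optional[frozenset[str]] = None,
) -> TrainedModel:
    """Fit Platt's sigmoid P(coding|d) = 1/(1+exp(A*d+B)) on validation
    decision values.

    The validation set must be disjoint from training, enforced through
    record-content fingerprints when ``val_hashes`` is given (the
    training pipelines always pass them).  Calibrated scores are
    monotone in the raw decision value, so example ranking is unchanged.
    """
    if val_hashes is not None:
        overlap = frozenset(val_hashes) & model.fingerprint.get(
            "row_hashes", frozenset()
        )
        if overlap:
            raise ModelError(
                f"calibration set overlaps the training set "
                f"({len(overlap)} example(s))"
            )
    d = model.decision_values(np.asarray(X_val, dtype=np.float64))
    if np.ptp(d) == 0.0:
        raise ValueError("degenerate calibration input: constant decision values")
    lr = LogisticRegression(C=1e6, solver="lbfgs", max_iter=10_000)
    lr.fit(d[:, None], np.asarray(y_val))
    idx = int(np.flatnonzero(lr.classes_ == 1)[0])
    sign = 1.0 if idx == 1 else -1.0
    A = -sign * float(lr.coef_[0, 0])
    B = -sign * float(lr.intercept_[0])
    return dataclasses.replace(model, platt=(A, B))


def _sigmoid_score(d: np.ndarray, platt: tuple[float, float]) -> np.ndarray:
    A, B = platt
    return 1.0 / (1.0 + np.exp(A * d + B))


def score_matrix(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Calibrated coding probabilities in [0, 1] for a feature matrix."""
    if model.platt is None:
        raise ModelError("model is not calibrated; run calibrate_platt first")
    return _sigmoid_score(model.decision_values(np.asarray(X, dtype=np.float64)),
                          model.platt)


def score(model: TrainedModel, fv: FeatureVector) -> float:
    """Calibrated coding probability of one feature vector."""
    if fv.window_used != model.window_size:
        raise RoutingError(
            f"feature vector was extracted with a {fv.window_used}-nt window "
            f"but the model expects {model.window_size} nt"
        )
    return float(score_matrix(model, fv.values(model.feature_config.feature_set)[None, :])[0])


def save_model(model: TrainedModel, path) -> None:
    """Persist a model as a single-file archive with a metadata block."""
    payload = {
        "format_version": FORMAT_VERSION,
        "metadata": {
            "algorithm": model.algorithm,
            "hyperparams": model.hyperparams,
            "window_size": model.window_size,
            "feature_config": dataclasses.asdict(model.feature_config),
            "platt": model.platt,
            "fingerprint": {
                **{k: v for k, v in model.fingerprint.items() if k != "row_hashes"},
                "row_hashes": sorted(model.fingerprint.get("row_hashes", ())),
            },
        },
        "estimator": model.estimator,
    }
    joblib.dump(payload, path)


def load_model(path) -> TrainedModel:
    try:
        payload = joblib.load(path)
        version = payload["format_version"]
        meta = payload["metadata"]
    except ModelFileError:
        raise
    except Exception as exc:
        raise ModelFileError(f"unreadable model file {path}: {exc}") from exc
    if version != FORMAT_VERSION:
        raise ModelFileError(
            f"model file {path} has format version {version}; "
            f"this build reads version {FORMAT_VERSION}"
        )
    fingerprint = dict(meta["fingerprint"])
    fingerprint["row_hashes"] = frozenset(fingerprint.get("row_hashes", ()))
    platt = meta["platt"]
    return TrainedModel(
        algorithm=meta["algorithm"],
        hyperparams=meta["hyperparams"],
        window_size=meta["window_size"],
        feature_config=FeatureConfig(**meta["feature_config"]),
        estimator=payload["estimator"],
        platt=tuple(platt) if platt is not None else None,
        fingerprint=fingerprint,
    )


# ---------------------------------------------------------------------------
# higher-level training pipelines


def labels_of(records: Sequence[SorfRecord]) -> np.ndarray:
    return np.array([LABEL_TO_INT[r.label] for r in records], dtype=int)


def train_calibrated_model(
    splits: dict[str, list[SorfRecord]],
    feature_config: FeatureConfig,
    grid: Optional[HyperGrid] = None,
    k_folds: int = 10,
    seed: int = 0,
) -> tuple[TrainedModel, dict]:
    """Grid search on the train split, retrain, calibrate on validation.

    ``feature_config.cc_window`` must be a fixed size (one model per
    window).  Returns the calibrated model and an info dict with the CV
    table and chosen hyper-parameters.
    """
    if feature_config.cc_window == "auto":
        raise ValueError("training requires a fixed cc_window per model")
    grid = grid or compact_rbf_grid()
    X_tr, _, excl_tr = feature_matrix(splits["train"], feature_config)
    X_va, _, excl_va = feature_matrix(splits["validation"], feature_config)
    kept_tr = [r for r in splits["train"] if r.id not in {e.id for e in excl_tr}]
    kept_va = [r for r in splits["validation"]
               if r.id not in {e.id for e in excl_va}]
    y_tr = labels_of(kept_tr)
    y_va = labels_of(kept_va)
    best, table = grid_search(X_tr, y_tr, grid, k_folds=k_folds, seed=seed)
    cv_score = float(table["mean_cv_accuracy"].max())
    model = train_final(
        X_tr, y_tr, grid.algorithm, best, feature_config,
        window_size=int(feature_config.cc_window), seed=seed, cv_score=cv_score,
        training_hashes=record_hashes(kept_tr),
    )
    model = calibrate_platt(model, X_va, y_va, val_hashes=record_hashes(kept_va))
    info = {"best_params": best, "cv_table": table, "cv_score": cv_score,
            "n_excluded": len(excl_tr) + len(excl_va)}
    return model, info


FEATURE_SUITE = {
    "TIS": ("tis", 54),
    "CC54": ("cc", 54),
    "CC99": ("cc", 99),
    "CC180": ("cc", 180),
    "CP54": ("cp", 54),
    "CP99": ("cp", 99),
    "CP180": ("cp", 180),
}


def train_feature_suite(
    pos_records: Sequence[SorfRecord],
    neg_records: Sequence[SorfRecord],
    names: Optional[Sequence[str]] = None,
    grid: Optional[HyperGrid] = None,
    split_spec: Optional[SplitSpec] = None,
    skip_signal_peptide: bool = False,
    frequency_normalized: bool = False,
    k_folds: int = 10,
    seed: int = 0,
) -> tuple[dict[str, TrainedModel], dict[str, list[SorfRecord]], pd.DataFrame]:
    """Train the comparison suite of feature configurations.

    The full suite spans TIS alone, each CC window alone, and each
    combined (CP) configuration — seven models from one shared
    train/validation/test split of the pooled records.  Returns
    (models, splits, summary table).

    By default models consume the CC block as in-frame counts rather
    than frequencies: within a fixed-window model the two differ only by
    the constant window/3, but counts share the O(1) scale of the TIS
    bits, so a single isotropic kernel can weigh both feature families
    instead of letting the one-hot block dominate every distance.
    """
    names = list(names) if names is not None else list(FEATURE_SUITE)
    unknown = set(names) - set(FEATURE_SUITE)
    if unknown:
        raise ValueError(f"unknown feature-set name(s): {sorted(unknown)}")
    split_spec = split_spec or SplitSpec(seed=seed)
    splits = split_dataset(list(pos_records) + list(neg_records), split_spec)
    models: dict[str, TrainedModel] = {}
    rows = []
    for name in names:
        feature_set, window = FEATURE_SUITE[name]
        config = FeatureConfig(
            feature_set=feature_set, cc_window=window,
            skip_signal_peptide=skip_signal_peptide,
            frequency_normalized=frequency_normalized,
        )
        models[name], info = train_calibrated_model(
            splits, config, grid=grid, k_folds=k_folds, seed=seed
        )
        rows.append({"name": name, "feature_set": feature_set, "window": window,
                     "cv_accuracy": info["cv_score"],
                     "params": _combo_key(info["best_params"])})
    return models, splits, pd.DataFrame(rows)
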