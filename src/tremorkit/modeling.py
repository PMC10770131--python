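"""Nested cross-validation, classifier registry, weighting, metrics, matching.

Evaluation protocol: subjects are stratified into ``outer_k`` test folds at
the subject level (every segment of an individual stays in one fold, so no
identity confounding).  Within each outer training fold an inner
``inner_k``-fold CV drives a grid search over input source (acceleration,
rotation, both), feature option (manual spectral features vs BOSS), and
classifier (RBF-kernel SVM, gradient-boosted trees, feed-forward network),
maximising balanced accuracy.  The winning setup is refit on the whole
training fold with gender-by-class sample weights and scored on the untouched
test fold, both in full and on a gender-matched random under-sample.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import HistGradientBoostingClassifier
from sklearn.metrics import (
    balanced_accuracy_score,
    f1_score,
    precision_score,
    recall_score,
)
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .feature_matrix import FeatureMatrix
from .features_boss import BossFeaturizer, DEFAULT_WINDOWS
from .features_manual import ManualFeatureConfig, featurize_manual_cohort
from .preprocess import PreprocessConfig, preprocess_session, segment_plan
from .protocol import DEFAULT_PROTOCOL, SENSORS
from .session_io import assemble_channels

logger = logging.getLogger(__name__)

__all__ = [
    "CohortData",
    "build_cohort_data",
    "CVPlan",
    "make_cv_plan",
    "compute_sample_weights",
    "compute_metrics",
    "gender_match_subset",
    "GridPoint",
    "default_grid",
    "make_classifier",
    "fit_classifier",
    "grid_search_inner",
    "evaluate_outer",
    "FoldResult",
    "EvaluationReport",
    "derive_seed",
]


def derive_seed(seed: int, *tags) -> int:
    """Deterministic sub-seed below 2**31 from a master seed and stage tags."""
    digest = hashlib.sha256(":".join([str(seed), *map(str, tags)]).encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


# --- cohort container -------------------------------------------------------

@dataclass
class CohortData:
    """Preprocessed cohort: channel tensors, questionnaire, labels, metadata."""

    subject_ids: list[str]
    labels: np.ndarray      # condition per subject
    genders: np.ndarray
    tensors: list           # ChannelTensor per subject (all selected sensors)
    questionnaire: np.ndarray  # (n, 30)
    manual_features: FeatureMatrix  # stateless per-subject features, precomputed

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def subset(self, idx: np.ndarray) -> "CohortData":
        idx = np.asarray(idx)
        return CohortData(
            [self.subject_ids[i] for i in idx],
            self.labels[idx],
            self.genders[idx],
            [self.tensors[i] for i in idx],
            self.questionnaire[idx],
            FeatureMatrix(
                self.manual_features.values[idx],
                [self.subject_ids[i] for i in idx],
                self.manual_features.columns,
            ),
        )

    def task_subset(self, classes: tuple[str, str]) -> "CohortData":
        mask = np.isin(self.labels, classes)
        return self.subset(np.flatnonzero(mask))


def _select_tensor_sensors(tensor, sensors: tuple[str, ...]):
    from .session_io import ChannelTensor

    mask = np.asarray([s in sensors for s in tensor.sensors])
    return ChannelTensor(
        tensor.subject_id,
        tensor.data[mask],
        [l for l, m in zip(tensor.labels, mask) if m],
        [c for c, m in zip(tensor.categories, mask) if m],
        [s for s, m in zip(tensor.sensors, mask) if m],
    )


def build_cohort_data(
    sessions,
    preprocess_config: PreprocessConfig | None = None,
    protocol=DEFAULT_PROTOCOL,
    manual_config: ManualFeatureConfig | None = None,
) -> CohortData:
    """Run the preprocessing pipeline and cache the stateless manual features."""
    pp = preprocess_config or PreprocessConfig()
    mc = manual_config or ManualFeatureConfig()
    order = segment_plan(protocol, pp.removed_steps, pp.split_long_recordings)
    tensors = []
    for session in sessions:
        segments = preprocess_session(session, pp, protocol)
        tensors.append(assemble_channels(session.subject_id, segments, order, SENSORS))
    manual = featurize_manual_cohort(tensors, mc)
    return CohortData(
        subject_ids=[s.subject_id for s in sessions],
        labels=np.asarray([s.condition for s in sessions]),
        genders=np.asarray([s.gender for s in sessions]),
        tensors=tensors,
        questionnaire=np.vstack([s.questionnaire for s in sessions]),
        manual_features=manual,
    )


# --- CV plan ----------------------------------------------------------------

@dataclass
class CVPlan:
    outer_k: int
    inner_k: int
    seed: int
    assignment: dict[str, int]  # subject_id -> outer test fold

    def fold_indices(self, subject_ids: list[str], fold: int) -> tuple[np.ndarray, np.ndarray]:
        """(train_idx, test_idx) positions for one outer fold."""
        folds = np.asarray([self.assignment[s] for s in subject_ids])
        return np.flatnonzero(folds != fold), np.flatnonzero(folds == fold)


def make_cv_plan(
    subject_ids: list[str],
    labels: np.ndarray,
    outer_k: int = 5,
    inner_k: int = 5,
    seed: int = 0,
) -> CVPlan:
    """Subject-level stratified outer-fold assignment, deterministic under seed."""
    labels = np.asarray(labels)
    values, counts = np.unique(labels, return_counts=True)
    lacking = values[counts < outer_k]
    if lacking.size:
        raise ValueError(
            f"classes {lacking.tolist()} have fewer subjects than outer_k={outer_k}"
        )
    skf = StratifiedKFold(n_splits=outer_k, shuffle=True, random_state=seed)
    assignment: dict[str, int] = {}
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        for i in test_idx:
            assignment[subject_ids[i]] = fold
    return CVPlan(outer_k, inner_k, seed, assignment)


# --- weighting, metrics, matching --------------------------------------------

def compute_sample_weights(labels: np.ndarray, genders: np.ndarray) -> np.ndarray:
    """Weights inversely proportional to gender-by-class group frequencies.

    For group g: w_g = N / (G * n_g) with N subjects, G non-empty groups,
    n_g the group size — so every group carries equal total weight N / G.
    """
    labels = np.asarray(labels)
    genders = np.asarray(genders)
    if labels.size == 0:
        raise ValueError("empty label vector")
    groups = np.char.add(np.char.add(labels.astype(str), "|"), genders.astype(str))
    values, inverse, counts = np.unique(groups, return_inverse=True, return_counts=True)
    n, g = labels.size, values.size
    return n / (g * counts[inverse].astype(float))


def compute_metrics(y_true, y_pred, positive: str = "PD") -> dict[str, float]:
    """Balanced accuracy plus positive-class precision/recall/F1."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if np.unique(y_true).size < 2:
        raise ValueError("balanced accuracy undefined: a class is absent from y_true")
    return {
        "balanced_accuracy": float(balanced_accuracy_score(y_true, y_pred)),
        "precision": float(precision_score(y_true, y_pred, pos_label=positive, zero_division=0)),
        "recall": float(recall_score(y_true, y_pred, pos_label=positive, zero_division=0)),
        "f1": float(f1_score(y_true, y_pred, pos_label=positive, zero_division=0)),
    }


def gender_match_subset(labels, genders, seed: int = 0) -> np.ndarray:
    """Random under-sample equalising the gender mix across the two classes.

    Within each gender, every class cell is down-sampled to the smallest
    class's cell size, so the gender proportion becomes identical across
    classes.  Returns sorted positional indices; deterministic under seed.
    """
    labels = np.asarray(labels)
    genders = np.asarray(genders)
    classes = np.unique(labels)
    rng = np.random.default_rng(seed)
    keep: list[np.ndarray] = []
    for gender in np.unique(genders):
        cells = {}
        for cls in classes:
            cell = np.flatnonzero((labels == cls) & (genders == gender))
            if cell.size == 0:
                raise ValueError(f"empty gender-by-class cell: ({cls}, {gender})")
            cells[cls] = cell
        m = min(c.size for c in cells.values())
        for cls in classes:
            keep.append(rng.choice(cells[cls], size=m, replace=False))
    return np.sort(np.concatenate(keep))


# --- classifier registry ------------------------------------------------------

@dataclass(frozen=True)
class GridPoint:
    """One fully specified pipeline: input source + feature option + classifier."""

    input_source: str        # acceleration | rotation | both
    feature_option: str      # A (manual) | B (BOSS)
    classifier: str          # svm | gbdt | nn
    params: tuple[tuple[str, object], ...] = ()

    def __post_init__(self) -> None:
        if self.input_source not in ("acceleration", "rotation", "both"):
            raise ValueError(f"unknown input source {self.input_source!r}")
        if self.feature_option not in ("A", "B"):
            raise ValueError(f"unknown feature option {self.feature_option!r}")
        if self.classifier not in ("svm", "gbdt", "nn"):
            raise ValueError(f"unknown classifier {self.classifier!r}")

    @property
    def params_dict(self) -> dict:
        return dict(self.params)

    def describe(self) -> str:
        p = ", ".join(f"{k}={v}" for k, v in self.params)
        return f"{self.input_source}/option-{self.feature_option}/{self.classifier}({p})"


def make_classifier(name: str, params: dict, seed: int):
    """Instantiate a probability-capable classifier from the registry."""
    if name == "svm":
        # sigmoid-calibrated SVC provides class probabilities for stacking
        svc = SVC(kernel="rbf", C=params.get("C", 1.0), gamma=params.get("gamma", "scale"))
        return Pipeline([
            ("scale", StandardScaler()),
            ("clf", CalibratedClassifierCV(svc, method="sigmoid", cv=3, ensemble=False)),
        ])
    if name == "gbdt":
        return HistGradientBoostingClassifier(
            random_state=seed,
            max_iter=params.get("max_iter", 100),
            max_depth=params.get("max_depth", None),
            min_samples_leaf=params.get("min_samples_leaf", 5),
        )
    if name == "nn":
        return Pipeline([
            ("scale", StandardScaler()),
            ("clf", MLPClassifier(
                hidden_layer_sizes=params.get("hidden_layer_sizes", (64, 32)),
                activation="relu", max_iter=params.get("max_iter", 400),
                random_state=seed,
            )),
        ])
    raise ValueError(f"unknown classifier {name!r}")


def fit_classifier(estimator, X, y, sample_weight=None):
    """Fit, routing sample weights to learners that accept them.

    The MLP has no per-sample loss weighting, so it is fitted unweighted;
    SVM and gradient-boosted trees receive the weights.
    """
    if sample_weight is None:
        return estimator.fit(X, y)
    if isinstance(estimator, Pipeline):
        final = estimator.steps[-1][1]
        if isinstance(final, MLPClassifier):
            return estimator.fit(X, y)
        return estimator.fit(X, y, **{f"{estimator.steps[-1][0]}__sample_weight": sample_weight})
    return estimator.fit(X, y, sample_weight=sample_weight)


def default_grid(
    sources: tuple[str, ...] = ("acceleration", "rotation", "both"),
    options: tuple[str, ...] = ("A", "B"),
    classifiers: tuple[str, ...] = ("svm", "gbdt"),
    svm_C: tuple[float, ...] = (1.0, 10.0),
) -> list[GridPoint]:
    """Compact default hyperparameter grid (enumeration order = tie-break order)."""
    grid: list[GridPoint] = []
    for source in sources:
        for option in options:
            for clf in classifiers:
                if clf == "svm":
                    for C in svm_C:
                        grid.append(GridPoint(source, option, clf, (("C", C),)))
                else:
                    grid.append(GridPoint(source, option, clf))
    return grid


# --- feature provisioning within folds ---------------------------------------

def _sensors_for(source: str) -> tuple[str, ...]:
    return SENSORS if source == "both" else (source,)


def features_for_point(
    data: CohortData,
    point: GridPoint,
    train_idx: np.ndarray,
    eval_idx: np.ndarray,
    boss_kwargs: dict | None = None,
):
    """(X_train, X_eval, fitted featurizer or None) for one grid point.

    Option A features are stateless per subject, so row slicing of the
    precomputed matrix cannot leak evaluation-fold information.  Option B
    bins are fitted on the training rows only.
    """
    sensors = _sensors_for(point.input_source)
    if point.feature_option == "A":
        fm = data.manual_features.select_sensors(sensors)
        return fm.values[train_idx], fm.values[eval_idx], None
    featurizer = BossFeaturizer(**(boss_kwargs or {}))
    train_tensors = [_select_tensor_sensors(data.tensors[i], sensors) for i in train_idx]
    eval_tensors = [_select_tensor_sensors(data.tensors[i], sensors) for i in eval_idx]
    featurizer.fit(train_tensors)
    X_train = featurizer.transform(train_tensors).values
    X_eval = featurizer.transform(eval_tensors).values if len(eval_idx) else np.empty((0, X_train.shape[1]))
    return X_train, X_eval, featurizer


# --- nested CV ----------------------------------------------------------------

def grid_search_inner(
    data: CohortData,
    train_idx: np.ndarray,
    grid: list[GridPoint],
    inner_k: int = 5,
    seed: int = 0,
    boss_kwargs: dict | None = None,
) -> tuple[GridPoint, dict[GridPoint, float]]:
    """Inner-CV grid search on the training fold only.

    Returns the grid point with the highest mean inner-validation balanced
    accuracy (ties broken by enumeration order) and all mean scores.  Grid
    points that fail to train are skipped with a warning.
    """
    if not grid:
        raise ValueError("empty hyperparameter grid")
    train_idx = np.asarray(train_idx)
    y_train = data.labels[train_idx]
    skf = StratifiedKFold(n_splits=inner_k, shuffle=True, random_state=seed)
    sums = {p: 0.0 for p in grid}
    fails: set[GridPoint] = set()

    # share featurization across classifiers with the same (source, option)
    feature_groups: dict[tuple[str, str], list[GridPoint]] = {}
    for p in grid:
        feature_groups.setdefault((p.input_source, p.feature_option), []).append(p)

    n_splits = 0
    for split_i, (iti, ivi) in enumerate(skf.split(np.zeros(len(train_idx)), y_train)):
        n_splits += 1
        g_tr, g_val = train_idx[iti], train_idx[ivi]
        w_tr = compute_sample_weights(data.labels[g_tr], data.genders[g_tr])
        for (source, option), points in feature_groups.items():
            probe = points[0]
            X_tr, X_val, _ = features_for_point(data, probe, g_tr, g_val, boss_kwargs)
            for p in points:
                try:
                    est = make_classifier(p.classifier, p.params_dict, derive_seed(seed, split_i))
                    fit_classifier(est, X_tr, data.labels[g_tr], w_tr)
                    pred = est.predict(X_val)
                    score = balanced_accuracy_score(data.labels[g_val], pred)
                except Exception as exc:  # noqa: BLE001 - point skipped, logged
                    warnings.warn(f"grid point {p.describe()} failed: {exc}")
                    fails.add(p)
                    continue
                sums[p] += score
                logger.debug("inner split %d: %s -> %.4f", split_i, p.describe(), score)

    means = {p: sums[p] / n_splits for p in grid if p not in fails}
    if not means:
        raise RuntimeError("all grid points failed during the inner search")
    best = max(means, key=lambda p: (means[p], -grid.index(p)))
    logger.info("inner selection: %s (mean balanced accuracy %.4f)", best.describe(), means[best])
    return best, means


@dataclass
class FoldResult:
    fold: int
    setup: GridPoint
    n_test: int
    metrics_full: dict[str, float]
    n_matched: int | None = None
    metrics_matched: dict[str, float] | None = None

    def to_dict(self) -> dict:
        return {
            "fold": self.fold,
            "setup": self.setup.describe(),
            "n_test": self.n_test,
            "metrics_full": self.metrics_full,
            "n_matched": self.n_matched,
            "metrics_matched": self.metrics_matched,
        }


METRIC_NAMES = ("balanced_accuracy", "precision", "recall", "f1")


@dataclass
class EvaluationReport:
    folds: list[FoldResult] = field(default_factory=list)

    def summary(self, matched: bool = False) -> dict[str, tuple[float, float]]:
        """Per-metric (mean, SD) across folds."""
        out = {}
        for m in METRIC_NAMES:
            vals = [
                (f.metrics_matched if matched else f.metrics_full)[m]
                for f in self.folds
                if (f.metrics_matched is not None or not matched)
            ]
            arr = np.asarray(vals, dtype=float)
            out[m] = (float(arr.mean()), float(arr.std(ddof=0))) if arr.size else (np.nan, np.nan)
        return out

    def to_dict(self) -> dict:
        return {
            "folds": [f.to_dict() for f in self.folds],
            "summary_full": {m: list(v) for m, v in self.summary(False).items()},
            "summary_matched": {m: list(v) for m, v in self.summary(True).items()},
        }


def evaluate_outer(
    data: CohortData,
    plan: CVPlan,
    grid: list[GridPoint],
    seed: int = 0,
    positive: str = "PD",
    boss_kwargs: dict | None = None,
) -> EvaluationReport:
    """Full nested-CV evaluation: inner selection, weighted refit, outer scoring."""
    report = EvaluationReport()
    for fold in range(plan.outer_k):
        train_idx, test_idx = plan.fold_indices(data.subject_ids, fold)
        best, _ = grid_search_inner(
            data, train_idx, grid, plan.inner_k, derive_seed(seed, "inner", fold), boss_kwargs
        )
        weights = compute_sample_weights(data.labels[train_idx], data.genders[train_idx])
        X_tr, X_te, _ = features_for_point(data, best, train_idx, test_idx, boss_kwargs)
        est = make_classifier(best.classifier, best.params_dict, derive_seed(seed, "refit", fold))
        fit_classifier(est, X_tr, data.labels[train_idx], weights)
        pred = est.predict(X_te)
        result = FoldResult(
            fold=fold,
            setup=best,
            n_test=len(test_idx),
            metrics_full=compute_metrics(data.labels[test_idx], pred, positive),
        )
        try:
            m_idx = gender_match_subset(
                data.labels[test_idx], data.genders[test_idx],
                derive_seed(seed, "match", fold),
            )
            result.n_matched = len(m_idx)
            result.metrics_matched = compute_metrics(
                data.labels[test_idx][m_idx], pred[m_idx], positive
            )
        except ValueError as exc:
            logger.warning("fold %d: gender matching skipped (%s)", fold, exc)
        report.folds.append(result)
    return report
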