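"""Two-modality classifier stacking with an out-of-fold logistic meta-model.

The sensor sub-model (best input/feature/classifier setup from the inner
grid search) and the questionnaire sub-model (gradient-boosted trees on the
30 raw yes/no answers) each contribute one positive-class probability.  The
logistic meta-classifier is trained on *out-of-fold* sub-model predictions —
each training subject's meta-feature comes from a sub-model that never saw
that subject — then the sub-models are refit on the full training fold for
test-time prediction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import HistGradientBoostingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .modeling import (
    CohortData,
    CVPlan,
    EvaluationReport,
    FoldResult,
    GridPoint,
    compute_metrics,
    compute_sample_weights,
    derive_seed,
    features_for_point,
    fit_classifier,
    gender_match_subset,
    grid_search_inner,
    make_classifier,
)

logger = logging.getLogger(__name__)

__all__ = [
    "StackedModel",
    "fit_stack",
    "predict_stack",
    "evaluate_stacked",
    "stacked_feature_grouping",
    "stacked_importance",
]


@dataclass
class StackedModel:
    sensor_setup: GridPoint
    sensor_model: object
    sensor_featurizer: object | None     # fitted BOSS featurizer for option B
    questionnaire_model: object
    meta: LogisticRegression
    positive: str
    classes_: np.ndarray
    meta_oof_fold: np.ndarray = field(default=None)  # inner fold of each meta row
    boss_kwargs: dict | None = None


def _positive_proba(model, X, positive: str) -> np.ndarray:
    proba = model.predict_proba(X)
    return proba[:, list(model.classes_).index(positive)]


def _sensor_matrix(data: CohortData, model: StackedModel, idx: np.ndarray) -> np.ndarray:
    from .modeling import _select_tensor_sensors, _sensors_for

    if model.sensor_setup.feature_option == "A":
        fm = data.manual_features.select_sensors(_sensors_for(model.sensor_setup.input_source))
        return fm.values[idx]
    sensors = _sensors_for(model.sensor_setup.input_source)
    tensors = [_select_tensor_sensors(data.tensors[i], sensors) for i in idx]
    return model.sensor_featurizer.transform(tensors).values


def fit_stack(
    data: CohortData,
    train_idx: np.ndarray,
    sensor_setup: GridPoint,
    inner_k: int = 5,
    seed: int = 0,
    positive: str = "PD",
    questionnaire_params: dict | None = None,
    boss_kwargs: dict | None = None,
) -> StackedModel:
    """Fit sub-models and the logistic meta-classifier on one training fold."""
    train_idx = np.asarray(train_idx)
    y = data.labels[train_idx]
    weights = compute_sample_weights(y, data.genders[train_idx])
    q_params = questionnaire_params if questionnaire_params is not None else {
        "min_samples_leaf": 5
    }

    if not hasattr(make_classifier(sensor_setup.classifier, sensor_setup.params_dict, 0),
                   "predict_proba"):
        raise ValueError("sensor sub-model must be probability-capable")

    # out-of-fold meta features via the inner CV
    skf = StratifiedKFold(n_splits=inner_k, shuffle=True, random_state=seed)
    meta_X = np.full((len(train_idx), 2), np.nan)
    oof_fold = np.full(len(train_idx), -1)
    for split_i, (iti, ivi) in enumerate(skf.split(np.zeros(len(train_idx)), y)):
        g_tr, g_val = train_idx[iti], train_idx[ivi]
        w_tr = compute_sample_weights(data.labels[g_tr], data.genders[g_tr])

        Xs_tr, Xs_val, _ = features_for_point(data, sensor_setup, g_tr, g_val, boss_kwargs)
        sensor = make_classifier(
            sensor_setup.classifier, sensor_setup.params_dict, derive_seed(seed, "s", split_i)
        )
        fit_classifier(sensor, Xs_tr, data.labels[g_tr], w_tr)
        meta_X[ivi, 0] = _positive_proba(sensor, Xs_val, positive)

        quest = HistGradientBoostingClassifier(
            random_state=derive_seed(seed, "q", split_i), **q_params
        )
        quest.fit(data.questionnaire[g_tr], data.labels[g_tr], sample_weight=w_tr)
        meta_X[ivi, 1] = _positive_proba(quest, data.questionnaire[g_val], positive)
        oof_fold[ivi] = split_i

    assert not np.isnan(meta_X).any(), "every training subject needs an out-of-fold prediction"

    # refit sub-models on the full training fold
    Xs_full, _, featurizer = features_for_point(
        data, sensor_setup, train_idx, np.empty(0, dtype=int), boss_kwargs
    )
    sensor_model = make_classifier(
        sensor_setup.classifier, sensor_setup.params_dict, derive_seed(seed, "s", "full")
    )
    fit_classifier(sensor_model, Xs_full, y, weights)
    quest_model = HistGradientBoostingClassifier(
        random_state=derive_seed(seed, "q", "full"), **q_params
    )
    quest_model.fit(data.questionnaire[train_idx], y, sample_weight=weights)

    # unpenalised: two meta-features only, no need for regularisation
    meta = LogisticRegression(C=np.inf, max_iter=1000)
    meta.fit(meta_X, y, sample_weight=weights)

    return StackedModel(
        sensor_setup=sensor_setup,
        sensor_model=sensor_model,
        sensor_featurizer=featurizer,
        questionnaire_model=quest_model,
        meta=meta,
        positive=positive,
        classes_=meta.classes_,
        meta_oof_fold=oof_fold,
        boss_kwargs=boss_kwargs,
    )


def predict_stack(
    model: StackedModel, data: CohortData, idx: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Final labels and positive-class probabilities for the given subjects."""
    idx = np.asarray(idx)
    Xs = _sensor_matrix(data, model, idx)
    p_sensor = _positive_proba(model.sensor_model, Xs, model.positive)
    p_quest = _positive_proba(
        model.questionnaire_model, data.questionnaire[idx], model.positive
    )
    meta_X = np.column_stack([p_sensor, p_quest])
    labels = model.meta.predict(meta_X)
    proba = _positive_proba(model.meta, meta_X, model.positive)
    return labels, proba


def evaluate_stacked(
    data: CohortData,
    plan: CVPlan,
    grid: list[GridPoint],
    seed: int = 0,
    positive: str = "PD",
    questionnaire_params: dict | None = None,
    boss_kwargs: dict | None = None,
    return_models: bool = False,
):
    """Nested-CV evaluation of the stack and of each modality alone.

    Returns reports keyed ``stacked``, ``sensor``, ``questionnaire``; all
    three score the same outer test folds.  With ``return_models`` the
    per-fold fitted stacks are returned too (for importance analysis).
    """
    reports = {k: EvaluationReport() for k in ("stacked", "sensor", "questionnaire")}
    models: list[StackedModel] = []
    for fold in range(plan.outer_k):
        train_idx, test_idx = plan.fold_indices(data.subject_ids, fold)
        best, _ = grid_search_inner(
            data, train_idx, grid, plan.inner_k, derive_seed(seed, "inner", fold), boss_kwargs
        )
        model = fit_stack(
            data, train_idx, best, plan.inner_k, derive_seed(seed, "stack", fold),
            positive, questionnaire_params, boss_kwargs,
        )
        models.append(model)
        y_test = data.labels[test_idx]
        stacked_pred, _ = predict_stack(model, data, test_idx)
        Xs_test = _sensor_matrix(data, model, test_idx)
        sensor_pred = model.sensor_model.predict(Xs_test)
        quest_pred = model.questionnaire_model.predict(data.questionnaire[test_idx])

        match_seed = derive_seed(seed, "match", fold)
        for key, pred in (
            ("stacked", stacked_pred), ("sensor", sensor_pred), ("questionnaire", quest_pred)
        ):
            result = FoldResult(
                fold=fold, setup=best, n_test=len(test_idx),
                metrics_full=compute_metrics(y_test, pred, positive),
            )
            try:
                m_idx = gender_match_subset(
                    y_test, data.genders[test_idx], match_seed
                )
                result.n_matched = len(m_idx)
                result.metrics_matched = compute_metrics(y_test[m_idx], pred[m_idx], positive)
            except ValueError as exc:
                logger.warning("fold %d (%s): gender matching skipped (%s)", fold, key, exc)
            reports[key].folds.append(result)
    if return_models:
        return reports, models
    return reports


def stacked_feature_grouping(data: CohortData, model: StackedModel, domains=None):
    """Column group labels for the concatenated [sensor | questionnaire] input.

    Sensor feature columns are grouped by their assessment-step task category
    (``"<category> tasks"``), questionnaire columns by symptom domain.
    """
    from .importance import FeatureGrouping, default_pdnms_domains

    if model.sensor_setup.feature_option == "A":
        from .modeling import _sensors_for

        sensor_groups = (
            data.manual_features.select_sensors(_sensors_for(model.sensor_setup.input_source))
            .columns["group"].to_numpy()
        )
    else:
        fz = model.sensor_featurizer
        vocab = fz.base_config.vocabulary_size
        sensor_groups = np.asarray([
            cat for cat in fz.channel_categories_ for _ in range(len(fz.windows) * vocab)
        ])
    labels = [f"{g} tasks" for g in sensor_groups]
    domains = domains or default_pdnms_domains()
    quest_labels = [""] * data.questionnaire.shape[1]
    for name, items in domains.items():
        for i in items:
            quest_labels[i] = name
    labels.extend(quest_labels)
    return FeatureGrouping.from_column_groups(labels), len(sensor_groups)


def stacked_importance(
    data: CohortData,
    model: StackedModel,
    test_idx: np.ndarray,
    n_repeats: int = 50,
    seed: int = 0,
    domains=None,
):
    """Grouped permutation importance of the stacked model on one test fold."""
    from .importance import grouped_permutation_importance

    test_idx = np.asarray(test_idx)
    Xs = _sensor_matrix(data, model, test_idx)
    Xq = data.questionnaire[test_idx].astype(float)
    X = np.hstack([Xs, Xq])
    grouping, d_sensor = stacked_feature_grouping(data, model, domains)

    def predict_fn(Xperm):
        p_s = _positive_proba(model.sensor_model, Xperm[:, :d_sensor], model.positive)
        p_q = _positive_proba(
            model.questionnaire_model, Xperm[:, d_sensor:], model.positive
        )
        return model.meta.predict(np.column_stack([p_s, p_q]))

    return grouped_permutation_importance(
        predict_fn, X, data.labels[test_idx], grouping, n_repeats, seed
    )
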