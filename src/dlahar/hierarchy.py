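"""Two-level hierarchical classification of the 13 daily-life activities.

Level 1 (BASE) discriminates four activity groups and two single
activities:

* HOUSE   — vacuuming (VC), sweeping (SW)
* REST    — sitting (SI), lying (LY), standing (ST)
* WALK    — walking (WK), ascending (AS) / descending (DS) stairs, running (RU)
* BICYCLE — ergometer bicycling at 50 W (BC50) and 100 W (BC100)
* WD, RJ  — washing dishes and rope jumping, routed directly

Level 2 resolves individual activities within each group.  BASE, HOUSE,
WALK and BICYCLE consume the generic 152-feature set; REST consumes the
12-feature gravity set, since orientation alone separates the postures.

Four classifier families are supported, with the method's fixed
hyperparameters: AdaBoost with 100 decision-stump learners (ADA), a Gini
CART tree, kNN with k = 5, and an RBF-kernel SVM with C = 1 and
gamma = 1 / n_features.  Distance/kernel-based classifiers (kNN, SVM) are
preceded by per-feature z-scoring fit on the training portion; trees and
boosting consume raw features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
from sklearn.ensemble import AdaBoostClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .activities import Activity, as_activity
from .errors import ParameterError, TrainingError
from .features import FeatureMatrix

CLASSIFIER_KINDS = ("ADA", "CART", "KNN", "SVM")

#: Activity -> BASE label.  Groups partition their member activities; the
#: two singletons map to themselves.
ROUTING_TABLE: dict[Activity, str] = {
    Activity.VC: "HOUSE",
    Activity.SW: "HOUSE",
    Activity.SI: "REST",
    Activity.LY: "REST",
    Activity.ST: "REST",
    Activity.WK: "WALK",
    Activity.AS: "WALK",
    Activity.DS: "WALK",
    Activity.RU: "WALK",
    Activity.BC50: "BICYCLE",
    Activity.BC100: "BICYCLE",
    Activity.RJ: "RJ",
    Activity.WD: "WD",
}

BASE_LABELS = ("HOUSE", "REST", "WALK", "BICYCLE", "RJ", "WD")
GROUP_MEMBERS: dict[str, tuple[Activity, ...]] = {
    "HOUSE": (Activity.VC, Activity.SW),
    "REST": (Activity.SI, Activity.LY, Activity.ST),
    "WALK": (Activity.WK, Activity.AS, Activity.DS, Activity.RU),
    "BICYCLE": (Activity.BC50, Activity.BC100),
}
SUBSYSTEMS = ("BASE", "HOUSE", "REST", "WALK", "BICYCLE")


def map_to_base_label(activity: Activity | str) -> str:
    """BASE-level label of an activity (group name or singleton)."""
    try:
        act = as_activity(activity)
    except ValueError as exc:
        raise ParameterError(str(exc)) from exc
    return ROUTING_TABLE[act]


@dataclass(frozen=True)
class ClassifierConfig:
    """One classifier family with the method's fixed hyperparameters.

    ``params`` overrides individual hyperparameters; the defaults are the
    published settings and should normally be left alone.
    """

    kind: str
    params: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ParameterError(
                f"kind must be one of {CLASSIFIER_KINDS}, got {self.kind!r}"
            )

    def make_estimator(self, seed: int = 0):
        """Fresh scikit-learn estimator for this configuration."""
        p = dict(self.params)
        if self.kind == "ADA":
            return AdaBoostClassifier(
                estimator=DecisionTreeClassifier(max_depth=1),
                n_estimators=int(p.pop("n_estimators", 100)),
                random_state=seed,
                **p,
            )
        if self.kind == "CART":
            return DecisionTreeClassifier(
                criterion=str(p.pop("criterion", "gini")), random_state=seed, **p
            )
        if self.kind == "KNN":
            return Pipeline(
                [
                    ("scale", StandardScaler()),
                    ("knn", KNeighborsClassifier(n_neighbors=int(p.pop("k", 5)), **p)),
                ]
            )
        # SVM: gamma="auto" is exactly 1 / n_features
        return Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "svm",
                    SVC(
                        C=float(p.pop("C", 1.0)),
                        kernel="rbf",
                        gamma=p.pop("gamma", "auto"),
                        **p,
                    ),
                ),
            ]
        )


#: Per-subsystem best classifiers of the published benchmark evaluation.
DEFAULT_CONFIGS: dict[str, ClassifierConfig] = {
    "BASE": ClassifierConfig("SVM"),
    "HOUSE": ClassifierConfig("ADA"),
    "REST": ClassifierConfig("SVM"),
    "WALK": ClassifierConfig("KNN"),
    "BICYCLE": ClassifierConfig("SVM"),
}

#: Fixed tie-break preference when selecting the best classifier.
_TIE_PRIORITY = {"SVM": 3, "KNN": 2, "ADA": 1, "CART": 0}


@dataclass
class HierarchyModel:
    """Trained BASE model, four trained subsystem models and the routing."""

    base: object
    subsystems: dict[str, object]
    configs: dict[str, ClassifierConfig]
    seed: int = 0


def _subsystem_problem(
    subsystem: str, generic: FeatureMatrix, rest: FeatureMatrix
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(X, y, subject_id) of one subsystem's own classification problem."""
    acts = np.array([str(a) for a in generic.activity])
    if subsystem == "BASE":
        y = np.array([map_to_base_label(a) for a in acts])
        return generic.values, y, np.asarray(generic.subject_id)
    members = {a.value for a in GROUP_MEMBERS[subsystem]}
    mask = np.array([a in members for a in acts])
    fm = rest if subsystem == "REST" else generic
    return fm.values[mask], acts[mask], np.asarray(fm.subject_id)[mask]


def _check_alignment(generic: FeatureMatrix, rest: FeatureMatrix) -> None:
    if generic.set_tag != "GENERIC" or rest.set_tag != "REST":
        raise ParameterError("expected a GENERIC and a REST feature matrix")
    if generic.n_windows != rest.n_windows or not np.array_equal(
        np.asarray(generic.activity), np.asarray(rest.activity)
    ):
        raise ParameterError(
            "GENERIC and REST matrices must describe the same windows in order"
        )


def train_hierarchy(
    generic: FeatureMatrix,
    rest: FeatureMatrix,
    configs: Mapping[str, ClassifierConfig] | None = None,
    seed: int = 0,
) -> HierarchyModel:
    """Train BASE and the four group subsystems.

    BASE sees every window with its group/singleton label; each group
    subsystem sees only the windows of its member activities.  A subsystem
    whose training data contains fewer than two of its classes raises
    :class:`TrainingError` naming the subsystem.
    """
    _check_alignment(generic, rest)
    cfgs = dict(DEFAULT_CONFIGS)
    if configs:
        cfgs.update(configs)

    models: dict[str, object] = {}
    for subsystem in SUBSYSTEMS:
        X, y, _ = _subsystem_problem(subsystem, generic, rest)
        if len(np.unique(y)) < 2:
            raise TrainingError(
                f"subsystem {subsystem} needs >= 2 classes in training data, "
                f"got {sorted(set(y))}"
            )
        est = cfgs[subsystem].make_estimator(seed)
        est.fit(X, y)
        models[subsystem] = est

    return HierarchyModel(
        base=models["BASE"],
        subsystems={k: models[k] for k in GROUP_MEMBERS},
        configs=cfgs,
        seed=seed,
    )


def predict_hierarchy(
    model: HierarchyModel, generic: FeatureMatrix, rest: FeatureMatrix
) -> np.ndarray:
    """Two-stage prediction; always returns one of the 13 activity labels.

    BASE routes each window; singleton labels are final, group labels are
    resolved by the corresponding subsystem.  A misrouted window receives
    the forced prediction of the (wrong) subsystem.
    """
    _check_alignment(generic, rest)
    base_pred = np.asarray(model.base.predict(generic.values), dtype=object)
    final = base_pred.copy()
    for group, sub in model.subsystems.items():
        mask = base_pred == group
        if not mask.any():
            continue
        X = rest.values[mask] if group == "REST" else generic.values[mask]
        final[mask] = sub.predict(X)
    return final


def subsystem_loso_rate(
    generic: FeatureMatrix,
    rest: FeatureMatrix,
    subsystem: str,
    config: ClassifierConfig,
    seed: int = 0,
) -> float:
    """Overall mean classification rate (%) of one subsystem under LOSO.

    Evaluates the subsystem's own problem (its labels, its feature set) with
    a leave-one-subject-out protocol and returns the unweighted mean of the
    per-class rates.
    """
    from .evaluation import loso_folds  # local import to avoid a cycle

    X, y, subjects = _subsystem_problem(subsystem, generic, rest)
    classes = sorted(set(y))
    correct = {c: 0 for c in classes}
    total = {c: 0 for c in classes}
    for train_ids, test_id in loso_folds(list(dict.fromkeys(subjects))):
        train_mask = np.isin(subjects, list(train_ids))
        test_mask = subjects == test_id
        if len(set(y[train_mask])) < 2 or not test_mask.any():
            raise TrainingError(
                f"subsystem {subsystem}: fold {test_id} lacks classes or test data"
            )
        est = config.make_estimator(seed)
        est.fit(X[train_mask], y[train_mask])
        pred = est.predict(X[test_mask])
        for yt, yp in zip(y[test_mask], pred):
            total[yt] += 1
            correct[yt] += int(yt == yp)
    rates = [100.0 * correct[c] / total[c] for c in classes if total[c] > 0]
    return float(np.mean(rates))


def select_best_classifiers(
    generic: FeatureMatrix,
    rest: FeatureMatrix,
    seed: int = 0,
    evaluate_fn: Callable[[str, ClassifierConfig], float] | None = None,
) -> tuple[dict[str, ClassifierConfig], dict[str, dict[str, float]]]:
    """Pick the best classifier family per subsystem by LOSO mean rate.

    Each of the five subsystems is evaluated with all four families on its
    own classification problem; the argmax of the overall mean rate wins,
    with ties broken by the fixed order SVM > KNN > ADA > CART.  Returns the
    chosen configs and the full subsystem x family rate table.
    ``evaluate_fn`` may replace the LOSO evaluation (used for testing).
    """
    if evaluate_fn is None:
        def evaluate_fn(subsystem: str, config: ClassifierConfig) -> float:
            return subsystem_loso_rate(generic, rest, subsystem, config, seed)

    chosen: dict[str, ClassifierConfig] = {}
    table: dict[str, dict[str, float]] = {}
    for subsystem in SUBSYSTEMS:
        rates = {
            kind: float(evaluate_fn(subsystem, ClassifierConfig(kind)))
            for kind in CLASSIFIER_KINDS
        }
        table[subsystem] = rates
        best = max(CLASSIFIER_KINDS, key=lambda k: (rates[k], _TIE_PRIORITY[k]))
        chosen[subsystem] = ClassifierConfig(best)
    return chosen, table
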