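"""Routing table, hierarchy training/prediction and classifier selection."""

from __future__ import annotations

import numpy as np
import pytest

from dlahar import (
    ACTIVITY_NAMES,
    Activity,
    ClassifierConfig,
    FeatureMatrix,
    HierarchyModel,
    ParameterError,
    TrainingError,
    evaluate_loso,
    map_to_base_label,
    predict_hierarchy,
    rates_from_confusion,
    select_best_classifiers,
    train_hierarchy,
)
from dlahar.features import generic_feature_names, rest_feature_names
from dlahar.hierarchy import BASE_LABELS, GROUP_MEMBERS, ROUTING_TABLE
from dlahar.reference import BENCHMARK_SUBSYSTEM_RATES


class TestRouting:
    def test_examples(self):
        assert map_to_base_label("VC") == "HOUSE"
        assert map_to_base_label(Activity.RJ) == "RJ"
        assert map_to_base_label("BC100") == "BICYCLE"

    def test_total_map_with_six_base_labels(self):
        assert set(ROUTING_TABLE) == set(Activity)
        assert set(ROUTING_TABLE.values()) == set(BASE_LABELS)
        assert len(set(ROUTING_TABLE.values())) == 6

    def test_groups_partition_their_activities(self):
        grouped = [a for members in GROUP_MEMBERS.values() for a in members]
        assert len(grouped) == len(set(grouped)) == 11
        assert set(grouped) | {Activity.RJ, Activity.WD} == set(Activity)

    def test_unknown_activity_rejected(self):
        with pytest.raises(ParameterError):
            map_to_base_label("JOGGING")


def _onehot_features(n_per_activity=6, subjects=("A", "B", "C")):
    """Oracle features: one-hot encoding of the true activity.

    Perfectly separable by construction for every subsystem; any classifier
    should reach 100% under LOSO.
    """
    acts, subj = [], []
    for s in subjects:
        for a in ACTIVITY_NAMES:
            acts += [a] * n_per_activity
            subj += [s] * n_per_activity
    acts, subj = np.array(acts, dtype=object), np.array(subj, dtype=object)
    n = len(acts)
    gen = np.zeros((n, 152))
    rst = np.zeros((n, 12))
    for i, a in enumerate(acts):
        k = ACTIVITY_NAMES.index(a)
        gen[i, k] = 1.0
        rst[i, k % 12] = 1.0
    return (
        FeatureMatrix(gen, generic_feature_names(), "GENERIC", acts, subj),
        FeatureMatrix(rst, rest_feature_names(), "REST", acts, subj),
    )


class TestTrainPredict:
    def test_training_bookkeeping(self):
        gen, rst = _onehot_features()
        model = train_hierarchy(gen, rst, seed=0)
        assert sorted(model.base.classes_) == sorted(BASE_LABELS)
        assert sorted(model.subsystems["WALK"].classes_) == ["AS", "DS", "RU", "WK"]
        assert sorted(model.subsystems["REST"].classes_) == ["LY", "SI", "ST"]

    def test_onehot_oracle_reaches_100_percent_loso(self):
        gen, rst = _onehot_features()
        cm = evaluate_loso(gen, rst, seed=0)
        assert np.all(cm.counts == np.diag(np.diag(cm.counts)))
        assert rates_from_confusion(cm).overall_mean == pytest.approx(100.0)

    def test_missing_group_activities_raise_naming_subsystem(self):
        gen, rst = _onehot_features()
        keep = ~np.isin(gen.activity.astype(str), ["BC50", "BC100"])

        def subset(fm):
            return FeatureMatrix(
                fm.values[keep], fm.names, fm.set_tag, fm.activity[keep], fm.subject_id[keep]
            )

        with pytest.raises(TrainingError, match="BICYCLE"):
            train_hierarchy(subset(gen), subset(rst))

    def test_singleton_short_circuits_subsystems(self):
        gen, rst = _onehot_features()

        class Stub:
            def __init__(self, label):
                self.label = label
                self.classes_ = np.array([label])

            def predict(self, X):
                return np.array([self.label] * len(X), dtype=object)

        class Exploding:
            def predict(self, X):  # pragma: no cover - must not be called
                raise AssertionError("subsystem consulted for a singleton route")

        model = HierarchyModel(
            base=Stub("WD"),
            subsystems={g: Exploding() for g in GROUP_MEMBERS},
            configs={},
        )
        pred = predict_hierarchy(model, gen, rst)
        assert set(pred) == {"WD"}

    def test_two_stage_composition(self):
        gen, rst = _onehot_features()

        class Stub:
            def __init__(self, label):
                self.label = label

            def predict(self, X):
                return np.array([self.label] * len(X), dtype=object)

        model = HierarchyModel(
            base=Stub("WALK"),
            subsystems={
                "WALK": Stub("AS"),
                "HOUSE": Stub("VC"),
                "REST": Stub("SI"),
                "BICYCLE": Stub("BC50"),
            },
            configs={},
        )
        pred = predict_hierarchy(model, gen, rst)
        assert set(pred) == {"AS"}

    def test_confusion_equals_path_enumeration_oracle(self, small_cohort_features):
        """The hierarchy's 13-class predictions must equal BASE routing
        composed with per-group resolution, enumerated window by window."""
        gen, rst = small_cohort_features
        model = train_hierarchy(gen, rst, seed=0)
        pred = predict_hierarchy(model, gen, rst)
        base_pred = model.base.predict(gen.values)
        for i in range(gen.n_windows):
            b = base_pred[i]
            if b in ("WD", "RJ"):
                expected = b
            elif b == "REST":
                expected = model.subsystems[b].predict(rst.values[i : i + 1])[0]
            else:
                expected = model.subsystems[b].predict(gen.values[i : i + 1])[0]
            assert pred[i] == expected
            assert pred[i] in ACTIVITY_NAMES

    def test_determinism(self, small_cohort_features):
        gen, rst = small_cohort_features
        p1 = predict_hierarchy(train_hierarchy(gen, rst, seed=5), gen, rst)
        p2 = predict_hierarchy(train_hierarchy(gen, rst, seed=5), gen, rst)
        assert np.array_equal(p1, p2)


class TestSelection:
    def test_stub_rates_reproduce_benchmark_choices(self):
        """With the published per-subsystem rate table as the evaluator, the
        selection must pick AdaBoost for HOUSE, kNN for WALK and SVM for
        BASE, REST and BICYCLE."""
        gen, rst = _onehot_features(n_per_activity=1, subjects=("A", "B"))
        chosen, table = select_best_classifiers(
            gen,
            rst,
            evaluate_fn=lambda sub, cfg: BENCHMARK_SUBSYSTEM_RATES[sub][cfg.kind],
        )
        kinds = {k: v.kind for k, v in chosen.items()}
        assert kinds == {
            "BASE": "SVM",
            "HOUSE": "ADA",
            "REST": "SVM",
            "WALK": "KNN",
            "BICYCLE": "SVM",
        }
        assert table["HOUSE"]["ADA"] == 89.9

    def test_tie_breaks_prefer_svm(self):
        gen, rst = _onehot_features(n_per_activity=1, subjects=("A", "B"))
        chosen, _ = select_best_classifiers(gen, rst, evaluate_fn=lambda s, c: 100.0)
        assert all(cfg.kind == "SVM" for cfg in chosen.values())

    def test_invalid_kind_rejected(self):
        with pytest.raises(ParameterError):
            ClassifierConfig("RF")
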