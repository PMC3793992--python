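"""Leave-one-subject-out evaluation and classification-rate metrics.

The unit of evaluation is the window ("epoch").  In each LOSO trial all
epochs of one subject are removed from the training set, the full hierarchy
is retrained on the remaining subjects, and the held-out subject's epochs
are predicted.  The per-fold 13x13 confusion matrices are summed
element-wise.

Metrics follow the benchmark convention:

* class-dependent classification rate (per-activity recall):
  ``100 * diagonal / row sum``;
* overall mean classification rate: unweighted (macro) mean of the defined
  class rates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .activities import ACTIVITY_NAMES
from .errors import ParameterError
from .features import FeatureMatrix
from .hierarchy import ClassifierConfig, predict_hierarchy, train_hierarchy


def loso_folds(subject_ids: Sequence[str]) -> list[tuple[tuple[str, ...], str]]:
    """One (train ids, test id) fold per subject.

    Requires at least two distinct subjects; a duplicated id is rejected
    because folds must cover each subject exactly once.
    """
    ids = list(subject_ids)
    if len(set(ids)) != len(ids):
        raise ParameterError("subject ids must be unique")
    if len(ids) < 2:
        raise ParameterError("leave-one-subject-out needs >= 2 subjects")
    return [
        (tuple(s for s in ids if s != test_id), test_id) for test_id in ids
    ]


@dataclass
class ConfusionMatrix:
    """13x13 epoch counts; rows are true activities, columns predictions."""

    counts: np.ndarray
    labels: tuple[str, ...] = field(default=ACTIVITY_NAMES)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise ParameterError(
                f"counts must be {k}x{k}, got shape {self.counts.shape}"
            )
        if (self.counts < 0).any():
            raise ParameterError("counts must be non-negative")

    @classmethod
    def from_labels(
        cls,
        y_true: Sequence[str],
        y_pred: Sequence[str],
        labels: tuple[str, ...] = ACTIVITY_NAMES,
    ) -> "ConfusionMatrix":
        index = {lab: i for i, lab in enumerate(labels)}
        counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
        for yt, yp in zip(y_true, y_pred, strict=True):
            counts[index[str(yt)], index[str(yp)]] += 1
        return cls(counts=counts, labels=labels)

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if self.labels != other.labels:
            raise ParameterError("cannot add confusion matrices with different labels")
        return ConfusionMatrix(self.counts + other.counts, self.labels)

    @property
    def grand_total(self) -> int:
        return int(self.counts.sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.labels), columns=list(self.labels))


@dataclass(frozen=True)
class RateReport:
    """Per-class rates (%) and their unweighted mean.

    Classes with no evaluated epochs carry ``nan`` and are excluded from the
    mean (this only arises on degenerate inputs).
    """

    class_rates: Mapping[str, float]
    overall_mean: float

    def rounded(self, decimals: int = 1) -> dict[str, float]:
        out = {k: round(v, decimals) for k, v in self.class_rates.items()}
        out["mean"] = round(self.overall_mean, decimals)
        return out


def rates_from_confusion(cm: ConfusionMatrix) -> RateReport:
    """Class-dependent rates and their macro mean from summed epoch counts.

    Rates are computed in full precision; rounding to the one-decimal
    reporting convention is left to :meth:`RateReport.rounded`.
    """
    row_sums = cm.counts.sum(axis=1)
    if cm.grand_total == 0:
        raise ParameterError("confusion matrix is all-zero")
    rates: dict[str, float] = {}
    defined = []
    for i, label in enumerate(cm.labels):
        if row_sums[i] == 0:
            warnings.warn(
                f"class {label} has no evaluated epochs; excluded from the mean",
                stacklevel=2,
            )
            rates[label] = float("nan")
        else:
            r = 100.0 * cm.counts[i, i] / row_sums[i]
            rates[label] = float(r)
            defined.append(r)
    return RateReport(class_rates=rates, overall_mean=float(np.mean(defined)))


def evaluate_loso(
    generic: FeatureMatrix,
    rest: FeatureMatrix,
    configs: Mapping[str, ClassifierConfig] | None = None,
    seed: int = 0,
) -> ConfusionMatrix:
    """Summed confusion matrix of the full hierarchy under LOSO.

    Every subsystem is retrained in every fold, so no information from the
    held-out subject leaks into any level of the hierarchy.
    """
    subjects = np.asarray(generic.subject_id)
    unique_subjects = list(dict.fromkeys(subjects))
    total = ConfusionMatrix(np.zeros((13, 13), dtype=np.int64))
    for train_ids, test_id in loso_folds(unique_subjects):
        train_mask = np.isin(subjects, list(train_ids))
        test_mask = subjects == test_id

        def _subset(fm: FeatureMatrix, mask: np.ndarray) -> FeatureMatrix:
            return FeatureMatrix(
                values=fm.values[mask],
                names=fm.names,
                set_tag=fm.set_tag,
                activity=np.asarray(fm.activity)[mask],
                subject_id=np.asarray(fm.subject_id)[mask],
            )

        try:
            model = train_hierarchy(
                _subset(generic, train_mask), _subset(rest, train_mask), configs, seed
            )
        except Exception as exc:
            raise type(exc)(f"fold {test_id}: {exc}") from exc
        pred = predict_hierarchy(model, _subset(generic, test_mask), _subset(rest, test_mask))
        total = total + ConfusionMatrix.from_labels(
            [str(a) for a in np.asarray(generic.activity)[test_mask]],
            [str(p) for p in pred],
        )
    return total
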