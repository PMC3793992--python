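"""Published benchmark results for the hierarchical system.

These tables are the reported results of the hierarchical classifier on the
public 19-subject daily-life-activity benchmark (recorded with the
wrist/chest/hip/ankle setup this package models).  They serve as inputs for
metric recomputation and for regression tests of the rate arithmetic — the
per-class rates are always *derived* from the epoch counts at run time,
never read off.
"""

from __future__ import annotations

import numpy as np

from .activities import ACTIVITY_NAMES
from .evaluation import ConfusionMatrix

#: Summed LOSO confusion matrix of the hierarchical system (epoch counts;
#: rows = true activity, columns = predicted), in canonical activity order.
BENCHMARK_CONFUSION_COUNTS = np.array(
    [
        # SI   LY   ST   WD   VC   SW   WK   AS   DS   RU  BC50 B100  RJ
        [383,   0,  22,  14,   1,   2,   0,   0,   2,   0,   7,   0,   0],  # SI
        [  0, 435,   0,   0,   0,   0,   0,   0,   0,   0,   0,   0,   0],  # LY
        [  0,   0, 386,  27,   9,   0,   0,   0,   0,   0,   8,   0,   0],  # ST
        [  0,   0,  10, 896,   5,   1,   0,   0,   0,   0,   1,   0,   0],  # WD
        [  0,   0,   0,   0, 369,  55,   0,   0,   0,   0,   6,   2,   0],  # VC
        [  0,   0,   1,   6,  43, 643,   4,   7,   5,   0,   4,   2,   0],  # SW
        [  0,   0,   0,   0,   4,   4, 1995,  5,   7,   0,   0,   0,   0],  # WK
        [  0,   0,   0,   0,   0,   3,  10, 279,   0,   0,   0,   0,   0],  # AS
        [  0,   0,   0,   0,   0,   1,  11,   0, 237,   0,   0,   0,   0],  # DS
        [  0,   0,   0,   0,   0,   0,   0,   0,   0, 886,   0,   0,   0],  # RU
        [  0,   0,   0,   0,   4,  22,   0,   1,   0,   0, 620, 250,   0],  # BC50
        [  0,   0,   0,   1,   0,   6,   0,   0,   0,   0, 410, 480,   0],  # BC100
        [  0,   0,   0,   0,   0,   0,   0,   0,   0,   0,   0,   0, 236],  # RJ
    ],
    dtype=np.int64,
)

#: Reported per-subsystem overall mean classification rates (%) for the four
#: classifier families under LOSO (subsystem -> family -> rate).
BENCHMARK_SUBSYSTEM_RATES: dict[str, dict[str, float]] = {
    "BASE": {"ADA": 64.8, "CART": 96.1, "KNN": 97.7, "SVM": 97.9},
    "HOUSE": {"ADA": 89.9, "CART": 84.0, "KNN": 86.5, "SVM": 85.5},
    "REST": {"ADA": 95.1, "CART": 92.7, "KNN": 96.1, "SVM": 97.4},
    "WALK": {"ADA": 94.7, "CART": 93.3, "KNN": 97.7, "SVM": 94.3},
    "BICYCLE": {"ADA": 60.8, "CART": 53.7, "KNN": 49.4, "SVM": 61.6},
}

#: Number of subjects in the benchmark after exclusions.
BENCHMARK_N_SUBJECTS = 19


def benchmark_confusion() -> ConfusionMatrix:
    """The benchmark confusion matrix as a :class:`ConfusionMatrix`."""
    return ConfusionMatrix(
        counts=BENCHMARK_CONFUSION_COUNTS.copy(), labels=ACTIVITY_NAMES
    )
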