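"""The 13 daily-life activities and their canonical ordering.

The activity set spans four categories: static postures (sitting, lying,
standing), household activities (washing dishes, vacuuming, sweeping),
locomotion (walking, stair ascent/descent, treadmill running), ergometer
bicycling at two resistance levels, and rope jumping.  All confusion
matrices and rate reports in this package use the fixed order below.
"""

from __future__ import annotations

from enum import Enum


class Activity(str, Enum):
    """Abbreviations for the 13 studied daily-life activities."""

    SI = "SI"  # sitting
    LY = "LY"  # lying
    ST = "ST"  # standing
    WD = "WD"  # washing dishes
    VC = "VC"  # vacuuming
    SW = "SW"  # sweeping
    WK = "WK"  # walking
    AS = "AS"  # ascending stairs
    DS = "DS"  # descending stairs
    RU = "RU"  # treadmill running
    BC50 = "BC50"  # bicycling, 50 W
    BC100 = "BC100"  # bicycling, 100 W
    RJ = "RJ"  # rope jumping

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Fixed row/column order of every confusion matrix and rate table.
ACTIVITY_ORDER: tuple[Activity, ...] = (
    Activity.SI,
    Activity.LY,
    Activity.ST,
    Activity.WD,
    Activity.VC,
    Activity.SW,
    Activity.WK,
    Activity.AS,
    Activity.DS,
    Activity.RU,
    Activity.BC50,
    Activity.BC100,
    Activity.RJ,
)

ACTIVITY_NAMES: tuple[str, ...] = tuple(a.value for a in ACTIVITY_ORDER)


def as_activity(value: "Activity | str") -> Activity:
    """Coerce a string abbreviation to an :class:`Activity`.

    Raises ``KeyError``-free ``ValueError`` for unknown labels so callers
    get a uniform error surface.
    """
    if isinstance(value, Activity):
        return value
    try:
        return Activity(value)
    except ValueError as exc:
        raise ValueError(f"unknown activity label: {value!r}") from exc
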