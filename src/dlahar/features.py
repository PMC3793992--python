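"""Per-window feature extraction: the generic 152-feature set and the
12-feature gravity (REST) set.

Generic set (used by the BASE, HOUSE, WALK and BICYCLE classifiers)
-------------------------------------------------------------------
Six features per sensor axis — minimum, maximum, mean, population variance,
spectral centroid and spectral bandwidth — over all 24 axes (144 features),
plus one energy feature per sensor type (accelerometer / gyroscope) per
node (8 features): 152 in total.

The energy of a sensor type is the mean squared amplitude pooled over its
three axes: sum the squared samples per axis, add the three sums, divide by
three, then divide by the number of samples.

Spectral centroid and bandwidth are computed on the one-sided magnitude
spectrum of the mean-removed window (rectangular taper, DC bin excluded):

    c  = sum_k f_k M_k / sum_k M_k
    bw = sqrt( sum_k (f_k - c)^2 M_k / sum_k M_k )

A constant window has an identically zero spectrum; both features are then
0 by convention.

REST set (static postures)
--------------------------
Only body orientation relative to gravity matters for sitting vs lying vs
standing, so the REST classifier consumes the gravitational component of
the 12 accelerometer axes: each axis is low-pass filtered with a
third-order elliptic IIR filter (cut-off 0.25 Hz) applied to the continuous
per-segment signal, and the per-window feature is the mean of the filtered
samples — 12 features.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import IntegrityError, ParameterError
from .imu_data import (
    CHANNEL_NAMES,
    CHANNEL_ORDER,
    NODE_ORDER,
    ImuRecording,
    LabeledSegment,
)
from .windowing import WindowSet, WindowSpec, slide_windows

AXIS_FEATURES = ("min", "max", "mean", "variance", "centroid", "bandwidth")
SENSOR_TYPES = ("accel", "gyro")  # accel = (ax, ay, az), gyro = (gx, gy, gz)

#: The 12 accelerometer channel names, in canonical node order.
ACCEL_CHANNEL_NAMES = tuple(
    f"{node}.{ch}" for node in NODE_ORDER for ch in ("ax", "ay", "az")
)


def generic_feature_names() -> tuple[str, ...]:
    """The 152 generic feature names in their fixed extraction order."""
    names = [
        f"{chan}.{feat}" for chan in CHANNEL_NAMES for feat in AXIS_FEATURES
    ]
    names += [
        f"{node}.{stype}.energy" for node in NODE_ORDER for stype in SENSOR_TYPES
    ]
    return tuple(names)


def rest_feature_names() -> tuple[str, ...]:
    """The 12 gravity feature names (one per accelerometer axis)."""
    return tuple(f"{chan}.gravity" for chan in ACCEL_CHANNEL_NAMES)


@dataclass(frozen=True)
class GravityFilterSpec:
    """Third-order elliptic IIR low-pass used for gravity separation.

    Order and cut-off are fixed by the method; passband ripple and stopband
    attenuation are configurable design margins.  Filtering is causal
    (single forward pass), mirroring a real-time implementation.
    """

    order: int = 3
    cutoff_hz: float = 0.25
    passband_ripple_db: float = 0.01
    stopband_atten_db: float = 100.0

    def __post_init__(self) -> None:
        if self.order < 1 or self.cutoff_hz <= 0:
            raise ParameterError("invalid gravity filter specification")

    def sos(self, rate: float) -> np.ndarray:
        if rate <= 2 * self.cutoff_hz:
            raise ParameterError(
                f"rate {rate} Hz too low for cutoff {self.cutoff_hz} Hz"
            )
        return _ellip_sos(
            self.order,
            self.passband_ripple_db,
            self.stopband_atten_db,
            self.cutoff_hz,
            rate,
        )


@lru_cache(maxsize=32)
def _ellip_sos(order, rp, rs, cutoff, rate) -> np.ndarray:
    return sps.ellip(order, rp, rs, cutoff / (rate / 2.0), btype="low", output="sos")


@dataclass(frozen=True)
class FeatureVector:
    """Ordered feature values with stable names and a set tag."""

    values: np.ndarray
    names: tuple[str, ...]
    set_tag: str  # "GENERIC" | "REST"

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if len(self.values) != len(self.names):
            raise IntegrityError("feature values and names differ in length")


@dataclass
class FeatureMatrix:
    """Windows x features, with per-window activity and subject annotations."""

    values: np.ndarray
    names: tuple[str, ...]
    set_tag: str
    activity: np.ndarray
    subject_id: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.names):
            raise IntegrityError(
                f"feature matrix shape {self.values.shape} does not match "
                f"{len(self.names)} names"
            )
        n = self.values.shape[0]
        if len(self.activity) != n or len(self.subject_id) != n:
            raise IntegrityError("annotations must match the number of rows")

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.names))
        df.insert(0, "subject_id", self.subject_id)
        df.insert(1, "activity", self.activity)
        return df

    @classmethod
    def concat(cls, parts: Sequence["FeatureMatrix"]) -> "FeatureMatrix":
        if not parts:
            raise ParameterError("cannot concatenate zero feature matrices")
        tags = {p.set_tag for p in parts}
        if len(tags) != 1:
            raise IntegrityError(f"mixed feature-set tags {sorted(tags)}")
        return cls(
            values=np.concatenate([p.values for p in parts], axis=0),
            names=parts[0].names,
            set_tag=parts[0].set_tag,
            activity=np.concatenate([p.activity for p in parts]),
            subject_id=np.concatenate([p.subject_id for p in parts]),
        )


# ---------------------------------------------------------------------------
# Elementary per-axis operations
# ---------------------------------------------------------------------------


def time_features(window_axis: Sequence[float]) -> tuple[float, float, float, float]:
    """(min, max, mean, population variance) of one axis window."""
    x = np.asarray(window_axis, dtype=float)
    if x.size == 0:
        raise ParameterError("window must be non-empty")
    return float(x.min()), float(x.max()), float(x.mean()), float(x.var())


def spectral_features(
    window_axis: Sequence[float], rate: float
) -> tuple[float, float]:
    """(spectral centroid, spectral bandwidth) in Hz of one axis window."""
    x = np.asarray(window_axis, dtype=float)
    if x.size == 0:
        raise ParameterError("window must be non-empty")
    if rate <= 0:
        raise ParameterError("rate must be positive")
    mags = np.abs(np.fft.rfft(x - x.mean()))
    mags[0] = 0.0  # DC excluded
    total = mags.sum()
    if total == 0.0:
        return 0.0, 0.0
    freqs = np.fft.rfftfreq(x.size, d=1.0 / rate)
    centroid = float((freqs * mags).sum() / total)
    bandwidth = float(np.sqrt(((freqs - centroid) ** 2 * mags).sum() / total))
    return centroid, bandwidth


def energy(window_3axes: Sequence[Sequence[float]]) -> float:
    """Mean squared amplitude pooled over the three axes of one sensor type."""
    axes = [np.asarray(a, dtype=float) for a in window_3axes]
    if len(axes) != 3:
        raise IntegrityError(f"expected exactly 3 axes, got {len(axes)}")
    n = axes[0].size
    if n < 1 or any(a.size != n for a in axes):
        raise IntegrityError("axes must be non-empty and of equal length")
    return float(sum(float(np.square(a).sum()) for a in axes) / (3.0 * n))


def gravity_component(
    signal_axis: Sequence[float],
    rate: float,
    spec: GravityFilterSpec = GravityFilterSpec(),
) -> np.ndarray:
    """Causal low-pass estimate of the gravitational acceleration component.

    The filter state is initialised to the steady state of the first sample,
    which removes the step transient for signals that start near their DC
    level; residual warm-up is on the order of 1 / cutoff seconds.
    """
    x = np.asarray(signal_axis, dtype=float)
    if x.size < 8:
        raise ParameterError("signal too short for gravity filtering (need >= 8 samples)")
    sos = spec.sos(rate)
    zi = sps.sosfilt_zi(sos) * x[0]
    y, _ = sps.sosfilt(sos, x, zi=zi)
    return y


# ---------------------------------------------------------------------------
# Whole-window extraction
# ---------------------------------------------------------------------------


def _generic_block(windows: np.ndarray, rate: float) -> np.ndarray:
    """Vectorized generic features for a stack ``(n, 24, W)`` -> ``(n, 152)``."""
    n, n_ch, W = windows.shape
    mins = windows.min(axis=2)
    maxs = windows.max(axis=2)
    means = windows.mean(axis=2)
    variances = windows.var(axis=2)

    mags = np.abs(np.fft.rfft(windows - means[:, :, None], axis=2))
    mags[:, :, 0] = 0.0
    freqs = np.fft.rfftfreq(W, d=1.0 / rate)
    totals = mags.sum(axis=2)
    safe = np.where(totals == 0.0, 1.0, totals)
    centroids = (mags * freqs).sum(axis=2) / safe
    deviations = (freqs[None, None, :] - centroids[:, :, None]) ** 2
    bandwidths = np.sqrt((mags * deviations).sum(axis=2) / safe)
    centroids = np.where(totals == 0.0, 0.0, centroids)
    bandwidths = np.where(totals == 0.0, 0.0, bandwidths)

    per_axis = np.stack(
        [mins, maxs, means, variances, centroids, bandwidths], axis=2
    )  # (n, 24, 6)

    sq = np.square(windows)
    # (n, 4, 2): node-major, accel triple then gyro triple
    energies = sq.reshape(n, 4, 2, 3, W).sum(axis=(3, 4)) / (3.0 * W)

    return np.concatenate(
        [per_axis.reshape(n, n_ch * len(AXIS_FEATURES)), energies.reshape(n, 8)],
        axis=1,
    )


def extract_generic(window: np.ndarray, rate: float) -> FeatureVector:
    """Generic 152-feature vector for one ``(24, W)`` window."""
    window = np.asarray(window, dtype=float)
    if window.ndim != 2 or window.shape[0] != len(CHANNEL_NAMES):
        raise IntegrityError(
            f"expected a (24, W) window, got shape {window.shape}"
        )
    if window.shape[1] == 0:
        raise ParameterError("window must be non-empty")
    values = _generic_block(window[None], rate)[0]
    return FeatureVector(values=values, names=generic_feature_names(), set_tag="GENERIC")


def extract_rest(window_accels: np.ndarray) -> FeatureVector:
    """REST 12-feature vector: per-axis mean of a gravity-filtered window.

    ``window_accels`` holds the 12 accelerometer axes (already low-pass
    filtered, see :func:`rest_features`) of one window.
    """
    window_accels = np.asarray(window_accels, dtype=float)
    if window_accels.ndim != 2 or window_accels.shape[0] != 12:
        raise IntegrityError(
            f"expected a (12, W) accelerometer window, got shape {window_accels.shape}"
        )
    if window_accels.shape[1] == 0:
        raise ParameterError("window must be non-empty")
    return FeatureVector(
        values=window_accels.mean(axis=1),
        names=rest_feature_names(),
        set_tag="REST",
    )


def generic_features(ws: WindowSet, chunk: int = 256) -> FeatureMatrix:
    """Generic feature matrix for a window set (chunked to bound FFT memory)."""
    if ws.n_windows == 0:
        values = np.empty((0, len(generic_feature_names())))
    else:
        values = np.concatenate(
            [
                _generic_block(ws.windows[i : i + chunk], ws.rate)
                for i in range(0, ws.n_windows, chunk)
            ]
        )
    return FeatureMatrix(
        values=values,
        names=generic_feature_names(),
        set_tag="GENERIC",
        activity=ws.activity,
        subject_id=ws.subject_id,
    )


def rest_features(
    rec: ImuRecording,
    segments: Sequence[LabeledSegment],
    wspec: WindowSpec = WindowSpec(),
    fspec: GravityFilterSpec = GravityFilterSpec(),
) -> FeatureMatrix:
    """REST feature matrix aligned window-for-window with the generic set.

    The gravity filter runs over each segment's continuous accelerometer
    signal before windowing, so window boundaries here are identical to
    those produced by :func:`~dlahar.windowing.slide_windows` on the raw
    recording with the same spec.
    """
    accel_rows = [
        i for i, name in enumerate(CHANNEL_NAMES) if name in ACCEL_CHANNEL_NAMES
    ]
    filtered = rec.signals.copy()
    for seg in segments:
        s0 = int(round(seg.t_start * rec.rate))
        s1 = min(int(round(seg.t_end * rec.rate)), rec.n_samples)
        if s1 - s0 < 8:
            continue
        for row in accel_rows:
            filtered[row, s0:s1] = gravity_component(
                rec.signals[row, s0:s1], rec.rate, fspec
            )
    filtered_rec = ImuRecording(rec.subject_id, rec.rate, filtered)
    ws = slide_windows(filtered_rec, segments, wspec)
    values = ws.windows[:, accel_rows, :].mean(axis=2)
    return FeatureMatrix(
        values=values,
        names=rest_feature_names(),
        set_tag="REST",
        activity=ws.activity,
        subject_id=ws.subject_id,
    )
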