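"""Sliding-window segmentation and linear-interpolation resampling.

Classification operates on fixed-width windows ("epochs") of 5 s with 50%
overlap.  At the native 204.8 Hz sampling rate this yields 1024-sample
windows advancing by 512 samples.  Windows are cut per labeled segment and
never span two activities; trailing partial windows are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import IntegrityError, ParameterError
from .imu_data import CHANNEL_NAMES, ImuRecording, LabeledSegment


@dataclass(frozen=True)
class WindowSpec:
    """Window width (s) and overlap fraction of the sliding segmentation."""

    width: float = 5.0
    overlap: float = 0.5

    def __post_init__(self) -> None:
        if not self.width > 0:
            raise ParameterError(f"width must be > 0, got {self.width}")
        if not 0 <= self.overlap < 1:
            raise ParameterError(f"overlap must be in [0, 1), got {self.overlap}")

    def window_length(self, rate: float) -> int:
        """Window length in samples: round(width x rate)."""
        return int(round(self.width * rate))

    def hop(self, rate: float) -> int:
        """Hop in samples: round(window_length x (1 - overlap)), at least 1."""
        return max(1, int(round(self.window_length(rate) * (1.0 - self.overlap))))


def n_windows(n_samples: int, window: int, hop: int) -> int:
    """Number of full windows in a segment of ``n_samples`` samples."""
    if window < 1 or hop < 1:
        raise ParameterError("window and hop must be >= 1")
    if n_samples < window:
        return 0
    return (n_samples - window) // hop + 1


@dataclass
class WindowSet:
    """A stack of fixed-length windows with per-window annotations.

    ``windows`` has shape ``(n_windows, n_channels, window_length)``;
    ``activity`` and ``subject_id`` are parallel arrays of labels.
    """

    windows: np.ndarray
    activity: np.ndarray
    subject_id: np.ndarray
    rate: float
    channel_names: tuple[str, ...] = field(default=CHANNEL_NAMES)

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows, dtype=float)
        self.activity = np.asarray(self.activity, dtype=object)
        self.subject_id = np.asarray(self.subject_id, dtype=object)
        if self.windows.ndim != 3:
            raise IntegrityError(f"windows must be 3-d, got shape {self.windows.shape}")
        n = self.windows.shape[0]
        if len(self.activity) != n or len(self.subject_id) != n:
            raise IntegrityError("annotation arrays must match the number of windows")

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]

    @classmethod
    def concat(cls, parts: Sequence["WindowSet"]) -> "WindowSet":
        parts = [p for p in parts if p.n_windows > 0]
        if not parts:
            raise ParameterError("cannot concatenate zero non-empty window sets")
        rates = {p.rate for p in parts}
        if len(rates) != 1:
            raise IntegrityError(f"mixed sampling rates {sorted(rates)}")
        return cls(
            windows=np.concatenate([p.windows for p in parts], axis=0),
            activity=np.concatenate([p.activity for p in parts]),
            subject_id=np.concatenate([p.subject_id for p in parts]),
            rate=parts[0].rate,
            channel_names=parts[0].channel_names,
        )


def slide_windows(
    rec: ImuRecording,
    segments: Sequence[LabeledSegment],
    spec: WindowSpec = WindowSpec(),
) -> WindowSet:
    """Cut overlapping fixed-length windows from each labeled segment.

    Segment boundaries are mapped to sample indices by ``round(t * rate)``
    (half-open interval).  Windows start at the segment start and advance by
    the hop; segments shorter than one window contribute none.
    """
    W = spec.window_length(rec.rate)
    H = spec.hop(rec.rate)
    blocks, acts = [], []
    for seg in segments:
        s0 = int(round(seg.t_start * rec.rate))
        s1 = min(int(round(seg.t_end * rec.rate)), rec.n_samples)
        count = n_windows(max(0, s1 - s0), W, H)
        for k in range(count):
            blocks.append(rec.signals[:, s0 + k * H : s0 + k * H + W])
            acts.append(seg.activity.value)
    if blocks:
        windows = np.stack(blocks)
    else:
        windows = np.empty((0, rec.signals.shape[0], W))
    return WindowSet(
        windows=windows,
        activity=np.array(acts, dtype=object),
        subject_id=np.array([rec.subject_id] * len(acts), dtype=object),
        rate=rec.rate,
    )


def resample_linear(
    signal: Sequence[float], rate_in: float, rate_out: float
) -> np.ndarray:
    """Resample a uniformly sampled signal by linear interpolation.

    Output samples lie at times ``k / rate_out`` covering the input span
    ``[0, (n - 1) / rate_in]``.  Used to down-sample the 204.8 Hz recordings
    to the rates of comparison methods.
    """
    if rate_in <= 0 or rate_out <= 0:
        raise ParameterError("rates must be positive")
    x = np.asarray(signal, dtype=float)
    if x.size < 2:
        raise ParameterError("signal must have at least 2 samples")
    duration = (x.size - 1) / rate_in
    # relative epsilon so an output sample landing exactly on the last input
    # sample is kept despite floating-point rounding
    m = int(np.floor(duration * rate_out * (1 + 1e-12))) + 1
    t_out = np.arange(m) / rate_out
    t_in = np.arange(x.size) / rate_in
    return np.interp(t_out, t_in, x)
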