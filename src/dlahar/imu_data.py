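"""Data model and I/O for synchronized multi-node IMU recordings.

A recording holds four body-worn sensor nodes (wrist, chest, hip, ankle),
each with a triaxial accelerometer (units: g) and a triaxial gyroscope
(units: deg/s), all sampled at one common rate (default 204.8 Hz).  The
module also provides the plate-drop synchronization detector used to align
nodes to a common start point, and the per-segment label trimming that
removes labeling jitter at activity boundaries.

On-disk formats
---------------
CSV bundle
    A directory with one file per node (``WRIST.csv`` ... ``ANKLE.csv``),
    header ``t,ax,ay,az,gx,gy,gz``, plus ``meta.json`` holding the subject
    id and sampling rate.  Labels live in a separate ``labels.csv`` with
    header ``activity,t_start,t_end``.
HDF5 bundle
    Datasets ``/subject_id``, ``/rate`` and ``/nodes/<POSITION>/<channel>``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np
import pandas as pd

from .activities import Activity, as_activity
from .errors import DetectionError, FormatError, IntegrityError, ParameterError

NODE_ORDER: tuple[str, ...] = ("WRIST", "CHEST", "HIP", "ANKLE")
CHANNEL_ORDER: tuple[str, ...] = ("ax", "ay", "az", "gx", "gy", "gz")
#: Flat channel names in canonical order, e.g. ``"WRIST.ax"`` ... ``"ANKLE.gz"``.
CHANNEL_NAMES: tuple[str, ...] = tuple(
    f"{node}.{ch}" for node in NODE_ORDER for ch in CHANNEL_ORDER
)
N_CHANNELS = len(CHANNEL_NAMES)  # 24

DEFAULT_RATE = 204.8  # Hz
ACCEL_RANGE_G = 6.0
GYRO_RANGE_DPS = {"WRIST": 500.0, "CHEST": 500.0, "HIP": 500.0, "ANKLE": 2000.0}


@dataclass(frozen=True)
class SensorNode:
    """Static description of one body-worn sensor node."""

    position: str
    accel_range_g: float = ACCEL_RANGE_G
    gyro_range_dps: float = 500.0

    def __post_init__(self) -> None:
        if self.position not in NODE_ORDER:
            raise ParameterError(f"unknown node position {self.position!r}")


#: The four nodes of the measurement setup.  Larger angular velocities are
#: expected at the lower extremities, hence the wider ankle gyroscope range.
SENSOR_NODES: dict[str, SensorNode] = {
    pos: SensorNode(pos, ACCEL_RANGE_G, GYRO_RANGE_DPS[pos]) for pos in NODE_ORDER
}


def channel_index(node: str, channel: str) -> int:
    """Row index of ``node.channel`` in the flat 24-channel signal block."""
    try:
        return NODE_ORDER.index(node) * len(CHANNEL_ORDER) + CHANNEL_ORDER.index(channel)
    except ValueError as exc:
        raise ParameterError(f"unknown channel {node}.{channel}") from exc


@dataclass
class ImuRecording:
    """One subject's synchronized multi-node signal block.

    ``signals`` has shape ``(24, n_samples)`` with rows ordered per
    :data:`CHANNEL_NAMES`.  Accelerometer rows are in g, gyroscope rows in
    deg/s.
    """

    subject_id: str
    rate: float
    signals: np.ndarray

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        if self.rate <= 0:
            raise ParameterError(f"rate must be positive, got {self.rate}")
        if self.signals.ndim != 2 or self.signals.shape[0] != N_CHANNELS:
            raise IntegrityError(
                f"signals must have shape (24, n); got {self.signals.shape}"
            )

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    def channel(self, node: str, channel: str) -> np.ndarray:
        """View of one channel, e.g. ``channel("HIP", "az")``."""
        return self.signals[channel_index(node, channel)]


@dataclass(frozen=True)
class LabeledSegment:
    """An activity label spanning ``[t_start, t_end)`` seconds of a recording."""

    activity: Activity
    t_start: float
    t_end: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "activity", as_activity(self.activity))
        if not self.t_end > self.t_start:
            raise ParameterError(
                f"segment must have t_end > t_start, got [{self.t_start}, {self.t_end}]"
            )

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


def trim_segment(seg: LabeledSegment, margin: float = 2.0) -> LabeledSegment | None:
    """Cut ``margin`` seconds from both ends of a labeled segment.

    The trimming removes measuring errors around the manually labeled
    activity boundaries.  Returns ``None`` when the trimmed duration is not
    positive (the segment is then discarded).
    """
    if margin < 0:
        raise ParameterError("margin must be >= 0")
    t0, t1 = seg.t_start + margin, seg.t_end - margin
    if t1 <= t0:
        return None
    return replace(seg, t_start=t0, t_end=t1)


def trim_segments(
    segments: Iterable[LabeledSegment], margin: float = 2.0
) -> list[LabeledSegment]:
    """Trim every segment, dropping those that become empty."""
    out = []
    for seg in segments:
        trimmed = trim_segment(seg, margin)
        if trimmed is not None:
            out.append(trimmed)
    return out


def detect_sync_start(
    vertical_accel: Sequence[float], rate: float, threshold: float = 1.0
) -> int:
    """Locate the onset of the plate-drop synchronization pattern.

    At the start of every recording the sensor nodes lie on a plate that is
    dropped twice with an up-down movement in between.  The detector returns
    the first sample where the vertical acceleration deviates from its
    resting baseline (median of the first 0.5 s) by more than ``threshold``
    (in g).  That index is the common start point used to align all nodes by
    truncation.
    """
    x = np.asarray(vertical_accel, dtype=float)
    if x.size == 0:
        raise ParameterError("signal must be non-empty")
    if threshold <= 0:
        raise ParameterError("threshold must be positive")
    n_base = max(1, int(round(0.5 * rate)))
    baseline = float(np.median(x[:n_base]))
    crossings = np.flatnonzero(np.abs(x - baseline) > threshold)
    if crossings.size == 0:
        raise DetectionError(
            f"no excursion beyond {threshold} g from baseline {baseline:.3f} g"
        )
    return int(crossings[0])


def apply_sync(
    rec: ImuRecording, segments: Sequence[LabeledSegment], start_index: int
) -> tuple[ImuRecording, list[LabeledSegment]]:
    """Truncate a recording at the synchronization start point.

    Sample ``start_index`` becomes the new time origin; label times are
    shifted accordingly.  Segments that would start before the new origin
    are rejected, since labels always refer to activity after setup.
    """
    if not 0 <= start_index < rec.n_samples:
        raise ParameterError(f"start_index {start_index} outside recording")
    shift = start_index / rec.rate
    out_segments = []
    for seg in segments:
        if seg.t_start < shift:
            raise IntegrityError(
                f"segment {seg.activity} starts before the synchronization point"
            )
        out_segments.append(
            replace(seg, t_start=seg.t_start - shift, t_end=seg.t_end - shift)
        )
    rec_out = ImuRecording(rec.subject_id, rec.rate, rec.signals[:, start_index:])
    return rec_out, out_segments


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        fmt = fmt.lower()
        if fmt not in ("csv", "hdf5"):
            raise ParameterError(f"unknown format {fmt!r}")
        return fmt
    if path.suffix in (".h5", ".hdf5"):
        return "hdf5"
    return "csv"


def write_recording(rec: ImuRecording, path: str | Path, fmt: str | None = None) -> Path:
    """Write a recording as a CSV bundle directory or a single HDF5 file."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "hdf5":
        with h5py.File(path, "w") as f:
            f.create_dataset("subject_id", data=rec.subject_id)
            f.create_dataset("rate", data=rec.rate)
            grp = f.create_group("nodes")
            for node in NODE_ORDER:
                g = grp.create_group(node)
                for ch in CHANNEL_ORDER:
                    g.create_dataset(ch, data=rec.channel(node, ch))
        return path
    path.mkdir(parents=True, exist_ok=True)
    t = np.arange(rec.n_samples) / rec.rate
    for node in NODE_ORDER:
        cols = {"t": t}
        for ch in CHANNEL_ORDER:
            cols[ch] = rec.channel(node, ch)
        pd.DataFrame(cols).to_csv(path / f"{node}.csv", index=False)
    (path / "meta.json").write_text(
        json.dumps({"subject_id": rec.subject_id, "rate": rec.rate})
    )
    return path


def read_recording(path: str | Path, fmt: str | None = None) -> ImuRecording:
    """Read a recording written by :func:`write_recording`.

    Raises :class:`FormatError` naming the first missing node or channel and
    :class:`IntegrityError` when channel lengths disagree.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file or directory: {path}")
    fmt = _infer_format(path, fmt)
    if fmt == "hdf5":
        with h5py.File(path, "r") as f:
            subject_id = f["subject_id"][()]
            if isinstance(subject_id, bytes):
                subject_id = subject_id.decode()
            rate = float(f["rate"][()])
            rows = []
            for node in NODE_ORDER:
                for ch in CHANNEL_ORDER:
                    key = f"nodes/{node}/{ch}"
                    if key not in f:
                        raise FormatError(f"missing channel {node}.{ch} in {path}")
                    rows.append(np.asarray(f[key]))
    else:
        meta_path = path / "meta.json"
        if meta_path.exists():
            meta = json.loads(meta_path.read_text())
            subject_id, rate = str(meta["subject_id"]), float(meta["rate"])
        else:
            subject_id, rate = path.name, None
        rows = []
        for node in NODE_ORDER:
            node_path = path / f"{node}.csv"
            if not node_path.exists():
                raise FormatError(f"missing node file {node}.csv in {path}")
            df = pd.read_csv(node_path)
            missing = [ch for ch in CHANNEL_ORDER if ch not in df.columns]
            if missing:
                names = ", ".join(f"{node}.{ch}" for ch in missing)
                raise FormatError(f"missing channel(s) {names} in {node_path}")
            if rate is None:
                t = df["t"].to_numpy()
                if len(t) < 2:
                    raise FormatError(f"cannot infer rate from {node_path}")
                rate = 1.0 / float(np.median(np.diff(t)))
            for ch in CHANNEL_ORDER:
                rows.append(df[ch].to_numpy(dtype=float))
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise IntegrityError(f"unequal channel lengths {sorted(lengths)} in {path}")
    return ImuRecording(subject_id=subject_id, rate=rate, signals=np.vstack(rows))


def write_labels(segments: Sequence[LabeledSegment], path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "activity": [s.activity.value for s in segments],
            "t_start": [s.t_start for s in segments],
            "t_end": [s.t_end for s in segments],
        }
    )
    df.to_csv(path, index=False)
    return path


def read_labels(path: str | Path) -> list[LabeledSegment]:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(path)
    for col in ("activity", "t_start", "t_end"):
        if col not in df.columns:
            raise FormatError(f"labels file {path} lacks column {col!r}")
    return [
        LabeledSegment(as_activity(row.activity), float(row.t_start), float(row.t_end))
        for row in df.itertuples()
    ]
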