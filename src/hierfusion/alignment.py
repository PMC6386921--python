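"""Time alignment between a motion-sensor stream and a photo stream.

A wearable hybrid logger emits two asynchronous streams: a 6-channel IMU
series (3-axis accelerometer + 3-axis gyroscope, nominally 90 Hz) and a
timestamped photo stream. Each frame shot at time ``t_c`` is associated
with the fixed-width sensor window ``[t_c - t_w/2, t_c + t_w/2)`` centered
on it; everything inside the window is "the sensor data of that frame" and
becomes the input of the motion-state classifier. At low frame rates
(one frame every >= 4 s with t_w = 3 s) consecutive windows are disjoint;
at high rates (window centers every 1 s) they overlap.

Windows are half-open so that adjacent non-overlapping windows partition
time. Segments are materialized at a fixed length ``L = round(fs * t_w)``
by nearest-sample-index binning; rows that fall outside the recorded
stream are filled by edge replication and flagged, so boundary windows of
a finite recording still yield fixed-shape classifier input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CHANNEL_NAMES = ("ax", "ay", "az", "gx", "gy", "gz")

__all__ = [
    "SensorStream",
    "TimeWindow",
    "SensorSegment",
    "FramePayload",
    "AlignedSample",
    "window_for_frame",
    "overlaps",
    "extract_segment",
    "segment_stream",
    "associate",
    "read_sensor_csv",
    "write_sensor_csv",
    "save_aligned",
    "load_aligned",
]


@dataclass(frozen=True)
class SensorStream:
    """Uniformly sampled 6-channel IMU stream.

    ``t0`` is the timestamp of the first sample, ``fs`` the sampling rate in
    Hz. ``values`` has shape (N, 6) ordered ax, ay, az (m/s^2), gx, gy, gz
    (rad/s). Timestamps are implicit: sample i sits at ``t0 + i / fs``.
    """

    t0: float
    fs: float
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[1] != 6:
            raise ValueError(f"sensor values must be (N, 6), got {v.shape}")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if v.shape[0] == 0:
            raise ValueError("empty sensor stream")
        object.__setattr__(self, "values", v)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def timestamps(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    @property
    def span(self) -> tuple[float, float]:
        """Half-open [start, end) of the recording."""
        return (self.t0, self.t0 + self.duration)


@dataclass(frozen=True)
class TimeWindow:
    """Half-open window [center - width/2, center + width/2)."""

    center: float
    width: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("window width must be positive")

    @property
    def start(self) -> float:
        return self.center - self.width / 2.0

    @property
    def end(self) -> float:
        return self.center + self.width / 2.0

    @property
    def span(self) -> tuple[float, float]:
        return (self.start, self.end)


@dataclass(frozen=True)
class SensorSegment:
    """Fixed-length (L, 6) sensor window; ``pad_flags[i]`` marks edge-padded rows."""

    samples: np.ndarray
    window: TimeWindow
    pad_flags: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        p = np.asarray(self.pad_flags, dtype=bool)
        if s.ndim != 2 or s.shape[1] != 6:
            raise ValueError(f"segment must be (L, 6), got {s.shape}")
        if p.shape != (s.shape[0],):
            raise ValueError("pad_flags length must match segment rows")
        object.__setattr__(self, "samples", s)
        object.__setattr__(self, "pad_flags", p)

    @property
    def length(self) -> int:
        return self.samples.shape[0]


@dataclass(frozen=True)
class FramePayload:
    """A single frame (low rate) or K-frame sequence (high rate).

    ``features`` is either a (d,) vector or a (K, d) matrix of per-frame
    feature vectors; ``images``, when present, is (H, W, C) or (K, H, W, C)
    raster data instead. ``timestamps`` gives the shooting time(s).
    """

    timestamps: np.ndarray
    features: np.ndarray | None = None
    images: np.ndarray | None = None

    def __post_init__(self) -> None:
        ts = np.atleast_1d(np.asarray(self.timestamps, dtype=float))
        object.__setattr__(self, "timestamps", ts)
        if (self.features is None) == (self.images is None):
            raise ValueError("payload needs exactly one of features or images")
        if self.features is not None:
            object.__setattr__(self, "features", np.asarray(self.features, dtype=float))

    @property
    def is_sequence(self) -> bool:
        data = self.features if self.features is not None else self.images
        return data.ndim >= 2 and len(self.timestamps) > 1

    @property
    def n_frames(self) -> int:
        return len(self.timestamps)


@dataclass
class AlignedSample:
    """One (sensor segment, frame payload) pair with optional ground truth."""

    segment: SensorSegment
    payload: FramePayload
    activity: str | None = None
    state: str | None = None
    sample_id: int | None = None


# -- window operations ----------------------------------------------------


def window_for_frame(t_c: float, t_w: float) -> TimeWindow:
    """Window of width ``t_w`` centered on a frame's shooting time ``t_c``."""
    return TimeWindow(center=float(t_c), width=float(t_w))


def overlaps(w1: TimeWindow, w2: TimeWindow) -> bool:
    """True iff the two half-open windows intersect."""
    return w1.start < w2.end and w2.start < w1.end


def segment_length(fs: float, t_w: float) -> int:
    return int(round(fs * t_w))


def extract_segment(stream: SensorStream, window: TimeWindow) -> SensorSegment:
    """Extract the fixed-length sample block covered by ``window``.

    Sample rows are selected by nearest-index binning from ``fs`` (jitter-free
    and deterministic). Rows whose nominal index falls before the first or
    after the last recorded sample are filled with the edge sample and
    flagged in ``pad_flags``. A window that touches no recorded data at all
    raises.
    """
    s0, s1 = stream.span
    if window.end <= s0 or window.start >= s1:
        raise ValueError(
            f"window [{window.start}, {window.end}) lies outside stream "
            f"[{s0}, {s1})"
        )
    L = segment_length(stream.fs, window.width)
    # nominal sample indices of the window rows relative to stream start
    first = int(round((window.start - stream.t0) * stream.fs))
    idx = first + np.arange(L)
    clipped = np.clip(idx, 0, stream.n_samples - 1)
    pad = (idx < 0) | (idx >= stream.n_samples)
    return SensorSegment(stream.values[clipped], window, pad)


def segment_stream(stream: SensorStream, t_w: float, dc: float) -> list[SensorSegment]:
    """Cut a stream into ``floor(D / dc)`` windows with centers every ``dc`` s.

    Centers sit at ``t0 + (k + 0.5) * dc``; with ``dc < t_w`` adjacent
    segments overlap, with ``dc >= t_w`` they are disjoint. Boundary windows
    are clipped against the recording and edge-padded to full length.
    """
    if t_w <= 0 or dc <= 0:
        raise ValueError("t_w and dc must be positive")
    D = stream.duration
    count = int(np.floor(D / dc + 1e-9))
    if count < 1:
        raise ValueError(f"stream duration {D:.3f}s shorter than spacing {dc}s")
    out = []
    for k in range(count):
        w = TimeWindow(stream.t0 + (k + 0.5) * dc, t_w)
        out.append(extract_segment(stream, w))
    return out


def associate(
    stream: SensorStream,
    manifest: list[FramePayload] | pd.DataFrame,
    t_w: float,
    labels: list[str] | None = None,
) -> tuple[list[AlignedSample], int]:
    """Pair every frame with its centered sensor window.

    ``manifest`` is a list of payloads (their first timestamp is the frame
    center) or a DataFrame with column ``t`` plus feature columns. Frames
    whose window misses the recording entirely are skipped with a warning;
    the number skipped is returned alongside the pairs. Order is preserved.
    """
    payloads: list[FramePayload]
    if isinstance(manifest, pd.DataFrame):
        feat_cols = [c for c in manifest.columns if c not in ("t", "label")]
        payloads = [
            FramePayload(timestamps=[row["t"]], features=row[feat_cols].to_numpy(float))
            for _, row in manifest.iterrows()
        ]
        if labels is None and "label" in manifest.columns:
            labels = list(manifest["label"])
    else:
        payloads = list(manifest)

    samples: list[AlignedSample] = []
    skipped = 0
    for i, payload in enumerate(payloads):
        t_c = float(payload.timestamps[0])
        window = window_for_frame(t_c, t_w)
        try:
            seg = extract_segment(stream, window)
        except ValueError:
            skipped += 1
            logger.warning(
                "frame %d at t=%.3fs has no intersecting sensor data; skipped", i, t_c
            )
            continue
        samples.append(
            AlignedSample(
                segment=seg,
                payload=payload,
                activity=labels[i] if labels is not None else None,
                sample_id=i,
            )
        )
    return samples, skipped


# -- I/O -------------------------------------------------------------------


def read_sensor_csv(path) -> SensorStream:
    """Read a stream from CSV with columns t, ax, ay, az, gx, gy, gz."""
    df = pd.read_csv(path)
    missing = [c for c in ("t",) + CHANNEL_NAMES if c not in df.columns]
    if missing:
        raise ValueError(f"sensor CSV missing columns: {missing}")
    t = df["t"].to_numpy(float)
    if len(t) < 2:
        raise ValueError("sensor CSV needs at least two samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("timestamps must be strictly increasing")
    fs = 1.0 / float(np.median(dt))
    return SensorStream(t0=float(t[0]), fs=fs, values=df[list(CHANNEL_NAMES)].to_numpy(float))


def write_sensor_csv(stream: SensorStream, path) -> None:
    df = pd.DataFrame(stream.values, columns=list(CHANNEL_NAMES))
    df.insert(0, "t", stream.timestamps)
    df.to_csv(path, index=False)


def save_aligned(samples: list[AlignedSample], path) -> None:
    """Serialize an aligned dataset to a single .npz archive."""
    import json

    segs = np.stack([s.segment.samples for s in samples])
    pads = np.stack([s.segment.pad_flags for s in samples])
    centers = np.array([s.segment.window.center for s in samples])
    widths = np.array([s.segment.window.width for s in samples])
    feats = np.stack([s.payload.features for s in samples])
    ftimes = np.stack([s.payload.timestamps for s in samples])
    meta = {
        "activities": [s.activity for s in samples],
        "states": [s.state for s in samples],
        "sample_ids": [s.sample_id for s in samples],
    }
    np.savez_compressed(
        path,
        segments=segs,
        pad_flags=pads,
        centers=centers,
        widths=widths,
        features=feats,
        frame_times=ftimes,
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
    )


def load_aligned(path) -> list[AlignedSample]:
    import json

    with np.load(path) as z:
        meta = json.loads(bytes(z["meta"]).decode())
        out = []
        for i in range(z["segments"].shape[0]):
            seg = SensorSegment(
                z["segments"][i],
                TimeWindow(float(z["centers"][i]), float(z["widths"][i])),
                z["pad_flags"][i],
            )
            payload = FramePayload(timestamps=z["frame_times"][i], features=z["features"][i])
            out.append(
                AlignedSample(
                    segment=seg,
                    payload=payload,
                    activity=meta["activities"][i],
                    state=meta["states"][i],
                    sample_id=meta["sample_ids"][i],
                )
            )
    return out
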