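"""Raw EEG handling: trimming, resampling, segmentation, PERCLOS labels.

The processing chain mirrors the vigilance-monitoring convention: recordings
are trimmed at both ends to drop setup/teardown noise, resampled to 200 Hz
(the five bands of interest all lie below 51 Hz, so this keeps every band
comfortably under Nyquist), cut into non-overlapping 8-second segments —
one vigilance label per segment — and each segment is split into
half-second frames for the temporal axis of the 4D feature tensor.

PERCLOS (percentage of eye closure) is the fraction of an observation
window during which the eyes are closed.  The binary awake/fatigue split
uses a 0.35 threshold; a ternary scheme adds a drowsy class at 0.7.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.signal import resample_poly

__all__ = [
    "RawRecording",
    "Segment",
    "PerclosRecord",
    "SEEDVIG_CHANNELS",
    "AWAKE",
    "FATIGUE",
    "DROWSY",
    "PERCLOS_FATIGUE_THRESHOLD",
    "PERCLOS_DROWSY_THRESHOLD",
    "trim_recording",
    "downsample",
    "segment_8s",
    "frame_segment",
    "perclos",
    "label_from_perclos",
    "load_recording",
    "save_recording",
    "load_label_stream",
    "load_seedvig_mat",
]

#: 10-20 channels of the 17-channel vigilance montage: twelve posterior
#: sites plus six temporal sites, with CPZ serving as the reference (and
#: therefore not a recording channel).
SEEDVIG_CHANNELS: tuple[str, ...] = (
    "FT7", "FT8", "T7", "T8", "TP7", "TP8",
    "CP1", "CP2", "P1", "PZ", "P2",
    "PO3", "POZ", "PO4", "O1", "OZ", "O2",
)

AWAKE, FATIGUE, DROWSY = 0, 1, 2
PERCLOS_FATIGUE_THRESHOLD = 0.35
PERCLOS_DROWSY_THRESHOLD = 0.70

SEGMENT_SECONDS = 8.0


@dataclass
class RawRecording:
    """Multi-channel EEG: ``data`` is channels x samples in microvolts."""

    data: np.ndarray
    rate: float
    channel_names: tuple[str, ...] = ()

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data))
        if self.data.ndim != 2:
            raise ValueError("recording data must be channels x samples")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if not self.channel_names:
            self.channel_names = tuple(f"ch{i}" for i in range(self.data.shape[0]))
        self.channel_names = tuple(self.channel_names)
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("one channel name per row required")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate


@dataclass
class Segment:
    """Exactly eight seconds of EEG plus its vigilance annotation."""

    data: np.ndarray
    rate: float
    channel_names: tuple[str, ...] = ()
    label: int | None = None
    perclos: float | None = None

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data))
        expected = int(round(SEGMENT_SECONDS * self.rate))
        if self.data.shape[1] != expected:
            raise ValueError(
                f"segment must hold exactly {expected} samples at {self.rate} Hz, "
                f"got {self.data.shape[1]}"
            )
        if not self.channel_names:
            self.channel_names = tuple(f"ch{i}" for i in range(self.data.shape[0]))


@dataclass
class PerclosRecord:
    """Eye-closure bookkeeping over one observation window."""

    eye_closure_time: float
    total_observed_time: float
    value: float = field(init=False)

    def __post_init__(self):
        if self.total_observed_time <= 0:
            raise ValueError("total observed time must be positive")
        if not 0 <= self.eye_closure_time <= self.total_observed_time:
            raise ValueError("eye closure time must lie within the observed window")
        self.value = self.eye_closure_time / self.total_observed_time


def trim_recording(rec: RawRecording, head_s: float, tail_s: float) -> RawRecording:
    """Drop ``head_s`` seconds from the start and ``tail_s`` from the end."""
    if head_s < 0 or tail_s < 0:
        raise ValueError("trim durations must be non-negative")
    head = int(round(head_s * rec.rate))
    tail = int(round(tail_s * rec.rate))
    if head + tail >= rec.n_samples:
        raise ValueError(
            f"cannot trim {head_s}+{tail_s} s from a {rec.duration:.1f} s recording"
        )
    stop = rec.n_samples - tail
    return RawRecording(rec.data[:, head:stop], rec.rate, rec.channel_names)


def downsample(rec: RawRecording, target_rate: float) -> RawRecording:
    """Anti-aliased (polyphase) resampling to ``target_rate``."""
    if target_rate > rec.rate:
        raise ValueError("target rate exceeds the recording rate")
    if target_rate == rec.rate:
        return RawRecording(rec.data.copy(), rec.rate, rec.channel_names)
    from fractions import Fraction

    frac = Fraction(target_rate / rec.rate).limit_denominator(1000)
    out = resample_poly(rec.data, frac.numerator, frac.denominator, axis=1)
    return RawRecording(out, target_rate, rec.channel_names)


def segment_8s(rec: RawRecording, labels=None, perclos_values=None) -> list[Segment]:
    """Cut into non-overlapping 8-s segments, chronological, remainder dropped.

    ``labels``/``perclos_values`` are optional per-window sequences (one entry
    per 8-s window, as in datasets that publish a label every 8 s).
    """
    win = int(round(SEGMENT_SECONDS * rec.rate))
    n = rec.n_samples // win
    segments = []
    for i in range(n):
        segments.append(
            Segment(
                rec.data[:, i * win : (i + 1) * win],
                rec.rate,
                rec.channel_names,
                label=None if labels is None else int(labels[i]),
                perclos=None if perclos_values is None else float(perclos_values[i]),
            )
        )
    return segments


def frame_segment(seg: Segment, frame_s: float = 0.5) -> np.ndarray:
    """Split a segment into non-overlapping frames: (m, 2T, rate*frame_s).

    ``frame_s`` must divide the 8-s segment exactly; the default half-second
    frames give 2T = 16.  Concatenating the frames reproduces the segment.
    """
    n_frames_f = SEGMENT_SECONDS / frame_s
    n_frames = int(round(n_frames_f))
    samples = int(round(frame_s * seg.rate))
    if abs(n_frames_f - n_frames) > 1e-9 or n_frames * samples != seg.data.shape[1]:
        raise ValueError(f"frame length {frame_s}s does not divide the 8 s segment")
    m = seg.data.shape[0]
    return seg.data.reshape(m, n_frames, samples)


def perclos(closure_s: float, window_s: float = 8.0) -> PerclosRecord:
    """PERCLOS = eye-closure time / total observed time (default 8-s window)."""
    return PerclosRecord(closure_s, window_s)


def label_from_perclos(
    p: PerclosRecord | float,
    scheme: str = "binary",
    strict_boundaries: bool = False,
) -> int:
    """Map a PERCLOS value to a class id.

    binary: awake below 0.35, fatigue at or above.  ternary: adds drowsy at
    0.7.  Values exactly on a threshold go to the higher (more fatigued)
    class unless ``strict_boundaries`` is set.
    """
    value = p.value if isinstance(p, PerclosRecord) else float(p)
    if not 0 <= value <= 1:
        raise ValueError("PERCLOS value must lie in [0, 1]")
    if scheme not in ("binary", "ternary"):
        raise ValueError(f"unknown labeling scheme: {scheme!r}")

    def at_least(threshold: float) -> bool:
        return value > threshold if strict_boundaries else value >= threshold

    if scheme == "ternary" and at_least(PERCLOS_DROWSY_THRESHOLD):
        return DROWSY
    if at_least(PERCLOS_FATIGUE_THRESHOLD):
        return FATIGUE
    return AWAKE


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def save_recording(path, rec: RawRecording) -> None:
    """Write a recording as ``<path>.npz`` plus a ``<path>.yaml`` sidecar."""
    path = Path(path)
    np.savez_compressed(path.with_suffix(".npz"), data=rec.data)
    meta = {"rate": float(rec.rate), "channel_names": list(rec.channel_names)}
    path.with_suffix(".yaml").write_text(yaml.safe_dump(meta))


def load_recording(path) -> RawRecording:
    """Read a channels x samples array container with a YAML/JSON sidecar."""
    path = Path(path)
    array_path = path if path.suffix in (".npz", ".npy") else path.with_suffix(".npz")
    if array_path.suffix == ".npz":
        with np.load(array_path) as data:
            arr = data["data"]
    else:
        arr = np.load(array_path)
    meta = None
    for ext in (".yaml", ".yml", ".json"):
        side = array_path.with_suffix(ext)
        if side.exists():
            text = side.read_text()
            meta = json.loads(text) if ext == ".json" else yaml.safe_load(text)
            break
    if meta is None:
        raise FileNotFoundError(f"no sidecar config next to {array_path}")
    return RawRecording(arr, float(meta["rate"]), tuple(meta.get("channel_names", ())))


def load_label_stream(path, window_s: float = 8.0) -> pd.DataFrame:
    """Read a label CSV with columns window_start_s and eye_closure_s or perclos.

    Returns a frame with window_start_s, perclos and a binary label column.
    """
    df = pd.read_csv(path)
    if "perclos" not in df.columns:
        if "eye_closure_s" not in df.columns:
            raise ValueError("label CSV needs an eye_closure_s or perclos column")
        df["perclos"] = df["eye_closure_s"] / window_s
    bad = (df["perclos"] < 0) | (df["perclos"] > 1)
    if bad.any():
        raise ValueError("PERCLOS values outside [0, 1] in label stream")
    df["label"] = [label_from_perclos(v) for v in df["perclos"]]
    return df


def load_seedvig_mat(path, key: str | None = None, rate: float = 200.0) -> RawRecording:
    """Best-effort reader for MATLAB containers holding channels x samples EEG."""
    from scipy.io import loadmat

    mat = loadmat(path)
    candidates = {k: v for k, v in mat.items() if isinstance(v, np.ndarray) and v.ndim == 2}
    if key is None:
        if not candidates:
            raise ValueError("no 2-D array found in MATLAB container")
        key = max(candidates, key=lambda k: candidates[k].size)
        if len(candidates) > 1:
            warnings.warn(f"multiple arrays in {path}; using {key!r}", stacklevel=2)
    arr = np.asarray(mat[key])
    if arr.shape[0] > arr.shape[1]:  # stored samples x channels
        arr = arr.T
    names = SEEDVIG_CHANNELS if arr.shape[0] == len(SEEDVIG_CHANNELS) else ()
    return RawRecording(arr, rate, names)
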