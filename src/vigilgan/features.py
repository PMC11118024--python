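"""4D differential-entropy features: band -> DE -> electrode grid -> time.

One 8-s segment becomes a tensor of shape ``(h, w, d, 2T)``:

* ``d = 5`` frequency bands — delta (1-4 Hz), theta (4-8), alpha (8-14),
  beta (14-31), gamma (31-51) — extracted with a zero-phase order-4
  Butterworth band-pass (band edges are the -3 dB corners);
* per half-second frame and band, the differential entropy of the
  band-limited signal.  Band-passed short frames are well modeled as
  Gaussian, so DE uses the Gaussian closed form
  ``DE = 1/2 ln(2 pi e sigma^2)`` with ``sigma^2`` the frame variance;
* ``(h, w) = (6, 9)``: DE values are placed on a 2D electrode-layout grid
  so convolutions can see scalp topography.  Grid cells without an
  electrode stay exactly zero;
* ``2T = 16`` half-second frames preserve within-segment temporal order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .preprocess import Segment, frame_segment

__all__ = [
    "BandSpec",
    "DEFAULT_BANDS",
    "DESegment",
    "ElectrodeGrid",
    "Feature4D",
    "bandpass",
    "differential_entropy",
    "map_to_grid",
    "build_features",
    "features_to_band_signals",
]

#: variance floor inside the DE logarithm (guards degenerate frames)
VARIANCE_FLOOR = 1e-12


@dataclass(frozen=True)
class BandSpec:
    """One frequency band: half-power corner frequencies in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self):
        if not 0 < self.low < self.high:
            raise ValueError(f"invalid band edges for {self.name}: {self.low}-{self.high}")


DEFAULT_BANDS: tuple[BandSpec, ...] = (
    BandSpec("delta", 1.0, 4.0),
    BandSpec("theta", 4.0, 8.0),
    BandSpec("alpha", 8.0, 14.0),
    BandSpec("beta", 14.0, 31.0),
    BandSpec("gamma", 31.0, 51.0),
)


def bands_from_yaml(path) -> tuple[BandSpec, ...]:
    """Load a band table from YAML: a list of {name, low, high} mappings."""
    import yaml

    entries = yaml.safe_load(Path(path).read_text())
    return tuple(BandSpec(e["name"], float(e["low"]), float(e["high"])) for e in entries)


@dataclass
class DESegment:
    """Differential entropies of one segment: (m channels, d bands, 2T frames)."""

    values: np.ndarray
    channel_names: tuple[str, ...]
    band_names: tuple[str, ...] = tuple(b.name for b in DEFAULT_BANDS)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("DESegment values must be (channels, bands, frames)")
        if not np.isfinite(self.values).all():
            raise ValueError("DE values must be finite")


# ---------------------------------------------------------------------------
# electrode grid
# ---------------------------------------------------------------------------

# Default dense 6x9 layout for the 17-channel montage.  Rows run
# front-to-back (FT / T / TP / CP / P / parieto-occipital+occipital sharing
# the bottom row), columns left to right; the exact published cell
# assignment is not recoverable, so this mapping ships as an editable,
# versioned table (see ElectrodeGrid.from_csv).
_DENSE_MAPPING: dict[str, tuple[int, int]] = {
    "FT7": (0, 0), "FT8": (0, 8),
    "T7": (1, 0), "T8": (1, 8),
    "TP7": (2, 0), "TP8": (2, 8),
    "CP1": (3, 3), "CP2": (3, 5),
    "P1": (4, 3), "PZ": (4, 4), "P2": (4, 5),
    "PO3": (5, 2), "O1": (5, 3), "POZ": (5, 4),
    "OZ": (5, 5), "O2": (5, 6), "PO4": (5, 7),
}


@dataclass
class ElectrodeGrid:
    """Injective map from channel names to (row, col) cells of an h x w grid."""

    mapping: dict[str, tuple[int, int]]
    height: int
    width: int
    style: str = "dense"

    def __post_init__(self):
        coords = list(self.mapping.values())
        if len(set(coords)) != len(coords):
            raise ValueError("two channels mapped to the same grid cell")
        for name, (r, c) in self.mapping.items():
            if not (0 <= r < self.height and 0 <= c < self.width):
                raise ValueError(f"channel {name} mapped outside the {self.height}x{self.width} grid")

    @classmethod
    def dense(cls) -> "ElectrodeGrid":
        """The default 6x9 dense layout of the 17-channel montage."""
        return cls(dict(_DENSE_MAPPING), 6, 9, "dense")

    @classmethod
    def sparse(cls) -> "ElectrodeGrid":
        """Full-scalp variant with zero cells interleaved (ablation layout)."""
        mapping = {name: (2 * r, 2 * c) for name, (r, c) in _DENSE_MAPPING.items()}
        return cls(mapping, 11, 17, "sparse")

    @classmethod
    def from_csv(cls, path, height: int, width: int, style: str = "custom") -> "ElectrodeGrid":
        df = pd.read_csv(path)
        mapping = {str(r.channel): (int(r.row), int(r.col)) for r in df.itertuples()}
        return cls(mapping, height, width, style)

    def to_csv(self, path) -> None:
        rows = [{"channel": ch, "row": r, "col": c} for ch, (r, c) in self.mapping.items()]
        pd.DataFrame(rows).to_csv(path, index=False)

    @property
    def mask(self) -> np.ndarray:
        """Boolean (h, w) array marking mapped cells."""
        m = np.zeros((self.height, self.width), dtype=bool)
        for r, c in self.mapping.values():
            m[r, c] = True
        return m


@dataclass
class Feature4D:
    """The (h, w, d, 2T) feature tensor of one segment."""

    values: np.ndarray
    label: int | None = None
    perclos: float | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 4:
            raise ValueError("Feature4D values must be (h, w, d, 2T)")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def _band_sos(band: BandSpec, rate: float, order: int = 4):
    nyq = rate / 2.0
    if band.high >= nyq:
        raise ValueError(f"band {band.name} ({band.low}-{band.high} Hz) exceeds Nyquist ({nyq} Hz)")
    return butter(order, [band.low / nyq, band.high / nyq], btype="bandpass", output="sos")


def bandpass(signal: np.ndarray, band: BandSpec, rate: float, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis."""
    sos = _band_sos(band, rate, order)
    return sosfiltfilt(sos, np.asarray(signal, dtype=float), axis=-1)


def differential_entropy(frame: np.ndarray, floor: float = VARIANCE_FLOOR) -> float | np.ndarray:
    """Gaussian differential entropy (nats) of sample vectors, last axis.

    ``DE = 1/2 ln(2 pi e sigma^2)``; degenerate (near-constant) frames are
    clamped to the variance floor with a warning.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.shape[-1] < 2:
        raise ValueError("differential entropy needs at least two samples")
    var = frame.var(axis=-1)
    if np.any(var <= floor):
        warnings.warn("zero-variance frame: differential entropy clamped to floor", stacklevel=2)
    var = np.maximum(var, floor)
    return 0.5 * np.log(2.0 * np.pi * np.e * var)


def de_segment(
    seg: Segment,
    bands: tuple[BandSpec, ...] = DEFAULT_BANDS,
    frame_s: float = 0.5,
) -> DESegment:
    """Band-pass the segment, frame it, and take per-frame DE: (m, d, 2T)."""
    m = seg.data.shape[0]
    out = []
    for band in bands:
        filtered = bandpass(seg.data, band, seg.rate)
        framed = Segment(filtered, seg.rate, seg.channel_names)
        frames = frame_segment(framed, frame_s)          # (m, 2T, samples)
        out.append(differential_entropy(frames))          # (m, 2T)
    values = np.stack(out, axis=1)                        # (m, d, 2T)
    return DESegment(values, tuple(seg.channel_names), tuple(b.name for b in bands))


def map_to_grid(de: DESegment, grid: ElectrodeGrid) -> Feature4D:
    """Scatter per-channel DE onto the 2D electrode grid; empty cells stay 0."""
    missing = [ch for ch in de.channel_names if ch not in grid.mapping]
    if missing:
        raise KeyError(f"channels without a grid coordinate: {missing}")
    m, d, t = de.values.shape
    out = np.zeros((grid.height, grid.width, d, t))
    for i, ch in enumerate(de.channel_names):
        r, c = grid.mapping[ch]
        out[r, c] = de.values[i]
    return Feature4D(out)


def build_features(
    seg: Segment,
    bands: tuple[BandSpec, ...] = DEFAULT_BANDS,
    grid: ElectrodeGrid | None = None,
    frame_s: float = 0.5,
) -> Feature4D:
    """Full pipeline for one segment: band-pass -> frame -> DE -> grid."""
    grid = grid or ElectrodeGrid.dense()
    feat = map_to_grid(de_segment(seg, bands, frame_s), grid)
    feat.label = seg.label
    feat.perclos = seg.perclos
    return feat


def features_to_band_signals(values: np.ndarray, grid: ElectrodeGrid | None = None) -> np.ndarray:
    """Collapse a Feature4D array to per-band DE time courses: (d, cells*2T).

    The mapped grid cells are flattened in a fixed order and concatenated
    along frames, giving one 1-D trace per frequency band.  This is the
    dimensionality reduction used when comparing real and generated feature
    tensors with wavelet coherence; it is deliberately simple and pluggable.
    """
    grid = grid or ElectrodeGrid.dense()
    values = np.asarray(values)
    rows, cols = np.nonzero(grid.mask)
    picked = values[rows, cols]          # (cells, d, 2T)
    d = picked.shape[1]
    return picked.transpose(1, 0, 2).reshape(d, -1)
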