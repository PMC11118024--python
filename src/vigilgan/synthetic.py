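"""Seeded synthetic EEG with class-dependent band power and PERCLOS labels.

The generator emulates the structure of a 17-channel, 200 Hz vigilance
recording: every 8-second window belongs to a vigilance class, and the
class determines the RMS amplitude of five narrowband rhythms (delta,
theta, alpha, beta, gamma).  The fatigue profile follows the conventional
drowsiness signature — elevated alpha and theta, suppressed beta/gamma —
with a 3x alpha contrast by default.  Oscillations are realized as
narrowband-filtered noise (not pure sinusoids) so per-frame variances are
non-degenerate, on top of a pink (1/f) background with a white floor.
Each window also carries an eye-closure duration drawn from a
class-dependent Beta distribution straddling the 0.35 PERCLOS threshold,
so labels can be recomputed from the eye-closure stream.

Everything is a deterministic function of the seed.  What this fixture
does NOT emulate: volume-conduction correlations between channels,
artifacts (blinks, EMG), non-stationarity within a window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import DEFAULT_BANDS, BandSpec, ElectrodeGrid, bandpass, build_features
from .preprocess import SEEDVIG_CHANNELS, RawRecording, label_from_perclos, segment_8s

__all__ = ["SyntheticConfig", "generate_recording", "generate_feature_dataset", "band_power_features"]

#: per-class band RMS amplitudes (microvolts); class 0 awake, class 1 fatigue
_DEFAULT_PROFILES = {
    0: {"delta": 4.0, "theta": 3.0, "alpha": 4.0, "beta": 6.0, "gamma": 3.0},
    1: {"delta": 4.0, "theta": 6.0, "alpha": 12.0, "beta": 3.0, "gamma": 1.5},
}

#: Beta(a, b) parameters of the per-window eye-closure fraction
_DEFAULT_PERCLOS = {0: (2.0, 16.0), 1: (9.0, 4.0)}


def _default_spatial_weights(channel_names, bands) -> np.ndarray:
    """Unit gains, alpha emphasized posteriorly, theta over fronto-temporal sites."""
    w = np.ones((len(channel_names), len(bands)))
    band_idx = {b.name: i for i, b in enumerate(bands)}
    for i, ch in enumerate(channel_names):
        if ch.startswith(("PO", "O")) and "alpha" in band_idx:
            w[i, band_idx["alpha"]] = 1.5
        if ch.startswith(("FT", "T", "TP")) and "theta" in band_idx:
            w[i, band_idx["theta"]] = 1.2
    return w


@dataclass
class SyntheticConfig:
    """Study conditions of the synthetic benchmark (all seeded)."""

    channel_names: tuple[str, ...] = SEEDVIG_CHANNELS
    rate: float = 200.0
    bands: tuple[BandSpec, ...] = DEFAULT_BANDS
    class_profiles: dict = field(default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_PROFILES.items()})
    spatial_weights: np.ndarray | None = None
    noise_sd: float = 1.0
    perclos_dynamics: dict = field(default_factory=lambda: dict(_DEFAULT_PERCLOS))

    def __post_init__(self):
        if self.spatial_weights is None:
            self.spatial_weights = _default_spatial_weights(self.channel_names, self.bands)
        self.spatial_weights = np.asarray(self.spatial_weights, dtype=float)
        if self.spatial_weights.shape != (len(self.channel_names), len(self.bands)):
            raise ValueError("spatial_weights must be channels x bands")
        for profile in self.class_profiles.values():
            if any(a < 0 for a in profile.values()):
                raise ValueError("band amplitudes must be non-negative")
        if self.rate <= 2 * max(b.high for b in self.bands):
            raise ValueError("sampling rate must exceed twice the highest band edge")

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)


def _pink_noise(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """1/f-amplitude noise with a 20% white floor, unit RMS per channel."""
    m, n = shape
    white = rng.standard_normal((m, n))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n)
    weight = np.zeros_like(freqs)
    weight[1:] = 1.0 / np.sqrt(freqs[1:])
    shaped = np.fft.irfft(spec * weight, n=n, axis=1)
    shaped /= shaped.std(axis=1, keepdims=True)
    out = 0.8 * shaped + 0.2 * rng.standard_normal((m, n))
    return out / out.std(axis=1, keepdims=True)


def generate_recording(
    cfg: SyntheticConfig,
    class_sequence,
    seed: int = 0,
) -> tuple[RawRecording, pd.DataFrame]:
    """Synthesize one recording plus its eye-closure label stream.

    ``class_sequence`` gives the vigilance class of each 8-s window.  The
    window signal is the sum over bands of
    ``amplitude(class, band) * spatial_weight(channel, band) * narrowband
    oscillation`` plus pink background noise, and the paired label stream
    holds one Beta-distributed eye-closure fraction per window.
    """
    classes = np.asarray(list(class_sequence), dtype=int)
    if classes.size == 0:
        raise ValueError("class_sequence must not be empty")
    unknown = set(classes.tolist()) - set(cfg.class_profiles)
    if unknown:
        raise ValueError(f"classes without a band profile: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    win = int(round(8.0 * cfg.rate))
    m, total = cfg.n_channels, classes.size * win

    data = np.zeros((m, total))
    for bi, band in enumerate(cfg.bands):
        osc = bandpass(rng.standard_normal((m, total)), band, cfg.rate)
        osc /= osc.std(axis=1, keepdims=True)
        amp_per_window = np.array([cfg.class_profiles[c][band.name] for c in classes])
        gains = np.repeat(amp_per_window[None, :], win, axis=0).T.reshape(1, total)
        data += osc * gains * cfg.spatial_weights[:, bi : bi + 1]
    if cfg.noise_sd > 0:
        data += cfg.noise_sd * _pink_noise(rng, (m, total))

    closure_frac = np.empty(classes.size)
    for i, c in enumerate(classes):
        a, b = cfg.perclos_dynamics[int(c)]
        closure_frac[i] = rng.beta(a, b)
    stream = pd.DataFrame(
        {
            "window_start_s": np.arange(classes.size) * 8.0,
            "eye_closure_s": closure_frac * 8.0,
            "perclos": closure_frac,
            "class": classes,
        }
    )
    stream["label"] = [label_from_perclos(v) for v in stream["perclos"]]
    rec = RawRecording(data, cfg.rate, cfg.channel_names)
    return rec, stream


def generate_feature_dataset(
    cfg: SyntheticConfig | None = None,
    n_per_class: tuple[int, ...] = (100, 100),
    seed: int = 0,
    grid: ElectrodeGrid | None = None,
    label_source: str = "requested",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """End-to-end synthetic dataset: (features (n, h, w, d, 2T), labels, perclos).

    ``n_per_class`` may be imbalanced, e.g. ``(100, 50)`` for a 2:1 ratio.
    ``label_source`` chooses between the requested window classes and the
    labels recomputed from the embedded eye-closure stream.
    """
    cfg = cfg or SyntheticConfig()
    grid = grid or ElectrodeGrid.dense()
    classes = np.concatenate([np.full(n, k, dtype=int) for k, n in enumerate(n_per_class)])
    rng = np.random.default_rng(seed)
    rng.shuffle(classes)
    rec, stream = generate_recording(cfg, classes, seed=seed + 1)
    segments = segment_8s(rec, labels=stream["class"], perclos_values=stream["perclos"])
    feats = np.stack([build_features(s, cfg.bands, grid).values for s in segments])
    if label_source == "requested":
        labels = stream["class"].to_numpy()
    elif label_source == "perclos":
        labels = stream["label"].to_numpy()
    else:
        raise ValueError(f"unknown label_source: {label_source!r}")
    return feats, labels, stream["perclos"].to_numpy()


def band_power_features(features: np.ndarray, grid: ElectrodeGrid | None = None) -> np.ndarray:
    """Mean DE per band over mapped cells and frames: (n, d) summary features."""
    grid = grid or ElectrodeGrid.dense()
    rows, cols = np.nonzero(grid.mask)
    picked = np.asarray(features)[:, rows, cols]     # (n, cells, d, 2T)
    return picked.mean(axis=(1, 3))
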