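"""Classification metrics and wavelet-coherence similarity between signals.

Classification quality uses the standard contingency metrics (accuracy,
precision, recall, F1, Cohen's kappa).  Similarity between two signal sets
— e.g. real versus generated feature traces — uses magnitude-squared
wavelet coherence

    wc(a, b) = |S( conj(Cx(a,b)) * Cy(a,b) )|^2
               -----------------------------------
               S(|Cx(a,b)|^2) * S(|Cy(a,b)|^2)

where ``Cx, Cy`` are continuous wavelet transforms (analytic Morlet,
omega0 = 6), ``a`` indexes scale, ``b`` time, and ``S`` is a smoothing
operator (boxcar in time with width proportional to scale, and a 3-voice
boxcar across scales).  Without smoothing the ratio is identically one;
with it, wc lies in [0, 1] per (scale, time) cell and is collapsed to a
scalar score by averaging along time and then across scales.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pywt
from scipy.ndimage import uniform_filter1d
from sklearn.metrics import (
    accuracy_score,
    cohen_kappa_score,
    f1_score,
    precision_score,
    recall_score,
)

__all__ = [
    "MetricsReport",
    "WcReport",
    "classification_metrics",
    "wavelet_coherence",
    "wc_scalar",
    "wc_multidim",
    "wc_groups",
]

#: analytic Morlet with omega0 = 6 (bandwidth 2, center frequency 6/(2 pi))
_WAVELET = "cmor2.0-0.9549"
_N_SCALES = 32


@dataclass
class MetricsReport:
    """Contingency-table metrics; kappa is NaN when truth has one class."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    kappa: float

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "kappa": self.kappa,
        }


@dataclass
class WcReport:
    """Wavelet-coherence matrix (scales x time) plus its scalar collapse."""

    matrix: np.ndarray
    scalar: float
    periods: np.ndarray


def classification_metrics(truth, pred) -> MetricsReport:
    """Standard metrics; binary averaging with class 1 (fatigue) positive,
    macro averaging beyond two classes."""
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    if truth.shape != pred.shape:
        raise ValueError("truth and prediction must have equal length")
    classes = np.unique(truth)
    average = "binary" if len(np.unique(np.concatenate([truth, pred]))) <= 2 else "macro"
    kwargs = {"average": average, "zero_division": 0}
    if average == "binary":
        kwargs["pos_label"] = int(classes.max()) if len(classes) else 1
    if len(classes) < 2:
        warnings.warn("single-class truth: kappa undefined (NaN)", stacklevel=2)
        kappa = float("nan")
    else:
        kappa = cohen_kappa_score(truth, pred)
    return MetricsReport(
        accuracy=float(accuracy_score(truth, pred)),
        precision=float(precision_score(truth, pred, **kwargs)),
        recall=float(recall_score(truth, pred, **kwargs)),
        f1=float(f1_score(truth, pred, **kwargs)),
        kappa=float(kappa),
    )


# ---------------------------------------------------------------------------
# wavelet coherence
# ---------------------------------------------------------------------------

def _cwt(x: np.ndarray, scales: np.ndarray) -> np.ndarray:
    coef, _ = pywt.cwt(x, scales, _WAVELET, method="fft")
    return coef


def _smooth(m: np.ndarray, scales: np.ndarray) -> np.ndarray:
    """Boxcar in time (width ~ 0.6 * scale, at least 3) then 3 voices in scale."""
    out = np.empty_like(m)
    for i, s in enumerate(scales):
        width = max(3, int(round(0.6 * s)))
        out[i] = uniform_filter1d(m[i], size=width, mode="nearest")
    return uniform_filter1d(out, size=3, axis=0, mode="nearest")


def _scale_grid(n: int) -> tuple[np.ndarray, np.ndarray]:
    periods = np.geomspace(4.0, n / 4.0, _N_SCALES)
    fc = pywt.central_frequency(_WAVELET)
    return periods * fc, periods


def wavelet_coherence(x, y) -> WcReport:
    """Smoothed magnitude-squared wavelet coherence of two equal-length series."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    if x.size < 32:
        raise ValueError("need at least 32 samples for wavelet coherence")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("wavelet coherence undefined for a constant series")

    scales, periods = _scale_grid(x.size)
    cx = _cwt(x, scales)
    cy = _cwt(y, scales)
    sxy = _smooth_complex(np.conj(cx) * cy, scales)
    sxx = _smooth(np.abs(cx) ** 2, scales)
    syy = _smooth(np.abs(cy) ** 2, scales)
    denom = sxx * syy
    with np.errstate(invalid="ignore", divide="ignore"):
        wc = np.abs(sxy) ** 2 / denom
    wc = np.clip(np.nan_to_num(wc, nan=0.0), 0.0, 1.0)
    return WcReport(matrix=wc, scalar=wc_scalar_from_matrix(wc), periods=periods)


def _smooth_complex(m: np.ndarray, scales: np.ndarray) -> np.ndarray:
    return _smooth(m.real, scales) + 1j * _smooth(m.imag, scales)


def wc_scalar_from_matrix(matrix: np.ndarray) -> float:
    """Collapse a coherence matrix: mean along time, then mean across scales."""
    return float(np.asarray(matrix).mean(axis=1).mean())


def wc_scalar(report: WcReport) -> float:
    return wc_scalar_from_matrix(report.matrix)


def wc_multidim(x: np.ndarray, y: np.ndarray) -> float:
    """Mean scalar coherence over matched channels of (channels, time) arrays."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if x.shape != y.shape:
        raise ValueError("signal sets must share (channels, time) shape")
    return float(np.mean([wavelet_coherence(xi, yi).scalar for xi, yi in zip(x, y)]))


def wc_groups(group_a, group_b) -> float:
    """Average pairwise multichannel coherence between two sets of signals."""
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValueError("both signal groups must be non-empty")
    scores = [wc_multidim(a, b) for a in group_a for b in group_b]
    return float(np.mean(scores))
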