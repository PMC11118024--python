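"""Confidence-based selection of generated samples and data-mixing studies.

Synthetic feature tensors are only admitted to a training set when the
discriminator's class head is confident about them: a sample conditioned on
class ``c`` is kept iff its maximum class posterior is at least the
threshold (default 0.90) AND the argmax class equals ``c``.  The argmax
requirement extends the plain confidence rule — without it, confidently
misclassified samples would enter the training set under the wrong label.

The mixing experiment trains a fresh classifier per data scenario:

* ``pure_real``       — the full budget of real samples;
* ``pure_synth``      — the full budget of selected synthetic samples;
* ``few_real``        — only the small real subset (default 20% of budget),
                        emulating data scarcity;
* ``few_real_plus_synth`` — the same small real subset topped up to the
                        full budget with selected synthetic samples.

The three full scenarios share the same total budget by construction, so
differences isolate the value of the data source rather than its volume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .evaluation import MetricsReport, classification_metrics
from .training import ACGANClassifier, ConditionalEEGGAN

__all__ = [
    "SelectionPolicy",
    "MixSpec",
    "SCENARIOS",
    "select_confident",
    "build_mix",
    "run_mixing_experiment",
]

SCENARIOS = ("pure_real", "pure_synth", "few_real", "few_real_plus_synth")


@dataclass
class SelectionPolicy:
    """Confidence threshold plus the classifier whose class head scores samples."""

    threshold: float = 0.90
    classifier: object = None  # anything with predict_proba + classes_

    def __post_init__(self):
        if not 0 < self.threshold <= 1:
            raise ValueError("confidence threshold must lie in (0, 1]")


@dataclass
class MixSpec:
    """One training-data scenario: total sample budget and real fraction."""

    scenario: str
    total: int
    real_fraction: float = 0.2

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; choose from {SCENARIOS}")
        if self.total < 1:
            raise ValueError("total size must be positive")
        if not 0 < self.real_fraction < 1:
            raise ValueError("real fraction must lie in (0, 1)")


def select_confident(
    samples: np.ndarray,
    labels: np.ndarray,
    policy: SelectionPolicy,
    probs: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Filter generated samples by class-head confidence.

    Keeps exactly those samples whose maximum class probability meets the
    threshold and whose argmax matches the conditioning label.  Returns
    (kept samples, kept labels, retention rate).  ``probs`` may be supplied
    directly (e.g. in tests); otherwise the policy's classifier scores the
    samples.
    """
    labels = np.asarray(labels, dtype=int)
    if probs is None:
        if policy.classifier is None:
            raise ValueError("selection policy has no classifier and no probabilities given")
        probs = policy.classifier.predict_proba(samples)
        classes = np.asarray(getattr(policy.classifier, "classes_", np.arange(probs.shape[1])))
    else:
        probs = np.asarray(probs, dtype=float)
        classes = np.arange(probs.shape[1])
    if probs.shape[0] != labels.shape[0]:
        raise ValueError("one probability row per sample required")
    argmax = classes[np.argmax(probs, axis=1)]
    keep = (probs.max(axis=1) >= policy.threshold) & (argmax == labels)
    retention = float(keep.mean()) if keep.size else 0.0
    if not keep.any():
        warnings.warn("confidence selection kept no samples", stacklevel=2)
    return np.asarray(samples)[keep], labels[keep], retention


def _balanced_choice(y: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """Sample n indices without replacement, preserving class balance."""
    classes, counts = np.unique(y, return_counts=True)
    fracs = counts / counts.sum()
    take = np.floor(fracs * n).astype(int)
    # distribute the remainder to the largest fractional parts
    rem = n - take.sum()
    order = np.argsort(-(fracs * n - take))
    take[order[:rem]] += 1
    if (take > counts).any():
        short = {int(c): int(t - cn) for c, t, cn in zip(classes, take, counts) if t > cn}
        raise ValueError(f"requested more samples than available per class: deficit {short}")
    idx = []
    for c, t in zip(classes, take):
        pool = np.flatnonzero(y == c)
        idx.append(rng.choice(pool, size=t, replace=False))
    return np.sort(np.concatenate(idx))


def build_mix(
    real: tuple[np.ndarray, np.ndarray],
    synth: tuple[np.ndarray, np.ndarray],
    spec: MixSpec,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Assemble one scenario's training set; deterministic per seed.

    Sampling is without replacement and class-balanced within each source.
    Returns (X, y, info) where info records the real/synthetic counts and
    the shared total budget.
    """
    rng = np.random.default_rng(seed)
    Xr, yr = np.asarray(real[0]), np.asarray(real[1], dtype=int)
    Xs, ys = np.asarray(synth[0]), np.asarray(synth[1], dtype=int)

    n_few = max(1, int(round(spec.real_fraction * spec.total)))
    wants = {
        "pure_real": (spec.total, 0),
        "pure_synth": (0, spec.total),
        "few_real": (n_few, 0),
        "few_real_plus_synth": (n_few, spec.total - n_few),
    }[spec.scenario]
    n_real, n_synth = wants
    if n_real > len(yr):
        raise ValueError(f"scenario {spec.scenario}: needs {n_real} real samples, have {len(yr)}")
    if n_synth > len(ys):
        raise ValueError(f"scenario {spec.scenario}: needs {n_synth} synthetic samples, have {len(ys)}")

    parts_X, parts_y = [], []
    if n_real:
        ridx = _balanced_choice(yr, n_real, rng)
        parts_X.append(Xr[ridx]); parts_y.append(yr[ridx])
    if n_synth:
        sidx = _balanced_choice(ys, n_synth, rng)
        parts_X.append(Xs[sidx]); parts_y.append(ys[sidx])
    X = np.concatenate(parts_X, axis=0)
    y = np.concatenate(parts_y, axis=0)
    info = {"scenario": spec.scenario, "total_budget": spec.total,
            "n_real": n_real, "n_synth": n_synth, "n_used": int(len(y))}
    return X, y, info


def run_mixing_experiment(
    real_train: tuple[np.ndarray, np.ndarray],
    real_test: tuple[np.ndarray, np.ndarray],
    gan: ConditionalEEGGAN,
    total: int = 100,
    real_fraction: float = 0.2,
    threshold: float = 0.90,
    oversample: int = 4,
    classifier_params: dict | None = None,
    seed: int = 0,
) -> dict[str, dict]:
    """Train a fresh classifier per scenario at equal budget; report metrics.

    Synthetic samples are drawn from the trained GAN, filtered by
    confidence (the GAN's own discriminator scores them), and the four
    scenarios are evaluated on the same held-out real test set.  Orderings
    between scenarios are reported, never enforced.
    """
    rng = np.random.default_rng(seed)
    need = total * oversample
    fake_labels = np.tile(np.arange(gan.config_.n_classes), need // gan.config_.n_classes + 1)[:need]
    fake_X, fake_y = gan.sample(need, labels=fake_labels, random_state=int(rng.integers(2**31)))
    policy = SelectionPolicy(threshold=threshold, classifier=gan)
    sel_X, sel_y, retention = select_confident(fake_X, fake_y, policy)
    if len(sel_y) < total:
        warnings.warn(
            f"only {len(sel_y)} confident synthetic samples for a budget of {total}; "
            "falling back to unfiltered samples to fill the deficit",
            stacklevel=2,
        )
        sel_X, sel_y = fake_X, fake_y

    results: dict[str, dict] = {}
    for i, scenario in enumerate(SCENARIOS):
        spec = MixSpec(scenario, total, real_fraction)
        X, y, info = build_mix(real_train, (sel_X, sel_y), spec, seed=seed + 1000 + i)
        params = dict(classifier_params or {})
        params.setdefault("seed", seed + i)
        clf = ACGANClassifier(**params).fit(X, y)
        report: MetricsReport = classification_metrics(real_test[1], clf.predict(real_test[0]))
        results[scenario] = {**info, "metrics": report, "retention": retention}
    return results
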