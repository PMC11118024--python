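"""Adversarial training: losses, update loop, cross-validation, estimators.

The model is an auxiliary-classifier Wasserstein GAN with gradient penalty.
Per update the discriminator minimizes

    L_D = -( E[D_adv(x)] - E[D_adv(G(z,c))] ) + lambda_gp * GP + lambda * L_cls^r

and the generator minimizes

    L_G = -E[D_adv(G(z,c))] + lambda * L_cls^f

with ``GP = E[(|| d D_adv(x_hat) / d x_hat ||_2 - 1)^2]`` evaluated on
per-sample uniform mixtures ``x_hat = eps * real + (1 - eps) * fake`` and
cross-entropy classification losses on the auxiliary head (real samples for
D, conditionally generated samples for G).  Defaults follow the study
conditions: lambda = 1, lambda_gp = 10, AdamW (weight decay 0.02) with
learning rates 1e-4 (G) and 3e-4 (D), batch cap 150, five-fold
cross-validation with fixed seeds.

Two scikit-learn style estimators wrap the loop:

* :class:`ACGANClassifier` — the discriminator trained with the
  classification loss only (fit/predict/predict_proba); used for fold
  evaluation and the data-mixing experiments.
* :class:`ConditionalEEGGAN` — full adversarial training (fit/sample),
  with the discriminator's class head exposed for confidence scoring.
"""

from __future__ import annotations

import gc
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold

from . import autodiff as ad
from . import nn
from .autodiff import Tensor
from .evaluation import MetricsReport, classification_metrics
from .networks import Discriminator, Generator, ModelConfig

__all__ = [
    "LossBundle",
    "TrainConfig",
    "TrainingDiverged",
    "adversarial_loss",
    "gradient_penalty",
    "classification_loss_real",
    "classification_loss_fake",
    "train_step",
    "crossvalidate",
    "ACGANClassifier",
    "ConditionalEEGGAN",
]


class TrainingDiverged(RuntimeError):
    """Raised when a loss becomes non-finite; carries the loss components."""


@dataclass
class LossBundle:
    """Loss components of one adversarial update.

    ``l_adv`` is the discriminator-side adversarial objective
    (Wasserstein gap minus the gradient penalty), so the optimized
    discriminator loss composes exactly as ``l_d = -l_adv + lam * l_cls_r``;
    ``l_adv_fake`` is the generator-side critic term, so
    ``l_g = l_adv_fake + lam * l_cls_f``.
    """

    l_adv: float
    l_cls_r: float
    l_cls_f: float
    l_adv_fake: float
    gp: float
    l_d: float
    l_g: float
    lam: float = 1.0
    lam_gp: float = 10.0

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in
                ("l_d", "l_g", "l_adv", "l_cls_r", "l_cls_f", "l_adv_fake", "gp")}


@dataclass
class TrainConfig:
    """Hyperparameters of the adversarial loop (defaults per study conditions)."""

    lr_g: float = 1e-4
    lr_d: float = 3e-4
    batch_size: int = 150
    weight_decay: float = 0.02
    lam: float = 1.0
    lam_gp: float = 10.0
    n_critic: int = 1
    epochs: int = 100
    folds: int = 5
    seed: int = 0
    cls_on_fake_for_d: bool = False

    def __post_init__(self):
        if self.batch_size < 2:
            raise ValueError("batch size must be at least 2")
        if min(self.lr_g, self.lr_d) <= 0:
            raise ValueError("learning rates must be positive")


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def _critic_score(D, x: Tensor) -> Tensor:
    out = D(x)
    return out[0] if isinstance(out, tuple) else out


def gradient_penalty(D, mix: Tensor | np.ndarray, lam_gp: float = 10.0) -> Tensor:
    """lambda_gp * E[(||grad_x D_adv(x)||_2 - 1)^2] on the given mixtures.

    The gradient norm is taken over all tensor entries of one sample; the
    penalty stays differentiable with respect to D's parameters (the inner
    gradient is built with ``create_graph``).
    """
    x_hat = mix if isinstance(mix, Tensor) else Tensor(mix)
    x_hat.requires_grad = True
    score = _critic_score(D, x_hat).sum()
    (gx,) = ad.grad(score, [x_hat], create_graph=True)
    axes = tuple(range(1, gx.ndim))
    norms = (ad.tsum(gx * gx, axis=axes) + 1e-12) ** 0.5
    return lam_gp * ((norms - 1.0) ** 2).mean()


def mix_samples(real: np.ndarray, fake: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Per-sample uniform interpolation x_hat = eps*real + (1-eps)*fake."""
    eps = rng.random(size=(real.shape[0],) + (1,) * (real.ndim - 1))
    return eps * real + (1.0 - eps) * np.asarray(fake)


def adversarial_loss(
    D,
    real_batch: np.ndarray,
    fake_batch: np.ndarray,
    mix: np.ndarray | None = None,
    lam_gp: float = 10.0,
    rng: np.random.Generator | None = None,
) -> Tensor:
    """E[D_adv(real)] - E[D_adv(fake)] + lambda_gp * GP (the Eq.-style
    adversarial objective; the discriminator maximizes the gap and is
    penalized toward unit gradient norm)."""
    if mix is None:
        rng = rng or np.random.default_rng(0)
        mix = mix_samples(np.asarray(real_batch), np.asarray(fake_batch), rng)
    gap = _critic_score(D, Tensor(real_batch)).mean() - _critic_score(D, Tensor(fake_batch)).mean()
    return gap + gradient_penalty(D, Tensor(mix), lam_gp)


def _cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    logp = nn.log_softmax(logits, axis=-1)
    n = logits.shape[0]
    picked = logp[(np.arange(n), np.asarray(labels, dtype=int))]
    return -picked.mean()


def classification_loss_real(D, real_batch, labels) -> Tensor:
    """Mean -log D_cls(true class | x) over a real batch."""
    _, logits = D(Tensor(real_batch))
    return _cross_entropy(logits, labels)


def classification_loss_fake(D, G, z_batch, labels) -> Tensor:
    """Mean -log D_cls(c | G(z, c)); gradients flow through G."""
    fake = G(Tensor(z_batch), labels)
    _, logits = D(fake)
    return _cross_entropy(logits, labels)


# ---------------------------------------------------------------------------
# update loop
# ---------------------------------------------------------------------------

def _check_finite(**losses: float) -> None:
    bad = {k: v for k, v in losses.items() if not np.isfinite(v)}
    if bad:
        raise TrainingDiverged(f"non-finite loss components: {bad}; all components: {losses}")


def train_step(
    G: Generator,
    D: Discriminator,
    opt_g: nn.AdamW,
    opt_d: nn.AdamW,
    real_x: np.ndarray,
    real_y: np.ndarray,
    cfg: TrainConfig,
    rng: np.random.Generator,
) -> LossBundle:
    """One discriminator update followed by one generator update."""
    b = real_x.shape[0]
    labels = np.asarray(real_y, dtype=int)

    # --- discriminator ---
    last = {}
    for _ in range(cfg.n_critic):
        z = rng.standard_normal((b, G.cfg.nz))
        fake_labels = rng.integers(0, G.cfg.n_classes, size=b)
        with ad.no_grad():
            fake = G(Tensor(z), fake_labels).numpy()
        gap = (
            _critic_score(D, Tensor(real_x)).mean()
            - _critic_score(D, Tensor(fake)).mean()
        )
        gp = gradient_penalty(D, Tensor(mix_samples(real_x, fake, rng)), cfg.lam_gp)
        l_cls_r = classification_loss_real(D, real_x, labels)
        if cfg.cls_on_fake_for_d:
            l_cls_r = 0.5 * (l_cls_r + classification_loss_real(D, fake, fake_labels))
        l_adv = gap - gp
        l_d = -l_adv + cfg.lam * l_cls_r
        opt_d.zero_grad()
        l_d.backward()
        _check_finite(l_d=l_d.item(), gap=gap.item(), gp=gp.item(), l_cls_r=l_cls_r.item())
        opt_d.step()
        last = {"gap": gap.item(), "gp": gp.item(), "l_adv": l_adv.item(),
                "l_cls_r": l_cls_r.item(), "l_d": l_d.item()}

    # --- generator ---
    z = rng.standard_normal((b, G.cfg.nz))
    gen_labels = rng.integers(0, G.cfg.n_classes, size=b)
    fake = G(Tensor(z), gen_labels)
    adv_fake = -_critic_score(D, fake).mean()
    _, logits = D(fake)
    l_cls_f = _cross_entropy(logits, gen_labels)
    l_g = adv_fake + cfg.lam * l_cls_f
    opt_g.zero_grad()
    l_g.backward()
    _check_finite(l_g=l_g.item(), adv_fake=adv_fake.item(), l_cls_f=l_cls_f.item())
    opt_g.step()
    gc.collect()

    return LossBundle(
        l_adv=last["l_adv"], l_cls_r=last["l_cls_r"], l_cls_f=l_cls_f.item(),
        l_adv_fake=adv_fake.item(), gp=last["gp"], l_d=last["l_d"], l_g=l_g.item(),
        lam=cfg.lam, lam_gp=cfg.lam_gp,
    )


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def _as_feature_array(X, cfg: ModelConfig) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    shape = cfg.feature_shape
    if X.ndim == 2 and X.shape[1] == int(np.prod(shape)):
        X = X.reshape((-1,) + shape)
    if X.ndim != 5 or X.shape[1:] != shape:
        raise ValueError(f"expected features of shape (n,)+{shape} or flattened, got {X.shape}")
    return X


class _Standardizer:
    """Per-feature z-scoring over the training set (fit on real data only)."""

    def fit(self, X: np.ndarray) -> "_Standardizer":
        flat = X.reshape(X.shape[0], -1)
        self.mean_ = flat.mean(axis=0)
        self.scale_ = flat.std(axis=0)
        self.scale_[self.scale_ < 1e-8] = 1.0
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        flat = (X.reshape(X.shape[0], -1) - self.mean_) / self.scale_
        return flat.reshape(X.shape)

    def inverse_transform(self, X: np.ndarray) -> np.ndarray:
        flat = X.reshape(X.shape[0], -1) * self.scale_ + self.mean_
        return flat.reshape(X.shape)


class ACGANClassifier(ClassifierMixin, BaseEstimator):
    """The discriminator architecture trained as a plain classifier.

    The adversarial head is left untrained; only the class head receives a
    cross-entropy loss.  Used for fold evaluation and for the data-mixing
    experiments, where a fresh classifier per scenario isolates the effect
    of the training data.

    Parameters default to the compact network configuration, which is the
    desk-scale problem size used throughout the synthetic benchmarks.
    """

    def __init__(self, model_config: ModelConfig | None = None, epochs: int = 5,
                 batch_size: int = 32, lr: float = 3e-4, weight_decay: float = 0.02,
                 seed: int = 0, standardize: bool = True, log_path=None):
        self.model_config = model_config
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.weight_decay = weight_decay
        self.seed = seed
        self.standardize = standardize
        self.log_path = log_path

    def _config(self, n_classes: int) -> ModelConfig:
        cfg = self.model_config or ModelConfig.compact()
        if cfg.n_classes != n_classes:
            cfg = ModelConfig.from_dict({**cfg.to_dict(), "n_classes": n_classes})
        return cfg

    def fit(self, X, y, eval_set=None):
        y = np.asarray(y, dtype=int)
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        cfg = self._config(len(self.classes_))
        X = _as_feature_array(X, cfg)
        rng = np.random.default_rng(self.seed)
        self.scaler_ = _Standardizer().fit(X)
        Xs = self.scaler_.transform(X) if self.standardize else X

        self.model_ = Discriminator(cfg, seed=int(rng.integers(2**31)))
        opt = nn.AdamW(self.model_.parameters(), lr=self.lr, weight_decay=self.weight_decay)
        n = Xs.shape[0]
        batch = min(self.batch_size, n)
        self.history_, self.eval_history_ = [], []
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            self.model_.train()
            epoch_loss = 0.0
            for start in range(0, n - batch + 1, batch):
                idx = order[start : start + batch]
                _, logits = self.model_(Tensor(Xs[idx]))
                loss = _cross_entropy(logits, y_enc[idx])
                opt.zero_grad()
                loss.backward()
                _check_finite(cls=loss.item())
                opt.step()
                epoch_loss += loss.item()
                gc.collect()
            self.history_.append(epoch_loss / max(1, n // batch))
            if eval_set is not None:
                report = classification_metrics(eval_set[1], self.predict(eval_set[0]))
                self.eval_history_.append(report)
        if self.log_path is not None:
            import pandas as pd

            pd.DataFrame({"epoch": range(len(self.history_)), "loss": self.history_}).to_csv(
                self.log_path, index=False
            )
        return self

    def predict_proba(self, X) -> np.ndarray:
        X = _as_feature_array(X, self.model_.cfg)
        Xs = self.scaler_.transform(X) if self.standardize else X
        self.model_.eval()
        probs = []
        for start in range(0, Xs.shape[0], 256):
            with ad.no_grad():
                _, logits = self.model_(Tensor(Xs[start : start + 256]))
                probs.append(nn.softmax(logits, axis=-1).numpy())
        return np.concatenate(probs, axis=0)

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


class ConditionalEEGGAN(BaseEstimator):
    """Full adversarial training of the conditional feature GAN.

    ``fit`` trains generator and discriminator on (features, labels);
    ``sample`` draws class-conditioned synthetic feature tensors in the
    original feature scale; ``predict_proba`` exposes the discriminator's
    class head (used for confidence-based selection).
    """

    def __init__(self, model_config: ModelConfig | None = None, steps: int = 300,
                 batch_size: int = 32, lr_g: float = 1e-4, lr_d: float = 3e-4,
                 weight_decay: float = 0.02, lam: float = 1.0, lam_gp: float = 10.0,
                 n_critic: int = 1, cls_on_fake_for_d: bool = False, seed: int = 0,
                 standardize: bool = True, log_path=None):
        self.model_config = model_config
        self.steps = steps
        self.batch_size = batch_size
        self.lr_g = lr_g
        self.lr_d = lr_d
        self.weight_decay = weight_decay
        self.lam = lam
        self.lam_gp = lam_gp
        self.n_critic = n_critic
        self.cls_on_fake_for_d = cls_on_fake_for_d
        self.seed = seed
        self.standardize = standardize
        self.log_path = log_path

    def fit(self, X, y):
        y = np.asarray(y, dtype=int)
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        cfg = self.model_config or ModelConfig.compact()
        if cfg.n_classes != len(self.classes_):
            cfg = ModelConfig.from_dict({**cfg.to_dict(), "n_classes": len(self.classes_)})
        self.config_ = cfg
        X = _as_feature_array(X, cfg)
        self.scaler_ = _Standardizer().fit(X)
        Xs = self.scaler_.transform(X) if self.standardize else X

        rng = np.random.default_rng(self.seed)
        self.generator_ = Generator(cfg, seed=int(rng.integers(2**31)))
        self.discriminator_ = Discriminator(cfg, seed=int(rng.integers(2**31)))
        opt_g = nn.AdamW(self.generator_.parameters(), lr=self.lr_g, weight_decay=self.weight_decay)
        opt_d = nn.AdamW(self.discriminator_.parameters(), lr=self.lr_d, weight_decay=self.weight_decay)
        tcfg = TrainConfig(
            lr_g=self.lr_g, lr_d=self.lr_d, batch_size=max(2, min(self.batch_size, X.shape[0])),
            weight_decay=self.weight_decay, lam=self.lam, lam_gp=self.lam_gp,
            n_critic=self.n_critic, cls_on_fake_for_d=self.cls_on_fake_for_d,
            seed=self.seed,
        )
        n, batch = Xs.shape[0], max(2, min(self.batch_size, X.shape[0]))
        self.history_ = []
        self.generator_.train()
        self.discriminator_.train()
        for step in range(self.steps):
            idx = rng.choice(n, size=batch, replace=False)
            bundle = train_step(
                self.generator_, self.discriminator_, opt_g, opt_d,
                Xs[idx], y_enc[idx], tcfg, rng,
            )
            self.history_.append(bundle)
        if self.log_path is not None:
            import pandas as pd

            pd.DataFrame([b.as_dict() for b in self.history_]).to_csv(self.log_path, index=False)
        return self

    def sample(self, n: int, labels=None, random_state: int | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Draw n synthetic feature tensors; returns (features, labels)."""
        rng = np.random.default_rng(self.seed + 7919 if random_state is None else random_state)
        if labels is None:
            labels = rng.integers(0, self.config_.n_classes, size=n)
        labels = np.asarray(labels, dtype=int)
        self.generator_.eval()
        outs = []
        for start in range(0, n, 256):
            z = rng.standard_normal((min(256, n - start), self.config_.nz))
            with ad.no_grad():
                out = self.generator_(Tensor(z), labels[start : start + z.shape[0]]).numpy()
            outs.append(out)
        fake = np.concatenate(outs, axis=0)
        if self.standardize:
            fake = self.scaler_.inverse_transform(fake)
        return fake, self.classes_[labels]

    def predict_proba(self, X) -> np.ndarray:
        X = _as_feature_array(X, self.config_)
        Xs = self.scaler_.transform(X) if self.standardize else X
        self.discriminator_.eval()
        with ad.no_grad():
            _, logits = self.discriminator_(Tensor(Xs))
            return nn.softmax(logits, axis=-1).numpy()


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def crossvalidate(
    X,
    y,
    estimator: ACGANClassifier | None = None,
    folds: int = 5,
    seed: int = 0,
    selection: str = "best",
) -> dict:
    """Stratified k-fold evaluation of the classifier.

    Per fold the classifier is trained from scratch; with
    ``selection="best"`` the reported fold metrics are those of the best
    epoch on the fold's test split (optimistic best-checkpoint selection —
    see the methods note), with ``"final"`` those of the last epoch.
    Returns per-fold reports and their means.
    """
    y = np.asarray(y, dtype=int)
    counts = np.bincount(y)
    if (counts[counts > 0] < folds).any():
        raise ValueError("every class needs at least `folds` samples for stratification")
    X = np.asarray(X, dtype=float)
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    reports: list[MetricsReport] = []
    for fold, (tr, te) in enumerate(splitter.split(np.zeros(len(y)), y)):
        est = ACGANClassifier(**(estimator.get_params() if estimator else {}))
        est.set_params(seed=(estimator.seed if estimator else 0) + fold)
        est.fit(X[tr], y[tr], eval_set=(X[te], y[te]))
        if selection == "best":
            report = max(est.eval_history_, key=lambda r: r.accuracy)
        elif selection == "final":
            report = est.eval_history_[-1]
        else:
            raise ValueError(f"unknown selection mode: {selection!r}")
        reports.append(report)
    mean = {
        k: float(np.mean([r.as_dict()[k] for r in reports]))
        for k in reports[0].as_dict()
    }
    return {"folds": reports, "mean": mean}
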