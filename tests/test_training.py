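"""Losses (gradient penalty, cross-entropies), update loop, cross-validation."""

import numpy as np
import pytest

from vigilgan import autodiff as ad
from vigilgan import nn
from vigilgan.autodiff import Tensor
from vigilgan.networks import Discriminator, Generator, ModelConfig
from vigilgan.training import (
    ACGANClassifier,
    ConditionalEEGGAN,
    TrainConfig,
    TrainingDiverged,
    adversarial_loss,
    classification_loss_fake,
    classification_loss_real,
    crossvalidate,
    gradient_penalty,
    train_step,
)

CFG = ModelConfig.compact()


class LinearCritic:
    """Analytic critic D(x) = <w, x> with known gradient norm ||w||."""

    def __init__(self, w: np.ndarray):
        self.w = Tensor(w)

    def __call__(self, x: Tensor):
        b = x.shape[0]
        flat = x.reshape((b, -1))
        return flat @ self.w.reshape((-1, 1))


class TestGradientPenalty:
    @pytest.fixture(autouse=True)
    def float64(self):
        with ad.default_dtype(np.float64):
            yield

    def unit_direction(self, shape, seed=0):
        v = np.random.default_rng(seed).normal(size=shape)
        return v / np.linalg.norm(v)

    def test_unit_norm_critic_zero_penalty(self):
        w = self.unit_direction((6 * 9 * 5 * 16,))
        mix = np.random.default_rng(1).normal(size=(4, 6, 9, 5, 16))
        gp = gradient_penalty(LinearCritic(w), Tensor(mix), lam_gp=10.0)
        assert gp.item() == pytest.approx(0.0, abs=1e-5)

    def test_norm_three_critic_penalty_forty(self):
        w = 3.0 * self.unit_direction((6 * 9 * 5 * 16,), seed=2)
        mix = np.random.default_rng(3).normal(size=(4, 6, 9, 5, 16))
        gp = gradient_penalty(LinearCritic(w), Tensor(mix), lam_gp=10.0)
        assert gp.item() == pytest.approx(40.0, abs=1e-5)

    def test_identical_batches_cancel_gap(self):
        w = self.unit_direction((6 * 9 * 5 * 16,), seed=4)
        x = np.random.default_rng(5).normal(size=(4, 6, 9, 5, 16))
        loss = adversarial_loss(LinearCritic(w), x, x, lam_gp=10.0,
                                rng=np.random.default_rng(6))
        # real and fake expectations cancel; only the (zero) GP remains
        assert loss.item() == pytest.approx(0.0, abs=1e-5)

    def test_penalty_differentiable_wrt_critic_weights(self):
        w0 = 2.0 * self.unit_direction((20,), seed=7)
        critic = LinearCritic(w0)
        critic.w.requires_grad = True
        mix = Tensor(np.random.default_rng(8).normal(size=(3, 20)))
        gp = gradient_penalty(critic, mix, lam_gp=10.0)
        gp.backward()
        # closed form: gp = 10 (||w|| - 1)^2, d/dw = 20 (||w|| - 1) w/||w||
        expected = 20.0 * (np.linalg.norm(w0) - 1.0) * w0 / np.linalg.norm(w0)
        np.testing.assert_allclose(critic.w.grad, expected, atol=1e-6)


class TestClassificationLosses:
    class FixedProbD:
        """Discriminator stub with hand-set class probabilities."""

        def __init__(self, probs):
            self.logits = np.log(np.asarray(probs, dtype=float))

        def __call__(self, x):
            b = x.shape[0]
            return Tensor(np.zeros(b)), Tensor(np.tile(self.logits, (b, 1)))

    def test_perfect_prediction_zero_loss(self):
        D = self.FixedProbD([1.0 - 1e-12, 1e-12])
        loss = classification_loss_real(D, np.zeros((3, 4)), np.array([0, 0, 0]))
        assert loss.item() == pytest.approx(0.0, abs=1e-6)

    def test_uniform_prediction_ln2(self):
        D = self.FixedProbD([0.5, 0.5])
        loss = classification_loss_real(D, np.zeros((5, 4)), np.array([1, 0, 1, 0, 1]))
        assert loss.item() == pytest.approx(np.log(2), abs=1e-6)

    def test_hand_set_probability(self):
        D = self.FixedProbD([0.8, 0.2])
        loss = classification_loss_real(D, np.zeros((1, 4)), np.array([0]))
        assert loss.item() == pytest.approx(-np.log(0.8), abs=1e-6)

    def test_fake_loss_mirrors_real(self):
        class IdentityG:
            def __call__(self, z, labels):
                return z

        D = self.FixedProbD([0.8, 0.2])
        loss = classification_loss_fake(D, IdentityG(), np.zeros((2, 4)), np.array([1, 1]))
        assert loss.item() == pytest.approx(-np.log(0.2), abs=1e-5)


def make_models(seed=0):
    G = Generator(CFG, seed=seed)
    D = Discriminator(CFG, seed=seed + 1)
    opt_g = nn.AdamW(G.parameters(), lr=1e-4)
    opt_d = nn.AdamW(D.parameters(), lr=3e-4)
    G.train(), D.train()
    return G, D, opt_g, opt_d


def toy_batch(n=8, seed=0):
    rng = np.random.default_rng(seed)
    y = np.arange(n) % 2
    X = rng.normal(size=(n, 6, 9, 5, 16)) + y[:, None, None, None, None] * 2.0
    return X.astype(np.float32), y


class TestTrainStep:
    def test_loss_composition_identity(self):
        G, D, og, od = make_models(seed=10)
        X, y = toy_batch(seed=11)
        cfg = TrainConfig(batch_size=8, lam=1.0, lam_gp=10.0)
        bundle = train_step(G, D, og, od, X, y, cfg, np.random.default_rng(12))
        assert bundle.l_d == pytest.approx(-bundle.l_adv + cfg.lam * bundle.l_cls_r, abs=1e-6)
        assert bundle.l_g == pytest.approx(bundle.l_adv_fake + cfg.lam * bundle.l_cls_f, abs=1e-6)

    def test_seed_determinism(self):
        X, y = toy_batch(seed=13)
        cfg = TrainConfig(batch_size=8)
        traces = []
        for _ in range(2):
            G, D, og, od = make_models(seed=14)
            rng = np.random.default_rng(15)
            traces.append([train_step(G, D, og, od, X, y, cfg, rng).l_d for _ in range(2)])
        assert traces[0] == traces[1]

    def test_lambda_zero_degenerates_to_wgan_gp(self):
        """With lam = 0 the classification terms must not influence updates."""
        X, y = toy_batch(seed=16)
        cfg = TrainConfig(batch_size=8, lam=0.0)
        G, D, og, od = make_models(seed=17)
        bundle = train_step(G, D, og, od, X, y, cfg, np.random.default_rng(18))
        assert bundle.l_d == pytest.approx(-bundle.l_adv, abs=1e-6)
        assert bundle.l_g == pytest.approx(bundle.l_adv_fake, abs=1e-6)

    def test_divergence_aborts_with_diagnostic(self):
        G, D, og, od = make_models(seed=19)
        D.head_adv.weight.data[:] = np.nan
        X, y = toy_batch(seed=20)
        with pytest.raises(TrainingDiverged, match="non-finite"):
            train_step(G, D, og, od, X, y, TrainConfig(batch_size=8), np.random.default_rng(21))


class TestClassifierEstimator:
    def test_learns_separable_toy_problem(self, small_dataset):
        X, y, _ = small_dataset
        clf = ACGANClassifier(epochs=2, batch_size=32, seed=0)
        clf.fit(X[:60], y[:60], eval_set=(X[60:], y[60:]))
        assert clf.eval_history_[-1].accuracy > 0.9

    def test_sklearn_contract(self, small_dataset):
        from sklearn.base import clone

        X, y, _ = small_dataset
        clf = ACGANClassifier(epochs=1, seed=1)
        cloned = clone(clf)
        cloned.fit(X[:40], y[:40])
        probs = cloned.predict_proba(X[40:50])
        assert probs.shape == (10, 2)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert set(cloned.predict(X[40:50])) <= set(cloned.classes_)

    def test_accepts_flattened_features(self, small_dataset):
        X, y, _ = small_dataset
        clf = ACGANClassifier(epochs=1, seed=2)
        clf.fit(X[:40].reshape(40, -1), y[:40])
        assert clf.predict(X[40:44].reshape(4, -1)).shape == (4,)


class TestGANEstimator:
    def test_fit_sample_roundtrip(self, small_dataset):
        X, y, _ = small_dataset
        gan = ConditionalEEGGAN(steps=2, batch_size=8, seed=3).fit(X[:24], y[:24])
        fake, labels = gan.sample(6, labels=[0, 1, 0, 1, 0, 1], random_state=4)
        assert fake.shape == (6, 6, 9, 5, 16)
        np.testing.assert_array_equal(labels, [0, 1, 0, 1, 0, 1])
        assert np.isfinite(fake).all()

    def test_sampling_deterministic_per_seed(self, small_dataset):
        X, y, _ = small_dataset
        gan = ConditionalEEGGAN(steps=1, batch_size=8, seed=5).fit(X[:16], y[:16])
        a, _ = gan.sample(4, random_state=11)
        b, _ = gan.sample(4, random_state=11)
        np.testing.assert_array_equal(a, b)

    def test_history_records_all_components(self, small_dataset):
        X, y, _ = small_dataset
        gan = ConditionalEEGGAN(steps=2, batch_size=8, seed=6).fit(X[:16], y[:16])
        assert len(gan.history_) == 2
        d = gan.history_[-1].as_dict()
        assert {"l_d", "l_g", "l_adv", "l_cls_r", "l_cls_f", "gp"} <= set(d)


class TestCrossValidation:
    def test_folds_partition_the_data(self):
        from sklearn.model_selection import StratifiedKFold

        y = np.arange(100) % 2
        splitter = StratifiedKFold(5, shuffle=True, random_state=0)
        tests = [te for _, te in splitter.split(np.zeros(100), y)]
        assert sorted(np.concatenate(tests).tolist()) == list(range(100))
        assert all(len(t) == 20 for t in tests)

    def test_mean_equals_hand_average(self, small_dataset):
        X, y, _ = small_dataset
        result = crossvalidate(X, y, ACGANClassifier(epochs=1, seed=7), folds=2, seed=8)
        hand = np.mean([r.accuracy for r in result["folds"]])
        assert result["mean"]["accuracy"] == pytest.approx(hand)

    def test_missing_class_rejected(self):
        X = np.zeros((6, 6, 9, 5, 16))
        y = np.array([0, 0, 0, 0, 0, 1])
        with pytest.raises(ValueError, match="stratification"):
            crossvalidate(X, y, folds=5)
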