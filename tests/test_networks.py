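"""Architecture contracts: shapes, identity configurations, gradient flow."""

import numpy as np
import pytest

from vigilgan import autodiff as ad
from vigilgan import nn
from vigilgan.autodiff import Tensor
from vigilgan.networks import (
    AttentionModule,
    BottleneckBlock,
    BottleneckModuleD,
    BottleneckModuleG,
    Discriminator,
    FrequencyAttention,
    Generator,
    ModelConfig,
    SpatialAttention,
    count_forward_gflops,
    discriminator_forward,
    generator_forward,
    load_checkpoint,
    save_checkpoint,
    summarize,
)

RNG = np.random.default_rng(0)
CFG = ModelConfig.compact()


def frames(n=4, h=6, w=9, d=5, seed=0):
    return Tensor(np.random.default_rng(seed).normal(size=(n, h, w, d)))


class TestAttention:
    def test_zero_input_zero_output(self):
        module = AttentionModule(5, np.random.default_rng(1))
        out = module(Tensor(np.zeros((3, 6, 9, 5))))
        np.testing.assert_allclose(out.numpy(), 0.0)

    def test_shape_preserved(self):
        module = AttentionModule(5, np.random.default_rng(2))
        assert module(frames()).shape == (4, 6, 9, 5)

    def test_saturated_gates_identity(self):
        module = AttentionModule(5, np.random.default_rng(3))
        # zero the gate convolutions and push biases far positive: both
        # sigmoids saturate at 1 and the 0.5-scaled sum reproduces the input
        module.spatial.squeeze.weight.data[:] = 0
        module.spatial.squeeze.bias.data[:] = 50.0
        module.frequency.fc1.weight.data[:] = 0
        module.frequency.fc1.bias.data[:] = 0
        module.frequency.fc2.weight.data[:] = 0
        module.frequency.fc2.bias.data[:] = 50.0
        x = frames(seed=4)
        np.testing.assert_allclose(module(x).numpy(), x.numpy(), atol=1e-6)

    def test_generic_input_not_identity(self):
        module = AttentionModule(5, np.random.default_rng(5))
        x = frames(seed=6)
        assert not np.allclose(module(x).numpy(), x.numpy())

    def test_frequency_gate_spatially_invariant(self):
        """Frequency attention pools globally, so its gate must not change
        when the spatial cells are permuted."""
        fa = FrequencyAttention(5, np.random.default_rng(7))
        x0 = np.random.default_rng(8).normal(size=(2, 6, 9, 5))
        perm = np.random.default_rng(9).permutation(54)
        xp = x0.reshape(2, 54, 5)[:, perm].reshape(2, 6, 9, 5)
        gate = lambda arr: fa(Tensor(arr)).numpy() / np.where(arr == 0, 1, arr)
        np.testing.assert_allclose(
            np.sort(gate(x0).ravel()), np.sort(gate(xp).ravel()), atol=1e-5
        )

    def test_spatial_gate_in_unit_interval(self):
        sa = SpatialAttention(5, np.random.default_rng(10))
        x = np.abs(np.random.default_rng(11).normal(size=(2, 6, 9, 5))) + 0.1
        ratio = sa(Tensor(x)).numpy() / x
        assert (ratio > 0).all() and (ratio < 1).all()


class TestBottleneck:
    def test_zero_weights_pure_residual(self):
        block = BottleneckBlock(8, 8, 2, np.random.default_rng(12))
        for p in block.parameters():
            p.data[:] = 0
        x = frames(d=8, seed=13)
        np.testing.assert_allclose(block(x).numpy(), x.numpy())

    def test_relu6_clamps_at_six(self):
        out = nn.relu6(Tensor(np.array([-1.0, 3.0, 7.0])))
        np.testing.assert_allclose(out.numpy(), [0.0, 3.0, 6.0])

    def test_parameter_count_closed_form(self):
        # C=64, k=6, C'=64: expansion 64*384 (+384), depthwise 384*9 (+384),
        # projection 384*64 (+64)
        block = BottleneckBlock(64, 64, 6, np.random.default_rng(14))
        expected = (64 * 384 + 384) + (384 * 9 + 384) + (384 * 64 + 64)
        assert block.n_parameters() == expected

    def test_no_residual_when_widths_differ(self):
        block = BottleneckBlock(8, 4, 2, np.random.default_rng(15))
        for p in block.parameters():
            p.data[:] = 0
        out = block(frames(d=8, seed=16))
        np.testing.assert_allclose(out.numpy(), 0.0)

    def test_standard_conv_variant(self):
        block = BottleneckBlock(5, 5, 2, np.random.default_rng(17), conv="standard")
        assert block(frames(seed=18)).shape == (4, 6, 9, 5)


class TestBottleneckModules:
    def test_discriminator_module_token_shape(self):
        module = BottleneckModuleD(CFG, np.random.default_rng(19))
        out = module(frames(n=2 * 16, seed=20))
        assert out.shape == (32, CFG.token_dim)

    def test_pooling_condenses_6x9_to_2x2(self):
        pool = nn.AvgPool(3, 4)
        out = pool(Tensor(np.ones((1, 6, 9, 7))))
        assert out.shape == (1, 2, 2, 7)

    def test_frames_processed_independently(self):
        """Frame-wise weight sharing: permuting frames permutes tokens."""
        module = BottleneckModuleD(CFG, np.random.default_rng(21))
        module.eval()
        x = np.random.default_rng(22).normal(size=(16, 6, 9, 5))
        perm = np.random.default_rng(23).permutation(16)
        with ad.no_grad():
            a = module(Tensor(x)).numpy()
            b = module(Tensor(x[perm])).numpy()
        np.testing.assert_allclose(a[perm], b, atol=1e-5)

    def test_generator_module_returns_band_planes(self):
        module = BottleneckModuleG(CFG, np.random.default_rng(24))
        assert module(frames(n=8, seed=25)).shape == (8, 6, 9, 5)

    def test_bounded_input_bounded_output(self):
        module = BottleneckModuleG(CFG, np.random.default_rng(26))
        out = module(Tensor(np.random.default_rng(27).uniform(-1, 1, (16, 6, 9, 5))))
        assert np.isfinite(out.numpy()).all()


class TestTransformer:
    def make(self, positional=True, dropout=0.1, seed=28):
        return nn.TransformerEncoder(
            64, 16, 2, 4, 128, dropout, np.random.default_rng(seed), positional
        )

    def test_shape_preserved(self):
        enc = self.make()
        enc.eval()
        x = Tensor(np.random.default_rng(29).normal(size=(3, 16, 64)))
        assert enc(x).shape == (3, 16, 64)

    def test_zeroed_projections_identity(self):
        enc = self.make(positional=False, dropout=0.0)
        enc.eval()
        for block in enc.blocks:
            block.attn.proj.weight.data[:] = 0
            block.attn.proj.bias.data[:] = 0
            block.fc2.weight.data[:] = 0
            block.fc2.bias.data[:] = 0
        x = Tensor(np.random.default_rng(30).normal(size=(2, 16, 64)))
        np.testing.assert_allclose(enc(x).numpy(), x.numpy(), atol=1e-6)

    def test_token_permutation_equivariance_without_positions(self):
        enc = self.make(positional=False, dropout=0.0)
        enc.eval()
        x = np.random.default_rng(31).normal(size=(1, 16, 64))
        perm = np.random.default_rng(32).permutation(16)
        with ad.no_grad():
            a = enc(Tensor(x)).numpy()
            b = enc(Tensor(x[:, perm])).numpy()
        np.testing.assert_allclose(a[:, perm], b, atol=1e-5)

    def test_indivisible_heads_rejected(self):
        with pytest.raises(ValueError, match="heads"):
            nn.MultiHeadSelfAttention(64, 5, np.random.default_rng(33))


class TestGeneratorDiscriminator:
    def test_generator_output_shape(self):
        G = Generator(CFG, seed=34)
        out = generator_forward(G, RNG.normal(size=(3, CFG.nz)), np.array([0, 1, 0]))
        assert out.shape == (3, 6, 9, 5, 16)

    def test_generator_deterministic_in_eval(self):
        G = Generator(CFG, seed=35)
        z = RNG.normal(size=(2, CFG.nz))
        labels = np.array([0, 1])
        np.testing.assert_array_equal(
            generator_forward(G, z, labels), generator_forward(G, z, labels)
        )

    def test_labels_condition_the_output(self):
        G = Generator(CFG, seed=36)
        z = RNG.normal(size=(1, CFG.nz))
        a = generator_forward(G, z, np.array([0]))
        b = generator_forward(G, z, np.array([1]))
        assert not np.allclose(a, b)

    def test_discriminator_output_contracts(self):
        D = Discriminator(CFG, seed=37)
        out = discriminator_forward(D, RNG.normal(size=(4, 6, 9, 5, 16)))
        assert out.adv.shape == (4,)
        np.testing.assert_allclose(out.cls.sum(axis=1), 1.0, atol=1e-6)
        assert out.cls.shape == (4, CFG.n_classes)

    def test_batch_independence(self):
        D = Discriminator(CFG, seed=38)
        x = RNG.normal(size=(5, 6, 9, 5, 16))
        batch = discriminator_forward(D, x)
        single = discriminator_forward(D, x[2:3])
        np.testing.assert_allclose(batch.adv[2], single.adv[0], atol=1e-5)
        np.testing.assert_allclose(batch.cls[2], single.cls[0], atol=1e-5)

    def test_end_to_end_g_then_d(self):
        G = Generator(CFG, seed=39)
        D = Discriminator(CFG, seed=40)
        fake = generator_forward(G, RNG.normal(size=(2, CFG.nz)), np.array([1, 0]))
        out = discriminator_forward(D, fake)
        assert out.adv.shape == (2,) and out.cls.shape == (2, 2)

    def test_all_parameters_receive_gradient(self):
        """No dead branch: every trainable parameter gets a nonzero gradient."""
        G = Generator(CFG, seed=41)
        D = Discriminator(CFG, seed=42)
        G.train(), D.train()
        z = Tensor(RNG.normal(size=(4, CFG.nz)))
        fake = G(z, np.array([0, 1, 0, 1]))
        adv, logits = D(fake)
        loss = adv.mean() + (logits**2).mean()
        loss.backward()
        for name, p in list(G.named_parameters()) + list(D.named_parameters()):
            assert p.grad is not None, name
            assert np.abs(p.grad).max() > 0, name

    def test_no_attention_ablation(self):
        cfg = ModelConfig.compact(use_attention=False)
        D = Discriminator(cfg, seed=43)
        assert D.attention is None
        out = discriminator_forward(D, RNG.normal(size=(2, 6, 9, 5, 16)))
        assert out.adv.shape == (2,)

    def test_checkpoint_roundtrip(self, tmp_path):
        G = Generator(CFG, seed=44)
        D = Discriminator(CFG, seed=45)
        save_checkpoint(tmp_path / "ckpt.npz", CFG, generator=G, discriminator=D)
        cfg2, states = load_checkpoint(tmp_path / "ckpt.npz")
        assert cfg2.to_dict() == CFG.to_dict()
        G2 = Generator(cfg2, seed=99)
        G2.load_state_dict(states["generator"])
        z = RNG.normal(size=(1, CFG.nz))
        np.testing.assert_allclose(
            generator_forward(G, z, np.array([0])),
            generator_forward(G2, z, np.array([0])),
            atol=1e-6,
        )


class TestAccounting:
    def test_full_width_flop_count_reported(self):
        D = Discriminator(ModelConfig(), seed=46)
        gflops = count_forward_gflops(D, np.zeros((1, 6, 9, 5, 16)))
        assert gflops > 0.05  # sanity: the full model is a few hundred MFLOPs

    def test_summary_lists_parameters(self):
        D = Discriminator(CFG, seed=47)
        text = summarize(D)
        assert "total parameters" in text and "head_cls" in text
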