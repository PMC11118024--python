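"""Generator and discriminator for the conditional EEG feature GAN.

Both networks share three building blocks:

* an attention module with a spatial branch (squeeze the band axis with a
  1x1 convolution, sigmoid gate per grid cell) and a frequency branch
  (global spatial pooling to one vector per band, a two-layer pointwise
  bottleneck, sigmoid gate per band);
* inverted bottleneck residual blocks (pointwise expansion -> 3x3 depthwise
  -> linear pointwise projection, ReLU6 everywhere except the projection,
  residual add when input and output widths match);
* a Transformer encoder over the 2T half-second time tokens.

The discriminator maps a 4D feature tensor ``(h, w, d, 2T)`` through
attention, the bottleneck stack (channel path d -> base -> branch ->
two-branch merge -> reduce), a single 3x4 average pooling to 2x2, and a
64-unit fully connected layer, yielding the token sequence ``Q in
R^{64 x 2T}``; the Transformer then mixes time, and two heads produce the
Wasserstein critic score and the class posterior.  The generator runs the
mirror image: latent+label -> linear -> 64 x 2T tokens -> Transformer ->
per-frame transposed convolution up to the electrode grid -> attention ->
bottleneck stack back down to d bands.

Convolutions act per half-second frame on the electrode grid with the band
axis as channels; frames share weights, and all temporal mixing is
delegated to the Transformer.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor


@dataclass
class ModelConfig:
    """Widths and switches of the generator/discriminator pair.

    The defaults are the full-size architecture (channel path
    5 -> 128 -> 64 -> 32, expansion factor 6, two Transformer blocks).
    :meth:`compact` returns a narrow variant for desk-scale CPU training.
    """

    n_classes: int = 2
    height: int = 6
    width: int = 9
    n_bands: int = 5
    n_frames: int = 16
    token_dim: int = 64
    nz: int = 64
    expansion: int = 6
    base_channels: int = 128
    branch_channels: int = 64
    reduce_channels: int = 32
    deconv_channels: int = 16
    n_transformer_blocks: int = 2
    n_heads: int = 4
    mlp_hidden: int = 128
    dropout: float = 0.1
    positional: bool = True
    use_attention: bool = True
    conv: str = "bottleneck"  # "bottleneck" | "standard" (ablation)

    @classmethod
    def compact(cls, **overrides) -> "ModelConfig":
        cfg = dict(
            expansion=2,
            base_channels=32,
            branch_channels=16,
            reduce_channels=8,
            deconv_channels=8,
            n_transformer_blocks=1,
            mlp_hidden=64,
        )
        cfg.update(overrides)
        return cls(**cfg)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]

    @property
    def feature_shape(self) -> tuple[int, int, int, int]:
        return (self.height, self.width, self.n_bands, self.n_frames)


# ---------------------------------------------------------------------------
# attention
# ---------------------------------------------------------------------------

class SpatialAttention(nn.Module):
    """Gate each grid cell: squeeze the band axis with a 1x1 conv, sigmoid."""

    def __init__(self, n_bands: int, rng: np.random.Generator):
        super().__init__()
        self.squeeze = nn.PointwiseConv(n_bands, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        gate = nn.sigmoid(self.squeeze(x))            # (N, H, W, 1)
        return x * gate


class FrequencyAttention(nn.Module):
    """Gate each band: global spatial pooling, two pointwise layers, sigmoid."""

    def __init__(self, n_bands: int, rng: np.random.Generator, reduction: int = 2):
        super().__init__()
        mid = max(1, n_bands // reduction)
        self.fc1 = nn.PointwiseConv(n_bands, mid, rng)
        self.fc2 = nn.PointwiseConv(mid, n_bands, rng)

    def forward(self, x: Tensor) -> Tensor:
        pooled = x.mean(axis=(1, 2), keepdims=True)   # (N, 1, 1, C)
        gate = nn.sigmoid(self.fc2(nn.relu6(self.fc1(pooled))))
        return x * gate


class AttentionModule(nn.Module):
    """Average of the spatially and frequency gated tensors.

    With both gates saturated at one the module is the identity, matching
    the squeeze-and-excitation reading of "merge with the original features".
    """

    def __init__(self, n_bands: int, rng: np.random.Generator):
        super().__init__()
        self.spatial = SpatialAttention(n_bands, rng)
        self.frequency = FrequencyAttention(n_bands, rng)

    def forward(self, x: Tensor) -> Tensor:
        return 0.5 * (self.spatial(x) + self.frequency(x))


# ---------------------------------------------------------------------------
# bottleneck residual
# ---------------------------------------------------------------------------

class BottleneckBlock(nn.Module):
    """Inverted residual block (expansion k, stride 1, linear projection)."""

    def __init__(self, c_in: int, c_out: int, expansion: int,
                 rng: np.random.Generator, conv: str = "bottleneck"):
        super().__init__()
        self.residual = c_in == c_out
        self.conv = conv
        if conv == "standard":
            self.full = nn.StandardConv3x3(c_in, c_out, rng)
        elif conv == "bottleneck":
            mid = expansion * c_in
            self.expand = nn.PointwiseConv(c_in, mid, rng)
            self.depthwise = nn.DepthwiseConv3x3(mid, rng)
            self.project = nn.PointwiseConv(mid, c_out, rng)
        else:
            raise ValueError(f"unknown conv variant: {conv!r}")

    def forward(self, x: Tensor) -> Tensor:
        if self.conv == "standard":
            out = nn.relu6(self.full(x))
        else:
            out = nn.relu6(self.expand(x))
            out = nn.relu6(self.depthwise(out))
            out = self.project(out)                   # linear activation
        if self.residual:
            out = out + x
        return out


class BottleneckModuleD(nn.Module):
    """Discriminator backbone: 8 blocks, two branches, pool, 64-unit FC.

    Channel path d -> base -> branch -> {A: 1 block, B: 2 blocks} -> add ->
    fuse -> reduce (2 blocks); 3x4 average pooling condenses the 6x9 grid to
    2x2 before the fully connected layer produces one 64-vector per frame.
    """

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        k, conv = cfg.expansion, cfg.conv
        self.expand = BottleneckBlock(cfg.n_bands, cfg.base_channels, k, rng, conv)
        self.halve = BottleneckBlock(cfg.base_channels, cfg.branch_channels, k, rng, conv)
        self.branch_a = BottleneckBlock(cfg.branch_channels, cfg.branch_channels, k, rng, conv)
        self.branch_b1 = BottleneckBlock(cfg.branch_channels, cfg.branch_channels, k, rng, conv)
        self.branch_b2 = BottleneckBlock(cfg.branch_channels, cfg.branch_channels, k, rng, conv)
        self.fuse = BottleneckBlock(cfg.branch_channels, cfg.branch_channels, k, rng, conv)
        self.reduce1 = BottleneckBlock(cfg.branch_channels, cfg.reduce_channels, k, rng, conv)
        self.reduce2 = BottleneckBlock(cfg.reduce_channels, cfg.reduce_channels, k, rng, conv)
        self.pool = nn.AvgPool(3, 4)
        pooled = (cfg.height // 3) * (cfg.width // 4) * cfg.reduce_channels
        self.fc = nn.Linear(pooled, cfg.token_dim, rng)
        self.cfg = cfg

    def forward(self, x: Tensor) -> Tensor:
        """(B*T, H, W, d) frames -> (B*T, token_dim)."""
        x = self.halve(self.expand(x))
        x = self.fuse(self.branch_a(x) + self.branch_b2(self.branch_b1(x)))
        x = self.reduce2(self.reduce1(x))
        x = self.pool(x)
        n = x.shape[0]
        return self.fc(x.reshape((n, -1)))


class BottleneckModuleG(nn.Module):
    """Generator backbone: same 8-block stack, final projection back to d bands."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        k, conv = cfg.expansion, cfg.conv
        self.expand = BottleneckBlock(cfg.n_bands, cfg.base_channels, k, rng, conv)
        self.halve = BottleneckBlock(cfg.base_channels, cfg.branch_channels, k, rng, conv)
        self.branch_a = BottleneckBlock(cfg.branch_channels, cfg.branch_channels, k, rng, conv)
        self.branch_b1 = BottleneckBlock(cfg.branch_channels, cfg.branch_channels, k, rng, conv)
        self.branch_b2 = BottleneckBlock(cfg.branch_channels, cfg.branch_channels, k, rng, conv)
        self.fuse = BottleneckBlock(cfg.branch_channels, cfg.branch_channels, k, rng, conv)
        self.final1 = BottleneckBlock(cfg.branch_channels, cfg.reduce_channels, k, rng, conv)
        self.final2 = BottleneckBlock(cfg.reduce_channels, cfg.n_bands, k, rng, conv)

    def forward(self, x: Tensor) -> Tensor:
        """(B*T, H, W, d) -> (B*T, H, W, d)."""
        x = self.halve(self.expand(x))
        x = self.fuse(self.branch_a(x) + self.branch_b2(self.branch_b1(x)))
        return self.final2(self.final1(x))


# ---------------------------------------------------------------------------
# generator / discriminator
# ---------------------------------------------------------------------------

def _fold_frames(x: Tensor) -> Tensor:
    """(B, H, W, d, T) -> (B*T, H, W, d)."""
    b, h, w, d, t = x.shape
    return x.transpose((0, 4, 1, 2, 3)).reshape((b * t, h, w, d))


def _unfold_frames(x: Tensor, batch: int, t: int) -> Tensor:
    """(B*T, H, W, d) -> (B, H, W, d, T)."""
    _, h, w, d = x.shape
    return x.reshape((batch, t, h, w, d)).transpose((0, 2, 3, 4, 1))


class Generator(nn.Module):
    """G(z, l) -> synthetic 4D feature tensor Y in R^{h x w x d x 2T}."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        t, dim = cfg.n_frames, cfg.token_dim
        self.fc_in = nn.Linear(cfg.nz + cfg.n_classes, t * dim, rng)
        self.transformer = nn.TransformerEncoder(
            dim, t, cfg.n_transformer_blocks, cfg.n_heads, cfg.mlp_hidden,
            cfg.dropout, rng, cfg.positional,
        )
        # DeConv stage: per-token linear to a 2x3 coarse map, then a
        # transposed convolution (kernel = stride = 3) up to the 6x9 grid
        self.coarse_h, self.coarse_w = cfg.height // 3, cfg.width // 3
        self.to_coarse = nn.Linear(dim, self.coarse_h * self.coarse_w * cfg.deconv_channels, rng)
        self.deconv = nn.Linear(cfg.deconv_channels, 9 * cfg.n_bands, rng)
        self.attention = AttentionModule(cfg.n_bands, rng) if cfg.use_attention else None
        self.backbone = BottleneckModuleG(cfg, rng)

    def forward(self, z: Tensor | np.ndarray, labels: np.ndarray) -> Tensor:
        cfg = self.cfg
        z = ad.as_tensor(z)
        b = z.shape[0]
        onehot = np.zeros((b, cfg.n_classes))
        onehot[np.arange(b), np.asarray(labels, dtype=int)] = 1.0
        w = self.fc_in(ad.concat([z, Tensor(onehot)], axis=1))
        tokens = w.reshape((b, cfg.n_frames, cfg.token_dim))
        tokens = self.transformer(tokens)
        frames = tokens.reshape((b * cfg.n_frames, cfg.token_dim))
        coarse = self.to_coarse(frames).reshape((-1, self.coarse_h, self.coarse_w, cfg.deconv_channels))
        up = self.deconv(coarse)                      # (N, ch, cw, 9*d)
        n = up.shape[0]
        up = up.reshape((n, self.coarse_h, self.coarse_w, 3, 3, cfg.n_bands))
        up = up.transpose((0, 1, 3, 2, 4, 5)).reshape((n, cfg.height, cfg.width, cfg.n_bands))
        if self.attention is not None:
            up = self.attention(up)
        out = self.backbone(up)
        return _unfold_frames(out, b, cfg.n_frames)

    def sample_latent(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.standard_normal((n, self.cfg.nz))


class Discriminator(nn.Module):
    """D(x) -> (Wasserstein critic score, class logits)."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.attention = AttentionModule(cfg.n_bands, rng) if cfg.use_attention else None
        self.backbone = BottleneckModuleD(cfg, rng)
        self.transformer = nn.TransformerEncoder(
            cfg.token_dim, cfg.n_frames, cfg.n_transformer_blocks, cfg.n_heads,
            cfg.mlp_hidden, cfg.dropout, rng, cfg.positional,
        )
        self.head_adv = nn.Linear(cfg.token_dim, 1, rng)
        self.head_cls = nn.Linear(cfg.token_dim, cfg.n_classes, rng)

    def features(self, x: Tensor | np.ndarray) -> Tensor:
        """(B, H, W, d, T) -> pooled (B, token_dim) trunk features."""
        x = ad.as_tensor(x)
        b, t = x.shape[0], self.cfg.n_frames
        frames = _fold_frames(x)
        if self.attention is not None:
            frames = self.attention(frames)
        tokens = self.backbone(frames).reshape((b, t, self.cfg.token_dim))
        tokens = self.transformer(tokens)
        return tokens.mean(axis=1)

    def forward(self, x: Tensor | np.ndarray) -> tuple[Tensor, Tensor]:
        feats = self.features(x)
        adv = self.head_adv(feats).reshape((-1,))
        cls_logits = self.head_cls(feats)
        return adv, cls_logits


@dataclass
class DiscriminatorOutput:
    """Critic score (unbounded real) and class posterior per sample."""

    adv: np.ndarray
    cls: np.ndarray


def generator_forward(G: Generator, z: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Evaluate the generator without tracing a gradient tape."""
    G.eval()
    with ad.no_grad():
        out = G(z, labels)
    return out.numpy()


def discriminator_forward(D: Discriminator, x: np.ndarray) -> DiscriminatorOutput:
    """Evaluate the discriminator; class head returned as probabilities."""
    D.eval()
    with ad.no_grad():
        adv, logits = D(x)
        probs = nn.softmax(logits, axis=-1)
    return DiscriminatorOutput(adv=adv.numpy(), cls=probs.numpy())


# ---------------------------------------------------------------------------
# accounting
# ---------------------------------------------------------------------------

def count_forward_gflops(model: nn.Module, *args) -> float:
    """Multiply-accumulate count (in GFLOPs) of one traced forward pass."""
    model.eval()
    with ad.no_grad(), ad.flop_counter() as counter:
        model(*args)
    return counter.gflops


def summarize(model: nn.Module, *forward_args) -> str:
    """Human-readable per-parameter summary with total params and FLOPs."""
    lines = [f"{type(model).__name__}"]
    for name, p in model.named_parameters():
        lines.append(f"  {name:<50s} {str(p.shape):>18s} {p.size:>10d}")
    lines.append(f"  total parameters: {model.n_parameters():,}")
    if forward_args:
        gf = count_forward_gflops(model, *forward_args)
        lines.append(f"  forward pass: {gf:.4f} GFLOPs (multiply-accumulate)")
    return "\n".join(lines)


def save_checkpoint(path, config: ModelConfig, **modules: nn.Module) -> None:
    """Write model weights plus the config (and its hash) to an .npz file."""
    arrays = {}
    for tag, module in modules.items():
        for name, arr in module.state_dict().items():
            arrays[f"{tag}:{name}"] = arr
    meta = json.dumps({"config": config.to_dict(), "hash": config.hash()})
    np.savez_compressed(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> tuple[ModelConfig, dict[str, dict[str, np.ndarray]]]:
    data = np.load(path)
    meta = json.loads(bytes(data["__meta__"]).decode())
    cfg = ModelConfig.from_dict(meta["config"])
    states: dict[str, dict[str, np.ndarray]] = {}
    for key in data.files:
        if key == "__meta__":
            continue
        tag, name = key.split(":", 1)
        states.setdefault(tag, {})[name] = data[key]
    return cfg, states
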