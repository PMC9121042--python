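"""The dual-input visual-saliency + transformer (VST) segmentation network.

Architecture
------------
Two identical CNN encoders (one fed the CT image, one fed the saliency map)
downsample by a factor of ``2**stages`` through repeated [conv3x3-ReLU x2,
maxpool2x2] blocks.  Their bottleneck feature maps are fused by channel
concatenation, flattened into a token sequence of length ``H*W / 4**stages``
(H·W/256 at the default four stages), summed with learnable position
embeddings, and passed through ``depth`` multi-head self-attention +
MLP layers.  The output tokens are reshaped back to a feature map and decoded
by a skip-connected upsampling CNN to a per-pixel class-score grid, with
optional auxiliary score heads at the intermediate decoder resolutions for
deep supervision.

Ablation ladder (all under one config):

- ``unet``: single image encoder, no transformer;
- ``multi_unet``: two encoders, both fed the image, no transformer;
- ``multi_unet_transformer``: two image-fed encoders + transformer;
- ``vst``: two encoders (image + saliency) + transformer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field

import numpy as np

from .nn import (
    Conv2d,
    LayerNorm,
    Linear,
    Module,
    ModuleList,
    Parameter,
    Tensor,
    concat,
    conv2d,
    maxpool2x2,
    relu,
    softmax,
    upsample2x_nearest,
)

MODES = ("unet", "multi_unet", "multi_unet_transformer", "vst")


@dataclass
class VSTConfig:
    """Hyper-parameters of the network.

    ``depth`` (transformer layers) and ``heads`` default to the ablation
    optimum L=8, h=8; ``stages`` and the channel doubling schedule give the
    standard input-to-bottleneck downsampling factor of 16 at 4 stages.
    """

    stages: int = 4
    base_channels: int = 32
    depth: int = 8
    heads: int = 8
    token_dim: int | None = None
    n_classes: int = 7
    input_size: tuple[int, int] = (512, 512)
    deep_supervision: bool = True
    mode: str = "vst"
    dual_skips: bool = False
    pre_norm: bool = True

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        h, w = self.input_size
        f = 2**self.stages
        if h % f or w % f:
            raise ValueError(
                f"input size {h}x{w} must be divisible by 2**stages = {f}"
            )
        d = self.resolved_token_dim
        if self.uses_transformer and d % self.heads:
            raise ValueError(f"token dim {d} not divisible by heads {self.heads}")

    @property
    def uses_transformer(self) -> bool:
        return self.mode in ("multi_unet_transformer", "vst")

    @property
    def n_encoders(self) -> int:
        return 1 if self.mode == "unet" else 2

    @property
    def channel_schedule(self) -> list[int]:
        return [self.base_channels * 2**s for s in range(self.stages)]

    @property
    def bottleneck_channels(self) -> int:
        return self.channel_schedule[-1]

    @property
    def fused_channels(self) -> int:
        return self.bottleneck_channels * self.n_encoders

    @property
    def resolved_token_dim(self) -> int:
        return self.token_dim if self.token_dim is not None else self.fused_channels

    @property
    def token_count(self) -> int:
        h, w = self.input_size
        return (h * w) // (2**self.stages) ** 2


def token_count(input_size: tuple[int, int], stages: int = 4) -> int:
    """Sequence length law: H*W / (2**stages)**2 tokens."""
    h, w = input_size
    return (h * w) // (2**stages) ** 2


# ---------------------------------------------------------------------------
# pure-array attention primitives (also the spec surface for oracle checks)
# ---------------------------------------------------------------------------

def _np_softmax(x, axis=-1):
    e = np.exp(x - x.max(axis=axis, keepdims=True))
    return e / e.sum(axis=axis, keepdims=True)


def self_attention(x: np.ndarray, wq: np.ndarray, wk: np.ndarray, wv: np.ndarray):
    """Residual scaled dot-product self-attention on a single token sequence.

    ``out = x + softmax(x wq (x wk)^T / sqrt(d)) x wv`` with d the projection
    width.  ``x`` is (n_tokens, c); wq/wk/wv are (c, d).
    """
    d = wq.shape[1]
    q, k, v = x @ wq, x @ wk, x @ wv
    att = _np_softmax(q @ k.T / np.sqrt(d), axis=-1)
    return x + att @ v


def msa(x: np.ndarray, head_params: list[tuple[np.ndarray, np.ndarray, np.ndarray]],
        wo: np.ndarray) -> np.ndarray:
    """Multi-head self-attention: heads concatenated then projected by wo.

    A single residual is applied after the output projection; with one head
    and an identity ``wo`` this collapses to :func:`self_attention`.
    """
    dh = head_params[0][0].shape[1]
    heads = []
    for wq, wk, wv in head_params:
        q, k, v = x @ wq, x @ wk, x @ wv
        att = _np_softmax(q @ k.T / np.sqrt(dh), axis=-1)
        heads.append(att @ v)
    return x + np.concatenate(heads, axis=-1) @ wo


# ---------------------------------------------------------------------------
# trainable modules
# ---------------------------------------------------------------------------

class ConvBlock(Module):
    """Two same-padded 3x3 convolutions, each followed by ReLU."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.conv1 = Conv2d(cin, cout, rng)
        self.conv2 = Conv2d(cout, cout, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return relu(self.conv2(relu(self.conv1(x))))


class Encoder(Module):
    """Stacked conv blocks with 2x2 max pooling between stages."""

    def __init__(self, config: VSTConfig, rng: np.random.Generator):
        chs = config.channel_schedule
        self.blocks = ModuleList(
            ConvBlock(cin, cout, rng)
            for cin, cout in zip([1] + chs[:-1], chs)
        )

    def __call__(self, x: Tensor) -> tuple[list[Tensor], Tensor]:
        """Return per-stage (pre-pool) skip features and the bottleneck."""
        skips = []
        for block in self.blocks:
            x = block(x)
            skips.append(x)
            x = maxpool2x2(x)
        return skips, x


class MultiHeadSelfAttention(Module):
    def __init__(self, d: int, h: int, rng: np.random.Generator):
        dh = d // h
        std = 1.0 / np.sqrt(d)

        def w(shape):
            return Parameter((rng.standard_normal(shape) * std).astype(np.float32))

        self.wq = [w((d, dh)) for _ in range(h)]
        self.wk = [w((d, dh)) for _ in range(h)]
        self.wv = [w((d, dh)) for _ in range(h)]
        self.wo = w((d, d))
        self.h, self.dh = h, dh

    def core(self, x: Tensor) -> Tensor:
        """Concat-of-heads projected by wo, without the residual."""
        heads = []
        scale = 1.0 / np.sqrt(self.dh)
        for i in range(self.h):
            q = x @ self.wq[i]
            k = x @ self.wk[i]
            v = x @ self.wv[i]
            att = softmax((q @ k.transpose((0, 2, 1))) * scale, axis=-1)
            heads.append(att @ v)
        return concat(heads, axis=-1) @ self.wo

    def __call__(self, x: Tensor) -> Tensor:
        return x + self.core(x)


class MLP(Module):
    """Two-layer feed-forward block with a 4x hidden expansion."""

    def __init__(self, d: int, rng: np.random.Generator):
        self.fc1 = Linear(d, 4 * d, rng)
        self.fc2 = Linear(4 * d, d, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(relu(self.fc1(x)))


class TransformerLayer(Module):
    """One MSA + MLP layer, each contributing through a residual.

    ``pre_norm=True`` (default) applies layer normalisation before MSA and
    MLP for trainability; ``pre_norm=False`` is the strict composition
    ``x_l = MSA(x_{l-1}) + MLP(MSA(x_{l-1}))`` with no normalisation, kept
    for oracle tests.
    """

    def __init__(self, d: int, h: int, rng: np.random.Generator, pre_norm=True):
        self.msa = MultiHeadSelfAttention(d, h, rng)
        self.mlp = MLP(d, rng)
        self.pre_norm = pre_norm
        if pre_norm:
            self.ln1 = LayerNorm(d)
            self.ln2 = LayerNorm(d)

    def __call__(self, x: Tensor) -> Tensor:
        if self.pre_norm:
            y = x + self.msa.core(self.ln1(x))
            return y + self.mlp(self.ln2(y))
        y = self.msa(x)
        return y + self.mlp(y)


class TransformerEncoder(Module):
    """Token embedding (flatten + learnable positions) and L attention layers."""

    def __init__(self, config: VSTConfig, rng: np.random.Generator):
        d = config.resolved_token_dim
        n = config.token_count
        cf = config.fused_channels
        # truncated-normal position embeddings, sd 0.02 clipped at 2 sd
        pos = rng.standard_normal((n, d)) * 0.02
        self.pos = Parameter(np.clip(pos, -0.04, 0.04).astype(np.float32))
        self.proj_in = Linear(cf, d, rng) if d != cf else None
        self.proj_out = Linear(d, cf, rng) if d != cf else None
        self.layers = ModuleList(
            TransformerLayer(d, config.heads, rng, config.pre_norm)
            for _ in range(config.depth)
        )

    def embed(self, feature: Tensor) -> Tensor:
        """Flatten an (N, C, h, w) feature map into tokens and add positions."""
        n, c, h, w = feature.data.shape
        x = feature.reshape(n, c, h * w).transpose((0, 2, 1))
        if self.proj_in is not None:
            x = self.proj_in(x)
        return x + self.pos

    def __call__(self, feature: Tensor) -> Tensor:
        n, c, h, w = feature.data.shape
        x = self.embed(feature)
        for layer in self.layers:
            x = layer(x)
        if self.proj_out is not None:
            x = self.proj_out(x)
        return x.transpose((0, 2, 1)).reshape(n, c, h, w)


class Decoder(Module):
    """Skip-connected upsampling decoder with optional auxiliary heads."""

    def __init__(self, config: VSTConfig, rng: np.random.Generator):
        chs = config.channel_schedule  # c_1 .. c_S
        self.bridge = Conv2d(config.fused_channels, chs[-1], rng, k=1)
        skip_mult = 2 if config.dual_skips else 1
        self.blocks = ModuleList()
        self.aux_heads = ModuleList()
        prev = chs[-1]
        for s in range(config.stages - 1, -1, -1):  # levels S..1
            out = chs[s]
            self.blocks.append(ConvBlock(prev + skip_mult * chs[s], out, rng))
            if config.deep_supervision and s > 0:
                self.aux_heads.append(Conv2d(out, config.n_classes, rng, k=1))
            prev = out
        self.head = Conv2d(chs[0], config.n_classes, rng, k=1)
        self.deep_supervision = config.deep_supervision
        # zero-init scoring heads: predictions start uniform over classes,
        # which keeps the initial loss at its chance value and avoids an
        # early collapse onto the majority (background) class
        for scorer in [self.head, *self.aux_heads]:
            scorer.weight.data[:] = 0.0
            scorer.bias.data[:] = 0.0

    def __call__(self, bottleneck: Tensor, skips: list[list[Tensor]]):
        x = self.bridge(bottleneck)
        aux = []
        n_levels = len(self.blocks)
        for i, block in enumerate(self.blocks):
            level = n_levels - 1 - i  # encoder stage index (0-based), S-1..0
            x = upsample2x_nearest(x)
            skip_feats = [s[level] for s in skips]
            x = block(concat([x] + skip_feats, axis=1))
            if self.deep_supervision and level > 0:
                aux.append(self.aux_heads[i](x))
        return self.head(x), aux


class VSTNet(Module):
    """Full dual-input network; see the module docstring for the layout."""

    def __init__(self, config: VSTConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.config = config
        self.encoder_image = Encoder(config, rng)
        self.encoder_second = Encoder(config, rng) if config.n_encoders == 2 else None
        self.transformer = TransformerEncoder(config, rng) if config.uses_transformer else None
        self.decoder = Decoder(config, rng)

    # -- pieces -------------------------------------------------------------
    def _prep(self, arr: np.ndarray) -> Tensor:
        arr = np.asarray(arr, dtype=np.float32)
        if arr.ndim == 2:
            arr = arr[None]
        if arr.ndim == 3:
            arr = arr[:, None]  # N,1,H,W
        h, w = arr.shape[-2:]
        eh, ew = self.config.input_size
        if (h, w) != (eh, ew):
            raise ValueError(f"input {h}x{w} does not match configured size {eh}x{ew}")
        return Tensor(arr)

    def fuse(self, bottleneck_image: Tensor, bottleneck_second: Tensor | None) -> Tensor:
        """Channel-concatenate the encoders' bottlenecks (identity for one)."""
        if bottleneck_second is None:
            return bottleneck_image
        if bottleneck_image.data.shape[-2:] != bottleneck_second.data.shape[-2:]:
            raise ValueError("encoder bottlenecks disagree in spatial shape")
        return concat([bottleneck_image, bottleneck_second], axis=1)

    # -- forward ------------------------------------------------------------
    def __call__(self, image: np.ndarray, saliency: np.ndarray | None = None):
        cfg = self.config
        if cfg.mode == "vst" and saliency is None:
            raise ValueError("vst mode is dual-input: a saliency map is required")
        if cfg.mode != "vst" and saliency is not None:
            raise ValueError(f"mode {cfg.mode!r} does not take a saliency input")
        x_img = self._prep(image)
        skips_img, bott_img = self.encoder_image(x_img)
        skips = [skips_img]
        bott_second = None
        if self.encoder_second is not None:
            second_in = self._prep(saliency) if cfg.mode == "vst" else x_img
            skips_second, bott_second = self.encoder_second(second_in)
            if cfg.dual_skips:
                skips.append(skips_second)
        fused = self.fuse(bott_img, bott_second)
        if self.transformer is not None:
            fused = self.transformer(fused)
        scores, aux = self.decoder(fused, skips)
        return {"scores": scores, "aux": aux}

    def predict_labels(self, image: np.ndarray, saliency: np.ndarray | None = None):
        out = self(image, saliency)
        return np.argmax(out["scores"].data, axis=1)

    # -- persistence --------------------------------------------------------
    def save(self, path) -> None:
        arrays = {name: p.data for name, p in self.named_parameters()}
        cfg = asdict(self.config)
        np.savez(path, __config__=np.frombuffer(
            json.dumps(cfg).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "VSTNet":
        with np.load(path) as z:
            cfg = json.loads(bytes(z["__config__"]).decode())
            cfg["input_size"] = tuple(cfg["input_size"])
            model = cls(VSTConfig(**cfg))
            params = dict(model.named_parameters())
            for name in z.files:
                if name == "__config__":
                    continue
                params[name].data = z[name].copy()
        return model
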