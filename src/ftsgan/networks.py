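"""Generator and discriminator architectures for the fusion GAN.

The generator is an autoencoder.  Its encoder is a five-layer densely
connected stack of size-preserving 3x3 "deconvolution" layers (stride 1,
padding 1): the input to layer k is the channel concatenation of the raw
2-channel input and the outputs of all previous layers, each layer adding
``growth_channels`` feature maps.  With the default growth of 16 the
concatenated inputs grow 2 -> 18 -> 34 -> 50 -> 66 and the final encoder
feature has 2 + 5*16 = 82 channels.  The decoder is five plain 3x3
convolutions narrowing 82 -> 64 -> 32 -> 16 -> 8 -> 1, with LeakyReLU
activations and a sigmoid output squashing the fused image into [0, 1].
Because every layer preserves spatial size, the generator is fully
convolutional and works at any input size of at least 8x8.

The discriminator scores whether an image looks like a real visible image:
three stride-2 3x3 convolutions (16, 32, 64 channels) with batch
normalization and LeakyReLU (slope 0.2), flattened into a single linear
unit with a sigmoid.  The linear head binds the discriminator to a fixed
training size (default 128).

Weights are He-initialized (fan-in, LeakyReLU gain) from a seeded
generator, so two builds with the same seed are bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import List, Tuple

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .exceptions import ConfigurationError, DimensionError
from .image_io import GrayImage, ImagePair, as_pixels

__all__ = [
    "GeneratorConfig",
    "DiscriminatorConfig",
    "FusionModel",
    "build_generator",
    "build_discriminator",
    "build_model",
    "fuse",
    "discriminate",
    "save_model",
    "load_model",
]

MIN_FUSE_SIZE = 8


@dataclass(frozen=True)
class GeneratorConfig:
    encoder_layers: int = 5
    decoder_layers: int = 5
    kernel: int = 3
    stride: int = 1
    padding: int = 1
    growth_channels: int = 16
    leaky_slope: float = 0.2
    input_channels: int = 2
    output_channels: int = 1

    def __post_init__(self):
        if self.growth_channels < 1:
            raise ConfigurationError("growth_channels must be a positive integer")
        if self.encoder_layers < 1 or self.decoder_layers < 1:
            raise ConfigurationError("layer counts must be positive")
        if self.kernel != 2 * self.padding + 1 or self.stride != 1:
            raise ConfigurationError(
                "generator layers must preserve spatial size (kernel = 2*padding + 1, stride 1)"
            )

    @property
    def encoder_feature_channels(self) -> int:
        return self.input_channels + self.encoder_layers * self.growth_channels

    @property
    def decoder_plan(self) -> Tuple[int, ...]:
        # Geometric narrowing from the dense feature to the fused channel.
        plan, c = [], self.encoder_feature_channels
        widths = [64, 32, 16, 8]
        for k in range(self.decoder_layers - 1):
            plan.append(widths[k] if k < len(widths) else max(widths[-1] // 2 ** (k - len(widths) + 1), 2))
        plan.append(self.output_channels)
        return tuple(plan)


@dataclass(frozen=True)
class DiscriminatorConfig:
    conv_layers: int = 3
    channel_plan: Tuple[int, ...] = (16, 32, 64)
    kernel: int = 3
    stride: int = 2
    padding: int = 1
    leaky_slope: float = 0.2
    batch_norm: bool = True
    input_size: int = 128
    input_channels: int = 1

    def __post_init__(self):
        if len(self.channel_plan) != self.conv_layers:
            raise ConfigurationError("channel_plan length must equal conv_layers")
        if any(c < 1 for c in self.channel_plan):
            raise ConfigurationError("channel_plan entries must be positive")
        if self.input_size % (self.stride**self.conv_layers) != 0:
            raise ConfigurationError(
                f"input_size {self.input_size} must be divisible by "
                f"{self.stride ** self.conv_layers}"
            )

    @property
    def flat_features(self) -> int:
        side = self.input_size // (self.stride**self.conv_layers)
        return self.channel_plan[-1] * side * side


# layers ---------------------------------------------------------------
def _he_init(rng: np.random.Generator, shape, fan_in: int, slope: float, dtype) -> np.ndarray:
    gain = np.sqrt(2.0 / (1.0 + slope**2))
    std = gain / np.sqrt(fan_in)
    return (rng.standard_normal(shape) * std).astype(dtype)


class Conv2d:
    def __init__(self, rng, in_ch, out_ch, kernel, stride, padding, slope, dtype=np.float32):
        fan_in = in_ch * kernel * kernel
        self.weight = Tensor(_he_init(rng, (out_ch, in_ch, kernel, kernel), fan_in, slope, dtype), requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch, dtype=dtype), requires_grad=True)
        self.stride, self.padding = stride, padding

    def __call__(self, x: Tensor) -> Tensor:
        return ad.conv2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)

    def parameters(self) -> List[Tensor]:
        return [self.weight, self.bias]


class Linear:
    def __init__(self, rng, in_features, out_features, dtype=np.float32):
        self.weight = Tensor(_he_init(rng, (in_features, out_features), in_features, 1.0, dtype), requires_grad=True)
        self.bias = Tensor(np.zeros(out_features, dtype=dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ad.matmul(x, self.weight) + self.bias

    def parameters(self) -> List[Tensor]:
        return [self.weight, self.bias]


class BatchNorm2d:
    """Per-channel batch normalization with running statistics for eval."""

    def __init__(self, channels, momentum=0.1, eps=1e-5, dtype=np.float32):
        self.gamma = Tensor(np.ones((1, channels, 1, 1), dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros((1, channels, 1, 1), dtype=dtype), requires_grad=True)
        self.running_mean = np.zeros((1, channels, 1, 1), dtype=dtype)
        self.running_var = np.ones((1, channels, 1, 1), dtype=dtype)
        self.momentum, self.eps = momentum, eps

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        if training:
            mu = ad.tmean(x, axis=(0, 2, 3), keepdims=True)
            var = ad.tmean((x - mu) * (x - mu), axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data
            self.running_var = (1 - m) * self.running_var + m * var.data
        else:
            mu, var = Tensor(self.running_mean), Tensor(self.running_var)
        xhat = (x - mu) / ad.sqrt(var + self.eps)
        return xhat * self.gamma + self.beta

    def parameters(self) -> List[Tensor]:
        return [self.gamma, self.beta]


# networks -------------------------------------------------------------
class Generator:
    def __init__(self, cfg: GeneratorConfig, seed: int):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        self.encoder: List[Conv2d] = []
        in_ch = cfg.input_channels
        for _ in range(cfg.encoder_layers):
            self.encoder.append(Conv2d(rng, in_ch, cfg.growth_channels, cfg.kernel, cfg.stride, cfg.padding, cfg.leaky_slope))
            in_ch += cfg.growth_channels
        self.decoder: List[Conv2d] = []
        c = cfg.encoder_feature_channels
        for out_ch in cfg.decoder_plan:
            self.decoder.append(Conv2d(rng, c, out_ch, cfg.kernel, cfg.stride, cfg.padding, cfg.leaky_slope))
            c = out_ch

    def forward(self, x: Tensor) -> Tensor:
        feats = [x]
        for conv in self.encoder:
            inp = feats[0] if len(feats) == 1 else ad.concat(feats, axis=1)
            feats.append(ad.leaky_relu(conv(inp), self.cfg.leaky_slope))
        h = ad.concat(feats, axis=1)
        for conv in self.decoder[:-1]:
            h = ad.leaky_relu(conv(h), self.cfg.leaky_slope)
        return ad.sigmoid(self.decoder[-1](h))

    def parameters(self) -> List[Tensor]:
        return [p for layer in self.encoder + self.decoder for p in layer.parameters()]

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


class Discriminator:
    def __init__(self, cfg: DiscriminatorConfig, seed: int):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        self.convs: List[Conv2d] = []
        self.norms: List[BatchNorm2d] = []
        in_ch = cfg.input_channels
        for out_ch in cfg.channel_plan:
            self.convs.append(Conv2d(rng, in_ch, out_ch, cfg.kernel, cfg.stride, cfg.padding, cfg.leaky_slope))
            if cfg.batch_norm:
                self.norms.append(BatchNorm2d(out_ch))
            in_ch = out_ch
        self.head = Linear(rng, cfg.flat_features, 1)

    def forward(self, x: Tensor, training: bool = False) -> Tensor:
        if x.shape[2] != self.cfg.input_size or x.shape[3] != self.cfg.input_size:
            raise DimensionError(
                f"discriminator expects {self.cfg.input_size}x{self.cfg.input_size} input, "
                f"got {x.shape[2]}x{x.shape[3]}"
            )
        h = x
        for k, conv in enumerate(self.convs):
            h = conv(h)
            if self.cfg.batch_norm:
                h = self.norms[k](h, training)
            h = ad.leaky_relu(h, self.cfg.leaky_slope)
        h = ad.reshape(h, (h.shape[0], -1))
        return ad.sigmoid(self.head(h))

    def parameters(self) -> List[Tensor]:
        params = [p for c in self.convs for p in c.parameters()]
        params += [p for n in self.norms for p in n.parameters()]
        params += self.head.parameters()
        return params

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


@dataclass
class FusionModel:
    generator: Generator
    discriminator: Discriminator
    gen_cfg: GeneratorConfig
    disc_cfg: DiscriminatorConfig
    seed: int = 0


# operations -----------------------------------------------------------
def build_generator(cfg: GeneratorConfig = GeneratorConfig(), seed: int = 0) -> Generator:
    """Deterministically initialize the dense autoencoder generator."""
    return Generator(cfg, seed)


def build_discriminator(cfg: DiscriminatorConfig = DiscriminatorConfig(), seed: int = 0) -> Discriminator:
    return Discriminator(cfg, seed)


def build_model(
    gen_cfg: GeneratorConfig = GeneratorConfig(),
    disc_cfg: DiscriminatorConfig = DiscriminatorConfig(),
    seed: int = 0,
) -> FusionModel:
    """Build a generator/discriminator pair from one seed.

    The two sub-networks draw from independent streams derived from the
    model seed so that changing the discriminator layout cannot perturb
    the generator's initialization.
    """
    g_seed, d_seed = (int(s) for s in np.random.SeedSequence(seed).generate_state(2) % (2**31))
    return FusionModel(
        generator=build_generator(gen_cfg, g_seed),
        discriminator=build_discriminator(disc_cfg, d_seed),
        gen_cfg=gen_cfg,
        disc_cfg=disc_cfg,
        seed=seed,
    )


def _pair_batch(pair: ImagePair, dtype=np.float32) -> Tensor:
    v = as_pixels(pair.visible).astype(dtype)
    i = as_pixels(pair.infrared).astype(dtype)
    return Tensor(np.stack([v, i])[None])


def fuse(model: FusionModel, pair: ImagePair) -> GrayImage:
    """Fuse one aligned pair into a single image (inference mode)."""
    m, n = pair.shape
    if m < MIN_FUSE_SIZE or n < MIN_FUSE_SIZE:
        raise DimensionError(f"fusion needs at least {MIN_FUSE_SIZE}x{MIN_FUSE_SIZE}, got {pair.shape}")
    with ad.no_grad():
        out = model.generator.forward(_pair_batch(pair))
    return GrayImage(np.clip(out.data[0, 0].astype(np.float64), 0.0, 1.0))


def discriminate(model: FusionModel, img) -> float:
    """Probability that an image is a real visible image (eval-mode BN)."""
    x = as_pixels(img).astype(np.float32)
    with ad.no_grad():
        score = model.discriminator.forward(Tensor(x[None, None]), training=False)
    return float(score.data.ravel()[0])


# serialization --------------------------------------------------------
def save_model(model: FusionModel, path) -> Path:
    """Serialize parameters + configs into a single ``.npz`` archive."""
    path = Path(path)
    arrays = {}
    for k, p in enumerate(model.generator.parameters()):
        arrays[f"g{k}"] = p.data
    for k, p in enumerate(model.discriminator.parameters()):
        arrays[f"d{k}"] = p.data
    for k, bn in enumerate(model.discriminator.norms):
        arrays[f"rm{k}"] = bn.running_mean
        arrays[f"rv{k}"] = bn.running_var
    meta = json.dumps(
        {"gen": asdict(model.gen_cfg), "disc": asdict(model.disc_cfg), "seed": model.seed}
    )
    arrays["meta"] = np.frombuffer(meta.encode(), dtype=np.uint8)
    np.savez(path, **arrays)
    return path


def load_model(path) -> FusionModel:
    with np.load(Path(path)) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        gen_cfg = GeneratorConfig(**meta["gen"])
        disc = dict(meta["disc"])
        disc["channel_plan"] = tuple(disc["channel_plan"])
        disc_cfg = DiscriminatorConfig(**disc)
        model = build_model(gen_cfg, disc_cfg, seed=meta["seed"])
        for k, p in enumerate(model.generator.parameters()):
            p.data = data[f"g{k}"]
        for k, p in enumerate(model.discriminator.parameters()):
            p.data = data[f"d{k}"]
        for k, bn in enumerate(model.discriminator.norms):
            bn.running_mean = data[f"rm{k}"]
            bn.running_var = data[f"rv{k}"]
    return model
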