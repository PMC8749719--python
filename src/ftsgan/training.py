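"""Adversarial training loop with loss-minimum balancing.

Each epoch alternates a discriminator pass (minimizing the binary
cross-entropy objective on real visible images vs. detached fused images)
and a generator pass (minimizing the composite F + TV + SSIM objective),
both driven by the Adamax optimizer (the infinity-norm variant of Adam).

A running minimum of each player's epoch loss is tracked.  After the main
passes, a player whose loss has failed to come within ``l_min_margin`` of
its running minimum during the last ``*_repeat_window`` epochs is granted
up to ``max_extra_passes`` additional passes in that epoch, a terminating
reading of the "repeat training until close to L_MIN" balancing rule.

Every ``eval_every`` epochs the generator is scored on a holdout set (the
training set if none is given) with the six fusion-quality metrics.
Everything is driven by one seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .exceptions import AlignmentError, ConfigurationError, TrainingError
from .fusion_metrics import MetricReport, evaluate_all
from .image_io import ImagePair, as_pixels
from .losses import LossWeights, TermToggles, discriminator_loss_t, generator_loss_t
from .networks import (
    DiscriminatorConfig,
    FusionModel,
    GeneratorConfig,
    build_model,
    fuse,
)

__all__ = [
    "TrainConfig",
    "EpochRecord",
    "TrainHistory",
    "Adamax",
    "train",
    "evaluate_checkpoint",
    "restore_checkpoint",
]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 200
    batch_size: int = 16
    learning_rate: float = 1e-3
    discriminator_lr: Optional[float] = None  # defaults to learning_rate
    beta1: float = 0.9
    beta2: float = 0.999
    loss_weights: LossWeights = field(default_factory=LossWeights)
    term_toggles: TermToggles = field(default_factory=TermToggles)
    ssim_blend: bool = False
    d_repeat_window: int = 5
    g_repeat_window: int = 5
    l_min_margin: float = 5.0
    max_extra_passes: int = 4
    eval_every: int = 20
    keep_checkpoints: bool = False
    seed: int = 0
    gen_config: GeneratorConfig = field(default_factory=GeneratorConfig)
    growth_channels: Optional[int] = None

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1 or self.eval_every < 1:
            raise ConfigurationError("epochs, batch_size and eval_every must be >= 1")
        if self.growth_channels is not None:
            object.__setattr__(
                self, "gen_config", replace(self.gen_config, growth_channels=self.growth_channels)
            )


@dataclass(frozen=True)
class EpochRecord:
    epoch: int
    lga: float
    lgb: float
    lgc: float
    lg: float
    ld: float
    extra_d_passes: int = 0
    extra_g_passes: int = 0


@dataclass
class TrainHistory:
    records: List[EpochRecord] = field(default_factory=list)
    checkpoints: Dict[int, MetricReport] = field(default_factory=dict)
    generator_snapshots: Dict[int, List[np.ndarray]] = field(default_factory=dict)
    l_min_g: float = float("inf")
    l_min_d: float = float("inf")

    def __len__(self) -> int:
        return len(self.records)

    def best_checkpoint(self, metric: str = "qabf") -> int:
        """Checkpoint epoch maximizing a fusion-quality metric."""
        if not self.checkpoints:
            raise ConfigurationError("no checkpoints recorded (eval_every > epochs?)")
        return max(self.checkpoints, key=lambda e: getattr(self.checkpoints[e], metric))


class Adamax:
    """Adam with an infinity-norm second moment (bias-corrected first moment)."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.u = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        bias = 1.0 - self.beta1**self.t
        for k, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.beta1 * self.m[k] + (1.0 - self.beta1) * g
            self.u[k] = np.maximum(self.beta2 * self.u[k], np.abs(g))
            p.data = p.data - (self.lr / bias) * self.m[k] / (self.u[k] + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def _stack_dataset(dataset: Sequence[ImagePair]) -> Tuple[np.ndarray, np.ndarray]:
    if not dataset:
        raise ConfigurationError("training dataset must be non-empty")
    shapes = {p.shape for p in dataset}
    if len(shapes) > 1:
        raise AlignmentError(f"all training pairs must share dimensions, got {sorted(shapes)}")
    vis = np.stack([as_pixels(p.visible) for p in dataset]).astype(np.float32)[:, None]
    ir = np.stack([as_pixels(p.infrared) for p in dataset]).astype(np.float32)[:, None]
    return vis, ir


def _batches(n: int, batch_size: int, perm: np.ndarray):
    for start in range(0, n, batch_size):
        yield perm[start : start + batch_size]


def _needs_repeat(recent: List[float], l_min: float, margin: float) -> bool:
    return bool(recent) and min(recent) > l_min + margin


def train(
    dataset: Sequence[ImagePair],
    cfg: TrainConfig = TrainConfig(),
    holdout: Optional[Sequence[ImagePair]] = None,
) -> Tuple[FusionModel, TrainHistory]:
    """Adversarially train a fusion model on aligned pairs.

    Returns the trained model and a per-epoch history with loss breakdowns,
    running minima, and checkpoint metric reports.
    """
    vis, ir = _stack_dataset(dataset)
    n, _, h, w = vis.shape
    size = h  # discriminator head binds to the training size
    if h != w:
        raise ConfigurationError("training currently requires square images")
    disc_cfg = DiscriminatorConfig(input_size=size)
    model = build_model(cfg.gen_config, disc_cfg, seed=cfg.seed)
    G, D = model.generator, model.discriminator
    opt_g = Adamax(G.parameters(), lr=cfg.learning_rate, beta1=cfg.beta1, beta2=cfg.beta2)
    d_lr = cfg.discriminator_lr if cfg.discriminator_lr is not None else cfg.learning_rate
    opt_d = Adamax(D.parameters(), lr=d_lr, beta1=cfg.beta1, beta2=cfg.beta2)
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 7)))
    history = TrainHistory()
    ld_hist: List[float] = []
    lg_hist: List[float] = []

    def d_pass(perm: np.ndarray) -> float:
        losses = []
        for idx in _batches(n, cfg.batch_size, perm):
            v_b, i_b = vis[idx], ir[idx]
            with ad.no_grad():
                fused = G.forward(Tensor(np.concatenate([v_b, i_b], axis=1)))
            s_real = D.forward(Tensor(v_b), training=True)
            s_fake = D.forward(Tensor(fused.data), training=True)
            loss = discriminator_loss_t(s_real, s_fake)
            opt_d.zero_grad()
            loss.backward()
            opt_d.step()
            losses.append(loss.item())
        return float(np.mean(losses))

    def g_pass(perm: np.ndarray) -> Tuple[float, float, float, float]:
        vals = []
        for idx in _batches(n, cfg.batch_size, perm):
            v_b, i_b = Tensor(vis[idx]), Tensor(ir[idx])
            fused = G.forward(ad.concat([v_b, i_b], axis=1))
            scores = D.forward(fused, training=True)
            total, lga, lgb, lgc = generator_loss_t(
                scores, fused, v_b, i_b, cfg.loss_weights, cfg.term_toggles, blend=cfg.ssim_blend
            )
            opt_g.zero_grad()
            for p in D.parameters():
                p.grad = None
            total.backward()
            opt_g.step()
            for p in D.parameters():
                p.grad = None
            vals.append((total.item(), lga.item(), lgb.item(), lgc.item()))
        return tuple(np.mean(vals, axis=0))  # type: ignore[return-value]

    eval_pairs = list(holdout) if holdout else list(dataset)
    for epoch in range(1, cfg.epochs + 1):
        perm = rng.permutation(n)
        ld = d_pass(perm)
        lg, lga, lgb, lgc = g_pass(perm)
        extra_d = extra_g = 0
        if _needs_repeat(ld_hist[-cfg.d_repeat_window :], history.l_min_d, cfg.l_min_margin):
            while extra_d < cfg.max_extra_passes and ld > history.l_min_d + cfg.l_min_margin:
                ld = d_pass(rng.permutation(n))
                extra_d += 1
        if _needs_repeat(lg_hist[-cfg.g_repeat_window :], history.l_min_g, cfg.l_min_margin):
            while extra_g < cfg.max_extra_passes and lg > history.l_min_g + cfg.l_min_margin:
                lg, lga, lgb, lgc = g_pass(rng.permutation(n))
                extra_g += 1
        if not (np.isfinite(ld) and np.isfinite(lg)):
            raise TrainingError(f"non-finite loss at epoch {epoch}: ld={ld}, lg={lg}")
        ld_hist.append(ld)
        lg_hist.append(lg)
        history.l_min_d = min(history.l_min_d, ld)
        history.l_min_g = min(history.l_min_g, lg)
        history.records.append(
            EpochRecord(
                epoch=epoch,
                lga=float(lga),
                lgb=float(lgb),
                lgc=float(lgc),
                lg=float(lg),
                ld=float(ld),
                extra_d_passes=extra_d,
                extra_g_passes=extra_g,
            )
        )
        if epoch % cfg.eval_every == 0:
            history.checkpoints[epoch] = evaluate_checkpoint(model, eval_pairs)
            if cfg.keep_checkpoints:
                history.generator_snapshots[epoch] = [p.data.copy() for p in G.parameters()]
    return model, history


def restore_checkpoint(model: FusionModel, history: TrainHistory, epoch: int) -> FusionModel:
    """Rebuild a fusion model with the generator weights of a kept checkpoint.

    The quality reports recorded every ``eval_every`` epochs are the
    procedure's model-selection signal; this restores the generator that
    produced a chosen report (training must have run with
    ``keep_checkpoints=True``).
    """
    if epoch not in history.generator_snapshots:
        raise ConfigurationError(
            f"no generator snapshot for epoch {epoch}; "
            f"available: {sorted(history.generator_snapshots)}"
        )
    restored = build_model(model.gen_cfg, model.disc_cfg, seed=model.seed)
    for p, data in zip(restored.generator.parameters(), history.generator_snapshots[epoch]):
        p.data = data.copy()
    return restored


def evaluate_checkpoint(model: FusionModel, holdout: Sequence[ImagePair]) -> MetricReport:
    """Mean six-metric report of the model's fusions over a holdout set."""
    if not holdout:
        raise ConfigurationError("holdout must be non-empty")
    reports = [evaluate_all(p, fuse(model, p)) for p in holdout]
    return MetricReport(
        en=float(np.mean([r.en for r in reports])),
        sd=float(np.mean([r.sd for r in reports])),
        mg=float(np.mean([r.mg for r in reports])),
        sf=float(np.mean([r.sf for r in reports])),
        psnr=float(np.mean([r.psnr for r in reports])),
        qabf=float(np.mean([r.qabf for r in reports])),
    )
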