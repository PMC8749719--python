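"""Composite F + TV + SSIM adversarial loss for image fusion.

The generator loss has three parts:

    L_G = L_Ga + (1 - L_Gb) + L_Gc

* ``L_Ga`` — the non-saturating adversarial term ``E[ln(1 - D(G(v,i)))]``.
* ``L_Gb`` — a structural-similarity term rewarding the fused image for
  matching the visible (weight 1.0) and infrared (weight 0.7) sources:
  ``(1*SSIM(G,v) + 0.7*SSIM(G,i)) / 1.7``.  A variant that instead scores
  ``SSIM(G, (v + 0.7 i)/1.7)`` is available via ``blend=True``.
* ``L_Gc`` — an intensity/gradient content term
  ``0.5*||G - i||_F + 0.7*||G - v||_F + 0.7*||G - v||_TV``.

The discriminator keeps the original binary cross-entropy objective
``E[-ln D(v)] + E[-ln(1 - D(G(v,i)))]``.

Norm conventions (resolution independence): the Frobenius distance is
divided by sqrt(M*N) and the anisotropic L1 total variation by M*N, so the
content term does not swamp the logarithmic adversarial term at 128x128.
Logs are natural throughout.  Discriminator probabilities are clamped to
[1e-7, 1 - 1e-7] inside the loss so early-training scores of exactly 0 or 1
cannot produce infinities.

Every primitive has a differentiable tensor core (suffix ``_t``) used by
the training loop, and a float64 numpy wrapper forming the public API.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .exceptions import AlignmentError, DimensionError, DomainError
from .image_io import GrayImage, as_pixels

__all__ = [
    "LossWeights",
    "TermToggles",
    "GeneratorLossBreakdown",
    "ssim",
    "tv_norm",
    "frob_dist",
    "ssim_fusion_term",
    "content_term",
    "generator_loss",
    "discriminator_loss",
    "SSIM_WINDOW",
    "SCORE_EPS",
]

ImageLike = Union[GrayImage, np.ndarray]

SSIM_WINDOW = 11
SSIM_SIGMA = 1.5
SSIM_C1 = (0.01 * 1.0) ** 2  # dynamic range R = 1 on the unit pixel scale
SSIM_C2 = (0.03 * 1.0) ** 2
SCORE_EPS = 1e-7


@dataclass(frozen=True)
class LossWeights:
    """Coefficients of the composite generator loss.

    The SSIM term weights visible 1.0 and infrared 0.7 and renormalizes by
    their sum 1.7; the content term weights the infrared Frobenius distance
    0.5 and the visible Frobenius and TV distances 0.7 each.
    """

    ssim_vis: float = 1.0
    ssim_ir: float = 0.7
    ssim_scale: float = 1.7
    f_ir: float = 0.5
    f_vis: float = 0.7
    tv_vis: float = 0.7

    def __post_init__(self):
        vals = (self.ssim_vis, self.ssim_ir, self.ssim_scale, self.f_ir, self.f_vis, self.tv_vis)
        if any(v < 0 for v in vals):
            raise DomainError("loss weights must be non-negative")
        if abs(self.ssim_scale - (self.ssim_vis + self.ssim_ir)) > 1e-9:
            raise DomainError("ssim_scale must equal ssim_vis + ssim_ir")


@dataclass(frozen=True)
class TermToggles:
    """Loss-term ablation switches (all on reproduces the full objective)."""

    ssim: bool = True
    frobenius: bool = True
    tv: bool = True


@dataclass(frozen=True)
class GeneratorLossBreakdown:
    lga: float
    lgb: float
    lgc: float
    total: float


# ----------------------------------------------------------------------
def _gaussian_kernel(size: int = SSIM_WINDOW, sigma: float = SSIM_SIGMA) -> np.ndarray:
    r = np.arange(size, dtype=np.float64) - (size - 1) / 2.0
    g = np.exp(-(r**2) / (2.0 * sigma**2))
    k = np.outer(g, g)
    return k / k.sum()


_GAUSS = _gaussian_kernel()


def _as_batch(img: ImageLike, dtype=np.float64) -> Tensor:
    x = as_pixels(img).astype(dtype)
    return Tensor(x[None, None])


def _check_aligned(*imgs: ImageLike) -> None:
    shapes = {as_pixels(i).shape for i in imgs}
    if len(shapes) > 1:
        raise AlignmentError(f"images must share dimensions, got {sorted(shapes)}")


# tensor cores ---------------------------------------------------------
def ssim_t(x: Tensor, y: Tensor) -> Tensor:
    """Mean local SSIM over valid Gaussian 11x11 windows, batched NCHW."""
    dtype = x.data.dtype
    win = Tensor(_GAUSS.astype(dtype)[None, None])
    mu_x = ad.conv2d(x, win)
    mu_y = ad.conv2d(y, win)
    mu_x2, mu_y2, mu_xy = mu_x * mu_x, mu_y * mu_y, mu_x * mu_y
    var_x = ad.conv2d(x * x, win) - mu_x2
    var_y = ad.conv2d(y * y, win) - mu_y2
    cov = ad.conv2d(x * y, win) - mu_xy
    num = (2.0 * mu_xy + SSIM_C1) * (2.0 * cov + SSIM_C2)
    den = (mu_x2 + mu_y2 + SSIM_C1) * (var_x + var_y + SSIM_C2)
    return ad.tmean(num / den)


def tv_norm_t(x: Tensor) -> Tensor:
    """Anisotropic L1 total variation, averaged over pixels and batch."""
    B, C, M, N = x.shape
    dh = x[:, :, :, 1:] - x[:, :, :, :-1]
    dv = x[:, :, 1:, :] - x[:, :, :-1, :]
    total = ad.tsum(ad.absolute(dh)) + ad.tsum(ad.absolute(dv))
    return total * (1.0 / (B * C * M * N))


def frob_dist_t(x: Tensor, y: Tensor) -> Tensor:
    """Frobenius distance per image, normalized by sqrt(M*N), batch mean."""
    B, C, M, N = x.shape
    d = x - y
    ss = ad.tsum(d * d, axis=(1, 2, 3))
    return ad.tmean(ad.sqrt(ss * (1.0 / (M * N))))


def ssim_fusion_term_t(fused: Tensor, v: Tensor, i: Tensor, w: LossWeights, blend: bool = False) -> Tensor:
    if blend:
        target = (v * w.ssim_vis + i * w.ssim_ir) * (1.0 / w.ssim_scale)
        return ssim_t(fused, target)
    s = ssim_t(fused, v) * w.ssim_vis + ssim_t(fused, i) * w.ssim_ir
    return s * (1.0 / w.ssim_scale)


def content_term_t(fused: Tensor, v: Tensor, i: Tensor, w: LossWeights, toggles: TermToggles = TermToggles()) -> Tensor:
    terms = []
    if toggles.frobenius:
        terms.append(frob_dist_t(fused, i) * w.f_ir)
        terms.append(frob_dist_t(fused, v) * w.f_vis)
    if toggles.tv:
        terms.append(tv_norm_t(fused - v) * w.tv_vis)
    if not terms:
        return Tensor(np.asarray(0.0, dtype=fused.data.dtype))
    out = terms[0]
    for t in terms[1:]:
        out = out + t
    return out


def adversarial_g_term_t(scores: Tensor) -> Tensor:
    """Non-saturating generator term: mean ln(1 - D(G))."""
    s = ad.clip(scores, SCORE_EPS, 1.0 - SCORE_EPS)
    return ad.tmean(ad.log(1.0 - s))


def discriminator_loss_t(scores_real: Tensor, scores_fake: Tensor) -> Tensor:
    sr = ad.clip(scores_real, SCORE_EPS, 1.0 - SCORE_EPS)
    sf = ad.clip(scores_fake, SCORE_EPS, 1.0 - SCORE_EPS)
    return -ad.tmean(ad.log(sr)) - ad.tmean(ad.log(1.0 - sf))


def generator_loss_t(
    scores: Tensor,
    fused: Tensor,
    v: Tensor,
    i: Tensor,
    w: LossWeights,
    toggles: TermToggles = TermToggles(),
    blend: bool = False,
):
    """Full generator objective on tensors; returns (total, lga, lgb, lgc)."""
    lga = adversarial_g_term_t(scores)
    if toggles.ssim:
        lgb = ssim_fusion_term_t(fused, v, i, w, blend=blend)
        total = lga + (1.0 - lgb)
    else:
        lgb = Tensor(np.asarray(0.0, dtype=fused.data.dtype))
        total = lga
    lgc = content_term_t(fused, v, i, w, toggles)
    total = total + lgc
    return total, lga, lgb, lgc


# public numpy API -----------------------------------------------------
def ssim(x: ImageLike, y: ImageLike) -> float:
    """Structural similarity of two images (Gaussian 11x11, sigma 1.5)."""
    _check_aligned(x, y)
    xa = as_pixels(x)
    if min(xa.shape) < SSIM_WINDOW:
        raise DimensionError(
            f"ssim needs images of at least {SSIM_WINDOW}x{SSIM_WINDOW}, got {xa.shape}"
        )
    with ad.no_grad():
        return ssim_t(_as_batch(x), _as_batch(y)).item()


def tv_norm(x: ImageLike) -> float:
    """Mean anisotropic total variation of an image (or residual array)."""
    arr = np.asarray(x.pixels if isinstance(x, GrayImage) else x, dtype=np.float64)
    if arr.ndim != 2 or min(arr.shape) < 2:
        raise DimensionError(f"tv_norm needs a 2-D grid of at least 2x2, got {arr.shape}")
    with ad.no_grad():
        return tv_norm_t(Tensor(arr[None, None])).item()


def frob_dist(x: ImageLike, y: ImageLike) -> float:
    """sqrt-sum-of-squares distance divided by sqrt(M*N)."""
    _check_aligned(x, y)
    with ad.no_grad():
        return frob_dist_t(_as_batch(x), _as_batch(y)).item()


def ssim_fusion_term(fused: ImageLike, v: ImageLike, i: ImageLike, w: LossWeights = LossWeights(), blend: bool = False) -> float:
    """L_Gb: renormalized weighted SSIM of the fused image against both sources."""
    _check_aligned(fused, v, i)
    with ad.no_grad():
        return ssim_fusion_term_t(_as_batch(fused), _as_batch(v), _as_batch(i), w, blend=blend).item()


def content_term(fused: ImageLike, v: ImageLike, i: ImageLike, w: LossWeights = LossWeights()) -> float:
    """L_Gc: weighted Frobenius distances to both sources plus visible-residual TV."""
    _check_aligned(fused, v, i)
    with ad.no_grad():
        return content_term_t(_as_batch(fused), _as_batch(v), _as_batch(i), w).item()


def _as_image_batch(imgs) -> list:
    if isinstance(imgs, (GrayImage, np.ndarray)):
        return [imgs]
    return list(imgs)


def _validate_scores(scores: np.ndarray) -> np.ndarray:
    scores = np.atleast_1d(np.asarray(scores, dtype=np.float64))
    if np.any(scores <= 0.0) or np.any(scores >= 1.0):
        raise DomainError("discriminator scores must lie strictly inside (0, 1)")
    return np.clip(scores, SCORE_EPS, 1.0 - SCORE_EPS)


def generator_loss(
    d_scores_on_fused,
    fused,
    v,
    i,
    w: LossWeights = LossWeights(),
    blend: bool = False,
) -> GeneratorLossBreakdown:
    """Generator objective L_G = L_Ga + (1 - L_Gb) + L_Gc over a batch.

    ``fused``/``v``/``i`` may be single images or equal-length sequences;
    ``d_scores_on_fused`` is one probability per fused image.
    """
    scores = _validate_scores(d_scores_on_fused)
    fs, vs, is_ = _as_image_batch(fused), _as_image_batch(v), _as_image_batch(i)
    if not (len(fs) == len(vs) == len(is_)):
        raise AlignmentError("fused/visible/infrared batches must have equal length")
    lga = float(np.mean(np.log(1.0 - scores)))
    lgb = float(np.mean([ssim_fusion_term(f, vv, ii, w, blend=blend) for f, vv, ii in zip(fs, vs, is_)]))
    lgc = float(np.mean([content_term(f, vv, ii, w) for f, vv, ii in zip(fs, vs, is_)]))
    total = lga + (1.0 - lgb) + lgc
    return GeneratorLossBreakdown(lga=lga, lgb=lgb, lgc=lgc, total=total)


def discriminator_loss(scores_real, scores_fake) -> float:
    """L_D = E[-ln D(v)] + E[-ln(1 - D(G(v,i)))]."""
    sr = _validate_scores(scores_real)
    sf = _validate_scores(scores_fake)
    return float(np.mean(-np.log(sr)) + np.mean(-np.log(1.0 - sf)))
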