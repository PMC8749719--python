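"""Reference-free and reference-based fusion-quality metrics.

Six scores evaluate a fused image: entropy (EN), standard deviation (SD),
mean gradient (MG), spatial frequency (SF), peak signal-to-noise ratio
(PSNR) against a reference, and the windowed fusion-quality index QABF.

All metrics operate on the internal [0, 1] pixel scale.  Entropy alone
re-quantizes to L = 256 uniform bins, the gray-level resolution of the
8-bit source data; with that convention EN is bounded by log2(256) = 8
bits.  QABF is built from the universal image quality index Q0 evaluated
over all 8x8 windows at stride 1, weighted per window by the local-variance
saliency ratio of the two source images.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Union

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .exceptions import AlignmentError, ConfigurationError
from .image_io import GrayImage, ImagePair, as_pixels

__all__ = [
    "MetricReport",
    "entropy",
    "std_dev",
    "mean_gradient",
    "spatial_frequency",
    "psnr",
    "q0_window",
    "qabf",
    "evaluate_all",
]

ImageLike = Union[GrayImage, np.ndarray]

GRAY_LEVELS = 256
QABF_WINDOW = 8


@dataclass(frozen=True)
class MetricReport:
    """The six quality scores for one fusion result.

    en is in bits; sd, mg and sf are in intensity units on the [0, 1]
    scale; psnr is in dB (``inf`` when the images are identical); qabf is
    unitless in [-1, 1].
    """

    en: float
    sd: float
    mg: float
    sf: float
    psnr: float
    qabf: float

    def as_dict(self) -> dict:
        return {
            "en": self.en,
            "sd": self.sd,
            "mg": self.mg,
            "sf": self.sf,
            "psnr": self.psnr,
            "qabf": self.qabf,
        }


def entropy(img: ImageLike) -> float:
    """Shannon entropy (bits) of the 256-bin gray-level histogram."""
    x = as_pixels(img)
    hist, _ = np.histogram(x, bins=GRAY_LEVELS, range=(0.0, 1.0))
    p = hist / hist.sum()
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def std_dev(img: ImageLike) -> float:
    """Population standard deviation of pixel intensity (1/(MN) norm)."""
    x = as_pixels(img)
    return float(np.sqrt(np.mean((x - x.mean()) ** 2)))


def mean_gradient(img: ImageLike) -> float:
    """Mean magnitude of the backward-difference gradient (texture proxy)."""
    x = as_pixels(img)
    dv = x[1:, 1:] - x[:-1, 1:]
    dh = x[1:, 1:] - x[1:, :-1]
    return float(np.mean(np.sqrt((dv**2 + dh**2) / 2.0)))


def spatial_frequency(img: ImageLike) -> float:
    """Root of squared row and column frequencies (gray-level change rate)."""
    x = as_pixels(img)
    m, n = x.shape
    rf2 = np.sum((x[:, 1:] - x[:, :-1]) ** 2) / (m * n)
    cf2 = np.sum((x[1:, :] - x[:-1, :]) ** 2) / (m * n)
    return float(np.sqrt(rf2 + cf2))


def psnr(reference: ImageLike, test: ImageLike) -> float:
    """Peak signal-to-noise ratio in dB, with MAX = 1 on the unit scale."""
    a, b = as_pixels(reference), as_pixels(test)
    if a.shape != b.shape:
        raise AlignmentError(f"psnr shape mismatch: {a.shape} vs {b.shape}")
    mse = float(np.mean((a - b) ** 2))
    if mse == 0.0:
        return math.inf
    return float(10.0 * np.log10(1.0 / mse))


def _q0_from_moments(mu_a, mu_f, va, vf, cov):
    """Universal image quality index from window moments, elementwise.

    Degenerate windows follow a fixed convention: if both windows are
    constant, Q0 is 1 when the means are equal and nonzero and 0 otherwise;
    if only the variance term vanishes the product form's natural zero
    applies (the covariance is then zero as well).
    """
    mu_a, mu_f = np.asarray(mu_a), np.asarray(mu_f)
    va, vf, cov = np.asarray(va), np.asarray(vf), np.asarray(cov)
    den = (va + vf) * (mu_a**2 + mu_f**2)
    both_const = (va == 0.0) & (vf == 0.0)
    const_val = np.where((mu_a == mu_f) & (mu_a != 0.0), 1.0, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.where(den > 0.0, 4.0 * cov * mu_a * mu_f / np.where(den > 0.0, den, 1.0), 0.0)
    return np.where(both_const, const_val, q)


def q0_window(a: ImageLike, f: ImageLike) -> float:
    """Universal image quality index of ``f`` against ``a`` over one window."""
    x, y = as_pixels(a), as_pixels(f)
    if x.shape != y.shape:
        raise AlignmentError(f"q0 shape mismatch: {x.shape} vs {y.shape}")
    mu_a, mu_f = x.mean(), y.mean()
    va, vf = np.mean((x - mu_a) ** 2), np.mean((y - mu_f) ** 2)
    cov = np.mean((x - mu_a) * (y - mu_f))
    return float(_q0_from_moments(mu_a, mu_f, va, vf, cov))


def _window_moments(x: np.ndarray, w: int):
    # two-pass moments: constant windows give an exact zero variance
    win = sliding_window_view(x, (w, w))
    mu = win.mean(axis=(-2, -1))
    dev = win - mu[..., None, None]
    return dev, mu, (dev * dev).mean(axis=(-2, -1))


def qabf(a: ImageLike, b: ImageLike, f: ImageLike, window: int = QABF_WINDOW) -> float:
    """Windowed fusion quality index Q(a, b, f).

    Averages, over all ``window x window`` sliding windows at stride 1, the
    saliency-weighted combination ``lam*Q0(a,f) + (1-lam)*Q0(b,f)`` where
    the weight ``lam`` is the local-variance share of source ``a`` (0.5 when
    both windows are flat).
    """
    xa, xb, xf = as_pixels(a), as_pixels(b), as_pixels(f)
    if not (xa.shape == xb.shape == xf.shape):
        raise AlignmentError("qabf requires three images of identical shape")
    m, n = xa.shape
    if m < window or n < window:
        raise ConfigurationError(
            f"image {xa.shape} smaller than the {window}x{window} window"
        )
    da, mu_a, va = _window_moments(xa, window)
    db, mu_b, vb = _window_moments(xb, window)
    df, mu_f, vf = _window_moments(xf, window)
    cov_af = (da * df).mean(axis=(-2, -1))
    cov_bf = (db * df).mean(axis=(-2, -1))
    q_af = _q0_from_moments(mu_a, mu_f, va, vf, cov_af)
    q_bf = _q0_from_moments(mu_b, mu_f, vb, vf, cov_bf)
    s = va + vb
    with np.errstate(divide="ignore", invalid="ignore"):
        lam = np.where(s > 0.0, va / np.where(s > 0.0, s, 1.0), 0.5)
    return float(np.mean(lam * q_af + (1.0 - lam) * q_bf))


def evaluate_all(pair: ImagePair, fused: ImageLike, psnr_reference: str = "visible") -> MetricReport:
    """Score one fusion result with all six metrics.

    EN/SD/MG/SF are computed on the fused image; PSNR against the visible
    image by default (``psnr_reference`` may be set to ``"infrared"``);
    QABF against both sources.
    """
    xf = as_pixels(fused)
    if xf.shape != pair.shape:
        raise AlignmentError(
            f"fused image {xf.shape} does not match pair {pair.shape}"
        )
    if psnr_reference not in ("visible", "infrared"):
        raise ConfigurationError(f"unknown psnr_reference {psnr_reference!r}")
    ref = pair.visible if psnr_reference == "visible" else pair.infrared
    return MetricReport(
        en=entropy(xf),
        sd=std_dev(xf),
        mg=mean_gradient(xf),
        sf=spatial_frequency(xf),
        psnr=psnr(ref, xf),
        qabf=qabf(pair.visible, pair.infrared, xf),
    )
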