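"""Seeded paired visible/infrared face phantoms.

The generator emulates the statistical structure of an aligned
visible/thermal face dataset in which identity information is split across
the two modalities:

* **geometry** (face ellipse axes, eye and mouth placement) is rendered in
  both channels;
* **fine texture** (a subject-specific oriented sinusoidal skin pattern and
  hard-edged eye/mouth features) appears only in the visible channel, which
  therefore has the higher spatial frequency;
* **thermal layout** (a subject-specific arrangement of smooth Gaussian
  hotspots) appears only in the infrared channel, whose structure is smooth
  with a distinct intensity histogram.

Each subject contributes ``n_poses`` images (12 by default, partitionable
into 6 folds of 2).  A pose is a small seeded rigid jitter — rotation up to
2.5 degrees and translation up to 1.5 pixels — applied identically to both
channels so pairs stay pixel-aligned.  Nuisance variation mimics what
limits each modality in practice: the visible channel varies in global
illumination (a 0.65-1.0 per-pose brightness factor) on top of mild pixel
noise (sigma 0.02); the noisier thermal channel gets stronger pixel noise
(sigma 0.05), a per-pose gain/offset drift (ambient and body temperature
change between captures), and a physiological drift of the hotspot pattern
itself.  Everything derives deterministically from the dataset seed, and
no single channel carries the whole identity signal, which is what lets a
fused image outperform either modality alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Tuple

import numpy as np

from .exceptions import ConfigurationError, GenerationError
from .image_io import GrayImage, ImagePair

__all__ = ["SubjectSpec", "SyntheticDataset", "generate_pair", "generate_dataset"]

MAX_ROTATION_DEG = 2.5
MAX_TRANSLATION_PX = 1.5
PIXEL_NOISE_SIGMA = 0.02
IR_NOISE_SIGMA = 0.05
IR_GAIN_JITTER = 0.15
IR_OFFSET_JITTER = 0.04
VIS_ILLUMINATION_RANGE = (0.65, 1.0)
HOTSPOT_DRIFT = 0.15
HOTSPOT_PEAK_DRIFT = 0.2
IR_BODY_AXES = (0.68, 0.84)
N_HOTSPOTS = 4
HOTSPOT_X_RANGE = (-0.45, 0.45)
HOTSPOT_Y_RANGE = (-0.55, 0.55)
HOTSPOT_WIDTH_RANGE = (0.14, 0.32)
HOTSPOT_PEAK_RANGE = (0.45, 0.95)


@dataclass(frozen=True)
class SubjectSpec:
    """Identity parameters of one synthetic subject.

    Geometry is expressed in normalized face coordinates (the frame spans
    [-1, 1] on each axis); hotspot peak intensities lie in [0, 1].
    """

    subject_id: int
    face_axes: Tuple[float, float]
    eye_offset: Tuple[float, float]
    eye_radius: float
    mouth_offset: float
    mouth_halfwidth: float
    skin_level: float
    texture_freq: float
    texture_angle: float
    texture_phase: float
    texture_contrast: float
    hotspot_centers: Tuple[Tuple[float, float], ...]
    hotspot_widths: Tuple[float, ...]
    hotspot_peaks: Tuple[float, ...]
    seed: int

    def __post_init__(self):
        ax, ay = self.face_axes
        if not (0.0 < ax < 1.0 and 0.0 < ay < 1.0):
            raise GenerationError(f"subject {self.subject_id}: face ellipse {self.face_axes} leaves the frame")
        if any(not (0.0 <= p <= 1.0) for p in self.hotspot_peaks):
            raise GenerationError(f"subject {self.subject_id}: hotspot peaks must lie in [0, 1]")

    @classmethod
    def from_seed(cls, subject_id: int, seed: int) -> "SubjectSpec":
        rng = np.random.default_rng(seed)
        centers = tuple(
            (float(rng.uniform(*HOTSPOT_X_RANGE)), float(rng.uniform(*HOTSPOT_Y_RANGE)))
            for _ in range(N_HOTSPOTS)
        )
        return cls(
            subject_id=subject_id,
            face_axes=(float(rng.uniform(0.55, 0.75)), float(rng.uniform(0.72, 0.9))),
            eye_offset=(float(rng.uniform(0.24, 0.36)), float(rng.uniform(-0.42, -0.26))),
            eye_radius=float(rng.uniform(0.07, 0.12)),
            mouth_offset=float(rng.uniform(0.3, 0.46)),
            mouth_halfwidth=float(rng.uniform(0.18, 0.34)),
            skin_level=float(rng.uniform(0.45, 0.68)),
            texture_freq=float(rng.uniform(2.5, 5.5)),
            texture_angle=float(rng.uniform(0.0, math.pi)),
            texture_phase=float(rng.uniform(0.0, 2.0 * math.pi)),
            texture_contrast=float(rng.uniform(0.14, 0.26)),
            hotspot_centers=centers,
            hotspot_widths=tuple(float(rng.uniform(*HOTSPOT_WIDTH_RANGE)) for _ in range(N_HOTSPOTS)),
            hotspot_peaks=tuple(float(rng.uniform(*HOTSPOT_PEAK_RANGE)) for _ in range(N_HOTSPOTS)),
            seed=int(seed),
        )


@dataclass(frozen=True)
class SyntheticDataset:
    """All pairs of a generated gallery: (pair, subject_id, pose_index)."""

    pairs: List[Tuple[ImagePair, int, int]]
    n_subjects: int
    n_poses: int
    image_size: Tuple[int, int]

    def __post_init__(self):
        if len(self.pairs) != self.n_subjects * self.n_poses:
            raise ConfigurationError("dataset must contain n_subjects * n_poses pairs")

    def image_pairs(self) -> List[ImagePair]:
        return [p for p, _, _ in self.pairs]

    def labels(self) -> np.ndarray:
        return np.array([s for _, s, _ in self.pairs], dtype=int)

    def pose_indices(self) -> np.ndarray:
        return np.array([q for _, _, q in self.pairs], dtype=int)


def _pose_grid(size: Tuple[int, int], rot_deg: float, shift_px: Tuple[float, float]):
    """Normalized face coordinates after the inverse pose transform."""
    m, n = size
    yy, xx = np.mgrid[0:m, 0:n].astype(np.float64)
    u = (xx - (n - 1) / 2.0 - shift_px[0]) / (n / 2.0)
    v = (yy - (m - 1) / 2.0 - shift_px[1]) / (m / 2.0)
    th = math.radians(rot_deg)
    c, s = math.cos(th), math.sin(th)
    return c * u + s * v, -s * u + c * v


def _render_visible(spec: SubjectSpec, u: np.ndarray, v: np.ndarray) -> np.ndarray:
    ax, ay = spec.face_axes
    face = (u / ax) ** 2 + (v / ay) ** 2 <= 1.0  # hard edge: high SF / MG
    ca, sa = math.cos(spec.texture_angle), math.sin(spec.texture_angle)
    phase = 2.0 * math.pi * spec.texture_freq * (ca * u + sa * v) + spec.texture_phase
    skin = spec.skin_level + spec.texture_contrast * np.sin(phase)
    img = np.full(u.shape, 0.15)
    img[face] = skin[face]
    ex, ey = spec.eye_offset
    for sx in (-1.0, 1.0):
        eye = (u - sx * ex) ** 2 + (v - ey) ** 2 <= spec.eye_radius**2
        img[eye] = 0.08
    mouth = (np.abs(u) <= spec.mouth_halfwidth) & (np.abs(v - spec.mouth_offset) <= 0.045)
    img[mouth & face] = 0.12
    return img


def _render_infrared(
    spec: SubjectSpec,
    u: np.ndarray,
    v: np.ndarray,
    gain: float = 1.0,
    offset: float = 0.0,
    center_jitter=None,
    peak_jitter=None,
) -> np.ndarray:
    """Smooth thermal channel.

    ``gain``/``offset`` model global per-pose thermal drift;
    ``center_jitter``/``peak_jitter`` model physiological drift of the
    hotspot pattern between captures.
    """
    # thermal silhouettes are blurry and generic: the warm body uses shared
    # axes, so the infrared identity lives in the hotspot layout, not geometry
    ax, ay = IR_BODY_AXES
    r2 = (u / ax) ** 2 + (v / ay) ** 2
    body = 1.0 / (1.0 + np.exp((r2 - 1.0) / 0.08))
    warmth = 0.35 * body
    if center_jitter is None:
        center_jitter = np.zeros((len(spec.hotspot_centers), 2))
    if peak_jitter is None:
        peak_jitter = np.zeros(len(spec.hotspot_centers))
    for k, ((cx, cy), w, p) in enumerate(
        zip(spec.hotspot_centers, spec.hotspot_widths, spec.hotspot_peaks)
    ):
        d2 = (u - cx - center_jitter[k, 0]) ** 2 + (v - cy - center_jitter[k, 1]) ** 2
        pk = np.clip(p + peak_jitter[k], 0.0, 1.0)
        warmth = warmth + 0.4 * pk * np.exp(-d2 / (2.0 * w**2)) * body
    img = 0.10 + 0.05 * (v + 1.0) / 2.0 + gain * warmth + offset
    return np.clip(img, 0.0, 1.0)


def generate_pair(spec: SubjectSpec, pose_index: int, size: Tuple[int, int] = (128, 128)) -> ImagePair:
    """Render one aligned visible/infrared pair for a subject and pose.

    The same rigid jitter transforms both channels; the noise streams are
    independent per channel but fully determined by (spec.seed, pose).
    """
    if pose_index < 1:
        raise ConfigurationError("pose_index must be >= 1")
    m, n = size
    if m < 32 or n < 32:
        raise ConfigurationError(f"size must be at least 32x32, got {size}")
    pose_rng = np.random.default_rng(np.random.SeedSequence((spec.seed, pose_index, 0)))
    rot = float(pose_rng.uniform(-MAX_ROTATION_DEG, MAX_ROTATION_DEG))
    shift = (
        float(pose_rng.uniform(-MAX_TRANSLATION_PX, MAX_TRANSLATION_PX)),
        float(pose_rng.uniform(-MAX_TRANSLATION_PX, MAX_TRANSLATION_PX)),
    )
    gain = float(pose_rng.uniform(1.0 - IR_GAIN_JITTER, 1.0 + IR_GAIN_JITTER))
    offset = float(pose_rng.uniform(-IR_OFFSET_JITTER, IR_OFFSET_JITTER))
    illumination = float(pose_rng.uniform(*VIS_ILLUMINATION_RANGE))
    n_spots = len(spec.hotspot_centers)
    center_jitter = pose_rng.uniform(-HOTSPOT_DRIFT, HOTSPOT_DRIFT, size=(n_spots, 2))
    peak_jitter = pose_rng.uniform(-HOTSPOT_PEAK_DRIFT, HOTSPOT_PEAK_DRIFT, size=n_spots)
    u, v = _pose_grid(size, rot, shift)
    vis = illumination * _render_visible(spec, u, v)
    ir = _render_infrared(
        spec, u, v, gain=gain, offset=offset, center_jitter=center_jitter, peak_jitter=peak_jitter
    )
    noise_rng = np.random.default_rng(np.random.SeedSequence((spec.seed, pose_index, 1)))
    vis = np.clip(vis + noise_rng.normal(0.0, PIXEL_NOISE_SIGMA, size), 0.0, 1.0)
    ir = np.clip(ir + noise_rng.normal(0.0, IR_NOISE_SIGMA, size), 0.0, 1.0)
    pair_id = f"s{spec.subject_id:03d}_p{pose_index:02d}"
    return ImagePair(visible=GrayImage(vis), infrared=GrayImage(ir), pair_id=pair_id)


def generate_dataset(
    n_subjects: int = 40,
    n_poses: int = 12,
    size: Tuple[int, int] = (128, 128),
    seed: int = 0,
) -> SyntheticDataset:
    """Generate a labeled gallery of ``n_subjects * n_poses`` aligned pairs.

    ``n_poses`` must be even so each subject's poses can be partitioned
    into folds of two images.
    """
    if n_subjects < 2:
        raise ConfigurationError("need at least 2 subjects")
    if n_poses < 2 or n_poses % 2 != 0:
        raise ConfigurationError("n_poses must be an even integer >= 2 (folds of 2)")
    pairs = []
    for sid in range(n_subjects):
        subject_seed = int(np.random.SeedSequence((seed, sid)).generate_state(1)[0] % (2**31))
        spec = SubjectSpec.from_seed(sid, subject_seed)
        for pose in range(1, n_poses + 1):
            pairs.append((generate_pair(spec, pose, size), sid, pose))
    return SyntheticDataset(pairs=pairs, n_subjects=n_subjects, n_poses=n_poses, image_size=size)
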