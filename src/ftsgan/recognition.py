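"""PCA-LDA nearest-neighbor face recognition with k-fold cross-validation.

The verification pipeline is the classical eigenface/fisherface cascade:
images are flattened, PCA reduces dimensionality (removing the small-sample
singularity that would make the within-class scatter non-invertible), LDA
finds at most C-1 discriminant directions maximizing the between/within
scatter ratio, and a probe is assigned the label of its Euclidean nearest
neighbor among the projected training images.

Each subject's poses are split pose-index-ordered into k folds (k = 6 with
two images per subject per fold for a 12-pose gallery).  ``run_cv`` trains
on k-1 folds and tests on the held-out fold; ``summarize`` averages the
retained folds for two modalities and reports the fused-minus-visible
accuracy delta (averages rounded to two decimals, the delta to one).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Union

import numpy as np
import scipy.linalg
from sklearn.decomposition import PCA

from .exceptions import ConfigurationError, FTSGANError, ReportError
from .image_io import GrayImage, as_pixels

__all__ = [
    "FaceGallery",
    "FoldPlan",
    "RecognitionResult",
    "PCAProjector",
    "LDAProjector",
    "pca_project",
    "lda_project",
    "classify_nn",
    "make_fold_plan",
    "run_cv",
    "summarize",
]

DEFAULT_K = 6
DEFAULT_VARIANCE_KEPT = 0.95


@dataclass(frozen=True)
class FaceGallery:
    """Labeled image set: one image per (subject, pose), single modality."""

    images: List[GrayImage]
    labels: np.ndarray
    pose_indices: np.ndarray
    modality: str = "visible"

    def __post_init__(self):
        labels = np.asarray(self.labels, dtype=int)
        poses = np.asarray(self.pose_indices, dtype=int)
        if not (len(self.images) == labels.size == poses.size):
            raise ConfigurationError("images, labels and pose indices must have equal counts")
        uniq, counts = np.unique(labels, return_counts=True)
        if uniq.size < 2:
            raise ConfigurationError("gallery needs at least 2 subjects")
        if np.unique(counts).size != 1:
            raise ConfigurationError("every subject must contribute the same number of images")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "pose_indices", poses)

    @property
    def images_per_subject(self) -> int:
        return int(np.sum(self.labels == self.labels[0]))

    @property
    def n_subjects(self) -> int:
        return int(np.unique(self.labels).size)

    def matrix(self) -> np.ndarray:
        return np.stack([as_pixels(im).ravel() for im in self.images])


@dataclass(frozen=True)
class FoldPlan:
    """Assignment of every gallery image to one of k folds (1-based)."""

    k: int
    assignment: np.ndarray
    images_per_fold_per_subject: int
    excluded_folds: Set[int] = field(default_factory=set)

    def fold_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == fold)


@dataclass(frozen=True)
class RecognitionResult:
    """Per-fold accuracies (percent) and the retained-fold average."""

    per_fold_accuracy: List[float]
    retained_average: float
    modality: str
    excluded_folds: Set[int] = field(default_factory=set)


@dataclass(frozen=True)
class PCAProjector:
    mean: np.ndarray
    components: np.ndarray  # rows are principal axes
    explained_variance: np.ndarray

    def project(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X) - self.mean) @ self.components.T


@dataclass(frozen=True)
class LDAProjector:
    scalings: np.ndarray  # columns are discriminant directions

    def project(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X) @ self.scalings


# operations -----------------------------------------------------------
def pca_project(train_matrix: np.ndarray, n_components: int):
    """Fit a mean-centered eigenbasis of the sample covariance.

    Returns ``(basis, projector)`` with components ordered by decreasing
    eigenvalue; the basis rows are the principal axes.
    """
    X = np.asarray(train_matrix, dtype=np.float64)
    limit = min(X.shape[0] - 1, X.shape[1])
    if not (1 <= n_components <= limit):
        raise ConfigurationError(
            f"n_components must be in [1, {limit}] for a {X.shape} matrix, got {n_components}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(X)
    projector = PCAProjector(
        mean=pca.mean_,
        components=pca.components_,
        explained_variance=pca.explained_variance_,
    )
    return pca.components_, projector


def lda_project(reduced_matrix: np.ndarray, labels) -> LDAProjector:
    """Fisher discriminant directions in a PCA-reduced space.

    Solves the generalized symmetric eigenproblem ``S_b w = lambda S_w w``
    and keeps the top ``C - 1`` directions.  A singular within-class
    scatter raises with advice to reduce the PCA dimension further.
    """
    X = np.asarray(reduced_matrix, dtype=np.float64)
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size < 2:
        raise ConfigurationError("LDA needs at least 2 classes")
    d = X.shape[1]
    overall_mean = X.mean(axis=0)
    s_w = np.zeros((d, d))
    s_b = np.zeros((d, d))
    for c in classes:
        Xc = X[y == c]
        mu_c = Xc.mean(axis=0)
        dev = Xc - mu_c
        s_w += dev.T @ dev
        diff = (mu_c - overall_mean)[:, None]
        s_b += Xc.shape[0] * (diff @ diff.T)
    try:
        eigvals, eigvecs = scipy.linalg.eigh(s_b, s_w)
    except scipy.linalg.LinAlgError as exc:
        raise FTSGANError(
            "within-class scatter is singular; reduce the PCA dimension "
            "(n_components must not exceed n_train - n_classes)"
        ) from exc
    order = np.argsort(eigvals)[::-1][: classes.size - 1]
    return LDAProjector(scalings=eigvecs[:, order])


def classify_nn(gallery_features: np.ndarray, gallery_labels, probe_feature: np.ndarray):
    """Label of the minimum-Euclidean-distance gallery feature.

    Exact distance ties resolve to the lowest gallery index.
    """
    G = np.asarray(gallery_features, dtype=np.float64)
    y = np.asarray(gallery_labels)
    if G.shape[0] == 0:
        raise ConfigurationError("gallery must be non-empty")
    p = np.asarray(probe_feature, dtype=np.float64).ravel()
    if p.size != G.shape[1]:
        raise ConfigurationError(f"probe has {p.size} features, gallery has {G.shape[1]}")
    d2 = np.sum((G - p) ** 2, axis=1)
    return y[int(np.argmin(d2))]


def make_fold_plan(gallery: FaceGallery, k: int = DEFAULT_K, seed: Optional[int] = None) -> FoldPlan:
    """Split each subject's poses into k folds, pose-index-ordered.

    The plan is deterministic (the optional seed is accepted for interface
    symmetry but the ordering is fixed by pose index, which is what the
    2-images-per-fold convention of a 12-pose gallery prescribes).
    """
    per = gallery.images_per_subject
    if per % k != 0:
        raise ConfigurationError(
            f"{per} poses per subject are not divisible into {k} folds"
        )
    m = per // k
    if m < 2:
        raise ConfigurationError(
            f"{per} poses over {k} folds leaves {m} image per subject per fold; need at least 2"
        )
    assignment = np.zeros(len(gallery.images), dtype=int)
    for subject in np.unique(gallery.labels):
        idx = np.flatnonzero(gallery.labels == subject)
        idx = idx[np.argsort(gallery.pose_indices[idx], kind="stable")]
        for rank, i in enumerate(idx):
            assignment[i] = rank // m + 1
    return FoldPlan(k=k, assignment=assignment, images_per_fold_per_subject=m)


def _pca_dim(train: np.ndarray, n_classes: int, variance_kept: float) -> int:
    cap = min(train.shape[0] - n_classes, train.shape[0] - 1, train.shape[1])
    probe = PCA(n_components=min(train.shape[0] - 1, train.shape[1]), svd_solver="full")
    probe.fit(train)
    cum = np.cumsum(probe.explained_variance_ratio_)
    wanted = int(np.searchsorted(cum, variance_kept) + 1)
    return max(1, min(wanted, cap))


def run_cv(
    gallery: FaceGallery,
    plan: FoldPlan,
    pca_components: Optional[int] = None,
    variance_kept: float = DEFAULT_VARIANCE_KEPT,
) -> RecognitionResult:
    """k-fold cross-validated PCA-LDA-NN accuracy, percent per fold.

    For each fold the pipeline is fit on the other k-1 folds only.  The
    default PCA dimension keeps ``variance_kept`` of the training variance,
    capped at ``n_train - n_classes`` so the within-class scatter stays
    invertible for LDA.
    """
    X = gallery.matrix()
    y = gallery.labels
    accuracies = []
    for fold in range(1, plan.k + 1):
        test_idx = plan.fold_indices(fold)
        train_idx = np.flatnonzero(plan.assignment != fold)
        Xtr, ytr = X[train_idx], y[train_idx]
        n_classes = np.unique(ytr).size
        dim = pca_components if pca_components is not None else _pca_dim(Xtr, n_classes, variance_kept)
        dim = max(1, min(dim, Xtr.shape[0] - n_classes, Xtr.shape[0] - 1, Xtr.shape[1]))
        _, pca = pca_project(Xtr, dim)
        Ztr = pca.project(Xtr)
        lda = lda_project(Ztr, ytr)
        Ftr = lda.project(Ztr)
        Fte = lda.project(pca.project(X[test_idx]))
        pred = np.array([classify_nn(Ftr, ytr, f) for f in Fte])
        accuracies.append(100.0 * float(np.mean(pred == y[test_idx])))
    retained = [a for f, a in enumerate(accuracies, start=1) if f not in plan.excluded_folds]
    return RecognitionResult(
        per_fold_accuracy=accuracies,
        retained_average=float(np.mean(retained)),
        modality=gallery.modality,
        excluded_folds=set(plan.excluded_folds),
    )


def summarize(
    results_fused: Union[RecognitionResult, Sequence[float]],
    results_visible: Union[RecognitionResult, Sequence[float]],
    excluded_folds: Iterable[int] = (),
) -> Dict[str, float]:
    """Retained-fold averages for both modalities and their delta.

    Accepts ``RecognitionResult`` objects or raw per-fold percentage lists
    (so printed table columns can be fed directly).  Averages are rounded
    to two decimals, the fused-minus-visible delta to one.
    """

    def folds(r) -> List[float]:
        return list(r.per_fold_accuracy) if isinstance(r, RecognitionResult) else list(r)

    fused, visible = folds(results_fused), folds(results_visible)
    if len(fused) != len(visible):
        raise ReportError(f"fold-structure mismatch: {len(fused)} vs {len(visible)} folds")
    excluded = set(int(f) for f in excluded_folds)
    retained = [f for f in range(1, len(fused) + 1) if f not in excluded]
    if not retained:
        raise ReportError("cannot exclude every fold")
    fused_avg = float(np.mean([fused[f - 1] for f in retained]))
    visible_avg = float(np.mean([visible[f - 1] for f in retained]))
    return {
        "fused_average": round(fused_avg, 2),
        "visible_average": round(visible_avg, 2),
        "delta": round(fused_avg - visible_avg, 1),
        "n_retained_folds": len(retained),
    }
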