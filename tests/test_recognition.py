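import numpy as np
import pytest

from ftsgan import recognition as rec
from ftsgan.exceptions import ConfigurationError, FTSGANError, ReportError
from ftsgan.image_io import GrayImage

TABLE_GLASSES_FUSED = [72.92, 93.75, 97.92, 95.83, 100.0, 95.83]
TABLE_GLASSES_VISIBLE = [66.67, 91.67, 95.83, 93.75, 100.0, 93.75]
TABLE_NOGLASSES_FUSED = [60.42, 85.42, 97.92, 93.75, 100.0, 87.5]
TABLE_NOGLASSES_VISIBLE = [56.25, 83.33, 95.26, 91.67, 100.0, 85.42]
TABLE_ALL_FUSED = [68.75, 88.21, 97.92, 94.72, 100.0, 91.32]
TABLE_ALL_VISIBLE = [64.58, 85.42, 95.41, 92.43, 100.0, 89.21]


def gaussian_classes(rng, n_classes=3, n_per_class=40, dim=20, sep=3.0, sigma=0.05):
    """Vector classes with means ``sep`` standard deviations apart, packed
    into small images so they can ride the image-gallery pipeline."""
    means = np.zeros((n_classes, dim))
    for c in range(n_classes):
        means[c, c] = sep * sigma
    X, y = [], []
    for c in range(n_classes):
        X.append(means[c] + rng.normal(0, sigma, (n_per_class, dim)))
        y += [c] * n_per_class
    X = np.clip(np.vstack(X) + 0.5, 0, 1)
    return X, np.array(y)


def vector_gallery(X, y, modality="visible"):
    images = [GrayImage(row.reshape(4, 5)) for row in X]
    seen: dict = {}
    poses = np.empty(len(y), dtype=int)
    for k, label in enumerate(y):
        seen[label] = seen.get(label, 0) + 1
        poses[k] = seen[label]
    return rec.FaceGallery(images=images, labels=y, pose_indices=poses, modality=modality)


class TestPCA:
    def test_line_data_explained_by_first_component(self, rng):
        t = rng.uniform(-1, 1, 30)
        X = np.outer(t, np.array([1.0, 2.0, -1.0])) + 5.0
        basis, proj = rec.pca_project(X, 1)
        assert proj.explained_variance[0] > 0
        recon = proj.project(X) @ basis + proj.mean
        assert recon == pytest.approx(X, abs=1e-10)

    def test_projection_is_idempotent(self, rng):
        X = rng.normal(size=(12, 10))
        _, proj = rec.pca_project(X, 4)
        Z = proj.project(X)
        back = Z @ proj.components + proj.mean
        assert proj.project(back) == pytest.approx(Z, abs=1e-10)

    def test_eigenvalues_match_dense_eigendecomposition(self, rng):
        X = rng.normal(size=(10, 12))
        _, proj = rec.pca_project(X, 6)
        cov = np.cov(X, rowvar=False)
        eigs = np.sort(np.linalg.eigvalsh(cov))[::-1][:6]
        assert proj.explained_variance == pytest.approx(eigs, abs=1e-10)

    def test_component_budget_enforced(self, rng):
        X = rng.normal(size=(8, 10))
        with pytest.raises(ConfigurationError):
            rec.pca_project(X, 8)  # max is n_samples - 1 = 7


class TestLDA:
    def test_two_class_direction_matches_closed_form(self, rng):
        n = 60
        X0 = rng.normal(0, 0.3, (n, 2)) + np.array([0.0, 0.0])
        X1 = rng.normal(0, 0.3, (n, 2)) + np.array([2.0, 1.0])
        X = np.vstack([X0, X1])
        y = np.array([0] * n + [1] * n)
        proj = rec.lda_project(X, y)
        w = proj.scalings[:, 0]
        # closed form: S_w^{-1} (mu1 - mu0)
        mu0, mu1 = X0.mean(axis=0), X1.mean(axis=0)
        sw = (X0 - mu0).T @ (X0 - mu0) + (X1 - mu1).T @ (X1 - mu1)
        ref = np.linalg.solve(sw, mu1 - mu0)
        cos = abs(w @ ref) / (np.linalg.norm(w) * np.linalg.norm(ref))
        assert cos == pytest.approx(1.0, abs=1e-10)

    def test_at_most_c_minus_one_directions(self, rng):
        X = rng.normal(size=(40, 6))
        y = np.repeat([0, 1, 2, 3], 10)
        assert rec.lda_project(X, y).scalings.shape == (6, 3)

    def test_sample_order_leaves_span_unchanged(self, rng):
        X = rng.normal(size=(30, 4))
        y = np.repeat([0, 1, 2], 10)
        perm = rng.permutation(30)
        W1 = rec.lda_project(X, y).scalings
        W2 = rec.lda_project(X[perm], y[perm]).scalings
        # compare column spans via projection operators
        P1 = W1 @ np.linalg.pinv(W1)
        P2 = W2 @ np.linalg.pinv(W2)
        assert P1 == pytest.approx(P2, abs=1e-8)

    def test_singular_within_scatter_is_diagnosed(self):
        X = np.zeros((6, 4))  # zero within-class scatter
        X[3:, 0] = 1.0
        y = np.array([0, 0, 0, 1, 1, 1])
        with pytest.raises(FTSGANError, match="PCA"):
            rec.lda_project(X, y)


class TestNearestNeighbor:
    def test_exact_gallery_match_wins(self, rng):
        G = rng.normal(size=(10, 3))
        y = np.arange(10)
        assert rec.classify_nn(G, y, G[4]) == 4

    def test_tie_breaks_to_lowest_index(self):
        G = np.array([[1.0, 0.0], [-1.0, 0.0]])
        assert rec.classify_nn(G, np.array([7, 3]), np.array([0.0, 0.0])) == 7

    def test_matches_exhaustive_distance_oracle(self, rng):
        G = rng.normal(size=(25, 6))
        y = rng.integers(0, 5, 25)
        for probe in rng.normal(size=(20, 6)):
            dists = [np.sqrt(np.sum((g - probe) ** 2)) for g in G]
            assert rec.classify_nn(G, y, probe) == y[int(np.argmin(dists))]


class TestFoldPlan:
    def test_paper_layout_fold_sizes(self):
        from ftsgan.synthetic_faces import generate_dataset

        ds = generate_dataset(5, 12, (32, 32), seed=1)
        g = rec.FaceGallery(
            images=[p.visible for p in ds.image_pairs()],
            labels=ds.labels(),
            pose_indices=ds.pose_indices(),
        )
        plan = rec.make_fold_plan(g, k=6)
        for fold in range(1, 7):
            idx = plan.fold_indices(fold)
            assert idx.size == 5 * 2  # two poses per subject per fold
            labels, counts = np.unique(g.labels[idx], return_counts=True)
            assert labels.size == 5 and (counts == 2).all()

    def test_single_image_per_fold_rejected(self, rng):
        imgs = [GrayImage(rng.uniform(0, 1, (4, 4))) for _ in range(12)]
        g = rec.FaceGallery(
            images=imgs,
            labels=np.repeat([0, 1], 6),
            pose_indices=np.tile(np.arange(1, 7), 2),
        )
        with pytest.raises(ConfigurationError):
            rec.make_fold_plan(g, k=6)

    def test_plan_is_deterministic(self, rng):
        imgs = [GrayImage(rng.uniform(0, 1, (4, 4))) for _ in range(24)]
        g = rec.FaceGallery(
            images=imgs,
            labels=np.repeat([0, 1], 12),
            pose_indices=np.tile(np.arange(1, 13), 2),
        )
        a = rec.make_fold_plan(g, k=6, seed=1)
        b = rec.make_fold_plan(g, k=6, seed=1)
        assert np.array_equal(a.assignment, b.assignment)


class TestRunCV:
    def test_near_duplicate_poses_give_perfect_accuracy(self, rng):
        """With (near-)zero pose variation the training set contains
        near-duplicates of every probe; accuracy must be 100% on every
        fold.  (Exactly duplicated poses are rejected: they make the
        within-class scatter singular, see the LDA diagnostics test.)"""
        protos = rng.uniform(0.2, 0.8, (3, 20))
        X = np.repeat(protos, 8, axis=0) + rng.normal(0, 1e-4, (24, 20))
        y = np.repeat([0, 1, 2], 8)
        gallery = vector_gallery(np.clip(X, 0, 1), y)
        plan = rec.make_fold_plan(gallery, k=4)
        result = rec.run_cv(gallery, plan, pca_components=2)
        assert result.per_fold_accuracy == [100.0] * 4

    def test_gaussian_class_recovery(self, rng):
        X, y = gaussian_classes(rng)
        gallery = vector_gallery(X, y)
        plan = rec.make_fold_plan(gallery, k=5)
        result = rec.run_cv(gallery, plan)
        assert result.retained_average >= 95.0

    def test_intensity_scaling_invariance(self, rng):
        X, y = gaussian_classes(rng)
        g1 = vector_gallery(X, y)
        g2 = vector_gallery(0.5 * X, y)
        plan = rec.make_fold_plan(g1, k=5)
        r1 = rec.run_cv(g1, plan, pca_components=5)
        r2 = rec.run_cv(g2, plan, pca_components=5)
        assert r1.per_fold_accuracy == pytest.approx(r2.per_fold_accuracy)


class TestSummarize:
    def test_glasses_table_average(self):
        report = rec.summarize(TABLE_GLASSES_FUSED, TABLE_GLASSES_VISIBLE, excluded_folds={1})
        assert report["fused_average"] == 96.67
        assert report["visible_average"] == 95.0
        assert report["delta"] == 1.7

    def test_no_glasses_table_average(self):
        report = rec.summarize(TABLE_NOGLASSES_FUSED, TABLE_NOGLASSES_VISIBLE, excluded_folds={1})
        assert report["fused_average"] == 92.92
        assert report["visible_average"] == 91.14
        assert report["delta"] == 1.8

    def test_all_images_table_average(self):
        report = rec.summarize(TABLE_ALL_FUSED, TABLE_ALL_VISIBLE, excluded_folds={1})
        assert report["fused_average"] == 94.43
        assert report["visible_average"] == 92.49
        assert report["delta"] == 1.9
        assert round(report["fused_average"], 1) == 94.4  # headline recognition rate

    def test_exclude_everything_rejected(self):
        with pytest.raises(ReportError):
            rec.summarize([90.0] * 6, [80.0] * 6, excluded_folds=set(range(1, 7)))

    def test_fold_mismatch_rejected(self):
        with pytest.raises(ReportError):
            rec.summarize([90.0] * 6, [80.0] * 5)


class TestPermutationNull:
    def test_label_permutation_drops_to_chance(self, rng):
        X, y = gaussian_classes(rng)
        accs = []
        for _ in range(20):
            yp = rng.permutation(y)
            try:
                gallery = vector_gallery(X, yp)
            except ConfigurationError:
                continue  # permutation broke the equal-count invariant? cannot happen: counts preserved
            plan = rec.make_fold_plan(gallery, k=5)
            accs.append(rec.run_cv(gallery, plan, pca_components=5).retained_average)
        chance = 100.0 / 3.0
        assert abs(np.mean(accs) - chance) < 8.0
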