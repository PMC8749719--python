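import math

import numpy as np
import pytest
from skimage.metrics import structural_similarity

from ftsgan import losses as L
from ftsgan.exceptions import AlignmentError, DomainError
from ftsgan.image_io import GrayImage

import oracles


class TestSSIM:
    def test_identity(self, rng):
        x = rng.uniform(0, 1, (16, 16))
        assert L.ssim(x, x) == pytest.approx(1.0, abs=1e-9)

    def test_symmetry(self, rng):
        x, y = rng.uniform(0, 1, (14, 14)), rng.uniform(0, 1, (14, 14))
        assert L.ssim(x, y) == pytest.approx(L.ssim(y, x), abs=1e-12)

    @pytest.mark.parametrize("trial", range(4))
    def test_matches_window_loop_oracle(self, trial):
        rng = np.random.default_rng(400 + trial)
        x, y = rng.uniform(0, 1, (13, 13)), rng.uniform(0, 1, (13, 13))
        assert L.ssim(x, y) == pytest.approx(oracles.ssim(x, y), abs=1e-8)

    def test_inverted_image_oracle_value(self, rng):
        x = rng.uniform(0.2, 0.8, (14, 14))
        x = x - x.mean() + 0.5  # mean exactly 0.5 so 1-x has the same mean
        y = 1.0 - x
        assert L.ssim(x, y) == pytest.approx(oracles.ssim(x, y), abs=1e-8)
        assert L.ssim(x, y) < 0.0  # structure fully anti-correlated

    def test_matches_skimage_reference(self, rng):
        """Independent library cross-check of the Gaussian-window SSIM."""
        x = rng.uniform(0, 1, (32, 32))
        y = np.clip(x + rng.normal(0, 0.1, x.shape), 0, 1)
        ref = structural_similarity(
            x, y, win_size=11, gaussian_weights=True, sigma=1.5,
            use_sample_covariance=False, data_range=1.0,
        )
        assert L.ssim(x, y) == pytest.approx(ref, abs=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(AlignmentError):
            L.ssim(rng.uniform(0, 1, (12, 12)), rng.uniform(0, 1, (12, 13)))


class TestTVAndFrobenius:
    def test_constant_tv_is_zero(self):
        assert L.tv_norm(np.full((5, 5), 0.7)) == 0.0

    def test_two_column_hand_count(self):
        x = np.array([[0.0, 1.0], [0.0, 1.0]])
        assert L.tv_norm(x) == pytest.approx(0.5, abs=1e-12)  # sum 2 over MN=4

    def test_tv_positive_homogeneity(self, rng):
        x = rng.uniform(0, 1, (6, 6))
        for c in (0.0, 0.3, 1.0):
            assert L.tv_norm(c * x) == pytest.approx(c * L.tv_norm(x), abs=1e-12)

    def test_frob_identity_and_hand_value(self):
        x = np.zeros((2, 2))
        y = np.array([[0.3, 0.4], [0.0, 0.0]])
        assert L.frob_dist(x, x) == 0.0
        assert L.frob_dist(x, y) == pytest.approx(0.25, abs=1e-12)  # 3-4-5 / sqrt(4)

    def test_frob_triangle_inequality(self, rng):
        x, y, z = (rng.uniform(0, 1, (7, 7)) for _ in range(3))
        assert L.frob_dist(x, z) <= L.frob_dist(x, y) + L.frob_dist(y, z) + 1e-12

    @pytest.mark.parametrize("trial", range(5))
    def test_match_loop_oracles(self, trial):
        rng = np.random.default_rng(500 + trial)
        shape = (int(rng.integers(2, 9)), int(rng.integers(2, 9)))
        x, y = rng.uniform(0, 1, shape), rng.uniform(0, 1, shape)
        assert L.tv_norm(x) == pytest.approx(oracles.tv_norm(x), abs=1e-8)
        assert L.frob_dist(x, y) == pytest.approx(oracles.frob_dist(x, y), abs=1e-8)


class TestCompositeTerms:
    def test_ssim_term_identity_case(self, rng):
        x = rng.uniform(0, 1, (16, 16))
        assert L.ssim_fusion_term(x, x, x) == pytest.approx(1.0, abs=1e-9)

    def test_ssim_term_composes_primitive_values(self, rng):
        f = rng.uniform(0, 1, (14, 14))
        v = np.clip(f + rng.normal(0, 0.02, f.shape), 0, 1)  # structurally close
        i = rng.uniform(0, 1, (14, 14))  # uncorrelated
        expected = (oracles.ssim(f, v) + 0.7 * oracles.ssim(f, i)) / 1.7
        assert L.ssim_fusion_term(f, v, i) == pytest.approx(expected, abs=1e-8)

    def test_degenerate_weights_reduce_to_single_ssim(self, rng):
        f, v, i = (rng.uniform(0, 1, (14, 14)) for _ in range(3))
        w = L.LossWeights(ssim_vis=1.0, ssim_ir=0.0, ssim_scale=1.0)
        assert L.ssim_fusion_term(f, v, i, w) == pytest.approx(L.ssim(f, v), abs=1e-12)

    def test_blend_variant_identity_case(self, rng):
        x = rng.uniform(0, 1, (16, 16))
        assert L.ssim_fusion_term(x, x, x, blend=True) == pytest.approx(1.0, abs=1e-9)

    def test_content_term_vanishes_at_identity(self, rng):
        x = rng.uniform(0, 1, (8, 8))
        assert L.content_term(x, x, x) == pytest.approx(0.0, abs=1e-12)

    def test_content_term_fused_equals_visible(self, rng):
        v, i = rng.uniform(0, 1, (8, 8)), rng.uniform(0, 1, (8, 8))
        assert L.content_term(v, v, i) == pytest.approx(0.5 * L.frob_dist(v, i), abs=1e-12)

    def test_content_term_composes_primitives(self, rng):
        f, v, i = (rng.uniform(0, 1, (8, 8)) for _ in range(3))
        expected = (
            0.5 * oracles.frob_dist(f, i)
            + 0.7 * oracles.frob_dist(f, v)
            + 0.7 * oracles.tv_norm(f - v)
        )
        assert L.content_term(f, v, i) == pytest.approx(expected, abs=1e-8)

    def test_invalid_weights_rejected(self):
        with pytest.raises(DomainError):
            L.LossWeights(ssim_vis=-1.0)
        with pytest.raises(DomainError):
            L.LossWeights(ssim_scale=2.0)


class TestAdversarialLosses:
    def test_identity_triple_with_balanced_score(self, rng):
        x = GrayImage(rng.uniform(0, 1, (16, 16)))
        br = L.generator_loss([0.5], x, x, x)
        assert br.lga == pytest.approx(math.log(0.5), abs=1e-12)
        assert br.lgb == pytest.approx(1.0, abs=1e-9)
        assert br.lgc == pytest.approx(0.0, abs=1e-10)
        assert br.total == pytest.approx(math.log(0.5), abs=1e-8)

    def test_total_is_definitional_sum(self, rng):
        f, v, i = (rng.uniform(0, 1, (16, 16)) for _ in range(3))
        br = L.generator_loss([0.3, 0.6], [f, f], [v, v], [i, i])
        assert br.total == pytest.approx(br.lga + (1.0 - br.lgb) + br.lgc, abs=1e-12)

    def test_adversarial_term_monotone_in_score(self, rng):
        x = rng.uniform(0, 1, (16, 16))
        totals = [L.generator_loss([s], x, x, x).lga for s in (0.1, 0.5, 0.9)]
        assert totals[0] > totals[1] > totals[2]

    def test_score_domain_enforced(self, rng):
        x = rng.uniform(0, 1, (16, 16))
        for bad in (0.0, 1.0, -0.2, 1.3):
            with pytest.raises(DomainError):
                L.generator_loss([bad], x, x, x)
        with pytest.raises(DomainError):
            L.discriminator_loss([1.0], [0.5])

    def test_discriminator_balanced_scores(self):
        assert L.discriminator_loss([0.5], [0.5]) == pytest.approx(2.0 * math.log(2.0), abs=1e-12)

    def test_discriminator_near_perfect(self):
        val = L.discriminator_loss([0.999], [0.001])
        assert val == pytest.approx(-2.0 * math.log(0.999), abs=1e-9)
        assert val == pytest.approx(0.002001, abs=1e-6)

    def test_discriminator_loss_nonnegative(self, rng):
        sr, sf = rng.uniform(0.01, 0.99, 5), rng.uniform(0.01, 0.99, 5)
        assert L.discriminator_loss(sr, sf) >= 0.0

    def test_structured_mix_beats_noise_candidates(self):
        """The composite objective prefers structural mixes of the two
        sources over pure noise, for any fixed discriminator score."""
        rng = np.random.default_rng(42)
        from ftsgan.synthetic_faces import SubjectSpec, generate_pair

        spec = SubjectSpec.from_seed(0, 99)
        pair = generate_pair(spec, 1, (32, 32))
        v, i = pair.visible.pixels, pair.infrared.pixels
        candidates = {
            "visible": v,
            "infrared": i,
            "mix": (v + 0.7 * i) / 1.7,
            "noise": rng.uniform(0, 1, v.shape),
        }
        totals = {k: L.generator_loss([0.5], c, v, i).total for k, c in candidates.items()}
        # the visible-weighted objective may prefer v itself or the blend,
        # but never pure noise
        assert min(totals, key=totals.get) in ("visible", "mix")
        assert totals["noise"] == max(totals.values())
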