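import numpy as np
import pytest

from boxseg3d import (
    VolumeImage,
    CRFParams,
    GaussianKernel,
    unary_from_box,
    kernel_weight,
    convcrf_infer,
    dense_crf_bruteforce,
    generate_pseudo_mask,
    box_from_mask,
    box_to_mask,
)


def _small_params(**kw):
    defaults = dict(
        kernels=[
            GaussianKernel(w=1.0, theta_spatial=2.0, theta_intensity=0.2),
            GaussianKernel(w=0.5, theta_spatial=1.0),
        ],
        D=2,
        n_iters=3,
    )
    defaults.update(kw)
    return CRFParams(**defaults)


def _random_instance(rng, shape=(5, 5, 4)):
    image = VolumeImage(rng.random(shape))
    fg = rng.uniform(0.05, 0.95, size=shape)
    unary = np.stack([1.0 - fg, fg])
    from boxseg3d.crf import LabelMarginals

    return image, LabelMarginals(unary)


class TestUnary:
    def test_uniform_box(self):
        params = _small_params(fg_prior_inside=0.7)
        m = unary_from_box(np.ones((3, 3, 3)), params)
        np.testing.assert_allclose(m.probs[1], 0.7)
        np.testing.assert_allclose(m.probs[0], 0.3)

    def test_hard_background_outside(self):
        params = _small_params(bg_clamp_eps=0.0)
        m = unary_from_box(np.zeros((3, 3, 3)), params)
        np.testing.assert_array_equal(m.probs[1], 0.0)

    def test_two_level_partition(self):
        params = _small_params()
        box = np.zeros((4, 4, 4))
        box[1:3, 1:3, 1:3] = 1
        m = unary_from_box(box, params)
        assert set(np.round(np.unique(m.probs[1]), 12)) == {
            params.bg_clamp_eps,
            params.fg_prior_inside,
        }
        assert np.all((m.probs[1] == params.fg_prior_inside) == (box > 0))


class TestKernelWeight:
    def test_identical_features(self):
        assert kernel_weight([1.0, 2.0], [1.0, 2.0], theta=1.0, D=3) == 1.0

    def test_truncation_by_position(self):
        v = kernel_weight([0.5], [0.5], theta=1.0, D=2, pos_i=[0, 0, 0], pos_j=[2, 1, 0])
        assert v == 0.0

    def test_gaussian_value(self):
        theta = 0.4
        v = kernel_weight([0.0], [theta * np.sqrt(2)], theta=theta, D=10)
        assert v == pytest.approx(np.exp(-1), rel=1e-12)

    def test_feature_length_mismatch(self):
        with pytest.raises(ValueError):
            kernel_weight([1.0], [1.0, 2.0], theta=1.0, D=2)


class TestMeanField:
    def test_unary_only_limit_is_identity_on_probs(self, rng):
        """With all kernel weights zero the output equals the unary marginals."""
        image, unary = _random_instance(rng)
        params = _small_params(
            kernels=[GaussianKernel(w=0.0, theta_spatial=1.0, theta_intensity=0.2)]
        )
        out = convcrf_infer(image, unary, params)
        np.testing.assert_allclose(out.probs, unary.probs, atol=1e-12)
        out_bf = dense_crf_bruteforce(image, unary, params)
        np.testing.assert_allclose(out_bf.probs, unary.probs, atol=1e-12)

    def test_symmetric_unary_on_constant_image_stays_symmetric(self):
        shape = (4, 4, 3)
        image = VolumeImage(np.full(shape, 0.5))
        from boxseg3d.crf import LabelMarginals

        unary = LabelMarginals(np.full((2,) + shape, 0.5))
        out = convcrf_infer(image, unary, _small_params())
        np.testing.assert_allclose(out.probs, 0.5, atol=1e-12)

    def test_single_voxel_no_pairs(self, rng):
        image, unary = _random_instance(rng, shape=(1, 1, 1))
        params = _small_params()
        out = dense_crf_bruteforce(image, unary, params)
        np.testing.assert_allclose(out.probs, unary.probs, atol=1e-12)
        out_c = convcrf_infer(image, unary, params)
        np.testing.assert_allclose(out_c.probs, unary.probs, atol=1e-12)

    def test_marginals_normalized_each_call(self, rng):
        image, unary = _random_instance(rng)
        out = convcrf_infer(image, unary, _small_params(n_iters=7))
        np.testing.assert_allclose(out.probs.sum(axis=0), 1.0, atol=1e-9)

    @pytest.mark.parametrize("normalize", [True, False])
    def test_oracle_equivalence_randomized(self, rng, normalize):
        """Windowed message passing equals the all-pairs oracle (<=500 voxels)."""
        for i in range(20):
            shape = tuple(rng.integers(2, 6, size=3))
            image, unary = _random_instance(rng, shape=shape)
            params = _small_params(
                D=int(rng.integers(1, 4)), n_iters=int(rng.integers(1, 4)), normalize=normalize
            )
            conv = convcrf_infer(image, unary, params)
            brute = dense_crf_bruteforce(image, unary, params)
            np.testing.assert_allclose(conv.probs, brute.probs, atol=1e-6)

    def test_oracle_equivalence_truncation_inactive(self, rng):
        """D beyond the image diameter: window covers every pair, still equal."""
        image, unary = _random_instance(rng, shape=(6, 6, 1))
        params = _small_params(D=12, n_iters=2)
        conv = convcrf_infer(image, unary, params)
        brute = dense_crf_bruteforce(image, unary, params)
        np.testing.assert_allclose(conv.probs, brute.probs, atol=1e-6)

    def test_truncation_saturates_beyond_diameter(self, rng):
        image, unary = _random_instance(rng, shape=(4, 4, 2))
        a = convcrf_infer(image, unary, _small_params(D=10, n_iters=2))
        b = convcrf_infer(image, unary, _small_params(D=20, n_iters=2))
        np.testing.assert_allclose(a.probs, b.probs, atol=1e-12)

    def test_bruteforce_guard(self, rng):
        image, unary = _random_instance(rng, shape=(10, 10, 10))
        with pytest.raises(ValueError):
            dense_crf_bruteforce(image, unary, _small_params())

    def test_shape_mismatch(self, rng):
        image, _ = _random_instance(rng, shape=(4, 4, 4))
        _, unary = _random_instance(rng, shape=(3, 4, 4))
        with pytest.raises(ValueError):
            convcrf_infer(image, unary, _small_params())


class TestPseudoMask:
    def test_tumor_filling_tight_box_keeps_box(self):
        """Noiseless cube tumor exactly filling its d=0 box: no evidence to shrink."""
        shape = (16, 16, 16)
        image = np.full(shape, 0.2)
        gt = np.zeros(shape, dtype=np.uint8)
        gt[5:11, 5:11, 5:11] = 1
        image[gt > 0] = 0.8
        box = box_from_mask(gt, margin_d=0)
        pm = generate_pseudo_mask(VolumeImage(image), box, CRFParams(D=4))
        assert np.array_equal(pm, gt)

    def test_hard_clamp_stays_inside_box(self, rng):
        shape = (14, 14, 14)
        image = rng.random(shape)
        gt = np.zeros(shape, dtype=np.uint8)
        gt[4:9, 4:9, 4:9] = 1
        box = box_from_mask(gt, margin_d=3)
        params = CRFParams(D=4, bg_clamp_eps=0.0)
        pm = generate_pseudo_mask(VolumeImage(image), box, params)
        box_mask = box_to_mask(box, shape)
        assert not np.any(pm & ~box_mask)

    def test_unnormalized_image_rejected(self, rng):
        image = VolumeImage(rng.uniform(-100, 100, size=(8, 8, 8)))
        gt = np.zeros((8, 8, 8), dtype=np.uint8)
        gt[2:5, 2:5, 2:5] = 1
        with pytest.raises(ValueError):
            generate_pseudo_mask(image, box_from_mask(gt, 0), CRFParams())
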