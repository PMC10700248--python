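import numpy as np
import pytest

from ovaseg.inference import (InferenceConfig, gaussian_window, sliding_window_predict,
                              tta_transforms, window_positions)


class TestWindowPositions:
    def test_exact_fit_single_window(self):
        assert window_positions((8, 8, 8), (8, 8, 8), 0.5) == [(0, 0, 0)]

    def test_axis10_window4_step_half(self):
        starts = sorted({p[0] for p in window_positions((10, 4, 4), (4, 4, 4), 0.5)})
        assert starts == [0, 2, 4, 6]

    def test_last_window_flush(self):
        for L in (10, 13, 17):
            zs = sorted({p[0] for p in window_positions((L, 4, 4), (4, 4, 4), 0.5)})
            assert zs[-1] == L - 4

    def test_full_coverage_random_instances(self, rng):
        for _ in range(25):
            shape = tuple(int(x) for x in rng.integers(4, 20, 3))
            window = tuple(int(rng.integers(2, s + 1)) for s in shape)
            frac = float(rng.uniform(0.2, 1.0))
            covered = np.zeros(shape, dtype=bool)
            for pos in window_positions(shape, window, frac):
                sl = tuple(slice(p, p + w) for p, w in zip(pos, window))
                covered[sl] = True
            assert covered.all()

    def test_sorted_lexicographically(self):
        pos = window_positions((8, 8, 8), (4, 4, 4), 0.5)
        assert pos == sorted(pos)


class TestGaussianWindow:
    def test_flip_symmetry(self):
        w = gaussian_window((5, 6, 7), 0.125)
        for ax in range(3):
            assert np.allclose(w, np.flip(w, axis=ax), atol=1e-12)

    def test_centre_and_corner_closed_form(self):
        size, scale = (9, 9, 9), 0.125
        w = gaussian_window(size, scale)
        assert w.max() == pytest.approx(1.0)
        assert w[4, 4, 4] == 1.0  # odd window: centre voxel carries the max
        sigma = scale * 9
        d = (9 - 1) / 2.0
        expect_corner = np.exp(-3 * d ** 2 / (2 * sigma ** 2))
        assert w[0, 0, 0] == pytest.approx(expect_corner, rel=1e-9)

    def test_even_window_matches_closed_form_after_normalisation(self):
        size, scale = (8, 6, 4), 0.2
        w = gaussian_window(size, scale)
        assert w.max() == pytest.approx(1.0)
        def g(idx):
            val = 1.0
            for i, n in zip(idx, size):
                d = i - (n - 1) / 2.0
                val *= np.exp(-d ** 2 / (2 * (scale * n) ** 2))
            return val
        peak = g((4, 3, 2))
        for idx in [(0, 0, 0), (3, 2, 1), (7, 5, 3), (4, 0, 2)]:
            assert w[idx] == pytest.approx(g(idx) / peak, rel=1e-9)

    def test_strictly_positive(self):
        assert (gaussian_window((16, 16, 16), 0.125) > 0).all()

    def test_large_sigma_limit_is_flat(self):
        w = gaussian_window((6, 6, 6), 1e6)
        assert np.allclose(w, 1.0, atol=1e-6)


class TestTTA:
    def test_count_is_eight(self):
        assert len(tta_transforms()) == 8

    def test_first_is_identity(self, rng):
        f, inv = tta_transforms()[0]
        x = rng.standard_normal((3, 4, 5))
        assert np.array_equal(f(x), x)

    def test_inverse_composed_with_forward_is_identity(self, rng):
        x = rng.standard_normal((3, 4, 5))
        for f, inv in tta_transforms():
            assert np.array_equal(inv(f(x)), x)

    def test_pairwise_distinct_on_asymmetric_probe(self):
        probe = np.arange(2 * 3 * 4, dtype=float).reshape(2, 3, 4)
        images = [f(probe).tobytes() for f, _ in tta_transforms()]
        assert len(set(images)) == 8


class _ConstantClass1Net:
    """Emits overwhelming class-1 scores everywhere."""
    n_classes = 3

    def patch_divisor(self):
        return (1, 1, 1)

    def __call__(self, x):
        s = np.zeros((*x.shape[:-1], 3), dtype=np.float32)
        s[..., 1] = 50.0
        return s


class _VoxelwiseNet:
    """Scores are a voxelwise function of the input: exactly flip-equivariant."""
    n_classes = 3

    def patch_divisor(self):
        return (1, 1, 1)

    def __call__(self, x):
        v = x[..., 0]
        return np.stack([-v, v, v ** 2], axis=-1)


class TestSlidingWindowPredict:
    def test_constant_network_gives_constant_labels(self, rng):
        img = rng.standard_normal((7, 9, 11)).astype(np.float32)
        cfg = InferenceConfig(window_size=(4, 4, 4), tta=True)
        prob = sliding_window_predict(img, [_ConstantClass1Net()], cfg)
        assert (prob.argmax(-1) == 1).all()
        assert np.allclose(prob.sum(-1), 1.0, atol=1e-5)

    def test_flip_equivariant_network_collapses_tta(self, rng):
        img = rng.standard_normal((8, 10, 12)).astype(np.float32)
        on = InferenceConfig(window_size=(4, 6, 6), tta=True)
        off = InferenceConfig(window_size=(4, 6, 6), tta=False)
        p_on = sliding_window_predict(img, [_VoxelwiseNet()], on)
        p_off = sliding_window_predict(img, [_VoxelwiseNet()], off)
        assert np.max(np.abs(p_on - p_off)) < 1e-6

    def test_two_identical_members_equal_single(self, rng):
        img = rng.standard_normal((6, 6, 6)).astype(np.float32)
        cfg = InferenceConfig(window_size=(4, 4, 4), tta=True)
        one = sliding_window_predict(img, [_VoxelwiseNet()], cfg)
        two = sliding_window_predict(img, [_VoxelwiseNet(), _VoxelwiseNet()], cfg)
        assert np.allclose(one, two, atol=1e-7)

    def test_volume_smaller_than_window_padded_and_unpadded(self, rng):
        img = rng.standard_normal((3, 3, 3)).astype(np.float32)
        cfg = InferenceConfig(window_size=(8, 8, 8), tta=False)
        prob = sliding_window_predict(img, [_VoxelwiseNet()], cfg)
        assert prob.shape == (3, 3, 3, 3)

    def test_determinism(self, rng):
        img = rng.standard_normal((6, 8, 8)).astype(np.float32)
        cfg = InferenceConfig(window_size=(4, 4, 4), tta=True)
        a = sliding_window_predict(img, [_VoxelwiseNet()], cfg)
        b = sliding_window_predict(img, [_VoxelwiseNet()], cfg)
        assert np.array_equal(a, b)


def test_predict_volume_end_to_end(small_phantom):
    from ovaseg.preprocessing import PreprocessPlan
    from ovaseg.inference import predict_volume
    plan = PreprocessPlan(target_spacing=(5.0, 1.4, 1.4))
    cfg = InferenceConfig(window_size=(8, 8, 8), tta=False)
    grid, labels = predict_volume(small_phantom.volume, [_ConstantClass1Net()], cfg, plan)
    assert labels.shape == small_phantom.volume.shape
    assert (labels.labels == 1).all()
    assert grid.provenance["n_members"] == 1
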