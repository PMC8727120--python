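import numpy as np
import pytest

from fmrifuse.pcanet import (
    FilterBank,
    PCANet3D,
    PCANetParams,
    block_histograms,
    convolve3d,
    extract_patches,
    heaviside_encode,
    learn_filters,
    pool_relu,
    stage_forward,
)


def oracle_convolve3d(data, kernel):
    """O(n * k^3) zero-padded triple-loop cross-correlation."""
    k = kernel.shape[0]
    r = (k - 1) // 2
    padded = np.pad(data, r, mode="constant")
    out = np.zeros_like(data, dtype=float)
    for x in range(data.shape[0]):
        for y in range(data.shape[1]):
            for z in range(data.shape[2]):
                out[x, y, z] = np.sum(padded[x : x + k, y : y + k, z : z + k] * kernel)
    return out


def oracle_pool_relu(data, pool, stride):
    shape = [(d - pool) // stride + 1 for d in data.shape]
    out = np.zeros(shape)
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                window = data[
                    x * stride : x * stride + pool,
                    y * stride : y * stride + pool,
                    z * stride : z * stride + pool,
                ]
                out[x, y, z] = max(window.max(), 0.0)
    return out


def oracle_encode(stage2_outputs):
    shape = stage2_outputs[0].shape
    out = np.zeros(shape, dtype=int)
    for idx in np.ndindex(shape):
        value = 0
        for h, omega in enumerate(stage2_outputs, start=1):
            if omega[idx] > 0:
                value += 2 ** (h - 1)
        out[idx] = value
    return out


def oracle_block_histograms(encoded, edge, stride, beta, n_bins):
    blocks = []
    for x0 in range(0, encoded.shape[0] - edge + 1, stride):
        for y0 in range(0, encoded.shape[1] - edge + 1, stride):
            for z0 in range(0, encoded.shape[2] - edge + 1, stride):
                blocks.append(encoded[x0 : x0 + edge, y0 : y0 + edge, z0 : z0 + edge])
    hists = []
    for block in blocks[:beta]:
        counts = np.zeros(n_bins)
        for v in block.ravel():
            counts[v] += 1
        hists.append(counts)
    return np.concatenate(hists)


class TestExtractPatches:
    def test_patch_count_and_length(self, rng):
        cols = extract_patches(rng.random((4, 4, 4)), k=2, stride=2)
        assert cols.shape == (8, 8)

    def test_constant_volume_gives_zero_columns(self):
        cols = extract_patches(np.full((5, 5, 5), 7.0), k=3)
        np.testing.assert_array_equal(cols, 0.0)

    def test_columns_match_window_enumeration_oracle(self, rng):
        data = rng.random((5, 5, 5))
        cols = extract_patches(data, k=3, stride=1)
        assert cols.shape == (27, 27)
        expected = []
        for x in range(3):
            for y in range(3):
                for z in range(3):
                    patch = data[x : x + 3, y : y + 3, z : z + 3].ravel()
                    expected.append(patch - patch.mean())
        np.testing.assert_allclose(cols, np.array(expected).T, atol=1e-12)

    def test_columns_are_mean_removed(self, rng):
        cols = extract_patches(rng.random((6, 6, 6)), k=3)
        np.testing.assert_allclose(cols.mean(axis=0), 0.0, atol=1e-12)

    def test_too_large_k_rejected(self, rng):
        with pytest.raises(ValueError):
            extract_patches(rng.random((4, 4, 4)), k=5)


class TestLearnFilters:
    def test_full_rank_bank_is_orthonormal(self, rng):
        patches = extract_patches(rng.random((6, 6, 6)), k=3)
        bank = learn_filters(patches, c=27, k=3)
        flat = bank.kernels.reshape(27, -1)
        np.testing.assert_allclose(flat @ flat.T, np.eye(27), atol=1e-10)

    def test_eigenvalues_non_increasing(self, rng):
        patches = extract_patches(rng.random((6, 6, 6)), k=3)
        bank = learn_filters(patches, c=8, k=3)
        assert np.all(np.diff(bank.eigenvalues) <= 1e-9)

    def test_planted_subspace_recovered(self, rng):
        d1 = rng.standard_normal(27)
        d2 = rng.standard_normal(27)
        for d in (d1, d2):
            d -= d.mean()
        coeffs = rng.standard_normal((2, 3000))
        patches = np.outer(d1, coeffs[0]) + np.outer(d2, coeffs[1])
        patches += 0.01 * rng.standard_normal(patches.shape)
        patches -= patches.mean(axis=0, keepdims=True)
        bank = learn_filters(patches, c=2, k=3)
        planted = np.linalg.qr(np.column_stack([d1, d2]))[0]
        learned = bank.kernels.reshape(2, -1).T
        # principal angles between the two 2D subspaces
        s = np.linalg.svd(planted.T @ np.linalg.qr(learned)[0], compute_uv=False)
        angles_deg = np.degrees(np.arccos(np.clip(s, -1, 1)))
        assert np.all(angles_deg < 5.0)

    def test_too_many_filters_rejected(self, rng):
        patches = extract_patches(rng.random((4, 4, 4)), k=3)
        with pytest.raises(ValueError):
            learn_filters(patches, c=28, k=3)


class TestConvolve3d:
    def test_delta_kernel_is_identity(self, rng):
        data = rng.random((6, 6, 6))
        kernel = np.zeros((3, 3, 3))
        kernel[1, 1, 1] = 1.0
        np.testing.assert_allclose(convolve3d(data, kernel), data, atol=1e-12)

    def test_sum_kernel_on_constant_volume(self):
        out = convolve3d(np.full((6, 6, 6), 2.0), np.ones((3, 3, 3)))
        assert out[3, 3, 3] == pytest.approx(54.0)  # interior: 27 * 2

    def test_matches_triple_loop_oracle(self, rng):
        data = rng.standard_normal((6, 7, 5))
        kernel = rng.standard_normal((3, 3, 3))
        np.testing.assert_allclose(
            convolve3d(data, kernel), oracle_convolve3d(data, kernel), atol=1e-10
        )

    def test_even_kernel_rejected(self, rng):
        with pytest.raises(ValueError):
            convolve3d(rng.random((6, 6, 6)), np.ones((2, 2, 2)))


class TestPoolRelu:
    def test_all_negative_becomes_zero(self):
        out = pool_relu(-np.ones((4, 4, 4)), pool=2, stride=2)
        np.testing.assert_array_equal(out, 0.0)

    def test_constant_positive_preserved(self):
        out = pool_relu(np.full((6, 6, 6), 3.0), pool=2, stride=2)
        assert out.shape == (3, 3, 3)
        np.testing.assert_array_equal(out, 3.0)

    def test_pool_one_is_relu(self, rng):
        data = rng.standard_normal((4, 4, 4))
        np.testing.assert_array_equal(pool_relu(data, 1, 1), np.maximum(data, 0))

    def test_matches_windowed_max_oracle(self, rng):
        data = rng.standard_normal((6, 6, 6))
        np.testing.assert_allclose(
            pool_relu(data, 2, 2), oracle_pool_relu(data, 2, 2), atol=1e-12
        )

    def test_gap_stride_warns(self, rng):
        with pytest.warns(UserWarning, match="skipped"):
            pool_relu(rng.standard_normal((8, 8, 8)), pool=2, stride=3)


class TestStageForward:
    def test_output_count_and_order(self, rng):
        bank = learn_filters(extract_patches(rng.random((6, 6, 6)), 3), c=3, k=3)
        images = [rng.random((6, 6, 6)) for _ in range(2)]
        outs = stage_forward(images, bank, pool=1, pool_stride=1)
        assert len(outs) == 6
        # image-major order: first 3 outputs come from image 0
        np.testing.assert_allclose(
            outs[0], np.maximum(convolve3d(images[0], bank.kernels[0]), 0)
        )
        np.testing.assert_allclose(
            outs[3], np.maximum(convolve3d(images[1], bank.kernels[0]), 0)
        )

    def test_delta_kernel_stage_is_relu(self, rng):
        kernel = np.zeros((3, 3, 3))
        kernel[1, 1, 1] = 1.0
        bank = FilterBank(kernels=kernel[None], eigenvalues=np.array([1.0]))
        image = rng.standard_normal((5, 5, 5))
        outs = stage_forward([image], bank, pool=1, pool_stride=1)
        np.testing.assert_allclose(outs[0], np.maximum(image, 0))

    def test_equals_manual_composition(self, rng):
        bank = learn_filters(extract_patches(rng.random((8, 8, 8)), 3), c=2, k=3)
        image = rng.standard_normal((8, 8, 8))
        outs = stage_forward([image], bank, pool=2, pool_stride=2)
        for kernel, got in zip(bank.kernels, outs):
            np.testing.assert_allclose(got, pool_relu(convolve3d(image, kernel), 2, 2))


class TestHeavisideEncode:
    def test_all_positive_gives_full_code(self):
        outs = [np.ones((3, 3, 3)) for _ in range(3)]
        np.testing.assert_array_equal(heaviside_encode(outs), 7)

    def test_non_positive_gives_zero(self):
        outs = [np.zeros((3, 3, 3)), -np.ones((3, 3, 3))]
        np.testing.assert_array_equal(heaviside_encode(outs), 0)

    def test_matches_bit_packing_oracle(self, rng):
        outs = [rng.standard_normal((4, 4, 4)) for _ in range(4)]
        np.testing.assert_array_equal(heaviside_encode(outs), oracle_encode(outs))

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            heaviside_encode([np.ones((3, 3, 3)), np.ones((4, 4, 4))])


class TestBlockHistograms:
    def test_constant_encoded_volume(self):
        p = PCANetParams(k=3, c2=3, beta=8, hist_block=2)
        encoded = np.full((4, 4, 4), 5, dtype=int)
        hist = block_histograms(encoded, p)
        assert hist.shape == (8 * 8,)
        per_block = hist.reshape(8, 8)
        np.testing.assert_array_equal(per_block[:, 5], 8)  # 2^3 voxels at bin 5
        assert per_block.sum() == 8 * 8

    def test_bin_sums_equal_block_volume(self, rng):
        p = PCANetParams(k=3, c2=4, beta=4, hist_block=3, overlap_r=0.4)
        encoded = rng.integers(0, 16, size=(7, 7, 7))
        hist = block_histograms(encoded, p).reshape(4, 16)
        np.testing.assert_array_equal(hist.sum(axis=1), 27)

    def test_matches_counting_oracle(self, rng):
        p = PCANetParams(k=3, c2=3, beta=6, hist_block=3, overlap_r=0.4)
        encoded = rng.integers(0, 8, size=(8, 8, 8))
        stride = max(1, round(3 * (1 - 0.4)))
        expected = oracle_block_histograms(encoded, 3, stride, 6, 8)
        np.testing.assert_array_equal(block_histograms(encoded, p), expected)

    def test_insufficient_blocks_reported(self, rng):
        p = PCANetParams(k=3, c2=2, beta=50, hist_block=3)
        with pytest.raises(ValueError, match="blocks"):
            block_histograms(rng.integers(0, 4, size=(4, 4, 4)), p)


class TestPCANet3D:
    @pytest.fixture
    def params(self):
        return PCANetParams(k=3, c1=3, c2=3, pool=2, pool_stride=2, beta=8, hist_block=2)

    @pytest.fixture
    def images(self, rng):
        return [rng.standard_normal((16, 16, 16)) for _ in range(6)]

    def test_duplicated_training_set_leaves_filters_unchanged(self, params, images):
        net1 = PCANet3D(params).fit(images)
        net2 = PCANet3D(params).fit(images + images)
        np.testing.assert_allclose(net1.stage1.kernels, net2.stage1.kernels, atol=1e-9)

    def test_refit_is_bitwise_deterministic(self, params, images):
        net1 = PCANet3D(params).fit(images)
        net2 = PCANet3D(params).fit(images)
        np.testing.assert_array_equal(net1.stage1.kernels, net2.stage1.kernels)
        np.testing.assert_array_equal(net2.stage2.kernels, net2.stage2.kernels)

    def test_banks_satisfy_invariants(self, params, images):
        net = PCANet3D(params).fit(images)
        for bank in (net.stage1, net.stage2):
            flat = bank.kernels.reshape(len(bank), -1)
            np.testing.assert_allclose(flat @ flat.T, np.eye(len(bank)), atol=1e-10)
            assert np.all(np.diff(bank.eigenvalues) <= 1e-9)

    def test_feature_length_formula(self, images):
        p = PCANetParams(k=3, c1=4, c2=4, beta=10, hist_block=2, overlap_r=0.4)
        features = PCANet3D(p).fit_transform(images)
        assert features.shape == (len(images), 4 * 10 * 16)  # C1 * beta * 2^C2

    def test_identical_images_identical_features(self, params, images):
        net = PCANet3D(params).fit(images)
        feats = net.transform([images[0], images[0]])
        np.testing.assert_array_equal(feats[0], feats[1])

    def test_transform_matches_chained_oracles(self, rng):
        p = PCANetParams(k=3, c1=2, c2=2, pool=1, pool_stride=1, beta=4, hist_block=4)
        images = [rng.standard_normal((8, 8, 8)) for _ in range(3)]
        net = PCANet3D(p).fit(images)
        got = net.transform([images[0]])[0]
        expected = []
        for l_kernel in net.stage1.kernels:
            pi = np.maximum(oracle_convolve3d(images[0], l_kernel), 0)
            omegas = [
                np.maximum(oracle_convolve3d(pi, h_kernel), 0)
                for h_kernel in net.stage2.kernels
            ]
            encoded = oracle_encode(omegas)
            expected.append(oracle_block_histograms(encoded, 4, 4, 4, 4))
        np.testing.assert_allclose(got, np.concatenate(expected), atol=1e-10)

    def test_transform_is_read_only_on_model(self, params, images, rng):
        net = PCANet3D(params).fit(images)
        before1 = net.stage1.kernels.copy()
        before2 = net.stage2.kernels.copy()
        net.transform([rng.standard_normal((16, 16, 16))])
        np.testing.assert_array_equal(net.stage1.kernels, before1)
        np.testing.assert_array_equal(net.stage2.kernels, before2)

    def test_transform_before_fit_rejected(self, params, rng):
        with pytest.raises(RuntimeError):
            PCANet3D(params).transform([rng.random((8, 8, 8))])

    def test_save_load_roundtrip(self, params, images, tmp_path, rng):
        net = PCANet3D(params).fit(images)
        path = tmp_path / "model.npz"
        net.save(path)
        loaded = PCANet3D.load(path)
        probe = [rng.standard_normal((16, 16, 16))]
        np.testing.assert_array_equal(net.transform(probe), loaded.transform(probe))

    def test_encoded_values_bounded(self, params, images):
        p = params
        net = PCANet3D(p).fit(images)
        feats = net.transform(images)
        assert np.all(feats >= 0)
        # per-block conservation: every block of every histogram sums to block volume
        per_block = feats.reshape(len(images), p.c1 * p.beta, p.n_bins)
        np.testing.assert_array_equal(per_block.sum(axis=2), p.histogram_block_edge**3)


class TestPCANetParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"k": 2},
            {"c1": 0},
            {"c2": 100},
            {"overlap_r": 1.0},
            {"beta": 0},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            PCANetParams(**kwargs)
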