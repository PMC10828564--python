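import numpy as np
import pytest

from cgrembed.embedders import (
    AHashEmbedder,
    FcgrEmbedder,
    PcaEmbedder,
    PHashEmbedder,
    WHashEmbedder,
    block_mean_downscale,
)


def naive_dct2(a):
    """Direct double-sum orthonormal type-II DCT (O(n^4) oracle)."""
    n, m = a.shape
    out = np.zeros((n, m))
    for u in range(n):
        for v in range(m):
            s = 0.0
            for i in range(n):
                for j in range(m):
                    s += (
                        a[i, j]
                        * np.cos(np.pi * (2 * i + 1) * u / (2 * n))
                        * np.cos(np.pi * (2 * j + 1) * v / (2 * m))
                    )
            cu = np.sqrt(1 / n) if u == 0 else np.sqrt(2 / n)
            cv = np.sqrt(1 / m) if v == 0 else np.sqrt(2 / m)
            out[u, v] = cu * cv * s
    return out


def recursive_average(a, target):
    """Oracle for the Haar approximation band up to scaling: repeated 2x2
    block averaging down to target x target."""
    while a.shape[0] > target:
        a = (a[0::2, 0::2] + a[0::2, 1::2] + a[1::2, 0::2] + a[1::2, 1::2]) / 4.0
    return a


class TestFcgrEmbedder:
    def test_row_major_flattening(self):
        X = np.array([[[1.0, 2.0], [3.0, 4.0]]])
        out = FcgrEmbedder().fit(X).transform(X)
        assert np.array_equal(out, [[1.0, 2.0, 3.0, 4.0]])

    def test_zero_image_flagged(self):
        X = np.zeros((1, 4, 4))
        with pytest.warns(UserWarning, match="zero embedding"):
            out = FcgrEmbedder().fit(X).transform(X)
        assert np.array_equal(out, np.zeros((1, 16)))

    def test_flatten_reshape_round_trip(self, rng):
        X = rng.random((6, 8, 8))
        out = FcgrEmbedder().fit(X).transform(X)
        assert np.array_equal(out.reshape(6, 8, 8), X)


class TestPcaEmbedder:
    def test_exact_recovery_of_low_rank_data(self, rng):
        """Images lying in a 3-dim affine subspace reconstruct to machine
        precision from 3 components."""
        basis = rng.normal(size=(3, 64))
        coefs = rng.normal(size=(30, 3))
        flat = coefs @ basis + rng.normal(size=64)
        X = flat.reshape(30, 8, 8)
        est = PcaEmbedder(dim=3).fit(X)
        E = est.transform(X)
        recon = E @ est.components_ + est.mean_
        assert np.allclose(recon, flat, atol=1e-9)

    def test_full_rank_preserves_distances(self, rng):
        X = rng.random((10, 4, 4))
        E = PcaEmbedder(dim=10).fit(X).transform(X)
        flat = X.reshape(10, -1)
        d_orig = np.linalg.norm(flat[:, None] - flat[None], axis=2)
        d_proj = np.linalg.norm(E[:, None] - E[None], axis=2)
        assert np.allclose(d_orig, d_proj, atol=1e-8)

    def test_variances_match_eigendecomposition_oracle(self, rng):
        """Explained variances equal the top eigenvalues of the empirical
        covariance computed independently."""
        X = rng.random((50, 8, 8))
        est = PcaEmbedder(dim=5).fit(X)
        flat = X.reshape(50, -1)
        cov = np.cov(flat, rowvar=False, ddof=1)
        eigvals = np.linalg.eigvalsh(cov)[::-1]
        assert np.allclose(est.explained_variance_, eigvals[:5], atol=1e-10)

    def test_sign_convention_largest_loading_positive(self, rng):
        X = rng.random((20, 4, 4))
        est = PcaEmbedder(dim=4).fit(X)
        for comp in est.components_:
            assert comp[np.abs(comp).argmax()] > 0

    def test_mean_image_embeds_to_zero(self, rng):
        X = rng.random((12, 4, 4))
        est = PcaEmbedder(dim=4).fit(X)
        mean_img = X.mean(axis=0)[None]
        assert np.allclose(est.transform(mean_img), 0.0, atol=1e-10)

    def test_dim_too_large_rejected(self, rng):
        with pytest.raises(ValueError, match="dim"):
            PcaEmbedder(dim=20).fit(rng.random((10, 4, 4)))


class TestHashEmbedders:
    def test_bits_are_plus_minus_one(self, rng):
        X = rng.random((3, 16, 16))
        for est in (AHashEmbedder(16), PHashEmbedder(16), WHashEmbedder(16)):
            out = est.fit(X).transform(X)
            assert set(np.unique(out)) <= {-1.0, 1.0}

    def test_cosine_hamming_identity(self, rng):
        """cosine(h1, h2) = 1 - 2 * hamming / d for +-1 hash vectors."""
        X = rng.random((2, 16, 16))
        h = AHashEmbedder(16).fit(X).transform(X)
        d = h.shape[1]
        hamming = float((h[0] != h[1]).sum())
        cos = float(h[0] @ h[1] / (np.linalg.norm(h[0]) * np.linalg.norm(h[1])))
        assert cos == pytest.approx(1 - 2 * hamming / d)

    def test_non_square_dim_rejected(self, rng):
        with pytest.raises(ValueError, match="perfect square"):
            AHashEmbedder(dim=10).fit(rng.random((1, 8, 8)))


class TestAHash:
    def test_constant_image_all_minus_one(self):
        X = np.full((1, 8, 8), 3.7)
        out = AHashEmbedder(4).fit(X).transform(X)
        assert np.array_equal(out, -np.ones((1, 4)))

    def test_bright_quadrant_positive(self):
        img = np.zeros((8, 8))
        img[:4, :4] = 10.0
        out = AHashEmbedder(4).fit(img[None]).transform(img[None])[0]
        assert out[0] == 1.0 and np.array_equal(out[1:], -np.ones(3))

    def test_matches_two_pass_oracle(self, rng):
        X = rng.random((1, 64, 64))
        out = AHashEmbedder(64).fit(X).transform(X)[0]
        small = block_mean_downscale(X[0], 8)
        oracle = np.where(small.ravel() > small.mean(), 1.0, -1.0)
        assert np.array_equal(out, oracle)


class TestPHash:
    def test_constant_image_dc_only(self):
        X = np.full((1, 16, 16), 2.0)
        out = PHashEmbedder(4).fit(X).transform(X)[0]
        # AC coefficients are 0, the threshold median is 0; only the strictly
        # positive DC coefficient exceeds it
        assert out[0] == 1.0 and np.array_equal(out[1:], -np.ones(3))

    def test_brightness_scale_invariance(self, rng):
        X = rng.random((1, 32, 32))
        est = PHashEmbedder(16)
        a = est.fit(X).transform(X)
        b = est.transform(X * 37.5)
        assert np.array_equal(a, b)

    def test_coefficients_match_naive_dct_oracle(self, rng):
        from scipy.fft import dctn

        a = rng.random((8, 8))
        assert np.allclose(dctn(a, type=2, norm="ortho"), naive_dct2(a), atol=1e-10)

    def test_bits_match_oracle_pipeline(self, rng):
        X = rng.random((1, 32, 32))
        g = 4
        out = PHashEmbedder(g * g).fit(X).transform(X)[0]
        small = block_mean_downscale(X[0], 16)  # 4g = 16
        coeffs = naive_dct2(small)[:g, :g]
        med = np.median(coeffs.ravel()[1:])
        oracle = np.where(coeffs.ravel() > med, 1.0, -1.0)
        assert np.array_equal(out, oracle)


class TestWHash:
    def test_constant_image_detail_free(self):
        import pywt

        X = np.full((8, 8), 5.0)
        cA, (cH, cV, cD) = pywt.wavedec2(X, "haar", level=1)
        assert np.allclose(cH, 0) and np.allclose(cV, 0) and np.allclose(cD, 0)
        assert np.allclose(cA, cA[0, 0])

    def test_single_level_haar_2x2_hand_example(self):
        import pywt

        block = np.array([[1.0, 2.0], [3.0, 4.0]])
        cA, (cH, cV, cD) = pywt.wavedec2(block, "haar", level=1)
        # orthonormal Haar on a 2x2 block: approximation = 2 * mean,
        # details = half-sums of signed entries
        assert cA[0, 0] == pytest.approx(2 * block.mean())
        assert cH[0, 0] == pytest.approx(((1 + 2) - (3 + 4)) / 2)
        assert cV[0, 0] == pytest.approx(((1 + 3) - (2 + 4)) / 2)
        assert cD[0, 0] == pytest.approx(((1 + 4) - (2 + 3)) / 2)

    def test_bits_match_recursive_averaging_oracle(self, rng):
        X = rng.random((1, 64, 64))
        g = 8
        out = WHashEmbedder(g * g).fit(X).transform(X)[0]
        approx = recursive_average(X[0], g)  # proportional to the Haar band
        med = np.median(approx)
        oracle = np.where(approx.ravel() > med, 1.0, -1.0)
        assert np.array_equal(out, oracle)
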