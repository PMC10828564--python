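"""Classical image embedders: flattened FCGR, PCA, and LSH-style hashes.

All embedders are scikit-learn transformers over stacked CGR images of shape
(n, R, R) and produce (n, d) float embeddings to be compared by cosine
similarity. Hash embedders emit bits as +/-1 (not {0,1}) so the cosine of
two hashes is 1 - 2 * hamming/d, i.e. centered and meaningful.
"""

from __future__ import annotations

import warnings

import numpy as np
import pywt
from scipy.fft import dctn
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

__all__ = [
    "FcgrEmbedder",
    "PcaEmbedder",
    "AHashEmbedder",
    "PHashEmbedder",
    "WHashEmbedder",
    "block_mean_downscale",
]


def _check_images(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 3 or X.shape[1] != X.shape[2]:
        raise ValueError(f"expected (n, R, R) image stack, got shape {X.shape}")
    if not np.isfinite(X).all():
        raise ValueError("images contain non-finite values")
    return X


def block_mean_downscale(image: np.ndarray, out_size: int) -> np.ndarray:
    """Area-mean pooling to out_size x out_size (R must be divisible)."""
    r = image.shape[0]
    if r % out_size:
        raise ValueError(f"resolution {r} not divisible by target {out_size}")
    f = r // out_size
    return image.reshape(out_size, f, out_size, f).mean(axis=(1, 3))


class FcgrEmbedder(BaseEstimator, TransformerMixin):
    """Baseline: the raw CGR image flattened row-major to a R^2 vector."""

    def fit(self, X, y=None):
        X = _check_images(X)
        self.n_features_in_ = X.shape[1] * X.shape[2]
        return self

    def transform(self, X):
        X = _check_images(X)
        out = X.reshape(X.shape[0], -1)
        if (np.abs(out).sum(axis=1) == 0).any():
            warnings.warn("all-zero image yields a zero embedding (cosine undefined)")
        return out


class PcaEmbedder(BaseEstimator, TransformerMixin):
    """Mean-centered projection of flattened images onto top-d principal axes.

    Deterministic sign convention: each component's largest-magnitude loading
    is made positive.
    """

    def __init__(self, dim: int = 64):
        self.dim = dim

    def fit(self, X, y=None):
        X = _check_images(X)
        flat = X.reshape(X.shape[0], -1)
        if self.dim > min(flat.shape):
            raise ValueError(
                f"dim={self.dim} exceeds min(n_samples, n_pixels)={min(flat.shape)}"
            )
        pca = PCA(n_components=self.dim, svd_solver="full")
        pca.fit(flat)
        comps = pca.components_.copy()
        flip = np.sign(comps[np.arange(len(comps)), np.abs(comps).argmax(axis=1)])
        flip[flip == 0] = 1.0
        self.components_ = comps * flip[:, None]
        self.mean_ = pca.mean_
        self.explained_variance_ = pca.explained_variance_
        return self

    def transform(self, X):
        X = _check_images(X)
        flat = X.reshape(X.shape[0], -1)
        return (flat - self.mean_) @ self.components_.T


class _HashEmbedder(BaseEstimator, TransformerMixin):
    """Shared plumbing: d must be a perfect square (hash grid sqrt(d))."""

    def __init__(self, dim: int = 64):
        self.dim = dim

    def _grid(self) -> int:
        g = int(round(np.sqrt(self.dim)))
        if g * g != self.dim:
            raise ValueError(f"dim={self.dim} is not a perfect square")
        return g

    def fit(self, X, y=None):
        _check_images(X)
        self._grid()
        return self

    def transform(self, X):
        X = _check_images(X)
        g = self._grid()
        return np.stack([self._hash_one(img, g) for img in X])

    def _hash_one(self, image: np.ndarray, g: int) -> np.ndarray:
        raise NotImplementedError


class AHashEmbedder(_HashEmbedder):
    """Average hash: block-mean downscale to g x g, bit = cell > mean of cells.

    A constant image hashes to all -1 (strict inequality never holds).
    """

    def _hash_one(self, image, g):
        small = block_mean_downscale(image, g)
        bits = small > small.mean()
        return np.where(bits.ravel(), 1.0, -1.0)


class PHashEmbedder(_HashEmbedder):
    """Perceptual hash via the low-frequency block of a 2D type-II DCT.

    The image is block-mean downscaled to 4g x 4g (or kept at R if R <= 4g),
    DCT-transformed, and the top-left g x g low-frequency block retained. The
    threshold is the median of the retained coefficients *excluding* the DC
    term; every retained coefficient (DC included) is then compared against
    it. Bits are scale-invariant: uniform brightness scaling multiplies all
    coefficients and the median alike.
    """

    def _hash_one(self, image, g):
        r = image.shape[0]
        target = min(4 * g, r)
        if r % target:
            raise ValueError(f"resolution {r} not divisible by DCT size {target}")
        if target < g:
            raise ValueError(f"resolution {r} too small for a {g}x{g} hash")
        small = block_mean_downscale(image, target)
        coeffs = dctn(small, type=2, norm="ortho")[:g, :g]
        med = np.median(coeffs.ravel()[1:])
        return np.where(coeffs.ravel() > med, 1.0, -1.0)


class WHashEmbedder(_HashEmbedder):
    """Wavelet hash: Haar approximation band at scale g, median-thresholded.

    log2(R/g) levels of the 2D Haar transform reduce the image to its g x g
    low-frequency approximation (proportional to block means); bits compare
    each approximation coefficient to their median.
    """

    def _hash_one(self, image, g):
        r = image.shape[0]
        if r & (r - 1) or g & (g - 1) or r < g:
            raise ValueError("whash needs power-of-two resolution >= hash grid")
        levels = int(np.log2(r // g))
        if levels == 0:
            approx = image
        else:
            approx = pywt.wavedec2(image, "haar", level=levels)[0]
        med = np.median(approx)
        return np.where(approx.ravel() > med, 1.0, -1.0)
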