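"""Frozen feature backbones for the patch classifier.

The live system finetunes only a small head on top of a frozen, pretrained
feature extractor. The default backbone here is a fixed filter bank (color
pooling, gradient magnitude, Laplacian-of-Gaussian responses) followed by a
PCA whitening transform fitted on the synthetic pretraining corpus; fitting
the PCA is the "pretraining" step and its parameters are frozen afterwards.
Any object exposing ``dim``, ``transform`` and ``parameter_bytes`` can stand
in, which is how tests plug in stub backbones with controlled geometry.
"""

from __future__ import annotations

import hashlib

import numpy as np
from scipy import ndimage as ndi
from sklearn.decomposition import PCA

from . import patchio

#: average per-component feature standard deviation on the pretraining corpus.
#: Deep backbones feed their head activations well above unit scale; at the
#: protocol's very small learning rate this scale is what lets the readout
#: move appreciably within the early-stopping window.
FEATURE_STD = 10.0


def _raw_features(patches: np.ndarray) -> np.ndarray:
    """Hand-fixed filter-bank features for (n, h, w, 3) patch stacks.

    Patches are centroid-centered, so the responses are center-weighted: the
    central disk covers the nucleus the patch belongs to, the annulus its
    immediate surroundings, and a coarse grid the remaining context.
    """
    patches = np.asarray(patches, dtype=np.float64)
    n, h, w, _ = patches.shape
    yy, xx = np.mgrid[0:h, 0:w]
    r = np.sqrt((yy - (h - 1) / 2) ** 2 + (xx - (w - 1) / 2) ** 2)
    disk = r <= 0.2 * h
    annulus = (r > 0.2 * h) & (r <= 0.4 * h)

    feats = [
        patches[:, disk, :].mean(axis=1),  # nucleus color
        patches[:, disk, :].std(axis=1),  # nucleus texture strength
        patches[:, annulus, :].mean(axis=1),  # halo color
    ]
    gh, gw = max(h // 4, 1), max(w // 4, 1)
    grid = patches[:, : 4 * gh, : 4 * gw, :].reshape(n, 4, gh, 4, gw, 3).mean(axis=(2, 4))
    feats.append(grid.reshape(n, -1))  # coarse context layout
    for ch in range(3):
        plane = patches[..., ch]
        gx = ndi.sobel(plane, axis=2)
        gy = ndi.sobel(plane, axis=1)
        grad = np.sqrt(gx**2 + gy**2)
        log = np.abs(ndi.gaussian_laplace(plane, sigma=2.0))
        feats.append(grad[:, disk].mean(axis=1, keepdims=True))  # edge density
        feats.append(log[:, disk].mean(axis=1, keepdims=True))  # blob response
    return np.concatenate(feats, axis=1)


class FilterBankBackbone:
    """Frozen filter bank + PCA projection, fitted once on a pretraining corpus.

    The PCA is *not* whitened: class-discriminative directions with large
    corpus variance keep their weight, as the penultimate layer of a deep
    backbone would. ``feature_scale`` normalizes the average per-component
    variance on the corpus to 1 so the head's initialization is well matched.
    """

    def __init__(self, pca: PCA, norm_stats: patchio.NormStats, feature_scale: float):
        self._pca = pca
        self.norm_stats = norm_stats
        self.feature_scale = feature_scale
        self.dim = int(pca.n_components_)

    def transform(self, patches: np.ndarray) -> np.ndarray:
        """Embed raw (unnormalized) uint8/float patches → (n, dim) float64."""
        patches = np.asarray(patches, dtype=np.float64)
        if patches.ndim == 3:
            patches = patches[None]
        normalized = patchio.apply_norm(patches, self.norm_stats)
        return self._pca.transform(_raw_features(normalized)) * self.feature_scale

    def parameter_bytes(self) -> bytes:
        parts = [
            self._pca.components_.tobytes(),
            self._pca.mean_.tobytes(),
            self._pca.explained_variance_.tobytes(),
            np.asarray(self.norm_stats.mean).tobytes(),
            np.asarray(self.norm_stats.std).tobytes(),
            np.float64(self.feature_scale).tobytes(),
        ]
        return b"".join(parts)

    def fingerprint(self) -> str:
        return hashlib.sha256(self.parameter_bytes()).hexdigest()


def pretrain_backbone(
    corpus_patches: np.ndarray,
    n_components: int = 32,
) -> FilterBankBackbone:
    """Fit the backbone on a labeled-or-not patch corpus; labels are unused.

    Normalization statistics are computed from the corpus (the training set of
    the pretraining stage) exactly as the head's statistics would be.
    """
    corpus_patches = np.asarray(corpus_patches, dtype=np.float64)
    if corpus_patches.ndim != 4 or len(corpus_patches) < 2:
        raise ValueError("pretraining needs a (n>=2, h, w, 3) patch stack")
    stats = patchio.compute_norm_stats(corpus_patches)
    raw = _raw_features(patchio.apply_norm(corpus_patches, stats))
    n_components = min(n_components, raw.shape[0], raw.shape[1])
    pca = PCA(n_components=n_components, whiten=False, svd_solver="full")
    projected = pca.fit_transform(raw)
    feature_scale = float(FEATURE_STD / np.sqrt(projected.var(axis=0).mean()))
    return FilterBankBackbone(pca, stats, feature_scale)


class StubBackbone:
    """Deterministic lookup backbone for tests: cell patches carry their own
    embedding in the top-left pixels, or a caller-provided function maps
    patches to embeddings."""

    def __init__(self, func, dim: int, tag: bytes = b"stub"):
        self._func = func
        self.dim = dim
        self._tag = tag

    def transform(self, patches: np.ndarray) -> np.ndarray:
        patches = np.asarray(patches, dtype=np.float64)
        if patches.ndim == 3:
            patches = patches[None]
        return np.asarray(self._func(patches), dtype=np.float64)

    def parameter_bytes(self) -> bytes:
        return self._tag

    def fingerprint(self) -> str:
        return hashlib.sha256(self._tag).hexdigest()
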