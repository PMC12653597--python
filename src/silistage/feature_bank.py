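"""Imaging feature representation: frozen backbone + fold-fitted PLS-DA transform.

The imaging modality is represented in three stages:

1. A *frozen* backbone maps each preprocessed radiograph to a fixed-length
   feature vector; with a convolutional backbone this is the per-channel
   spatial mean of the final feature map (global average pooling, 1280-dim
   for the reference architecture).  The shipped default is a seeded,
   frozen random-projection stub so the package runs without any external
   weights; any extractor satisfying :class:`BackboneContract` can be
   plugged in.
2. A standard scaler fitted on the training features only.
3. PLS-DA against the binary SS/PMF label, projecting to ``n_components``
   latent scores (default 15), followed by a second standard scaler fitted
   on the training latent scores ("double standardization").

All fitting is strictly train-only so the transform can sit inside a
cross-validation fold without leakage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Protocol, runtime_checkable

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.preprocessing import StandardScaler

__all__ = [
    "DEFAULT_N_COMPONENTS",
    "BackboneContract",
    "RandomProjectionBackbone",
    "global_average_pool",
    "extract_features",
    "ImageTransformer",
    "fit_image_transformer",
    "transform_image_features",
]

DEFAULT_N_COMPONENTS = 15


def global_average_pool(feature_map: np.ndarray) -> np.ndarray:
    """Collapse an H x W x C feature map to a C-vector of per-channel spatial means."""
    feature_map = np.asarray(feature_map, dtype=float)
    if feature_map.ndim != 3:
        raise ValueError(f"expected an H x W x C feature map, got shape {feature_map.shape}")
    return feature_map.mean(axis=(0, 1))


@runtime_checkable
class BackboneContract(Protocol):
    """A frozen, stateless image -> feature-vector mapping."""

    name: str
    output_dim: int

    def extract(self, preprocessed: np.ndarray) -> np.ndarray: ...


@dataclass
class RandomProjectionBackbone:
    """Seeded frozen random projection of the preprocessed image.

    Flattens channel 0 of the ``size x size x 3`` input and projects it with
    a fixed Gaussian matrix (scaled by 1/sqrt(n_pixels)).  Deterministic for
    a given (seed, input_size, output_dim); intended for tests and synthetic
    runs, not for extracting clinically meaningful features.
    """

    output_dim: int = 64
    seed: int = 0
    input_size: int = 224
    name: str = "random-projection-stub"
    _weights: np.ndarray | None = field(default=None, repr=False)

    def _weight_matrix(self) -> np.ndarray:
        if self._weights is None:
            n = self.input_size * self.input_size
            rng = np.random.default_rng(self.seed)
            self._weights = rng.standard_normal((n, self.output_dim)) / np.sqrt(n)
        return self._weights

    def extract(self, preprocessed: np.ndarray) -> np.ndarray:
        preprocessed = np.asarray(preprocessed, dtype=float)
        expected = (self.input_size, self.input_size, 3)
        if preprocessed.shape != expected:
            raise ValueError(f"expected input of shape {expected}, got {preprocessed.shape}")
        return preprocessed[:, :, 0].ravel() @ self._weight_matrix()


def extract_features(preprocessed: np.ndarray, backbone: BackboneContract) -> np.ndarray:
    """Extract the backbone's feature vector for one preprocessed image."""
    if backbone is None:
        raise ValueError(
            "no backbone registered; use RandomProjectionBackbone for a "
            "weight-free frozen extractor"
        )
    vec = np.asarray(backbone.extract(preprocessed), dtype=float)
    if vec.shape != (backbone.output_dim,):
        raise ValueError(
            f"backbone {backbone.name!r} returned shape {vec.shape}, "
            f"expected ({backbone.output_dim},)"
        )
    if not np.all(np.isfinite(vec)):
        raise ValueError(f"backbone {backbone.name!r} produced non-finite features")
    return vec


def _sign_fix(rotations: np.ndarray, loadings: np.ndarray) -> np.ndarray:
    """Flip component signs so each component's largest-|.| loading is positive."""
    flips = np.ones(loadings.shape[1])
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            flips[j] = -1.0
    return flips


@dataclass
class ImageTransformer:
    """Fold-fitted scale -> PLS-DA -> scale transform for image features.

    ``fit`` uses training data only; ``transform`` is a pure function of the
    fitted parameters.  Components are sign-fixed so the largest-magnitude
    loading of each component is positive, making comparisons against
    reference implementations well-posed.
    """

    n_components: int = DEFAULT_N_COMPONENTS
    scaler1_: StandardScaler | None = None
    rotations_: np.ndarray | None = None
    loadings_: np.ndarray | None = None
    scaler2_: StandardScaler | None = None
    training_scores_: np.ndarray | None = None

    @property
    def fitted(self) -> bool:
        return self.scaler2_ is not None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ImageTransformer":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_samples x n_features)")
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("PLS-DA requires both classes in the training labels")
        n, d = X.shape
        cap = min(n - 1, d)
        k = self.n_components
        if k > cap:
            warnings.warn(
                f"n_components={k} exceeds the admissible maximum {cap} "
                f"for a {n}x{d} training set; capping",
                stacklevel=2,
            )
            k = cap
        if k < 1:
            raise ValueError(f"cannot fit PLS-DA with n_components < 1 (max admissible {cap})")

        self.scaler1_ = StandardScaler().fit(X)
        Xs = self.scaler1_.transform(X)
        # single 0/1 response (PLS1); scale=False since X is pre-standardized
        pls = PLSRegression(n_components=k, scale=False).fit(Xs, y)
        flips = _sign_fix(pls.x_rotations_, pls.x_loadings_)
        self.rotations_ = pls.x_rotations_ * flips
        self.loadings_ = pls.x_loadings_ * flips
        scores = Xs @ self.rotations_
        self.scaler2_ = StandardScaler().fit(scores)
        self.training_scores_ = self.scaler2_.transform(scores)
        self.n_components = k
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise ValueError("ImageTransformer is not fitted")
        X = np.asarray(X, dtype=float)
        single = X.ndim == 1
        if single:
            X = X[None, :]
        if X.shape[1] != self.scaler1_.mean_.shape[0]:
            raise ValueError(
                f"feature dimension {X.shape[1]} does not match fitted "
                f"dimension {self.scaler1_.mean_.shape[0]}"
            )
        scores = self.scaler2_.transform(self.scaler1_.transform(X) @ self.rotations_)
        return scores[0] if single else scores


def fit_image_transformer(
    train_features: np.ndarray,
    train_labels: np.ndarray,
    n_components: int = DEFAULT_N_COMPONENTS,
) -> ImageTransformer:
    """Fit the three-phase image transform on training data only."""
    return ImageTransformer(n_components=n_components).fit(train_features, train_labels)


def transform_image_features(transformer: ImageTransformer, features: np.ndarray) -> np.ndarray:
    """Project features into the fitted latent space (pure function of the fit)."""
    return transformer.transform(features)
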