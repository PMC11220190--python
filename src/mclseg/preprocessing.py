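"""PCA band reduction of hyperspectral cubes.

Hyperspectral bands are strongly correlated and carry shared acquisition
noise; projecting each pixel spectrum onto the top-k principal components of
the training pixels both denoises and shrinks the input (default k = 6
channels).  The model is fitted once on pixels pooled across all training
scenes — labeled and unlabeled — after per-band standardization, then frozen
and applied unchanged to every scene including test scenes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.decomposition import PCA

from .hsi_io import HyperCube

logger = logging.getLogger(__name__)

__all__ = ["PCAModel", "fit_pca", "apply_pca", "save_pca", "load_pca"]


@dataclass
class PCAModel:
    """Frozen per-band standardization + orthonormal projection to k channels."""

    band_means: np.ndarray  # (C,)
    band_scales: np.ndarray  # (C,) positive
    components: np.ndarray  # (k, C), orthonormal rows
    explained_variance_ratio: np.ndarray  # (k,), non-increasing

    def __post_init__(self) -> None:
        self.band_means = np.asarray(self.band_means, dtype=np.float64)
        self.band_scales = np.asarray(self.band_scales, dtype=np.float64)
        self.components = np.asarray(self.components, dtype=np.float64)
        self.explained_variance_ratio = np.asarray(
            self.explained_variance_ratio, dtype=np.float64
        )
        k, c = self.components.shape
        gram = self.components @ self.components.T
        if not np.allclose(gram, np.eye(k), atol=1e-6):
            raise ValueError("component rows are not orthonormal")
        evr = self.explained_variance_ratio
        if np.any(np.diff(evr) > 1e-12) or np.any(evr < -1e-12) or evr.sum() > 1 + 1e-9:
            raise ValueError("invalid explained variance ratios")
        if np.any(self.band_scales <= 0):
            raise ValueError("band scales must be positive")

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    @property
    def n_bands(self) -> int:
        return self.components.shape[1]


def _fix_signs(components: np.ndarray) -> np.ndarray:
    """Make each component's largest-magnitude entry positive (reproducible sign)."""
    out = components.copy()
    for row in out:
        pivot = np.argmax(np.abs(row))
        if row[pivot] < 0:
            row *= -1.0
    return out


def fit_pca(
    cubes: list[HyperCube],
    k: int = 6,
    pixel_subsample: int = 100_000,
    seed: int = 0,
) -> PCAModel:
    """Fit PCA on pixels pooled across ``cubes`` after band standardization.

    At most ``pixel_subsample`` pixels are used (seeded uniform subsample).
    An all-constant band gets its scale clamped to 1 with a warning.
    """
    if not cubes:
        raise ValueError("need at least one cube to fit PCA")
    c = cubes[0].shape[2]
    if k > c:
        raise ValueError(f"k={k} exceeds band count {c}")
    pixels = np.concatenate([cube.data.reshape(-1, c) for cube in cubes]).astype(np.float64)
    if pixels.shape[0] > pixel_subsample:
        rng = np.random.default_rng(seed)
        idx = rng.choice(pixels.shape[0], size=pixel_subsample, replace=False)
        pixels = pixels[idx]
    if pixels.shape[0] < k:
        raise ValueError(f"only {pixels.shape[0]} pixels for k={k} components")
    means = pixels.mean(axis=0)
    scales = pixels.std(axis=0)
    constant = scales <= 1e-10 * np.maximum(1.0, np.abs(means))
    if np.any(constant):
        logger.warning(
            "band(s) %s have zero variance; scale clamped to 1",
            np.nonzero(constant)[0].tolist(),
        )
        scales = np.where(constant, 1.0, scales)
    z = (pixels - means) / scales
    pca = PCA(n_components=k, svd_solver="full")
    pca.fit(z)
    return PCAModel(
        band_means=means,
        band_scales=scales,
        components=_fix_signs(pca.components_),
        explained_variance_ratio=np.clip(pca.explained_variance_ratio_, 0.0, None),
    )


def apply_pca(model: PCAModel, cube: HyperCube | np.ndarray) -> np.ndarray:
    """Project every pixel of a cube onto the fitted components -> (H, W, k)."""
    data = cube.data if isinstance(cube, HyperCube) else np.asarray(cube)
    if data.shape[-1] != model.n_bands:
        raise ValueError(
            f"cube has {data.shape[-1]} bands, model expects {model.n_bands}"
        )
    z = (data.astype(np.float64) - model.band_means) / model.band_scales
    out = z @ model.components.T
    if not np.all(np.isfinite(out)):
        raise ValueError("non-finite values after projection")
    return out.astype(np.float32)


def save_pca(model: PCAModel, path: str | Path) -> None:
    np.savez(
        path,
        band_means=model.band_means,
        band_scales=model.band_scales,
        components=model.components,
        explained_variance_ratio=model.explained_variance_ratio,
    )


def load_pca(path: str | Path) -> PCAModel:
    with np.load(path) as npz:
        return PCAModel(
            band_means=npz["band_means"],
            band_scales=npz["band_scales"],
            components=npz["components"],
            explained_variance_ratio=npz["explained_variance_ratio"],
        )
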