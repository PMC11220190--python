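"""Synthetic hyperspectral pathology scenes with ground-truth tumor masks.

The generator emulates the structure of microscopic hyperspectral pathology
data — tens of contiguous bands over 550-1000 nm, a binary tumor/normal
annotation, and a spectral contrast between the two tissue classes — at a
desk-tractable spatial size.  The modeling assumption it reproduces is the one
hyperspectral segmentation rests on: tissues with similar biochemical
composition show similar spectra, so class identity is encoded per pixel as a
smooth spectral signature plus noise.

Each scene is built as

    cube[p, b] = spectrum(class(p), b) * illum(p) + noise_pix(p, b) + offset(b)

where ``spectrum`` is a sum of Gaussian bumps over wavelength (distinct bumps
per class, amplitudes jittered per scene by ``sigma_spec``), ``illum`` is a
smooth multiplicative field emulating uneven illumination, ``noise_pix`` is
i.i.d. Gaussian pixel noise (``sigma_pix``) and ``offset`` is a per-band
offset shared by every pixel (``sigma_band``), which gives the PCA
preprocessing correlated band noise to remove.  Tumor morphology is either a
smooth random blob field or a connected annulus ("ring") whose opening never
breaks — mimicking the circular duct cross-sections seen in biliary-tract
pathology.  Everything is a pure function of ``(seed, scene_index)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import hsi_io
from .hsi_io import DatasetManifest, HyperCube, LabelMask, ManifestEntry

__all__ = [
    "SpectralSignature",
    "SyntheticConfig",
    "default_signatures",
    "generate_scene",
    "generate_dataset",
]


@dataclass
class SpectralSignature:
    """A class's mean reflectance spectrum as Gaussian bumps over wavelength.

    ``bumps`` is a list of (center_nm, width_nm, amplitude); the mean spectrum
    at wavelength w is ``baseline + sum_k amp_k * exp(-(w-c_k)^2 / (2 s_k^2))``.
    ``sigma_spec`` scales the per-scene jitter of the bump amplitudes
    (within-class spectral variation).
    """

    class_id: int
    bumps: list[tuple[float, float, float]]
    baseline: float = 0.2
    sigma_spec: float = 0.02

    def mean_spectrum(self, wavelengths_nm: np.ndarray) -> np.ndarray:
        wl = np.asarray(wavelengths_nm, dtype=np.float64)
        out = np.full_like(wl, self.baseline)
        for center, width, amp in self.bumps:
            out += amp * np.exp(-((wl - center) ** 2) / (2.0 * width**2))
        return out

    def sample_spectrum(self, wavelengths_nm: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Mean spectrum with per-scene amplitude jitter of scale sigma_spec."""
        wl = np.asarray(wavelengths_nm, dtype=np.float64)
        out = np.full_like(wl, self.baseline)
        for center, width, amp in self.bumps:
            jitter = 1.0 + self.sigma_spec * rng.standard_normal()
            out += amp * jitter * np.exp(-((wl - center) ** 2) / (2.0 * width**2))
        return np.clip(out, 0.0, None)


def default_signatures(sigma_spec: float = 0.02) -> tuple[SpectralSignature, SpectralSignature]:
    """Normal and tumor signatures with clearly separated band profiles."""
    normal = SpectralSignature(
        class_id=0,
        bumps=[(620.0, 60.0, 0.9), (850.0, 120.0, 0.45)],
        baseline=0.20,
        sigma_spec=sigma_spec,
    )
    tumor = SpectralSignature(
        class_id=1,
        bumps=[(680.0, 70.0, 0.55), (930.0, 80.0, 0.85)],
        baseline=0.25,
        sigma_spec=sigma_spec,
    )
    return normal, tumor


@dataclass
class SyntheticConfig:
    """Desk-scale default: 64 x 64 scenes, 16 bands over 550-1000 nm, 80 scenes
    (66 train / 14 test), mixed blob+ring morphology, tumor fraction 0.15-0.45."""

    height: int = 64
    width: int = 64
    n_bands: int = 16
    wavelength_range_nm: tuple[float, float] = (550.0, 1000.0)
    n_scenes: int = 80
    morphology: str = "mix"  # blob | ring | mix (alternates by scene index)
    tumor_fraction: tuple[float, float] = (0.15, 0.45)
    sigma_pix: float = 0.08
    sigma_band: float = 0.04
    sigma_spec: float = 0.02
    illum_amplitude: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        f_lo, f_hi = self.tumor_fraction
        if not (0.0 < f_lo <= f_hi < 1.0):
            raise ValueError(f"tumor fraction range must satisfy 0 < lo <= hi < 1, got {self.tumor_fraction}")
        if self.n_bands < 3:
            raise ValueError("need at least 3 bands")
        if min(self.sigma_pix, self.sigma_band, self.sigma_spec) < 0:
            raise ValueError("noise scales must be non-negative")
        if self.morphology not in ("blob", "ring", "mix"):
            raise ValueError(f"unknown morphology {self.morphology!r}")

    @property
    def wavelengths_nm(self) -> np.ndarray:
        lo, hi = self.wavelength_range_nm
        return np.linspace(lo, hi, self.n_bands)

    def signatures(self) -> tuple[SpectralSignature, SpectralSignature]:
        normal, tumor = default_signatures(self.sigma_spec)
        sep = np.max(np.abs(
            normal.mean_spectrum(self.wavelengths_nm)
            - tumor.mean_spectrum(self.wavelengths_nm)
        ))
        if sep < 1e-3:
            raise ValueError("class mean spectra are not separated")
        return normal, tumor


def _smooth_field(rng: np.random.Generator, h: int, w: int, scale: float) -> np.ndarray:
    """Zero-mean, unit-std smooth random field (Gaussian-filtered white noise)."""
    g = ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma=scale, mode="reflect")
    g -= g.mean()
    std = g.std()
    return g / std if std > 0 else g


def _blob_mask(rng: np.random.Generator, h: int, w: int, k: int) -> np.ndarray:
    """Threshold a smooth field at its k-th largest pixel: exactly k tumor pixels."""
    g = _smooth_field(rng, h, w, scale=max(h, w) / 8.0)
    flat = np.sort(g.ravel())[::-1]
    return (g >= flat[k - 1]).astype(np.uint8)


def _ring_mask(rng: np.random.Generator, h: int, w: int, k: int) -> np.ndarray:
    """Connected annulus of exactly k pixels around a jittered center.

    The k pixels nearest (in |distance - r_mid|) to a circle of radius r_mid
    form a closed band; feasibility requires the band to keep a hole and stay
    inside the image.
    """
    r_img = min(h, w) / 2.0
    jitter = 0.05 * r_img
    cy = (h - 1) / 2.0 + rng.uniform(-jitter, jitter)
    cx = (w - 1) / 2.0 + rng.uniform(-jitter, jitter)
    r_mid = rng.uniform(0.28, 0.34) * min(h, w)
    yy, xx = np.mgrid[0:h, 0:w]
    d = np.hypot(yy - cy, xx - cx)
    band = np.abs(d - r_mid)
    tau = np.sort(band.ravel())[k - 1]
    border = min(cy, cx, h - 1 - cy, w - 1 - cx)
    if r_mid + tau > border or tau > 0.85 * r_mid:
        raise ValueError(
            f"ring morphology infeasible: {k} pixels need a band of half-width "
            f"{tau:.1f} around radius {r_mid:.1f} on a {h}x{w} scene"
        )
    return (band <= tau).astype(np.uint8)


def _scene_rng(seed: int, scene_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, scene_index]))


def generate_scene(cfg: SyntheticConfig, scene_index: int) -> tuple[HyperCube, LabelMask]:
    """Generate one scene; deterministic in (cfg.seed, scene_index)."""
    rng = _scene_rng(cfg.seed, scene_index)
    h, w = cfg.height, cfg.width
    f_lo, f_hi = cfg.tumor_fraction
    n_pix = h * w
    # exact tumor pixel count, clamped so the measured fraction stays in range
    f = rng.uniform(f_lo, f_hi)
    k = int(np.clip(round(f * n_pix), math.ceil(f_lo * n_pix), math.floor(f_hi * n_pix)))
    morph = cfg.morphology
    if morph == "mix":
        morph = "blob" if scene_index % 2 == 0 else "ring"
    mask = _blob_mask(rng, h, w, k) if morph == "blob" else _ring_mask(rng, h, w, k)

    wavelengths = cfg.wavelengths_nm
    normal_sig, tumor_sig = cfg.signatures()
    spectra = np.stack(
        [normal_sig.sample_spectrum(wavelengths, rng),
         tumor_sig.sample_spectrum(wavelengths, rng)]
    )  # (2, C)
    cube = spectra[mask.astype(np.intp)]  # (H, W, C)
    illum = 1.0 + cfg.illum_amplitude * _smooth_field(rng, h, w, scale=max(h, w) / 6.0)
    cube = cube * illum[..., None]
    if cfg.sigma_pix > 0:
        cube = cube + cfg.sigma_pix * rng.standard_normal(cube.shape)
    if cfg.sigma_band > 0:
        cube = cube + cfg.sigma_band * rng.standard_normal(cfg.n_bands)
    cube = np.clip(cube, 0.0, None).astype(np.float32)
    scene_id = f"scene_{scene_index:04d}"
    return HyperCube(cube, wavelengths, scene_id=scene_id), LabelMask(mask)


def generate_dataset(
    cfg: SyntheticConfig,
    out_dir: str | Path,
    labeled_fraction: float = 0.10,
    test_count: int = 14,
    cube_dialect: str = "npz",
) -> DatasetManifest:
    """Write a full synthetic dataset and its manifest under ``out_dir``.

    The last ``test_count`` scene indices form the test split; of the
    remaining training scenes, ``floor(labeled_fraction * n_train)`` are
    labeled (66 train scenes at 10% -> 6 labeled / 60 unlabeled, at 20% ->
    13 / 53).  Masks are written for every scene so oracle evaluation is
    possible, but unlabeled manifest entries list no mask.
    """
    if not (0.0 < labeled_fraction <= 1.0):
        raise ValueError(f"labeled_fraction must be in (0, 1], got {labeled_fraction}")
    if cfg.n_scenes <= test_count:
        raise ValueError(f"n_scenes={cfg.n_scenes} must exceed test_count={test_count}")
    n_train = cfg.n_scenes - test_count
    n_labeled = int(math.floor(labeled_fraction * n_train))
    if n_labeled == 0:
        raise ValueError(
            f"labeled_fraction {labeled_fraction} yields zero labeled scenes of {n_train}"
        )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    suffix = ".npz" if cube_dialect == "npz" else ".raw"
    entries: list[ManifestEntry] = []
    for idx in range(cfg.n_scenes):
        cube, mask = generate_scene(cfg, idx)
        cube_name = f"{cube.scene_id}{suffix}"
        mask_name = f"{cube.scene_id}_mask.png"
        hsi_io.write_cube(cube, out_dir / cube_name, dialect=cube_dialect)
        hsi_io.write_mask(mask, out_dir / mask_name)
        if idx >= n_train:
            split, mask_entry = "test", mask_name
        elif idx < n_labeled:
            split, mask_entry = "labeled", mask_name
        else:
            split, mask_entry = "unlabeled", None
        entries.append(ManifestEntry(cube.scene_id, cube_name, mask_entry, split))
    manifest = DatasetManifest(entries, base_dir=out_dir)
    hsi_io.save_manifest(manifest, out_dir / "manifest.csv")
    return manifest
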