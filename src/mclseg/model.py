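"""MCL-Net: one shared U-Net encoder, n independent U-Net decoders.

Decoder 0 is the *primary* decoder: it receives the bottleneck features FA
unperturbed and is the only decoder run at inference time.  Each auxiliary
decoder i >= 1 receives ``featurenoise(FA)`` — Gaussian noise with its own
(mean, std), resampled every training forward pass from a run-level seeded
stream.  Additive mode (FA + eps, eps ~ N(mu, sigma^2), the default reading
of "Gaussian noise with mean 1" added to the features) and multiplicative
mode (FA * eps) are both available.  With n = 1 the model reduces to a plain
supervised 2-D U-Net.  Skip connections always carry unperturbed encoder
features; only the bottleneck is perturbed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .nn import UNetDecoder, UNetEncoder
from .nn.functional import softmax_channel
from .nn.layers import Module

__all__ = [
    "ModelConfig",
    "MCLNet",
    "build_model",
    "perturb_features",
    "save_checkpoint",
    "load_checkpoint",
]

DEFAULT_NOISE = ((1.0, 1.2), (1.0, 1.5))


@dataclass
class ModelConfig:
    """Architecture and perturbation settings.

    ``noise`` lists one (mean, std) pair per auxiliary decoder, so its length
    must be ``n_decoders - 1``; defaults follow the three-decoder setup with
    N(1, 1.2^2) on one auxiliary branch and N(1, 1.5^2) on the other.
    """

    in_channels: int = 6
    n_classes: int = 2
    n_decoders: int = 3
    depth: int = 4
    base_width: int = 16
    noise: tuple[tuple[float, float], ...] = DEFAULT_NOISE
    noise_mode: str = "additive"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_decoders < 1:
            raise ValueError(f"n_decoders must be >= 1, got {self.n_decoders}")
        self.noise = tuple(tuple(map(float, pair)) for pair in self.noise)
        if self.n_decoders == 1 and len(self.noise) > 0:
            self.noise = ()
        if len(self.noise) != self.n_decoders - 1:
            raise ValueError(
                f"{len(self.noise)} noise specs for {self.n_decoders - 1} "
                "auxiliary decoders"
            )
        if any(sigma < 0 for _, sigma in self.noise):
            raise ValueError("noise std must be >= 0")
        if self.noise_mode not in ("additive", "multiplicative"):
            raise ValueError(f"unknown noise mode {self.noise_mode!r}")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")


def perturb_features(
    fa: np.ndarray,
    mu: float,
    sigma: float,
    rng: np.random.Generator,
    mode: str = "additive",
) -> np.ndarray:
    """Apply elementwise Gaussian feature noise eps ~ N(mu, sigma^2) to FA."""
    eps = (mu + sigma * rng.standard_normal(fa.shape)).astype(fa.dtype)
    if mode == "additive":
        return fa + eps
    if mode == "multiplicative":
        return fa * eps
    raise ValueError(f"unknown noise mode {mode!r}")


class MCLNet(Module):
    """Shared encoder + n decoders; see the module docstring."""

    def __init__(self, cfg: ModelConfig, noise_seed: int | None = None):
        init_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0]))
        self.cfg = cfg
        self.encoder = UNetEncoder(cfg.in_channels, cfg.base_width, cfg.depth, init_rng)
        self.decoders = [
            UNetDecoder(cfg.n_classes, cfg.base_width, cfg.depth, init_rng)
            for _ in range(cfg.n_decoders)
        ]
        self.reseed_noise(cfg.seed if noise_seed is None else noise_seed)

    def reseed_noise(self, seed: int) -> None:
        """Reset the run-level stream the feature noise is drawn from."""
        self.noise_rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))

    @property
    def n_decoders(self) -> int:
        return len(self.decoders)

    def forward(self, batch: np.ndarray, training: bool = False) -> list[np.ndarray]:
        """Probability maps for a channel-last batch (N, H, W, C_in).

        Training mode runs every decoder (auxiliary bottlenecks perturbed) and
        returns n maps of shape (N, H, W, 2); inference mode runs the primary
        decoder only and returns a single map.
        """
        x = self._to_nchw(batch)
        skips, fa, _ = self.encoder.forward(x, train=training)
        maps = []
        n_run = self.n_decoders if training else 1
        for i in range(n_run):
            fa_i = fa
            if training and i > 0:
                mu, sigma = self.cfg.noise[i - 1]
                fa_i = perturb_features(fa, mu, sigma, self.noise_rng, self.cfg.noise_mode)
            logits, _ = self.decoders[i].forward(fa_i, skips, train=training)
            maps.append(softmax_channel(logits).transpose(0, 2, 3, 1))
        return maps

    def _to_nchw(self, batch: np.ndarray) -> np.ndarray:
        batch = np.asarray(batch, dtype=np.float32)
        if batch.ndim == 3:
            batch = batch[None]
        if batch.ndim != 4 or batch.shape[-1] != self.cfg.in_channels:
            raise ValueError(
                f"expected (N, H, W, {self.cfg.in_channels}) input, got {batch.shape}"
            )
        return np.ascontiguousarray(batch.transpose(0, 3, 1, 2))


def build_model(cfg: ModelConfig, noise_seed: int | None = None) -> MCLNet:
    """Construct an MCL-Net with seeded initialization."""
    return MCLNet(cfg, noise_seed=noise_seed)


def save_checkpoint(model: MCLNet, path: str | Path, extra: dict | None = None) -> None:
    """Serialize weights, BN statistics and the architecture config to .npz."""
    arrays: dict[str, np.ndarray] = {}
    for name, p in model.named_parameters():
        arrays[f"param:{name}"] = p.data
    for name, b in model.named_buffers():
        arrays[f"buffer:{name}"] = b
    meta = {"config": asdict(model.cfg), "extra": extra or {}}
    arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path: str | Path) -> tuple[MCLNet, dict]:
    with np.load(Path(path)) as npz:
        meta = json.loads(bytes(npz["meta"].tobytes()).decode())
        cfg_dict = meta["config"]
        cfg_dict["noise"] = tuple(tuple(p) for p in cfg_dict["noise"])
        model = MCLNet(ModelConfig(**cfg_dict))
        params = dict(model.named_parameters())
        for key in npz.files:
            if key.startswith("param:"):
                params[key[6:]].data[...] = npz[key]
        buffers = dict(model.named_buffers())
        for key in npz.files:
            if key.startswith("buffer:"):
                buffers[key[7:]][...] = npz[key]
    return model, meta["extra"]
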