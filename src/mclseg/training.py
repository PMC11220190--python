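"""Semi-supervised training loop and full-image inference.

Each iteration pairs one random crop from a labeled scene with one from an
unlabeled scene (batch 1 + 1).  The labeled crop passes through the encoder
and primary decoder and incurs the supervised CE + Dice loss; the unlabeled
crop passes through the encoder once and through every decoder (auxiliary
bottlenecks perturbed), each decoder's map is turned into a Soft-Hard
pseudo-label, and all ordered decoder pairs incur the multi-consistency
loss.  The total objective is ``lambda * L_s + beta(t) * L_u`` with the
Gaussian warm-up ``beta``; parameters are updated by SGD with momentum.

An *epoch* is one pass over the unlabeled pool (the labeled pool cycles with
reshuffling), since unlabeled scenes dominate; with no unlabeled scenes the
loop degrades to supervised-only training over the labeled pool.  Three
seeded random streams keep ablations orthogonal: data order, feature noise,
and weight initialization.

Full scenes are segmented by tiled inference: overlapping tiles (50% overlap
by default), per-pixel probabilities averaged over covering tiles, then
thresholded at 0.5 (ties to normal).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import hsi_io, losses, metrics
from .hsi_io import DatasetManifest, HyperCube, LabelMask
from .losses import LossWeights, make_pseudo_labels, warmup_beta
from .model import MCLNet, ModelConfig, build_model, load_checkpoint, save_checkpoint
from .nn import SGD
from .nn.functional import softmax_backward, softmax_channel
from .preprocessing import PCAModel, apply_pca, fit_pca

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "TrainState",
    "Batch",
    "SceneStore",
    "make_batches",
    "train_step",
    "train",
    "predict",
    "TrainResult",
]


@dataclass
class TrainConfig:
    """Optimization settings: SGD(lr=0.01, momentum=0.9), 100 epochs,
    batch 1 labeled + 1 unlabeled, random square crops (default 64)."""

    epochs: int = 100
    lr: float = 0.01
    momentum: float = 0.9
    crop_size: int = 64
    max_iterations: int | None = None  # overrides epochs * iters-per-epoch
    seed: int = 0
    deterministic: bool = True
    val_every: int = 1  # epochs between labeled-pool Dice checks

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.crop_size < 1:
            raise ValueError("crop size must be >= 1")


@dataclass
class TrainState:
    t: int = 0
    t_max: int = 1
    loss_supervised: float = 0.0
    loss_consistency: float = 0.0
    loss_total: float = 0.0
    best_dice: float = -1.0


@dataclass
class Batch:
    labeled_x: np.ndarray  # (H, W, k) PCA-reduced crop
    labeled_y: np.ndarray  # (H, W) class map
    unlabeled_x: np.ndarray | None  # (H, W, k) or None in supervised-only mode


@dataclass
class TrainResult:
    model: MCLNet
    pca: PCAModel
    log: pd.DataFrame
    state: TrainState
    checkpoint_path: Path | None = None
    best_checkpoint_path: Path | None = None


class SceneStore:
    """Manifest scenes loaded into memory as PCA-reduced arrays."""

    def __init__(self, manifest: DatasetManifest, pca: PCAModel):
        self.pca = pca
        self.labeled: list[tuple[np.ndarray, np.ndarray]] = []
        self.unlabeled: list[np.ndarray] = []
        for entry in manifest.split_entries("labeled"):
            cube = hsi_io.read_cube(manifest.resolve(entry.cube_path))
            mask = hsi_io.read_mask(manifest.resolve(entry.mask_path))
            if mask.shape != cube.shape[:2]:
                raise ValueError(f"mask/cube shape mismatch for {entry.scene_id}")
            self.labeled.append((apply_pca(pca, cube), mask.data.astype(np.int64)))
        for entry in manifest.split_entries("unlabeled"):
            cube = hsi_io.read_cube(manifest.resolve(entry.cube_path))
            self.unlabeled.append(apply_pca(pca, cube))
        if not self.labeled:
            raise ValueError("training requires at least one labeled scene")


def _random_crop(arr: np.ndarray, size: int, rng: np.random.Generator) -> tuple[int, int]:
    h, w = arr.shape[:2]
    if h < size or w < size:
        raise ValueError(f"scene {h}x{w} smaller than crop size {size}")
    return rng.integers(0, h - size + 1), rng.integers(0, w - size + 1)


class _CyclingSampler:
    """Yields indices in epoch-shuffled order, reshuffling when exhausted."""

    def __init__(self, n: int, rng: np.random.Generator):
        self.n = n
        self.rng = rng
        self.order: list[int] = []

    def next(self) -> int:
        if not self.order:
            self.order = list(self.rng.permutation(self.n))
        return self.order.pop(0)


def make_batches(store: SceneStore, crop_size: int, rng: np.random.Generator,
                 n_iterations: int):
    """Generate ``n_iterations`` mixed batches, deterministic given ``rng``.

    Unlabeled scenes are visited in epoch permutations (each scene exactly
    once per pass); labeled scenes cycle with reshuffling.
    """
    labeled_sampler = _CyclingSampler(len(store.labeled), rng)
    unlabeled_sampler = (
        _CyclingSampler(len(store.unlabeled), rng) if store.unlabeled else None
    )
    for _ in range(n_iterations):
        lx, ly = store.labeled[labeled_sampler.next()]
        i0, j0 = _random_crop(lx, crop_size, rng)
        labeled_x = lx[i0 : i0 + crop_size, j0 : j0 + crop_size]
        labeled_y = ly[i0 : i0 + crop_size, j0 : j0 + crop_size]
        unlabeled_x = None
        if unlabeled_sampler is not None:
            ux = store.unlabeled[unlabeled_sampler.next()]
            i0, j0 = _random_crop(ux, crop_size, rng)
            unlabeled_x = ux[i0 : i0 + crop_size, j0 : j0 + crop_size]
        yield Batch(labeled_x, labeled_y, unlabeled_x)


def train_step(model: MCLNet, batch: Batch, weights: LossWeights,
               optimizer: SGD) -> dict[str, float]:
    """One SGD update; returns the loss components actually applied."""
    beta = warmup_beta(weights.t, weights.t_max,
                       weights.beta_amplitude, weights.beta_shape)

    # labeled pass: encoder + primary decoder, supervised CE + Dice
    xl = np.ascontiguousarray(batch.labeled_x.transpose(2, 0, 1)[None])
    skips, fa, enc_cache = model.encoder.forward(xl, train=True)
    logits, dec_cache = model.decoders[0].forward(fa, skips, train=True)
    probs = softmax_channel(logits)
    l_s, gprobs = losses._supervised_grad(
        probs[0].transpose(1, 2, 0).astype(np.float64), batch.labeled_y
    )
    gprobs_nchw = (weights.lam * gprobs).transpose(2, 0, 1)[None].astype(np.float32)
    glogits = softmax_backward(probs, gprobs_nchw)
    gfa, gskips = model.decoders[0].backward(dec_cache, glogits)
    model.encoder.backward(enc_cache, gskips, gfa)

    # unlabeled pass: all decoders, Soft-Hard pseudo-labels, pairwise loss
    l_u = 0.0
    run_consistency = (
        batch.unlabeled_x is not None and model.n_decoders > 1 and beta > 0.0
    )
    if run_consistency:
        xu = np.ascontiguousarray(batch.unlabeled_x.transpose(2, 0, 1)[None])
        skips_u, fa_u, enc_cache_u = model.encoder.forward(xu, train=True)
        maps, caches, noise_eps = [], [], []
        for i, decoder in enumerate(model.decoders):
            fa_i = fa_u
            eps = None
            if i > 0:
                mu, sigma = model.cfg.noise[i - 1]
                eps = (mu + sigma * model.noise_rng.standard_normal(fa_u.shape)
                       ).astype(fa_u.dtype)
                fa_i = fa_u + eps if model.cfg.noise_mode == "additive" else fa_u * eps
            logits_i, cache_i = decoder.forward(fa_i, skips_u, train=True)
            maps.append(softmax_channel(logits_i))
            caches.append(cache_i)
            noise_eps.append(eps)
        maps_hwc = [m[0].transpose(1, 2, 0).astype(np.float64) for m in maps]
        pseudo = [
            make_pseudo_labels(m, weights.temperature, source=i)
            for i, m in enumerate(maps_hwc)
        ]
        l_u, gmaps = losses._multi_consistency_grad(
            maps_hwc, pseudo, weights.consistency_mode
        )
        gfa_total = np.zeros_like(fa_u)
        gskips_total = [None] * len(skips_u)
        for i, decoder in enumerate(model.decoders):
            g_nchw = (beta * gmaps[i]).transpose(2, 0, 1)[None].astype(np.float32)
            glogits_i = softmax_backward(maps[i], g_nchw)
            gfa_i, gskips_i = decoder.backward(caches[i], glogits_i)
            if model.cfg.noise_mode == "multiplicative" and noise_eps[i] is not None:
                gfa_i = gfa_i * noise_eps[i]
            gfa_total += gfa_i
            for level, gs in enumerate(gskips_i):
                if gs is None:
                    continue
                gskips_total[level] = gs if gskips_total[level] is None else gskips_total[level] + gs
        model.encoder.backward(enc_cache_u, gskips_total, gfa_total)

    l_total = weights.lam * l_s + beta * l_u
    if not np.isfinite(l_total):
        raise FloatingPointError(
            f"non-finite loss at t={weights.t}: L_s={l_s}, L_u={l_u}"
        )
    optimizer.step()
    optimizer.zero_grad()
    return {"L_s": l_s, "L_u": l_u, "beta": beta, "L": l_total}


def _labeled_dice(model: MCLNet, store: SceneStore) -> float:
    """Pooled hard Dice of primary-decoder predictions on the labeled pool."""
    pooled = metrics.ConfusionCounts(0, 0, 0, 0)
    for reduced, mask in store.labeled:
        probs = model.forward(reduced[None], training=False)[0][0]
        pred = (probs[..., 1] > 0.5).astype(np.uint8)
        pooled = pooled + metrics.confusion_counts(pred, mask.astype(np.uint8))
    return metrics.dice_coefficient(pooled)


def train(
    manifest: DatasetManifest,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    weights: LossWeights | None = None,
    pca: PCAModel | None = None,
    out_dir: str | Path | None = None,
) -> TrainResult:
    """Run the full semi-supervised loop; returns model, log and checkpoints.

    If no PCA model is given, one is fitted on all training cubes (labeled +
    unlabeled pooled) with k = ``model_cfg.in_channels``.  ``t_max`` is
    epochs x iterations-per-epoch where an epoch spans the unlabeled pool
    (``max_iterations`` overrides it directly).
    """
    weights = weights or LossWeights()
    if train_cfg.crop_size % 2**model_cfg.depth:
        raise ValueError(
            f"crop size {train_cfg.crop_size} not divisible by 2^depth "
            f"= {2**model_cfg.depth}"
        )
    if pca is None:
        cubes = [
            hsi_io.read_cube(manifest.resolve(e.cube_path))
            for e in manifest.entries
            if e.split in ("labeled", "unlabeled")
        ]
        pca = fit_pca(cubes, k=model_cfg.in_channels, seed=train_cfg.seed)
    store = SceneStore(manifest, pca)

    iters_per_epoch = max(len(store.unlabeled), 1)
    if train_cfg.max_iterations is not None:
        t_max = int(train_cfg.max_iterations)
    else:
        t_max = train_cfg.epochs * iters_per_epoch
    if t_max < 1:
        raise ValueError("t_max must be >= 1")

    model = build_model(model_cfg, noise_seed=train_cfg.seed)
    optimizer = SGD(model.parameters(), lr=train_cfg.lr, momentum=train_cfg.momentum)
    data_rng = np.random.default_rng(np.random.SeedSequence([train_cfg.seed, 2]))
    state = TrainState(t=0, t_max=t_max)
    rows = []
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    batches = make_batches(store, train_cfg.crop_size, data_rng, t_max)
    best_path = None
    for t, batch in enumerate(batches, start=1):
        step_weights = replace(weights, t=t, t_max=t_max)
        parts = train_step(model, batch, step_weights, optimizer)
        state.t = t
        state.loss_supervised = parts["L_s"]
        state.loss_consistency = parts["L_u"]
        state.loss_total = parts["L"]
        rows.append({"t": t, **parts})
        epoch_end = t % iters_per_epoch == 0
        epoch = t // iters_per_epoch
        if epoch_end and epoch % train_cfg.val_every == 0:
            dice = _labeled_dice(model, store)
            if dice > state.best_dice:
                state.best_dice = dice
                if out_dir is not None:
                    best_path = out_dir / "checkpoint_best.npz"
                    save_checkpoint(model, best_path, {"t": t, "labeled_dice": dice})
            logger.info("epoch %d (t=%d): L=%.4f labeled Dice=%.4f",
                        epoch, t, parts["L"], dice)

    log = pd.DataFrame(rows)
    final_path = None
    if out_dir is not None:
        final_path = out_dir / "checkpoint_final.npz"
        save_checkpoint(model, final_path, {"t": state.t})
        log.to_csv(out_dir / "training_log.csv", index=False)
    return TrainResult(model=model, pca=pca, log=log, state=state,
                       checkpoint_path=final_path, best_checkpoint_path=best_path)


def _tile_starts(length: int, tile: int, stride: int) -> list[int]:
    if tile >= length:
        return [0]
    starts = list(range(0, length - tile, stride))
    starts.append(length - tile)
    return starts


def predict(
    model: MCLNet | str | Path,
    cube: HyperCube,
    pca: PCAModel,
    tile_size: int | None = None,
    overlap: float = 0.5,
) -> tuple[LabelMask, np.ndarray]:
    """Segment a full scene with the primary decoder via overlapping tiles.

    Returns the thresholded mask (tumor probability > 0.5; ties to normal)
    and the averaged tumor-probability map.
    """
    if not isinstance(model, MCLNet):
        model, _ = load_checkpoint(model)
    if not 0.0 <= overlap < 1.0:
        raise ValueError(f"overlap must be in [0, 1), got {overlap}")
    reduced = apply_pca(pca, cube)
    h, w = reduced.shape[:2]
    factor = 2**model.cfg.depth
    if tile_size is None:
        tile_size = min(h, w, 64)
        tile_size -= tile_size % factor
    if tile_size % factor or tile_size < factor:
        raise ValueError(f"tile size {tile_size} not divisible by 2^depth = {factor}")
    if tile_size > min(h, w):
        raise ValueError(f"tile size {tile_size} exceeds scene {h}x{w}")
    stride = max(1, int(round(tile_size * (1.0 - overlap))))
    prob_sum = np.zeros((h, w), dtype=np.float64)
    cover = np.zeros((h, w), dtype=np.float64)
    for i0 in _tile_starts(h, tile_size, stride):
        for j0 in _tile_starts(w, tile_size, stride):
            tile = reduced[i0 : i0 + tile_size, j0 : j0 + tile_size]
            probs = model.forward(tile[None], training=False)[0][0]
            prob_sum[i0 : i0 + tile_size, j0 : j0 + tile_size] += probs[..., 1]
            cover[i0 : i0 + tile_size, j0 : j0 + tile_size] += 1.0
    tumor_prob = prob_sum / cover
    return LabelMask((tumor_prob > 0.5).astype(np.uint8)), tumor_prob
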