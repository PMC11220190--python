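"""Batching, the semi-supervised step, the loop, and tiled inference."""

import numpy as np
import pytest

from mclseg import hsi_io
from mclseg.losses import LossWeights, warmup_beta
from mclseg.model import ModelConfig, build_model
from mclseg.nn import SGD
from mclseg.training import (
    Batch,
    SceneStore,
    TrainConfig,
    make_batches,
    predict,
    train,
    train_step,
)
from mclseg.preprocessing import fit_pca, apply_pca


def model_cfg(**kw):
    base = dict(in_channels=3, n_decoders=3, depth=2, base_width=4, seed=0)
    base.update(kw)
    return ModelConfig(**base)


class FakeStore:
    """In-memory stand-in for SceneStore (synthetic arrays, no disk)."""

    def __init__(self, rng, n_labeled, n_unlabeled, size=16, channels=3):
        self.labeled = [
            (rng.random((size, size, channels)).astype(np.float32),
             rng.integers(0, 2, size=(size, size)))
            for _ in range(n_labeled)
        ]
        self.unlabeled = [
            rng.random((size, size, channels)).astype(np.float32)
            for _ in range(n_unlabeled)
        ]


def test_batches_cycle_labeled_and_cover_unlabeled(rng):
    """One 60-iteration epoch with 6 labeled / 60 unlabeled scenes visits
    every unlabeled scene exactly once and each labeled scene 10 +- 1 times."""
    store = FakeStore(rng, 6, 60, size=8)
    for i, (lx, ly) in enumerate(store.labeled):
        lx[0, 0, 0] = i  # tag scenes via a corner value
    for i, ux in enumerate(store.unlabeled):
        ux[0, 0, 0] = 100 + i
    # crop = full size so tags survive cropping
    batches = list(make_batches(store, 8, np.random.default_rng(0), 60))
    assert len(batches) == 60
    unlabeled_seen = sorted(int(b.unlabeled_x[0, 0, 0]) for b in batches)
    assert unlabeled_seen == list(range(100, 160))
    labeled_counts = np.bincount(
        [int(b.labeled_x[0, 0, 0]) for b in batches], minlength=6
    )
    assert all(9 <= c <= 11 for c in labeled_counts)


def test_batches_deterministic_given_seed(rng):
    store = FakeStore(rng, 2, 3, size=8)
    b1 = list(make_batches(store, 4, np.random.default_rng(5), 12))
    b2 = list(make_batches(store, 4, np.random.default_rng(5), 12))
    for a, b in zip(b1, b2):
        np.testing.assert_array_equal(a.labeled_x, b.labeled_x)
        np.testing.assert_array_equal(a.unlabeled_x, b.unlabeled_x)


def test_supervised_only_mode_without_unlabeled(rng):
    store = FakeStore(rng, 2, 0, size=8)
    batches = list(make_batches(store, 8, np.random.default_rng(0), 4))
    assert all(b.unlabeled_x is None for b in batches)


def test_train_step_bookkeeping_identity(rng):
    model = build_model(model_cfg())
    opt = SGD(model.parameters(), lr=0.01, momentum=0.9)
    store = FakeStore(rng, 1, 1, size=8)
    batch = Batch(*store.labeled[0], store.unlabeled[0])
    w = LossWeights(t=50, t_max=100)
    parts = train_step(model, batch, w, opt)
    beta = warmup_beta(50, 100)
    assert parts["beta"] == pytest.approx(beta, abs=1e-12)
    assert parts["L"] == pytest.approx(
        w.lam * parts["L_s"] + beta * parts["L_u"], abs=1e-6
    )
    assert parts["L_u"] > 0


def test_zero_beta_matches_pure_supervised_updates(rng):
    """With beta = 0 and lambda = 1 the update equals plain supervised U-Net
    training of encoder + primary decoder; auxiliary weights do not move."""
    store = FakeStore(rng, 1, 1, size=8)
    batch = Batch(*store.labeled[0], store.unlabeled[0])
    w = LossWeights(lam=1.0, beta_amplitude=0.0, t=1, t_max=10)

    mcl = build_model(model_cfg())
    aux_before = {
        name: p.data.copy() for name, p in mcl.named_parameters()
        if name.startswith("decoders.1") or name.startswith("decoders.2")
    }
    opt = SGD(mcl.parameters(), lr=0.01, momentum=0.9)
    train_step(mcl, batch, w, opt)
    for name, p in mcl.named_parameters():
        if name in aux_before:
            np.testing.assert_array_equal(p.data, aux_before[name])

    # reference: the same seeds but a single-decoder model
    ref = build_model(model_cfg(n_decoders=1))
    opt_ref = SGD(ref.parameters(), lr=0.01, momentum=0.9)
    train_step(ref, Batch(batch.labeled_x, batch.labeled_y, None), w, opt_ref)
    ref_params = dict(ref.named_parameters())
    for name, p in mcl.named_parameters():
        if name.startswith("encoder") or name.startswith("decoders.0"):
            np.testing.assert_allclose(
                p.data, ref_params[name].data, atol=1e-7, err_msg=name
            )


def test_pseudo_label_targets_receive_no_gradient(rng):
    """Recomputing the targets from detached copies changes nothing: the
    gradients already flow only through the prediction side."""
    store = FakeStore(rng, 1, 1, size=8)
    batch = Batch(*store.labeled[0], store.unlabeled[0])
    w = LossWeights(t=10, t_max=10)
    grads = {}
    for run in range(2):
        model = build_model(model_cfg())
        model.reseed_noise(123)
        opt = SGD(model.parameters(), lr=0.01, momentum=0.9)
        train_step(model, batch, w, opt)
        grads[run] = {n: p.data.copy() for n, p in model.named_parameters()}
    for name in grads[0]:
        np.testing.assert_array_equal(grads[0][name], grads[1][name])


def test_train_loop_logs_beta_trace_and_t_max(tiny_dataset):
    mc = model_cfg(in_channels=3)
    tc = TrainConfig(epochs=2, crop_size=16, seed=0, val_every=1)
    result = train(tiny_dataset, mc, tc)
    n_unlabeled = tiny_dataset.counts()["unlabeled"]
    assert result.state.t_max == 2 * n_unlabeled
    expected_beta = [warmup_beta(t, result.state.t_max) for t in result.log.t]
    np.testing.assert_allclose(result.log.beta.values, expected_beta, atol=1e-12)
    # final-iteration beta reaches the warm-up amplitude
    assert result.log.beta.iloc[-1] == pytest.approx(0.001, abs=1e-12)
    # reported L is the recombination of its logged parts
    recombined = 0.5 * result.log.L_s + result.log.beta * result.log.L_u
    np.testing.assert_allclose(result.log.L.values, recombined.values, atol=1e-6)


def test_train_deterministic_loss_trace(tiny_dataset):
    mc = model_cfg(in_channels=3)
    tc = TrainConfig(epochs=1, crop_size=16, seed=3, val_every=5)
    r1 = train(tiny_dataset, mc, tc)
    r2 = train(tiny_dataset, mc, tc)
    np.testing.assert_array_equal(r1.log.L.values, r2.log.L.values)


def test_doubling_epochs_never_decreases_t_max(tiny_dataset):
    mc = model_cfg(in_channels=3)
    t1 = train(tiny_dataset, mc, TrainConfig(epochs=1, crop_size=16, val_every=9)).state.t_max
    t2 = train(tiny_dataset, mc, TrainConfig(epochs=2, crop_size=16, val_every=9)).state.t_max
    assert t2 >= t1 and t2 == 2 * t1


def test_crop_size_must_match_depth(tiny_dataset):
    with pytest.raises(ValueError, match="crop size"):
        train(tiny_dataset, model_cfg(depth=3), TrainConfig(epochs=1, crop_size=12))


def test_predict_single_tile_equals_direct_forward(tiny_dataset, rng):
    entry = tiny_dataset.split_entries("test")[0]
    cube = hsi_io.read_cube(tiny_dataset.resolve(entry.cube_path))
    cubes = [cube]
    pca = fit_pca(cubes, k=3)
    model = build_model(model_cfg())
    mask, prob = predict(model, cube, pca, tile_size=32, overlap=0.5)
    direct = model.forward(apply_pca(pca, cube)[None], training=False)[0][0]
    np.testing.assert_allclose(prob, direct[..., 1], atol=1e-6)
    np.testing.assert_array_equal(mask.data, (direct[..., 1] > 0.5).astype(np.uint8))


def test_predict_tiled_matches_whole_image(tiny_dataset):
    """Tiled inference with averaging approximates the single-pass forward."""
    entry = tiny_dataset.split_entries("test")[0]
    cube = hsi_io.read_cube(tiny_dataset.resolve(entry.cube_path))
    pca = fit_pca([cube], k=3)
    model = build_model(model_cfg())
    _, whole = predict(model, cube, pca, tile_size=32)
    _, tiled = predict(model, cube, pca, tile_size=16, overlap=0.5)
    # BN statistics are global, so tiles differ slightly from the whole pass
    assert np.mean(np.abs(whole - tiled)) < 0.1


def test_predict_overlap_invariant_on_constant_input(rng):
    h = w = 32
    cube = hsi_io.HyperCube(
        np.full((h, w, 4), 0.5, dtype=np.float32), np.linspace(550, 1000, 4)
    )
    varying = hsi_io.HyperCube(
        np.clip(rng.random((h, w, 4)), 0, None).astype(np.float32),
        np.linspace(550, 1000, 4),
    )
    pca = fit_pca([varying], k=3)
    model = build_model(model_cfg())
    m0, p0 = predict(model, cube, pca, tile_size=16, overlap=0.0)
    m50, p50 = predict(model, cube, pca, tile_size=16, overlap=0.5)
    np.testing.assert_array_equal(m0.data, m50.data)
    # probabilities agree up to convolution border effects of the tiles
    np.testing.assert_allclose(p0, p50, atol=1e-3)


def test_predict_validation(tiny_dataset):
    entry = tiny_dataset.split_entries("test")[0]
    cube = hsi_io.read_cube(tiny_dataset.resolve(entry.cube_path))
    pca = fit_pca([cube], k=3)
    model = build_model(model_cfg())
    with pytest.raises(ValueError, match="2\\^depth"):
        predict(model, cube, pca, tile_size=10)
    with pytest.raises(ValueError, match="exceeds"):
        predict(model, cube, pca, tile_size=64)
    wrong = hsi_io.HyperCube(
        np.ones((32, 32, 5), dtype=np.float32), np.linspace(550, 1000, 5)
    )
    with pytest.raises(ValueError):
        predict(model, wrong, pca)
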