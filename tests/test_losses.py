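"""Closed-form values, brute-force oracles and invariants of the objectives."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mclseg import losses
from mclseg.losses import (
    LossWeights,
    PseudoLabels,
    cross_entropy_loss,
    dice_loss,
    hard_label,
    make_pseudo_labels,
    multi_consistency_loss,
    sharpen,
    supervised_loss,
    total_loss,
    warmup_beta,
)

EPS = losses.DICE_EPS


def one_pixel(p_normal: float) -> np.ndarray:
    return np.array([[[p_normal, 1.0 - p_normal]]])


# ---------------------------------------------------------------------------
# independent brute-force oracles


def oracle_ce(probs, target):
    """Literal per-pixel -log p(target), python loops."""
    h, w, _ = probs.shape
    total = 0.0
    for i in range(h):
        for j in range(w):
            p = min(max(probs[i, j, int(target[i, j])], 1e-7), 1 - 1e-7)
            total += -np.log(p)
    return total / (h * w)


def oracle_dice(probs, target):
    terms = []
    for c in range(2):
        num = den_p = den_y = 0.0
        h, w, _ = probs.shape
        for i in range(h):
            for j in range(w):
                y = 1.0 if target[i, j] == c else 0.0
                num += 2.0 * probs[i, j, c] * y
                den_p += probs[i, j, c]
                den_y += y
        terms.append(1.0 - (num + EPS) / (den_p + den_y + EPS))
    return sum(terms) / 2.0


def oracle_multi_consistency(maps, pseudo, mode="hard"):
    """Naive double loop over ordered decoder pairs."""
    total = 0.0
    for i, m in enumerate(maps):
        for j, pl in enumerate(pseudo):
            if i == j:
                continue
            target = pl.hard if mode == "hard" else pl.soft
            if mode == "hard":
                total += oracle_ce(m, target) + oracle_dice(m, target)
            else:
                tch = np.stack([1 - target, target], axis=-1)
                clipped = np.clip(m, 1e-7, 1 - 1e-7)
                total += float(-(tch * np.log(clipped)).mean(axis=(0, 1)).sum())
                for c in range(2):
                    pass  # soft dice handled by the package formula below
                num = 2 * (m * tch).sum(axis=(0, 1)) + EPS
                den = m.sum(axis=(0, 1)) + tch.sum(axis=(0, 1)) + EPS
                total += float(np.mean(1 - num / den))
    return total


# ---------------------------------------------------------------------------
# cross-entropy and Dice


def test_cross_entropy_closed_forms():
    # perfect one-hot prediction
    probs = np.zeros((2, 2, 2))
    target = np.array([[0, 1], [1, 0]])
    probs[..., 0] = 1 - target
    probs[..., 1] = target
    assert cross_entropy_loss(probs, target) <= 1e-6
    # uniform prediction -> ln 2
    uniform = np.full((3, 3, 2), 0.5)
    assert cross_entropy_loss(uniform, np.zeros((3, 3))) == pytest.approx(
        np.log(2), abs=1e-9
    )
    # single pixel (0.8, 0.2), target tumor -> -ln 0.2
    assert cross_entropy_loss(one_pixel(0.8), np.ones((1, 1))) == pytest.approx(
        -np.log(0.2), abs=1e-9
    )


def test_dice_closed_forms():
    probs = np.zeros((2, 2, 2))
    target = np.array([[0, 1], [1, 0]])
    probs[..., 0] = 1 - target
    probs[..., 1] = target
    assert dice_loss(probs, target) <= 1e-4
    # single pixel (0.8, 0.2) vs tumor: class-0 term ~ 1, class-1 term 1 - 0.4/1.2
    val = dice_loss(one_pixel(0.8), np.ones((1, 1)))
    assert val == pytest.approx(oracle_dice(one_pixel(0.8), np.ones((1, 1))), abs=1e-12)
    assert val == pytest.approx(0.83333, abs=1e-4)
    # disjoint one-hots -> ~1
    assert dice_loss(one_pixel(1.0), np.ones((1, 1))) == pytest.approx(1.0, abs=1e-4)


def test_supervised_loss_is_ce_plus_dice_single_pixel():
    # probs (0.9, 0.1), target normal: -ln 0.9 + dice
    probs = one_pixel(0.9)
    target = np.zeros((1, 1))
    expected = oracle_ce(probs, target) + oracle_dice(probs, target)
    assert supervised_loss(probs, target) == pytest.approx(expected, abs=1e-12)
    # the rounded hand value treats the empty class's Dice term as exactly 1;
    # the eps = 1e-5 smoothing shifts it by ~5e-5
    assert supervised_loss(probs, target) == pytest.approx(0.63168, abs=1e-4)


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=20, deadline=None)
def test_ce_and_dice_match_oracle_on_random_maps(seed):
    rng = np.random.default_rng(seed)
    h, w = rng.integers(1, 6, size=2)
    raw = rng.random((h, w, 2))
    probs = raw / raw.sum(axis=-1, keepdims=True)
    target = rng.integers(0, 2, size=(h, w))
    assert cross_entropy_loss(probs, target) == pytest.approx(
        oracle_ce(probs, target), abs=1e-9
    )
    assert dice_loss(probs, target) == pytest.approx(
        oracle_dice(probs, target), abs=1e-9
    )


def test_loss_gradients_match_finite_differences(rng):
    probs = rng.random((3, 3, 2))
    probs /= probs.sum(axis=-1, keepdims=True)
    target = rng.integers(0, 2, size=(3, 3))
    for fn in (losses._cross_entropy_grad, losses._dice_grad):
        val, grad = fn(probs, target)
        eps = 1e-6
        for idx in [(0, 0, 0), (1, 2, 1), (2, 1, 0)]:
            bumped = probs.copy()
            bumped[idx] += eps
            num = (fn(bumped, target, want_grad=False)[0] - val) / eps
            assert num == pytest.approx(grad[idx], abs=1e-4)


def test_shape_mismatch_rejected():
    with pytest.raises(ValueError):
        cross_entropy_loss(np.full((2, 2, 2), 0.5), np.zeros((3, 3)))
    with pytest.raises(ValueError):
        dice_loss(np.full((2, 2, 3), 0.5), np.zeros((2, 2)))


# ---------------------------------------------------------------------------
# Soft-Hard pseudo-labels


def test_sharpen_fixed_point_identity_and_example():
    for t in (0.01, 0.1, 0.5, 1.0, 2.0):
        assert sharpen(np.array(0.5), t) == pytest.approx(0.5, abs=1e-12)
    p = np.linspace(0, 1, 11)
    np.testing.assert_allclose(sharpen(p, 1.0), p, atol=1e-12)
    assert sharpen(np.array(0.8), 0.5) == pytest.approx(0.64 / 0.68, abs=1e-9)


def test_sharpen_sharpens_below_unit_temperature():
    p = np.linspace(0, 1, 101)
    for t in (0.1, 0.5, 0.9):
        s = sharpen(p, t)
        assert np.all(np.abs(s - 0.5) >= np.abs(p - 0.5) - 1e-12)
        interior = (p > 1e-9) & (p < 1 - 1e-9) & (np.abs(p - 0.5) > 1e-9)
        assert np.all(np.abs(s[interior] - 0.5) > np.abs(p[interior] - 0.5))


def test_sharpen_rejects_bad_inputs():
    with pytest.raises(ValueError):
        sharpen(np.array(0.5), 0.0)
    with pytest.raises(ValueError):
        sharpen(np.array(1.5), 0.5)


def test_hard_label_thresholds_and_tie_break():
    assert hard_label(np.array(0.941)) == 1
    assert hard_label(np.array(0.5)) == 0
    assert hard_label(np.array(0.499)) == 0


def test_hard_label_of_sharpen_is_temperature_invariant():
    """Sharpening is strictly monotone, so the hard path cannot depend on T."""
    p = np.linspace(0, 1, 101)
    baseline = hard_label(p)
    for t in (0.01, 0.1, 0.5, 1.0):
        np.testing.assert_array_equal(hard_label(sharpen(p, t)), baseline)


# ---------------------------------------------------------------------------
# multi-consistency


def test_multi_consistency_empty_pair_sum_and_agreement():
    m = np.zeros((2, 2, 2))
    m[..., 0] = 1.0
    pl = make_pseudo_labels(m, 0.5)
    assert multi_consistency_loss([m], [pl]) == 0.0
    maps = [m.copy() for _ in range(3)]
    pseudo = [make_pseudo_labels(x, 0.5, i) for i, x in enumerate(maps)]
    assert multi_consistency_loss(maps, pseudo) <= 1e-4


def test_multi_consistency_two_decoder_hand_value():
    m1 = one_pixel(0.8)  # tumor prob 0.2 -> P_H = 0
    m2 = one_pixel(0.3)  # tumor prob 0.7 -> P_H = 1
    pseudo = [make_pseudo_labels(m, 0.5, i) for i, m in enumerate((m1, m2))]
    expected = oracle_multi_consistency([m1, m2], pseudo)
    got = multi_consistency_loss([m1, m2], pseudo)
    assert got == pytest.approx(expected, abs=1e-9)
    assert got == pytest.approx(4.41597, abs=1e-4)


@given(st.integers(0, 2**31 - 1), st.sampled_from([2, 3]))
@settings(max_examples=50, deadline=None)
def test_multi_consistency_matches_naive_double_loop(seed, n):
    rng = np.random.default_rng(seed)
    h, w = rng.integers(1, 9, size=2)
    maps = []
    for _ in range(n):
        raw = rng.random((h, w, 2))
        maps.append(raw / raw.sum(axis=-1, keepdims=True))
    mode = rng.choice(["hard", "soft"])
    pseudo = [make_pseudo_labels(m, 0.5, i) for i, m in enumerate(maps)]
    assert multi_consistency_loss(maps, pseudo, mode) == pytest.approx(
        oracle_multi_consistency(maps, pseudo, mode), abs=1e-6
    )


def test_multi_consistency_gradient_only_through_map_side(rng):
    """The target (pseudo-label) side is detached: altering pseudo-label j
    changes decoder i's loss target but contributes no gradient path, and the
    analytic gradient matches finite differences taken with targets frozen."""
    maps = []
    for _ in range(2):
        raw = rng.random((2, 2, 2))
        maps.append(raw / raw.sum(axis=-1, keepdims=True))
    pseudo = [make_pseudo_labels(m, 0.5, i) for i, m in enumerate(maps)]
    val, grads = losses._multi_consistency_grad(maps, pseudo)
    eps = 1e-6
    bumped = [m.copy() for m in maps]
    bumped[0][0, 0, 1] += eps
    # targets recomputed from ORIGINAL maps: frozen target side
    num = (losses._multi_consistency_grad(bumped, pseudo, want_grad=False)[0] - val) / eps
    assert num == pytest.approx(grads[0][0, 0, 1], abs=1e-4)


def test_multi_consistency_input_validation():
    m = np.full((1, 1, 2), 0.5)
    pl = make_pseudo_labels(m, 0.5)
    with pytest.raises(ValueError):
        multi_consistency_loss([], [])
    with pytest.raises(ValueError):
        multi_consistency_loss([m, m], [pl])


# ---------------------------------------------------------------------------
# warm-up and total


def test_warmup_beta_closed_forms():
    assert warmup_beta(100, 100) == pytest.approx(0.001, abs=1e-15)
    assert warmup_beta(0, 100) == pytest.approx(0.001 * np.exp(-5), rel=1e-9)
    assert warmup_beta(50, 100) == pytest.approx(0.001 * np.exp(-1.25), rel=1e-9)
    assert warmup_beta(0, 100) == pytest.approx(6.7379e-6, rel=1e-4)
    assert warmup_beta(50, 100) == pytest.approx(2.8650e-4, rel=1e-4)


def test_warmup_beta_monotone_and_validated():
    t_max = 37
    values = [warmup_beta(t, t_max) for t in range(t_max + 1)]
    assert all(b2 >= b1 for b1, b2 in zip(values, values[1:]))
    with pytest.raises(ValueError):
        warmup_beta(0, 0)
    with pytest.raises(ValueError):
        warmup_beta(5, 4)


def test_total_loss_combination():
    w = LossWeights(lam=0.5, t=100, t_max=100)
    assert total_loss(0.63168, 4.41597, w) == pytest.approx(
        0.5 * 0.63168 + 0.001 * 4.41597, abs=1e-9
    )
    assert total_loss(0.63168, 4.41597, w) == pytest.approx(0.32026, abs=1e-4)
    w0 = LossWeights(lam=0.0, beta_amplitude=0.0, t=0, t_max=100)
    assert total_loss(1.0, 1.0, w0) == pytest.approx(0.0, abs=1e-12)
    # no unlabeled term -> just lambda * L_s
    assert total_loss(2.0, 0.0, w) == pytest.approx(0.5 * 2.0, abs=1e-9)
    with pytest.raises(ValueError):
        total_loss(np.nan, 0.0, w)


def test_loss_weights_validation():
    with pytest.raises(ValueError):
        LossWeights(temperature=0.0)
    with pytest.raises(ValueError):
        LossWeights(consistency_mode="fuzzy")
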