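"""Loss terms against hand-computed oracles, invariants and gradient
checks."""

import numpy as np
import pytest

from causalseg import nn, objective
from causalseg.objective import (LossWeights, PriorTemplate, balanced_ce_loss,
                                 causal_loss, dice_loss, smoothness_loss,
                                 total_loss)
from causalseg.scm import CausalGraph


def _probs_from(labels, n_classes=4, conf=1.0):
    onehot = nn.one_hot(labels, n_classes)
    uniform = np.full_like(onehot, 1.0 / n_classes)
    return onehot * conf + uniform * (1 - conf)


# ---------------------------------------------------------------------------
# Dice
# ---------------------------------------------------------------------------

def test_dice_perfect_prediction_near_zero(rng):
    labels = rng.integers(0, 4, size=(1, 4, 4, 4))
    probs = _probs_from(labels)
    assert float(dice_loss(probs, nn.one_hot(labels, 4)).data) < 1e-4


def test_dice_uniform_probs_on_single_class_target_matches_closed_form():
    """Uniform 0.25 over 4 classes, all-class-1 target on a 2x2x2 grid.

    Per-class soft Dice: class 1: (2·0.25·8 + ε)/(0.25·8 + 8 + ε);
    classes 2,3: (0 + ε)/(2 + ε). Loss = 1 − mean over classes 1..3.
    """
    labels = np.ones((1, 2, 2, 2), dtype=int)
    probs = np.full((1, 4, 2, 2, 2), 0.25)
    eps = 1e-5
    d1 = (2 * 0.25 * 8 + eps) / (0.25 * 8 + 8 + eps)
    d23 = eps / (2 + eps)
    expected = 1 - (d1 + 2 * d23) / 3
    got = float(dice_loss(probs, nn.one_hot(labels, 4)).data)
    assert got == pytest.approx(expected, rel=1e-5)


def test_dice_absent_class_contributes_zero_loss():
    # only background and class 1 appear and are predicted perfectly
    labels = np.zeros((1, 2, 2, 2), dtype=int)
    labels[0, 0] = 1
    probs = _probs_from(labels)
    assert float(dice_loss(probs, nn.one_hot(labels, 4)).data) < 1e-4


def test_dice_is_permutation_invariant_to_voxel_order(rng):
    labels = rng.integers(0, 4, size=(1, 2, 2, 2))
    probs = rng.dirichlet(np.ones(4), size=8).T.reshape(1, 4, 2, 2, 2)
    base = float(dice_loss(probs, nn.one_hot(labels, 4)).data)
    perm = rng.permutation(8)
    probs_p = probs.reshape(1, 4, 8)[:, :, perm].reshape(1, 4, 2, 2, 2)
    labels_p = labels.reshape(1, 8)[:, perm].reshape(1, 2, 2, 2)
    assert float(dice_loss(probs_p, nn.one_hot(labels_p, 4)).data) \
        == pytest.approx(base, rel=1e-6)


# ---------------------------------------------------------------------------
# Balanced cross-entropy
# ---------------------------------------------------------------------------

def test_balanced_ce_perfect_prediction_tiny():
    labels = np.zeros((1, 2, 2, 2), dtype=int)
    probs = np.zeros((1, 4, 2, 2, 2))
    probs[:, 0] = 1.0
    assert float(balanced_ce_loss(probs, nn.one_hot(labels, 4)).data) <= 1e-6


def test_balanced_ce_matches_hand_weighted_nll():
    """2-class toy: 3 background + 1 foreground voxel, uniform probs.

    Weights ∝ (1/3, 1/1) normalised to mean 1 → (0.5, 1.5); each voxel's
    NLL is log 2 → loss = (3·0.5 + 1·1.5)/4 · log 2 = 0.75·log 2.
    """
    labels = np.array([0, 0, 0, 1]).reshape(1, 4, 1, 1)
    probs = np.full((1, 2, 4, 1, 1), 0.5)
    got = float(balanced_ce_loss(probs, nn.one_hot(labels, 2)).data)
    assert got == pytest.approx(0.75 * np.log(2), rel=1e-6)


def test_balanced_ce_equal_frequencies_reduce_to_plain_ce(rng):
    labels = np.array([0, 1, 2, 3]).reshape(1, 4, 1, 1)
    probs = rng.dirichlet(np.ones(4), size=4).T.reshape(1, 4, 4, 1, 1)
    got = float(balanced_ce_loss(probs, nn.one_hot(labels, 4)).data)
    plain = -np.mean([np.log(probs[0, labels[0, i, 0, 0], i, 0, 0])
                      for i in range(4)])
    assert got == pytest.approx(plain, rel=1e-5)


# ---------------------------------------------------------------------------
# Causal loss
# ---------------------------------------------------------------------------

def test_causal_loss_zero_weights_is_zero():
    g = CausalGraph()
    assert float(causal_loss(g, [], PriorTemplate(), 0.0, 0.0).data) == 0.0


def test_causal_loss_without_samples_is_sparsity_only():
    g = CausalGraph()
    sparsity = float((nn.softplus(g.w_mz_raw).sum()
                      + (nn.softplus(g.w_my_raw)
                         * nn.Tensor(g.mask_my)).sum()
                      + nn.softplus(g.w_zy_raw).sum()).data)
    got = float(causal_loss(g, [], PriorTemplate(), 0.01, 1.0).data)
    assert got == pytest.approx(0.01 * sparsity, rel=1e-6)


def test_sparsity_is_l1_of_masked_gates():
    from causalseg.scm import regularizer_terms
    g = CausalGraph()
    g.mask_my = np.zeros_like(g.mask_my)   # forbid all m→Y edges
    val, _ = regularizer_terms(g)
    expect = float((nn.softplus(g.w_mz_raw).sum()
                    + nn.softplus(g.w_zy_raw).sum()).data)
    assert float(val.data) == pytest.approx(expect, rel=1e-6)
    # doubling every effective weight doubles the value (homogeneity)
    raw_of = lambda v: float(np.log(np.expm1(v)))
    g2, g3 = CausalGraph(), CausalGraph()
    for graph, scale in ((g2, 0.5), (g3, 1.0)):
        graph.w_mz_raw.data[:] = raw_of(scale)
        graph.w_my_raw.data[:] = raw_of(scale)
        graph.w_zy_raw.data[:] = raw_of(scale)
    v2, _ = regularizer_terms(g2)
    v3, _ = regularizer_terms(g3)
    assert float(v3.data) == pytest.approx(2 * float(v2.data), rel=1e-6)


def test_prior_term_zero_when_realized_matches_template():
    g = CausalGraph()
    sparsity = float(causal_loss(g, [], PriorTemplate(), 1.0, 0.0).data)
    # realized delta equal to the template over the region
    delta = np.zeros((1, 4, 2, 2, 2))
    region = np.full((1, 2, 2, 2), 3)     # all voxels labelled ET
    delta[:, 3] = 0.9                     # ET loses ~all its probability
    delta[:, 0] = -0.9                    # which reappears as background
    loss = causal_loss(g, [("ablate:t1ce", nn.Tensor(delta), region)],
                       PriorTemplate(), 1.0, 5.0)
    assert float(loss.data) == pytest.approx(sparsity, abs=1e-6)


# ---------------------------------------------------------------------------
# Smoothness
# ---------------------------------------------------------------------------

def test_smoothness_constant_logits_zero(rng):
    logits = np.ones((1, 4, 3, 3, 3)) * 2.0
    vol = rng.normal(size=(1, 4, 3, 3, 3))
    assert float(smoothness_loss(logits, vol).data) == 0.0


def test_smoothness_hand_computed_two_voxel_instance():
    """Constant image, one unit logit step along x on a 2-voxel grid:
    penalty = exp(0)·1² / n_pairs with n_pairs = 1."""
    logits = np.zeros((1, 1, 2, 1, 1))
    logits[0, 0, 1] = 1.0
    vol = np.ones((1, 4, 2, 1, 1))
    got = float(smoothness_loss(logits, vol, sigma_i=1.0).data)
    assert got == pytest.approx(1.0, rel=1e-6)


def test_smoothness_decreases_with_intensity_contrast():
    logits = np.zeros((1, 1, 2, 1, 1))
    logits[0, 0, 1] = 1.0
    values = []
    for contrast in (0.0, 0.5, 1.0, 2.0):
        vol = np.zeros((1, 4, 2, 1, 1))
        vol[:, :, 1] = contrast
        values.append(float(smoothness_loss(logits, vol, sigma_i=1.0).data))
    assert all(a >= b for a, b in zip(values, values[1:]))
    assert values[0] > values[-1]


# ---------------------------------------------------------------------------
# Composite
# ---------------------------------------------------------------------------

def test_total_is_dice_only_when_other_weights_zero():
    w = LossWeights(alpha=0.0, beta=0.0, gamma=0.0)
    comps = {"dice": nn.Tensor(0.7), "ce": nn.Tensor(5.0),
             "causal": nn.Tensor(3.0), "smooth": nn.Tensor(2.0)}
    total, breakdown = total_loss(comps, w)
    assert float(total.data) == pytest.approx(0.7)


def test_doubling_beta_doubles_causal_contribution():
    comps = {"dice": nn.Tensor(0.5), "ce": nn.Tensor(0.2),
             "causal": nn.Tensor(0.4), "smooth": nn.Tensor(0.1)}
    _, b1 = total_loss(comps, LossWeights(beta=1.0))
    _, b2 = total_loss(comps, LossWeights(beta=2.0))
    assert b2["causal"] == pytest.approx(2 * b1["causal"])


def test_breakdown_sums_to_total():
    comps = {"dice": nn.Tensor(0.5), "ce": nn.Tensor(0.2),
             "causal": nn.Tensor(0.4), "smooth": nn.Tensor(0.1),
             "extra": nn.Tensor(0.05)}
    total, breakdown = total_loss(comps, LossWeights())
    parts = sum(v for k, v in breakdown.items() if k != "total")
    assert parts == pytest.approx(float(total.data), abs=1e-6)


def test_non_finite_term_raises_naming_the_term():
    comps = {"dice": nn.Tensor(np.nan)}
    with pytest.raises(FloatingPointError, match="dice"):
        total_loss(comps, LossWeights())


def test_all_zero_configuration_reaches_near_zero_total(rng):
    labels = rng.integers(0, 4, size=(1, 2, 2, 2))
    probs = _probs_from(labels)
    logits = np.zeros((1, 4, 2, 2, 2))
    vol = np.ones((1, 4, 2, 2, 2))
    g = CausalGraph(init=1e-6, init_prior=1e-6)
    comps = {
        "dice": dice_loss(probs, nn.one_hot(labels, 4)),
        "ce": balanced_ce_loss(np.clip(probs, 1e-7, 1), nn.one_hot(labels, 4)),
        "causal": causal_loss(g, [], PriorTemplate(), 1e-6, 0.1),
        "smooth": smoothness_loss(logits, vol),
    }
    total, _ = total_loss(comps, LossWeights())
    assert float(total.data) <= 1e-4


# ---------------------------------------------------------------------------
# Gradients
# ---------------------------------------------------------------------------

def _fd_grad_check(f, x, eps=1e-6):
    out = f(x)
    out.backward()
    g = x.grad.copy()
    worst = 0.0
    flat = x.data.ravel()
    for i in range(flat.size):
        old = flat[i]
        flat[i] = old + eps
        fp = float(f(x).data)
        flat[i] = old - eps
        fm = float(f(x).data)
        flat[i] = old
        num = (fp - fm) / (2 * eps)
        if abs(num) + abs(g.ravel()[i]) < 1e-10:
            continue
        worst = max(worst, abs(num - g.ravel()[i])
                    / max(1e-8, abs(num) + abs(g.ravel()[i])))
    return worst


@pytest.mark.parametrize("term", ["dice", "ce", "smooth"])
def test_loss_gradients_match_finite_differences_on_2cube(term, rng):
    labels = rng.integers(0, 3, size=(1, 2, 2, 2))
    onehot = nn.one_hot(labels, 3)
    vol = rng.normal(size=(1, 4, 2, 2, 2))

    def f(x):
        probs = nn.softmax(x, axis=1)
        if term == "dice":
            return dice_loss(probs, onehot)
        if term == "ce":
            return balanced_ce_loss(probs, onehot)
        return smoothness_loss(x, vol, sigma_i=0.7)

    x = nn.Tensor(rng.normal(size=(1, 3 if term != "smooth" else 3, 2, 2, 2)),
                  requires_grad=True)
    assert _fd_grad_check(f, x) < 1e-3


def test_causal_loss_gradient_matches_finite_differences(rng):
    region = rng.integers(0, 4, size=(1, 2, 2, 2))
    g = CausalGraph()

    def f(x):
        return causal_loss(g, [("ablate:t1ce", x, region)],
                           PriorTemplate(), 0.0, 1.0)

    x = nn.Tensor(rng.normal(size=(1, 4, 2, 2, 2)) * 0.3, requires_grad=True)
    assert _fd_grad_check(f, x) < 1e-3
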