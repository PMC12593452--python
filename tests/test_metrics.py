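"""Metric implementations against independent brute-force oracles on
small grids, plus invariants and the graph-recovery scorer."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from causalseg.metrics import (CalibrationReport, boundary_f1, calibration,
                               dice_coefficient, graph_recovery, hd95,
                               overlap_metrics,
                               uncertainty_error_correlation,
                               volume_error_pct)


# ---------------------------------------------------------------------------
# Brute-force oracles
# ---------------------------------------------------------------------------

def oracle_dice(p, g):
    p, g = p.astype(bool), g.astype(bool)
    if not p.any() and not g.any():
        return 1.0
    return 2 * np.logical_and(p, g).sum() / (p.sum() + g.sum())


def _oracle_surface(mask):
    return mask & ~ndi.binary_erosion(mask) if mask.any() else mask


def oracle_hd95(p, g, spacing=(1.0, 1.0, 1.0)):
    p, g = p.astype(bool), g.astype(bool)
    if not p.any() and not g.any():
        return 0.0
    if not p.any() or not g.any():
        return float(np.linalg.norm(np.array(p.shape) * np.array(spacing)))
    sp = np.argwhere(_oracle_surface(p)) * np.asarray(spacing)
    sg = np.argwhere(_oracle_surface(g)) * np.asarray(spacing)
    d = np.linalg.norm(sp[:, None] - sg[None], axis=-1)  # all pairs
    return float(max(np.percentile(d.min(axis=1), 95),
                     np.percentile(d.min(axis=0), 95)))


def oracle_bf1(p, g, tol=2.0):
    p, g = p.astype(bool), g.astype(bool)
    if not p.any() and not g.any():
        return 1.0
    if not p.any() or not g.any():
        return 0.0
    sp = np.argwhere(_oracle_surface(p)).astype(float)
    sg = np.argwhere(_oracle_surface(g)).astype(float)
    d = np.linalg.norm(sp[:, None] - sg[None], axis=-1)
    prec = (d.min(axis=1) <= tol).mean()
    rec = (d.min(axis=0) <= tol).mean()
    return 0.0 if prec + rec == 0 else 2 * prec * rec / (prec + rec)


def oracle_ece(conf, correct, n_bins):
    edges = np.linspace(0, 1, n_bins + 1)
    total = 0.0
    mx = 0.0
    for b in range(n_bins):
        lo, hi = edges[b], edges[b + 1]
        sel = (conf >= lo) & (conf < hi) if b < n_bins - 1 \
            else (conf >= lo) & (conf <= hi)
        if not sel.any():
            continue
        gap = abs(correct[sel].mean() - conf[sel].mean())
        total += sel.sum() / conf.size * gap
        mx = max(mx, gap)
    return 100 * total, 100 * mx


# ---------------------------------------------------------------------------
# Oracle equivalence on random 5³ instances
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("density", [0.1, 0.3, 0.6])
def test_overlap_metrics_match_bruteforce_oracles(density, rng):
    for trial in range(40):
        p = rng.random((5, 5, 5)) < density
        g = rng.random((5, 5, 5)) < density
        assert dice_coefficient(p, g) == pytest.approx(oracle_dice(p, g))
        assert hd95(p, g) == pytest.approx(oracle_hd95(p, g), abs=1e-9)
        assert boundary_f1(p, g) == pytest.approx(oracle_bf1(p, g), abs=1e-9)


def test_hd95_with_anisotropic_spacing_matches_oracle(rng):
    spacing = (1.0, 2.0, 0.5)
    for _ in range(20):
        p = rng.random((5, 5, 5)) < 0.2
        g = rng.random((5, 5, 5)) < 0.2
        assert hd95(p, g, spacing) == pytest.approx(
            oracle_hd95(p, g, spacing), abs=1e-9)


def test_two_single_voxels_three_apart():
    p = np.zeros((8, 8, 8), bool)
    g = np.zeros((8, 8, 8), bool)
    p[1, 1, 1] = True
    g[4, 1, 1] = True
    assert hd95(p, g, (1.0, 1.0, 1.0)) == pytest.approx(3.0)


def test_identical_masks_are_perfect():
    m = np.zeros((6, 6, 6), bool)
    m[2:5, 2:5, 2:5] = True
    assert dice_coefficient(m, m) == 1.0
    assert hd95(m, m) == 0.0
    assert boundary_f1(m, m) == 1.0
    assert volume_error_pct(m, m) == 0.0


def test_half_volume_subset_closed_form():
    g = np.zeros((8, 8, 8), bool)
    g[:4] = True            # 256 voxels
    p = np.zeros_like(g)
    p[:2] = True            # half of G, subset
    assert dice_coefficient(p, g) == pytest.approx(2 / 3)
    assert volume_error_pct(p, g) == pytest.approx(50.0)


def test_symmetry_of_dice_and_hd95(rng):
    for _ in range(20):
        p = rng.random((5, 5, 5)) < 0.3
        g = rng.random((5, 5, 5)) < 0.3
        assert dice_coefficient(p, g) == dice_coefficient(g, p)
        assert hd95(p, g) == hd95(g, p)


def test_empty_conventions():
    e = np.zeros((4, 4, 4), bool)
    f = np.zeros((4, 4, 4), bool)
    f[1, 1, 1] = True
    assert dice_coefficient(e, e) == 1.0 and hd95(e, e) == 0.0
    assert dice_coefficient(e, f) == 0.0
    assert hd95(e, f) == pytest.approx(np.sqrt(3 * 16))


def test_overlap_metrics_region_unions(rng):
    pred = rng.integers(0, 4, size=(6, 6, 6))
    true = rng.integers(0, 4, size=(6, 6, 6))
    report = overlap_metrics(pred, true)
    assert report.regions["TC"]["dice"] == pytest.approx(
        oracle_dice(np.isin(pred, (1, 3)), np.isin(true, (1, 3))))
    assert report.regions["WT"]["dice"] == pytest.approx(
        oracle_dice(pred > 0, true > 0))


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def test_perfect_confident_predictions_score_zero():
    labels = np.array([0, 1, 2, 3] * 4).reshape(1, 4, 2, 2)
    probs = np.eye(4)[labels.ravel()].T.reshape(1, 4, 4, 2, 2)
    rep = calibration(probs, labels)
    assert rep.ece_pct == 0.0 and rep.mce_pct == 0.0
    assert rep.brier == 0.0 and rep.nll == pytest.approx(0.0, abs=1e-9)


def test_single_bin_hand_computation():
    """Every voxel confidence 0.8, accuracy 0.5 → ECE = MCE = 30%."""
    n = 40
    labels = np.zeros((1, n, 1, 1), dtype=int)
    labels[0, : n // 2] = 1              # half the argmax calls are wrong
    probs = np.zeros((1, 2, n, 1, 1))
    probs[0, 0] = 0.8
    probs[0, 1] = 0.2
    rep = calibration(probs, labels)
    assert rep.ece_pct == pytest.approx(30.0)
    assert rep.mce_pct == pytest.approx(30.0)


def test_calibration_matches_binning_oracle(rng):
    for _ in range(10):
        probs = rng.dirichlet(np.ones(4), size=100).T.reshape(1, 4, 100, 1, 1)
        labels = rng.integers(0, 4, size=(1, 100, 1, 1))
        rep = calibration(probs, labels, n_bins=15)
        conf = probs.max(axis=1).ravel()
        correct = (probs.argmax(axis=1) == labels).ravel()
        ece, mce = oracle_ece(conf, correct, 15)
        assert rep.ece_pct == pytest.approx(ece, abs=1e-9)
        assert rep.mce_pct == pytest.approx(mce, abs=1e-9)
        assert rep.ece_pct <= rep.mce_pct + 1e-12


def test_ece_never_exceeds_mce(rng):
    for _ in range(20):
        probs = rng.dirichlet(np.ones(3), size=50).T.reshape(1, 3, 50, 1, 1)
        labels = rng.integers(0, 3, size=(1, 50, 1, 1))
        rep = calibration(probs, labels)
        assert rep.ece_pct <= rep.mce_pct + 1e-12


# ---------------------------------------------------------------------------
# Uncertainty-error correlation
# ---------------------------------------------------------------------------

def _noisy_cohort(rng, n_cases=12):
    """Cases whose noise level drives both entropy and error together."""
    probs_list, labels_list = [], []
    for i in range(n_cases):
        noise = 0.05 + 0.9 * i / (n_cases - 1)
        labels = rng.integers(0, 2, size=(4, 4, 4))
        conf = 1.0 - noise / 2
        p1 = np.where(labels == 1, conf, 1 - conf)
        flip = rng.random((4, 4, 4)) < noise / 2
        p1 = np.where(flip, 1 - p1, p1)
        probs_list.append(np.stack([1 - p1, p1]))
        labels_list.append(labels)
    return probs_list, labels_list


def test_monotone_cohort_gives_strong_positive_rho(rng):
    probs, labels = _noisy_cohort(rng)
    out = uncertainty_error_correlation(probs, labels)
    assert out["rho_case"] > 0.8
    assert not out["degenerate_case"]


def test_constant_uncertainty_reports_zero_with_flag():
    labels = [np.zeros((2, 2, 2), dtype=int)] * 3
    probs = [np.stack([np.full((2, 2, 2), 0.7),
                       np.full((2, 2, 2), 0.3)])] * 3
    out = uncertainty_error_correlation(probs, labels)
    assert out["rho_case"] == 0.0 and out["degenerate_case"]


def test_rank_correlation_invariant_to_monotone_transform(rng):
    probs, labels = _noisy_cohort(rng)
    base = uncertainty_error_correlation(probs, labels)
    # exponentiate entropies by sharpening all probabilities monotonically:
    # instead verify directly with transformed case statistics
    from scipy import stats
    ents = [(-np.clip(p, 1e-12, 1) * np.log(np.clip(p, 1e-12, 1))).sum(0).mean()
            for p in probs]
    errs = [(p.argmax(0) != l).mean() for p, l in zip(probs, labels)]
    rho_t = stats.spearmanr(np.exp(ents), errs).statistic
    assert base["rho_case"] == pytest.approx(rho_t)


def test_single_case_raises():
    with pytest.raises(ValueError):
        uncertainty_error_correlation([np.ones((2, 2, 2, 2))],
                                      [np.zeros((2, 2, 2), dtype=int)])


# ---------------------------------------------------------------------------
# Graph recovery
# ---------------------------------------------------------------------------

def test_truth_scores_recover_perfectly():
    truth = np.zeros((4, 3), dtype=int)
    truth[0, 0] = truth[2, 1] = truth[3, 2] = 1
    auroc, prec = graph_recovery(truth.astype(float), truth)
    assert auroc == 1.0 and prec == 1.0


def test_inverted_scores_score_zero():
    truth = np.zeros((4, 3), dtype=int)
    truth[0, 0] = truth[2, 1] = truth[3, 2] = 1
    auroc, _ = graph_recovery(1.0 - truth.astype(float), truth)
    assert auroc == 0.0


def test_random_scores_have_null_auroc_half(rng):
    truth = np.zeros((4, 3), dtype=int)
    truth[0, 0] = truth[2, 1] = truth[3, 2] = 1
    aurocs = [graph_recovery(rng.random(12), truth)[0] for _ in range(1000)]
    assert abs(np.mean(aurocs) - 0.5) < 0.05


def test_degenerate_truth_raises():
    with pytest.raises(ValueError):
        graph_recovery(np.random.rand(12), np.ones((4, 3), dtype=int))
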