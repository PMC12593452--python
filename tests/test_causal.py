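"""Interventions, CE maps, abduction and the counterfactual pipeline on a
deterministic untrained model (behavioural contracts that do not require
training)."""

import time

import numpy as np
import pytest

import causalseg as cs
from causalseg.causal import (CEMap, Intervention, abduct, apply_intervention,
                              ce_map, counterfactual, explain)
from causalseg.scm import ExogenousNoise


@pytest.fixture()
def volumes(small_case):
    vol, _ = cs.preprocess(small_case.volume, small_case.mask,
                           target_shape=(24, 24, 24))
    return vol.data[None]


# ---------------------------------------------------------------------------
# Intervention specification
# ---------------------------------------------------------------------------

def test_invalid_interventions_rejected():
    with pytest.raises(ValueError, match="modality"):
        Intervention.ablate("dwi")
    with pytest.raises(ValueError, match="empty"):
        Intervention.feature_clamp(np.zeros((3, 3, 3), bool), 0.0)
    with pytest.raises(ValueError, match="finite"):
        Intervention.scale_modality("t1", np.inf)


def test_intervention_ids_are_stable():
    assert Intervention.ablate("t1ce").id == "ablate:t1ce"
    assert Intervention.scale_modality("flair", 0.5).id == "scale:flair:0.5"
    assert Intervention.null().id == "null"


# ---------------------------------------------------------------------------
# apply_intervention
# ---------------------------------------------------------------------------

def test_unit_scale_is_identity(tiny_model, volumes):
    state = tiny_model.factual(volumes)
    out = apply_intervention(tiny_model, state,
                             Intervention.scale_modality("t2", 1.0))
    assert out["volume"] is state.volume
    assert out["z"] is state.z


def test_ablation_replaces_features_with_silent_embedding(tiny_model, volumes):
    state = tiny_model.factual(volumes)
    out = apply_intervention(tiny_model, state, Intervention.ablate("flair"))
    lat, vox = out["feats"]
    # FLAIR features become the embedding of zero (spatially constant)
    for c in range(lat[2].shape[1]):
        assert np.ptp(lat[2].data[0, c]) == 0.0
    # other modalities untouched
    for mi in (0, 1, 3):
        np.testing.assert_array_equal(lat[mi].data, state.feats[0][mi].data)


def test_feature_clamp_sets_region_exactly(tiny_model, volumes):
    state = tiny_model.factual(volumes)
    region = np.zeros((3, 3, 3), bool)
    region[1, 1, 1] = True
    out = apply_intervention(tiny_model, state,
                             Intervention.feature_clamp(region, 2.5))
    z = out["z"].data
    assert (z[:, :, region] == 2.5).all()
    np.testing.assert_array_equal(z[:, :, ~region],
                                  state.z.data[:, :, ~region])


def test_do_locality_nontargeted_inputs_untouched(tiny_model, volumes):
    state = tiny_model.factual(volumes)
    out = apply_intervention(tiny_model, state, Intervention.ablate("t1"))
    np.testing.assert_array_equal(out["volume"].data[:, 1:],
                                  state.volume.data[:, 1:])
    assert (out["volume"].data[:, 0] == 0).all()


# ---------------------------------------------------------------------------
# CE maps
# ---------------------------------------------------------------------------

def test_identical_probs_give_zero_map(rng):
    p = rng.dirichlet(np.ones(4), size=8).T.reshape(1, 4, 2, 2, 2)
    cem = ce_map(p, p.copy(), Intervention.null())
    assert (cem.delta == 0).all()


def test_full_probability_swing_is_plus_one():
    a = np.zeros((1, 2, 1, 1, 1))
    a[0, 0] = 1.0
    b = np.zeros((1, 2, 1, 1, 1))
    b[0, 1] = 1.0
    cem = ce_map(a, b, Intervention.null())
    assert cem.delta[0, 0, 0, 0, 0] == 1.0


def test_ce_values_bounded(tiny_model, volumes):
    for m in ("t1", "t2", "flair", "t1ce"):
        _, _, cem = counterfactual(tiny_model, volumes,
                                   Intervention.ablate(m))
        assert np.abs(cem.delta).max() <= 1.0 + 1e-6


def test_shape_mismatch_raises():
    with pytest.raises(ValueError, match="shape"):
        ce_map(np.ones((1, 2, 2, 2, 2)) / 2, np.ones((1, 2, 3, 3, 3)) / 2,
               Intervention.null())


# ---------------------------------------------------------------------------
# Abduction
# ---------------------------------------------------------------------------

def test_zero_noise_factual_abducts_to_zero(tiny_model, volumes):
    state = tiny_model.factual(volumes)
    eps = abduct(tiny_model, state)
    assert np.abs(eps.eps_z.data).max() < 1e-6
    assert np.abs(eps.eps_y.data).max() < 1e-6


def test_injected_noise_recovered_to_machine_precision(tiny_model, volumes,
                                                       rng):
    noise = ExogenousNoise(
        eps_z=rng.normal(size=(1, tiny_model.backbone.latent_channels,
                               3, 3, 3)).astype(np.float32) * 0.3,
        eps_y=rng.normal(size=(1, 4, 24, 24, 24)).astype(np.float32) * 0.3)
    state = tiny_model.factual(volumes, noise=noise)
    eps_hat = abduct(tiny_model, state)
    np.testing.assert_allclose(eps_hat.eps_z.data, noise.eps_z, atol=1e-5)
    np.testing.assert_allclose(eps_hat.eps_y.data, noise.eps_y, atol=1e-5)


def test_abduction_is_stateless(tiny_model, volumes):
    state = tiny_model.factual(volumes)
    a = abduct(tiny_model, state)
    b = abduct(tiny_model, state)
    np.testing.assert_array_equal(a.eps_z.data, b.eps_z.data)
    np.testing.assert_array_equal(a.eps_y.data, b.eps_y.data)


# ---------------------------------------------------------------------------
# Counterfactuals
# ---------------------------------------------------------------------------

def test_null_intervention_counterfactual_equals_factual(tiny_model, volumes):
    state = tiny_model.factual(volumes)
    probs_cf, _, cem = counterfactual(tiny_model, volumes,
                                      Intervention.null())
    assert np.abs(probs_cf - state.probs_scm).max() <= 1e-5
    assert np.abs(cem.delta).max() <= 1e-5


def test_counterfactual_is_deterministic(tiny_model, volumes):
    a = counterfactual(tiny_model, volumes, Intervention.ablate("t1ce"))
    b = counterfactual(tiny_model, volumes, Intervention.ablate("t1ce"))
    np.testing.assert_array_equal(a[0], b[0])
    np.testing.assert_array_equal(a[1], b[1])


def test_fully_masked_modality_gives_identically_zero_ce(volumes):
    cfg = cs.TrainConfig(seed=0)
    model = cs.CausalSegModel(cfg.backbone_config(), seed=0)
    model.scm.graph.mask_mz[1] = 0.0
    model.scm.graph.mask_my[1, :] = 0.0
    _, _, cem = counterfactual(model, volumes, Intervention.ablate("t2"))
    assert (cem.delta == 0).all()


# ---------------------------------------------------------------------------
# explain
# ---------------------------------------------------------------------------

def test_empty_intervention_set_returns_empty_dict(tiny_model, volumes):
    seg, e = explain(tiny_model, volumes, [])
    assert seg.shape == (1, 24, 24, 24)
    assert e == {}


def test_null_explanation_is_all_zero(tiny_model, volumes):
    _, e = explain(tiny_model, volumes, [Intervention.null()])
    assert set(e) == {"null"}
    assert np.abs(e["null"]["ce"].delta).max() <= 1e-5


def test_four_ablations_contract_and_runtime(tiny_model, volumes):
    ivs = [Intervention.ablate(m) for m in ("t1", "t2", "flair", "t1ce")]
    t0 = time.time()
    state = tiny_model.factual(volumes)
    t_fact = time.time() - t0
    t0 = time.time()
    seg, e = explain(tiny_model, volumes, ivs)
    t_explain = time.time() - t0
    assert len(e) == 4
    for key, entry in e.items():
        assert entry["ce"].delta.shape == (1, 4, 24, 24, 24)
        assert entry["mask_cf"].shape == (1, 24, 24, 24)
    assert t_explain <= 5 * max(t_fact, 0.2)
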