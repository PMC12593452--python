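"""do-interventions, causal-effect maps and counterfactual reasoning.

An intervention do(V = v) replaces the mechanism of a causal variable with
a constant and recomputes everything downstream of it along the *allowed*
edges of the graph. Three families are supported: modality-level (complete
ablation do(X^m = 0) or intensity scaling do(X^m = s·X^m)), feature-level
(clamping the latent grid on a spatial region to a fixed value) and
lesion-specific (intensity edits inside an input-grid region of interest).
A modality whose outgoing edges are all masked propagates nothing, so its
ablation leaves the SCM branch bitwise unchanged.

The causal-effect (CE) map of an intervention is the per-voxel, per-class
probability difference Δ_c(x) = p_factual(c|x) − p_interventional(c|x);
positive values mark voxels where the intervention reduces class-c
probability. Both terms come from the same (SCM) branch by default; an
``alg2_literal`` flag instead differences the decoder's factual
probabilities against the SCM branch's interventional ones.

Counterfactuals follow Abduction-Action-Prediction: infer the exogenous
noise from the observed factual pass (closed form under additive noise:
ε̂ = observed − deterministic part, the degenerate one-step Newton update),
apply the intervention, re-predict with ε̂ held fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .io_prep import MODALITIES, MODALITY_INDEX
from .scm import ExogenousNoise

__all__ = ["Intervention", "CEMap", "apply_intervention", "ce_map",
           "abduct", "counterfactual", "counterfactual_probs", "explain"]


# ---------------------------------------------------------------------------
# Intervention specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Intervention:
    """A do(·) specification.

    ``kind`` is one of ``null``, ``modality_ablate``, ``modality_scale``,
    ``feature_clamp`` or ``roi_intensity``.
    """

    kind: str = "null"
    modality: str | None = None
    scale: float = 1.0
    offset: float = 0.0
    region: np.ndarray | None = field(default=None, compare=False)
    value: float | np.ndarray | None = field(default=None, compare=False)

    # -- constructors -------------------------------------------------------
    @classmethod
    def null(cls) -> "Intervention":
        return cls(kind="null")

    @classmethod
    def ablate(cls, modality: str) -> "Intervention":
        cls._check_modality(modality)
        return cls(kind="modality_ablate", modality=modality)

    @classmethod
    def scale_modality(cls, modality: str, s: float) -> "Intervention":
        cls._check_modality(modality)
        if not np.isfinite(s):
            raise ValueError("scale must be finite")
        return cls(kind="modality_scale", modality=modality, scale=float(s))

    @classmethod
    def feature_clamp(cls, region: np.ndarray, value) -> "Intervention":
        region = np.asarray(region, dtype=bool)
        if not region.any():
            raise ValueError("feature_clamp region is empty")
        return cls(kind="feature_clamp", region=region, value=value)

    @classmethod
    def roi_intensity(cls, region: np.ndarray, offset: float = 0.0,
                      scale: float = 1.0) -> "Intervention":
        region = np.asarray(region, dtype=bool)
        if not region.any():
            raise ValueError("roi_intensity region is empty")
        return cls(kind="roi_intensity", region=region, offset=float(offset),
                   scale=float(scale))

    @staticmethod
    def _check_modality(m: str):
        if m not in MODALITY_INDEX:
            raise ValueError(f"unknown modality '{m}'; valid: {MODALITIES}")

    @property
    def id(self) -> str:
        if self.kind == "null":
            return "null"
        if self.kind == "modality_ablate":
            return f"ablate:{self.modality}"
        if self.kind == "modality_scale":
            return f"scale:{self.modality}:{self.scale:g}"
        if self.kind == "feature_clamp":
            return f"clamp:{int(self.region.sum())}vox"
        return f"roi:{int(self.region.sum())}vox:{self.offset:g}:{self.scale:g}"

    def is_identity(self) -> bool:
        return (self.kind == "null"
                or (self.kind == "modality_scale" and self.scale == 1.0)
                or (self.kind == "roi_intensity" and self.scale == 1.0
                    and self.offset == 0.0))


@dataclass
class CEMap:
    """Per-class voxel-wise causal-effect map Δ_c(x) in [−1, 1]."""

    delta: np.ndarray             # (N, C, X, Y, Z)
    intervention: Intervention

    def __post_init__(self):
        self.delta = np.asarray(self.delta, dtype=np.float32)
        if np.abs(self.delta).max(initial=0.0) > 1.0 + 1e-6:
            raise ValueError("CE values must lie in [-1, 1]")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def apply_intervention(model, state, intervention: Intervention):
    """do-semantics on a factual forward state.

    Returns a new state-like dict with fields ``volume`` (Tensor), ``feats``
    and ``z`` recomputed downstream of the intervened variable along allowed
    graph edges only. Identity interventions return the factual quantities
    unchanged (bitwise).
    """
    if intervention.is_identity():
        return {"volume": state.volume, "feats": state.feats, "z": state.z}

    if intervention.kind in ("modality_ablate", "modality_scale"):
        mi = MODALITY_INDEX[intervention.modality]
        vol = state.volume.data.copy()
        if intervention.kind == "modality_ablate":
            vol[:, mi] = 0.0
        else:
            vol[:, mi] *= intervention.scale
        vol_t = nn.Tensor(vol)
        if model.scm.graph.modality_blocked(mi):
            # every outgoing edge forbidden: nothing propagates
            return {"volume": vol_t, "feats": state.feats, "z": state.z}
        feats = model.scm.pool_modality_features(vol_t, state.z.shape[2:])
        z_do, _ = model.backbone.encode(vol_t)
        return {"volume": vol_t, "feats": feats, "z": z_do}

    if intervention.kind == "roi_intensity":
        region = intervention.region
        if region.shape != state.volume.shape[2:]:
            raise ValueError("roi region does not match the input grid")
        vol = state.volume.data.copy()
        vol[:, :, region] = vol[:, :, region] * intervention.scale \
            + intervention.offset
        vol_t = nn.Tensor(vol)
        feats = model.scm.pool_modality_features(vol_t, state.z.shape[2:])
        z_do, _ = model.backbone.encode(vol_t)
        return {"volume": vol_t, "feats": feats, "z": z_do}

    if intervention.kind == "feature_clamp":
        region = intervention.region
        if region.shape != state.z.shape[2:]:
            raise ValueError("clamp region does not match the latent grid")
        z = state.z.data.copy()
        z[:, :, region] = intervention.value
        return {"volume": state.volume, "feats": state.feats,
                "z": nn.Tensor(z)}

    raise ValueError(f"unknown intervention kind '{intervention.kind}'")


def ce_map(factual_probs: np.ndarray, interventional_probs: np.ndarray,
           intervention: Intervention) -> CEMap:
    """Δ_c(x) = p_factual − p_interventional (positive where the
    intervention reduces class-c probability)."""
    factual_probs = np.asarray(factual_probs)
    interventional_probs = np.asarray(interventional_probs)
    if factual_probs.shape != interventional_probs.shape:
        raise ValueError(
            f"probability grids differ in shape: {factual_probs.shape} vs "
            f"{interventional_probs.shape}")
    for name, p in (("factual", factual_probs),
                    ("interventional", interventional_probs)):
        if p.min() < -1e-6 or np.abs(p.sum(axis=1) - 1.0).max() > 1e-4:
            raise ValueError(f"{name} probabilities are not a valid softmax "
                             f"output")
    return CEMap(delta=factual_probs - interventional_probs,
                 intervention=intervention)


def abduct(model, state, observed_latent=None, observed_logits=None,
           ) -> ExogenousNoise:
    """Closed-form abduction under additive exogenous noise.

    ε̂_Z = Z_observed − f_Z(·) and ε̂_Y = logits_observed − f_Y(·), the exact
    solution to which the one-step Newton update degenerates. Defaults take
    the factual pass's realised SCM outputs as the observations, so a
    zero-noise factual pass abducts ε̂ ≈ 0 and injected noise is recovered
    exactly. Stateless: repeated calls give identical results.
    """
    layer = model.scm
    z_obs = nn.astensor(observed_latent) if observed_latent is not None \
        else state.z_scm
    fz = layer.f_z(state.feats[0])
    eps_z = z_obs - fz
    y_obs = nn.astensor(observed_logits) if observed_logits is not None \
        else state.logits_scm
    if layer.z_blend > 0:
        z_in = state.z * (1.0 - layer.z_blend) + z_obs * layer.z_blend
    else:
        z_in = state.z
    fy = layer.f_y(z_in, state.feats[1], state.volume.shape[2:])
    eps_y = y_obs - fy
    return ExogenousNoise(eps_z=eps_z, eps_y=eps_y)


def counterfactual(model, volumes, intervention: Intervention,
                   noise: ExogenousNoise | None = None,
                   alg2_literal: bool = False):
    """Abduction-Action-Prediction counterfactual.

    Returns ``(probs_cf, mask_cf, CEMap)``: the counterfactual class
    probabilities and argmax mask from the SCM branch with the abducted
    exogenous noise held fixed, plus the CE map against the factual
    prediction (same branch both sides unless ``alg2_literal``, which
    differences the decoder's factual probabilities instead).
    """
    state = model.factual(volumes, noise=noise)
    eps = abduct(model, state)
    modified = apply_intervention(model, state, intervention)
    _, logits_cf = model.scm.forward(modified["feats"], modified["z"],
                                     noise=eps)
    probs_cf = nn.softmax(logits_cf, axis=1).data
    mask_cf = probs_cf.argmax(axis=1).astype(np.int16)
    fact_probs = state.probs_dec if alg2_literal else state.probs_scm
    cem = ce_map(fact_probs, probs_cf, intervention)
    return probs_cf, mask_cf, cem


def counterfactual_probs(model, volumes, intervention: Intervention,
                         factual=None) -> np.ndarray:
    """Counterfactual SCM-branch probabilities, reusing a precomputed
    factual state when supplied (used by batched edge scoring)."""
    state = factual if factual is not None else model.factual(volumes)
    eps = abduct(model, state)
    modified = apply_intervention(model, state, intervention)
    _, logits_cf = model.scm.forward(modified["feats"], modified["z"],
                                     noise=eps)
    return nn.softmax(logits_cf, axis=1).data


def explain(model, volumes, interventions: list[Intervention],
            alg2_literal: bool = False):
    """One factual pass plus one interventional SCM pass per intervention.

    Returns ``(segmentation, E)`` where ``segmentation`` is the decoder's
    argmax mask and ``E`` maps intervention ids to ``{"ce": CEMap,
    "mask_cf": counterfactual mask, "probs_cf": probabilities}``. An empty
    intervention set returns the segmentation with an empty dictionary.
    """
    state = model.factual(volumes)
    segmentation = state.probs_dec.argmax(axis=1).astype(np.int16)
    explanations: dict[str, dict] = {}
    if not interventions:
        return segmentation, explanations
    eps = abduct(model, state)
    fact_probs = state.probs_dec if alg2_literal else state.probs_scm
    for iv in interventions:
        modified = apply_intervention(model, state, iv)
        _, logits_cf = model.scm.forward(modified["feats"], modified["z"],
                                         noise=eps)
        probs_cf = nn.softmax(logits_cf, axis=1).data
        explanations[iv.id] = {
            "ce": ce_map(fact_probs, probs_cf, iv),
            "mask_cf": probs_cf.argmax(axis=1).astype(np.int16),
            "probs_cf": probs_cf,
        }
    return segmentation, explanations
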