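"""Composite training objective.

    L = L_Dice + α·L_CE + β·L_Causal + γ·L_Smooth

L_Dice is soft multi-class Dice over foreground classes; L_CE is
class-balanced cross-entropy (per-class weights proportional to inverse
batch frequency, normalised to mean one); L_Causal = λ₁·||A ⊙ W||₁ +
λ₂·E_do||Δ_c − Δ_c^prior||₁ combines edge-weight sparsity with a weak
prior on region-mean causal effects of the sampled interventions; L_Smooth
is a boundary-preserving CRF-style pairwise penalty on logits, weighted by
an intensity-difference kernel so logit variation is penalised inside
homogeneous regions but relaxed across intensity edges.

All terms accept and return autodiff tensors; every term is nonnegative
and the total decomposes exactly into the logged breakdown.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .io_prep import ED, ET, NCR
from .scm import CausalGraph

__all__ = ["LossWeights", "PriorTemplate", "dice_loss", "balanced_ce_loss",
           "causal_loss", "smoothness_loss", "total_loss"]

_DICE_EPS = 1e-5
_PROB_FLOOR = 1e-7


@dataclass
class LossWeights:
    """Weights of the composite loss; defaults chosen so no term dominates
    at initialisation on phantom batches."""

    alpha: float = 1.0      # class-balanced cross-entropy
    beta: float = 1.0       # causal consistency
    gamma: float = 0.1      # CRF-style smoothness
    lambda1: float = 5e-3   # edge-weight sparsity (inside L_Causal)
    lambda2: float = 2.0    # prior consistency (inside L_Causal)

    def __post_init__(self):
        for name in ("alpha", "beta", "gamma", "lambda1", "lambda2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


def _default_expectations() -> dict:
    carried = {"t1": NCR, "flair": ED, "t1ce": ET}
    out = {}
    for m in ("t1", "t2", "flair", "t1ce"):
        iv = "ablate:" + m
        for c in (NCR, ED, ET):
            if carried.get(m) == c:
                # the carried class loses (nearly) all its probability
                # over its own region, and that mass reads as background
                out[(iv, c, c)] = 0.9
                out[(iv, c, 0)] = -0.9
            else:
                out[(iv, c, c)] = 0.0
    return out


@dataclass
class PriorTemplate:
    """Expected region-mean causal effects.

    Keys are ``(intervention id, region class, target class)`` — the
    expected Δ of the target class's probability over the region class's
    voxels — with ``(intervention id, class)`` accepted as shorthand for a
    class's effect on itself. The default template encodes the canonical
    domain expectations in both directions: ablating the modality that
    carries a class removes nearly all of that class's probability over
    its region and that probability reappears as background (the tissue
    simply stops displaying its distinguishing contrast), while ablating
    a modality with no edge into a class leaves the class unchanged. The
    zero entries are what make interventional training enforce
    disentanglement rather than mere sensitivity.
    """

    expectations: dict = field(default_factory=_default_expectations)

    def __post_init__(self):
        normalized = {}
        for key, v in self.expectations.items():
            if len(key) == 2:
                key = (key[0], key[1], key[1])
            if not -1.0 <= v <= 1.0:
                raise ValueError(f"prior for {key} outside [-1, 1]")
            normalized[key] = float(v)
        self.expectations = normalized

    def for_intervention(self, intervention_id: str,
                         ) -> list[tuple[int, int, float]]:
        """(region class, target class, expected Δ) entries."""
        return [(rc, tc, v) for (iid, rc, tc), v in self.expectations.items()
                if iid == intervention_id]


# ---------------------------------------------------------------------------
# Segmentation terms
# ---------------------------------------------------------------------------

def _check_shapes(probs, target_onehot):
    if probs.shape != target_onehot.shape:
        raise ValueError(f"probs {tuple(probs.shape)} and target "
                         f"{tuple(target_onehot.shape)} differ in shape")


def dice_loss(probs: nn.Tensor, target_onehot) -> nn.Tensor:
    """1 − mean over foreground classes of (2Σpg + ε)/(Σp + Σg + ε).

    A class absent from both prediction and target yields ε/ε = 1 for its
    Dice term and therefore contributes no loss.
    """
    probs = nn.astensor(probs)
    target = nn.astensor(target_onehot)
    _check_shapes(probs, target)
    axes = (0,) + tuple(range(2, probs.ndim))
    inter = (probs * target).sum(axis=axes)
    denom = probs.sum(axis=axes) + target.sum(axis=axes)
    dice_c = (2.0 * inter + _DICE_EPS) / (denom + _DICE_EPS)
    return 1.0 - dice_c[1:].mean()


def balanced_ce_loss(probs: nn.Tensor, target_onehot) -> nn.Tensor:
    """Voxelwise NLL with per-class inverse-frequency weights (mean 1).

    Weights are computed from the batch's target frequencies over present
    classes; absent classes get weight 0. Probabilities are floored at
    1e−7 so the loss stays finite.
    """
    probs = nn.astensor(probs)
    target = nn.astensor(target_onehot)
    _check_shapes(probs, target)
    axes = (0,) + tuple(range(2, probs.ndim))
    counts = target.data.sum(axis=axes)
    present = counts > 0
    weights = np.zeros_like(counts)
    weights[present] = 1.0 / counts[present]
    weights *= present.sum() / weights.sum()      # mean 1 over present
    wshape = (1, -1) + (1,) * (probs.ndim - 2)
    w = nn.Tensor(weights.reshape(wshape))
    nll = -(target * nn.clip(probs, _PROB_FLOOR, 1.0).log() * w)
    return nll.sum(axis=1).mean()


# ---------------------------------------------------------------------------
# Causal consistency
# ---------------------------------------------------------------------------

def causal_loss(graph: CausalGraph, sampled_ce_maps: list, priors: PriorTemplate,
                lambda1: float, lambda2: float) -> nn.Tensor:
    """λ₁·||A ⊙ W||₁ + λ₂·mean over sampled interventions of the L1
    distance between realised region-mean CE and the prior template.

    ``sampled_ce_maps`` holds ``(intervention_id, delta, region_labels)``
    triples from this batch's sampled interventions, where ``delta`` is the
    (N, C, ...) CE tensor and ``region_labels`` the factual argmax used to
    define per-class regions. The prior distance is the L1 norm over the
    template's class entries (realised region-mean CE vs expectation),
    averaged over the sampled interventions. Empty sample set ⇒ sparsity
    term only.
    """
    from .scm import regularizer_terms

    sparsity, _ = regularizer_terms(graph)
    total = sparsity * float(lambda1)
    if lambda2 == 0 or not sampled_ce_maps:
        return total

    per_intervention = []
    for iv_id, delta, region_labels in sampled_ce_maps:
        expectations = priors.for_intervention(iv_id)
        terms = []
        for region_class, target_class, target in expectations:
            region = np.asarray(region_labels) == region_class
            if not region.any():
                continue
            # voxel-level form of the region constraint: the mean L1
            # deviation of Δ from its expectation over the region (a
            # denser gradient than constraining only the region mean)
            terms.append((delta[:, target_class][region]
                          - float(target)).abs().mean())
        if terms:
            acc = terms[0]
            for t in terms[1:]:
                acc = acc + t
            per_intervention.append(acc)
    if per_intervention:
        acc = per_intervention[0]
        for t in per_intervention[1:]:
            acc = acc + t
        total = total + acc * (float(lambda2) / len(per_intervention))
    return total


# ---------------------------------------------------------------------------
# CRF-style smoothness
# ---------------------------------------------------------------------------

def smoothness_loss(logits: nn.Tensor, volume, sigma_i: float | None = None,
                    ) -> nn.Tensor:
    """Σ over 6-neighbour pairs of exp(−ΔI²/2σ_I²)·‖Δlogits‖², normalised
    by the pair count.

    ΔI is the mean-across-modalities intensity difference; σ_I defaults to
    the standard deviation of those differences over the batch, so the
    kernel adapts to the batch's contrast scale.
    """
    logits = nn.astensor(logits)
    vol = np.asarray(volume.data if isinstance(volume, nn.Tensor) else volume,
                     dtype=np.float32)
    intensity = vol.mean(axis=1)                    # (N, X, Y, Z)
    if sigma_i is None:
        diffs = [np.diff(intensity, axis=1 + ax).ravel() for ax in range(3)]
        sigma_i = float(np.concatenate(diffs).std())
    sigma_i = max(sigma_i, 1e-6)

    total = None
    n_pairs = 0
    for ax in range(3):
        sp = logits.shape[2 + ax]
        if sp < 2:
            continue
        lo = [slice(None)] * logits.ndim
        hi = [slice(None)] * logits.ndim
        lo[2 + ax] = slice(0, sp - 1)
        hi[2 + ax] = slice(1, sp)
        dlog = logits[tuple(hi)] - logits[tuple(lo)]
        di = np.take(intensity, range(1, sp), axis=1 + ax) \
            - np.take(intensity, range(0, sp - 1), axis=1 + ax)
        w = np.exp(-(di ** 2) / (2.0 * sigma_i ** 2))[:, None]
        term = (dlog.square() * nn.Tensor(w)).sum()
        total = term if total is None else total + term
        n_pairs += int(np.prod(di.shape))
    if total is None:
        return nn.Tensor(0.0)
    return total * (1.0 / max(n_pairs, 1))


# ---------------------------------------------------------------------------
# Composite
# ---------------------------------------------------------------------------

def total_loss(components: dict, weights: LossWeights,
               ) -> tuple[nn.Tensor, dict[str, float]]:
    """L = L_Dice + α·L_CE + β·L_Causal + γ·L_Smooth (+ any extra terms,
    added with unit weight). Returns the scalar and a per-term breakdown
    of the weighted contributions.
    """
    core = {"dice": 1.0, "ce": weights.alpha, "causal": weights.beta,
            "smooth": weights.gamma}
    total = None
    breakdown: dict[str, float] = {}
    for name, term in components.items():
        w = core.get(name, 1.0)
        term = nn.astensor(term)
        value = float(term.data)
        if not np.isfinite(value):
            raise FloatingPointError(f"loss term '{name}' is non-finite "
                                     f"({value})")
        contrib = term * w
        breakdown[name] = float(contrib.data)
        total = contrib if total is None else total + contrib
    if total is None:
        total = nn.Tensor(0.0)
    breakdown["total"] = float(total.data)
    return total, breakdown
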