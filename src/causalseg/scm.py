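"""Learnable structural causal model over modalities, latent features and
labels.

The causal graph has nodes M ∪ {Z, Y}: the four imaging modalities M, the
backbone's latent grid Z and the voxel-wise label field Y. Only forward
edges exist (m→Z, m→Y, Z→Y), so the graph is acyclic by construction.
Every edge carries a nonnegative learnable weight (softplus-parameterised)
multiplied by a binary mask A that encodes forbidden edges: the effective
gate is A ⊙ softplus(W), so a forbidden edge contributes exactly zero and
the output is bitwise independent of its weight.

Structural equations (additive exogenous noise):

    Z = f_Z( Σ_m g[m→Z] · φ_m , C_Z ) + ε_Z
    Y = f_Y( Z , Σ_m g[m→Y,c] · ψ_m , C_Y ) + ε_Y

φ_m are per-modality embeddings pooled to the latent grid (no cross-modal
mixing before gating); ψ_m are per-modality voxel embeddings at input
resolution; contexts C are 3×3×3 neighbourhood means; f_Z and f_Y are
shared-weight per-voxel maps (1×1×1 convolutions). m→Y gates are per
modality–class pair so that domain priors like FLAIR→ED are expressible;
the canonical priors (FLAIR→ED, T1CE→ET, T1→NCR) are registered on the
graph and consumed by the causal-consistency loss. The Y equation operates
at full input resolution (the label field is voxel-wise), with the latent
contribution upsampled trilinearly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import nn
from .io_prep import MODALITIES, MODALITY_INDEX, NCR, ED, ET

__all__ = ["CausalGraph", "SCMLayer", "ExogenousNoise",
           "pool_modality_features", "scm_forward", "regularizer_terms",
           "edge_importance", "PRIOR_EDGES"]

#: Canonical prior edges as (modality name, class id).
PRIOR_EDGES: tuple[tuple[str, int], ...] = (
    ("flair", ED), ("t1ce", ET), ("t1", NCR))


@dataclass
class ExogenousNoise:
    """Additive exogenous terms; zero in the factual pass."""

    eps_z: np.ndarray | nn.Tensor | float = 0.0
    eps_y: np.ndarray | nn.Tensor | float = 0.0

    @classmethod
    def zero(cls) -> "ExogenousNoise":
        return cls(0.0, 0.0)


class CausalGraph(nn.Module):
    """Masked nonnegative edge weights for m→Z, m→Y (per class) and Z→Y."""

    def __init__(self, n_classes: int = 4, init: float = 0.3,
                 init_prior: float = 1.0,
                 mask_mz: np.ndarray | None = None,
                 mask_my: np.ndarray | None = None,
                 allow_zy: bool = True,
                 prior_edges=PRIOR_EDGES):
        n_mod = len(MODALITIES)
        self.n_classes = n_classes

        def _raw(v):
            # softplus(raw) = v  at  raw = log(expm1(v))
            return float(np.log(np.expm1(v)))

        # prior-consistent initialisation: the registered domain-prior
        # edges start strong, everything else weak, so training refines a
        # prior-shaped graph rather than discovering signs from scratch
        my = np.full((n_mod, n_classes), _raw(init), dtype=np.float32)
        for m, c in prior_edges:
            my[MODALITY_INDEX[m], int(c)] = _raw(init_prior)
        self.w_mz_raw = nn.Tensor(np.full(n_mod, _raw(0.55),
                                          dtype=np.float32),
                                  requires_grad=True)
        self.w_my_raw = nn.Tensor(my, requires_grad=True)
        self.w_zy_raw = nn.Tensor(np.full((1,), _raw(0.55),
                                          dtype=np.float32),
                                  requires_grad=True)
        # default adjacency mask: every modality may inform the shared
        # latent (m→Z), but direct modality→class edges are restricted to
        # the biologically plausible prior set — masking forbids edges
        # such as T2→ET that have no radiological basis, and closes the
        # shortcut of explaining one class by the *absence* of another
        # modality's signal
        if mask_my is None:
            mask_my = np.zeros((n_mod, n_classes))
            for m, c in prior_edges:
                mask_my[MODALITY_INDEX[m], int(c)] = 1.0
        self.mask_mz = (np.ones(n_mod) if mask_mz is None
                        else np.asarray(mask_mz, dtype=float))
        self.mask_my = np.asarray(mask_my, dtype=float)
        self.mask_zy = 1.0 if allow_zy else 0.0
        self.prior_edges = tuple(prior_edges)

    # -- gates --------------------------------------------------------------
    def gate_mz(self) -> nn.Tensor:
        return nn.softplus(self.w_mz_raw) * nn.Tensor(self.mask_mz)

    def gate_my(self) -> nn.Tensor:
        return nn.softplus(self.w_my_raw) * nn.Tensor(self.mask_my)

    def gate_zy(self) -> nn.Tensor:
        return nn.softplus(self.w_zy_raw) * nn.Tensor(
            np.asarray([self.mask_zy]))

    def modality_blocked(self, m: int | str) -> bool:
        """True if every outgoing edge of modality ``m`` is forbidden."""
        mi = MODALITY_INDEX[m] if isinstance(m, str) else int(m)
        return self.mask_mz[mi] == 0 and not self.mask_my[mi].any()

    # -- serialisation ------------------------------------------------------
    def export(self) -> dict:
        return {
            "modalities": list(MODALITIES),
            "n_classes": self.n_classes,
            "w_mz": nn.softplus(self.w_mz_raw).data.tolist(),
            "w_my": nn.softplus(self.w_my_raw).data.tolist(),
            "w_zy": float(nn.softplus(self.w_zy_raw).data[0]),
            "mask_mz": self.mask_mz.tolist(),
            "mask_my": self.mask_my.tolist(),
            "mask_zy": self.mask_zy,
            "prior_edges": [[m, int(c)] for m, c in self.prior_edges],
        }

    def save_json(self, path: str | Path):
        Path(path).write_text(json.dumps(self.export(), indent=2))


class SCMLayer(nn.Module):
    """Structural functions f_Z, f_Y plus the causal graph."""

    def __init__(self, latent_channels: int, n_classes: int = 4,
                 feat_dim: int = 8, hidden: int = 32, z_compress: int = 16,
                 z_blend: float = 1.0, graph: CausalGraph | None = None,
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        self.n_classes = n_classes
        self.feat_dim = feat_dim
        self.z_blend = float(z_blend)
        self.graph = graph if graph is not None else CausalGraph(n_classes)
        # per-modality embeddings (no cross-modality mixing before gating)
        self.embed_lat = [nn.Conv3d(1, feat_dim, k=1, rng=rng)
                          for _ in MODALITIES]
        self.embed_vox = [nn.Conv3d(1, feat_dim, k=1, rng=rng)
                          for _ in MODALITIES]
        self.act_lat = [nn.PReLU(feat_dim) for _ in MODALITIES]
        self.act_vox = [nn.PReLU(feat_dim) for _ in MODALITIES]
        # f_Z: gated modality sum + context -> latent contribution
        self.fz1 = nn.Conv3d(2 * feat_dim, hidden, k=1, rng=rng)
        self.fz_act = nn.PReLU(hidden)
        self.fz2 = nn.Conv3d(hidden, latent_channels, k=1, rng=rng)
        # f_Y: compressed/upsampled latent + context trunk, plus per-class
        # gated modality contributions
        self.z_cmp = nn.Conv3d(latent_channels, z_compress, k=1, rng=rng)
        self.fy1 = nn.Conv3d(2 * z_compress, hidden, k=1, rng=rng)
        self.fy_act = nn.PReLU(hidden)
        self.fy2 = nn.Conv3d(hidden, n_classes, k=1, rng=rng)
        self.psi = [nn.Conv3d(feat_dim, 1, k=1, rng=rng) for _ in MODALITIES]

    # -- modality features --------------------------------------------------
    def pool_modality_features(self, volume: nn.Tensor,
                               latent_shape: tuple[int, int, int]):
        """Per-modality feature grids: latent-resolution pooled embeddings
        (for f_Z) and input-resolution voxel embeddings (for f_Y)."""
        volume = nn.astensor(volume)
        n = volume.shape[0]
        sp = volume.shape[2:]
        factors = tuple(s // l for s, l in zip(sp, latent_shape))
        if any(s % l for s, l in zip(sp, latent_shape)):
            raise ValueError(f"input {sp} not divisible onto latent grid "
                             f"{latent_shape}")
        feats_lat, feats_vox = [], []
        for mi in range(len(MODALITIES)):
            ch = volume[:, mi:mi + 1]
            # block-average pooling to the latent grid
            pooled = ch.reshape(n, 1,
                                latent_shape[0], factors[0],
                                latent_shape[1], factors[1],
                                latent_shape[2], factors[2])
            pooled = pooled.mean(axis=(3, 5, 7))
            feats_lat.append(self.act_lat[mi](
                self.embed_lat[mi](pooled)))
            feats_vox.append(self.act_vox[mi](
                self.embed_vox[mi](ch)))
        return feats_lat, feats_vox

    # -- structural equations ----------------------------------------------
    def f_z(self, feats_lat: list[nn.Tensor]) -> nn.Tensor:
        g = self.graph.gate_mz()
        s = None
        for mi, f in enumerate(feats_lat):
            term = f * g[mi:mi + 1].reshape(1, 1, 1, 1, 1)
            s = term if s is None else s + term
        ctx = nn.box_filter3(s)
        return self.fz2(self.fz_act(self.fz1(nn.concat([s, ctx], axis=1))))

    def f_y(self, z_in: nn.Tensor, feats_vox: list[nn.Tensor],
            out_shape: tuple[int, int, int]) -> nn.Tensor:
        # latent trunk: gated, compressed, upsampled, with 3x3x3 context
        zc = self.z_cmp(z_in) * self.graph.gate_zy().reshape(1, 1, 1, 1, 1)
        zu = nn.trilinear_resize(zc, out_shape)
        trunk = self.fy2(self.fy_act(self.fy1(
            nn.concat([zu, nn.box_filter3(zu)], axis=1))))
        # per-class gated modality contributions; ψ is tanh-bounded so the
        # contribution magnitude is carried by the gate, not the embedding,
        # and baseline-subtracted so a silent (zeroed) modality contributes
        # exactly its ablated level, i.e. nothing
        g = self.graph.gate_my()  # (n_mod, C)
        psi_parts = []
        for mi, f in enumerate(feats_vox):
            zero = nn.Tensor(np.zeros((1, 1, 1, 1, 1), dtype=np.float32))
            silent = self.act_vox[mi](self.embed_vox[mi](zero))
            baseline = nn.tanh(self.psi[mi](silent))
            psi_parts.append(nn.tanh(self.psi[mi](f)) - baseline)
        psi = nn.concat(psi_parts, axis=1)
        n = psi.shape[0]
        nvox = int(np.prod(out_shape))
        flat = psi.reshape(n, len(MODALITIES), nvox).transpose((0, 2, 1))
        u = nn.matmul(flat, g)                     # (N, nvox, C)
        u = u.transpose((0, 2, 1)).reshape((n, self.n_classes) + out_shape)
        return trunk + u

    def forward(self, feats, z_backbone: nn.Tensor,
                noise: ExogenousNoise | None = None,
                ) -> tuple[nn.Tensor, nn.Tensor]:
        """Factual/interventional SCM pass.

        Returns ``(z_scm, y_logits)`` where ``z_scm = f_Z(·) + ε_Z`` and the
        Y equation consumes ``z_in = (1 − z_blend)·z_backbone +
        z_blend·z_scm`` plus the gated voxel features.
        """
        noise = noise or ExogenousNoise.zero()
        feats_lat, feats_vox = feats
        z_scm = self.f_z(feats_lat)
        if not _is_zero(noise.eps_z):
            z_scm = z_scm + nn.astensor(noise.eps_z)
        if self.z_blend > 0:
            z_in = z_backbone * (1.0 - self.z_blend) + z_scm * self.z_blend
        else:
            z_in = z_backbone
        out_shape = feats_vox[0].shape[2:]
        y = self.f_y(z_in, feats_vox, out_shape)
        if not _is_zero(noise.eps_y):
            y = y + nn.astensor(noise.eps_y)
        if not np.isfinite(y.data).all() or not np.isfinite(z_scm.data).all():
            raise FloatingPointError(
                "non-finite structural output (training divergence)")
        return z_scm, y


def _is_zero(x) -> bool:
    if isinstance(x, nn.Tensor):
        return x.size == 1 and float(x.data) == 0.0
    return np.isscalar(x) and float(x) == 0.0


# ---------------------------------------------------------------------------
# Functional surface
# ---------------------------------------------------------------------------

def pool_modality_features(layer: SCMLayer, volume,
                           latent_shape: tuple[int, int, int]):
    """Per-modality latent-resolution feature grids (plus voxel-resolution
    embeddings as the second element)."""
    return layer.pool_modality_features(nn.astensor(volume), latent_shape)


def scm_forward(layer: SCMLayer, modality_feats, latent_z,
                noise: ExogenousNoise | None = None):
    return layer.forward(modality_feats, nn.astensor(latent_z), noise)


def regularizer_terms(graph: CausalGraph) -> tuple[nn.Tensor, dict]:
    """L1 of the effective (masked) edge weights plus a hook carrying the
    graph's prior edges for the consistency term."""
    sparsity = (graph.gate_mz().abs().sum()
                + graph.gate_my().abs().sum()
                + graph.gate_zy().abs().sum())
    hook = {"prior_edges": graph.prior_edges}
    return sparsity, hook


def edge_importance(model, probe_volumes: np.ndarray,
                    tumor_classes: tuple[int, ...] = (NCR, ED, ET),
                    ) -> dict[tuple[str, int], float]:
    """Modality→class scores combining learned gates and interventional
    causal-effect magnitudes.

    For each modality m, runs do(X^m = 0) on the probe batch through the SCM
    branch and measures the mean positive part of Δ_c over voxels factually
    predicted as class c (a supporting edge means removing m *reduces*
    class-c probability over its own region; softmax re-normalisation can
    inflate |Δ| of unrelated classes, which the positive part discards);
    that CE component and the |A ⊙ W| gate component are each
    max-normalised over all (m, c) pairs and averaged. Deterministic given
    model and probe batch.
    """
    from . import causal  # local import: causal consumes assembled models

    gates = model.scm.graph.gate_my().data  # (n_mod, C)
    fact = model.factual(probe_volumes)
    fact_probs = fact.probs_scm
    fact_cls = fact_probs.argmax(axis=1)

    ce = np.zeros((len(MODALITIES), len(tumor_classes)))
    gate = np.zeros_like(ce)
    for mi, m in enumerate(MODALITIES):
        iv = causal.Intervention.ablate(m)
        probs_cf = causal.counterfactual_probs(model, probe_volumes, iv,
                                               factual=fact)
        delta = fact_probs - probs_cf
        for ci, c in enumerate(tumor_classes):
            region = fact_cls == c
            if region.any():
                ce[mi, ci] = np.maximum(delta[:, c][region], 0.0).mean()
            gate[mi, ci] = gates[mi, c]
    if ce.max() > 0:
        ce = ce / ce.max()
    if gate.max() > 0:
        gate = gate / gate.max()
    score = 0.5 * ce + 0.5 * gate
    return {(m, c): float(score[mi, ci])
            for mi, m in enumerate(MODALITIES)
            for ci, c in enumerate(tumor_classes)}
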