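"""Training and inference engine.

Houses the overall mapping f_θ: the assembled model (backbone + SCM
layer), the interventional training loop and the inference path.

Each training step runs a factual backbone pass and a factual SCM pass;
with probability p one intervention is sampled from the pool (the four
modality ablations by default) and an interventional SCM pass is executed
under do(I), with gradients flowing jointly through the factual and
interventional computations. The objective combines decoder segmentation
losses, SCM-branch segmentation losses (the Y structural equation is fit
to the observed labels), a latent-fit term for the Z equation, the causal
consistency regulariser and the CRF-style smoothness penalty. Optimisation
is AdamW with polynomial learning-rate decay.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn, objective
from .backbone import Backbone, BackboneConfig, build
from .causal import Intervention, apply_intervention
from .io_prep import (AugmentParams, MultiModalVolume, SegmentationMask,
                      augment, preprocess)
from .metrics import dice_coefficient
from .objective import LossWeights, PriorTemplate
from .scm import CausalGraph, ExogenousNoise, SCMLayer

__all__ = ["TrainConfig", "CausalSegModel", "ForwardState", "train_step",
           "fit", "infer", "save_checkpoint", "load_checkpoint"]


# ---------------------------------------------------------------------------
# Model assembly
# ---------------------------------------------------------------------------

@dataclass
class ForwardState:
    """Everything produced by one factual pass (autodiff tensors)."""

    volume: nn.Tensor
    z: nn.Tensor
    skips: list
    feats: tuple
    logits_dec: nn.Tensor | None
    z_scm: nn.Tensor
    logits_scm: nn.Tensor

    @property
    def probs_dec(self) -> np.ndarray:
        return nn.softmax(self.logits_dec, axis=1).data

    @property
    def probs_scm(self) -> np.ndarray:
        return nn.softmax(self.logits_scm, axis=1).data


class CausalSegModel(nn.Module):
    """Backbone + SCM layer behind one parameter surface."""

    def __init__(self, config: BackboneConfig, scm_kwargs: dict | None = None,
                 seed: int = 0):
        self.config = config
        self.scm_kwargs = dict(scm_kwargs or {})
        self.backbone: Backbone = build(config, seed=seed)
        self.scm = SCMLayer(latent_channels=self.backbone.latent_channels,
                            n_classes=config.n_classes,
                            seed=seed + 1, **self.scm_kwargs)

    def factual(self, volumes, noise: ExogenousNoise | None = None,
                with_decoder: bool = True) -> ForwardState:
        x = volumes if isinstance(volumes, nn.Tensor) \
            else nn.Tensor(np.asarray(volumes, dtype=np.float32))
        z, skips = self.backbone.encode(x)
        logits_dec = self.backbone.decode(z, skips) if with_decoder else None
        feats = self.scm.pool_modality_features(x, z.shape[2:])
        z_scm, logits_scm = self.scm.forward(feats, z, noise=noise)
        return ForwardState(volume=x, z=z, skips=skips, feats=feats,
                            logits_dec=logits_dec, z_scm=z_scm,
                            logits_scm=logits_scm)

    def predict(self, volumes) -> np.ndarray:
        """Decoder softmax probabilities (standard inference path)."""
        return self.backbone.predict(volumes)

    def scm_predict(self, volumes) -> dict[str, np.ndarray]:
        state = self.factual(volumes)
        return {"probs_dec": state.probs_dec, "probs_scm": state.probs_scm,
                "logits_scm": state.logits_scm.data, "z": state.z.data}


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

def default_intervention_pool() -> list[Intervention]:
    from .io_prep import MODALITIES
    return [Intervention.ablate(m) for m in MODALITIES]


@dataclass
class TrainConfig:
    patch_size: int = 24
    epochs: int = 10
    batch_size: int = 2
    base_lr: float = 2e-3
    poly_power: float = 0.9
    weight_decay: float = 1e-5
    intervention_prob: float = 0.2
    seed: int = 0
    device: str = "cpu"
    checkpoint_dir: str | None = None
    width_scale: float = 0.25
    norm_groups: int = 4
    loss_weights: LossWeights = field(default_factory=LossWeights)
    priors: PriorTemplate = field(default_factory=PriorTemplate)
    augment_params: AugmentParams = field(
        default_factory=lambda: AugmentParams(
            rotation_max_deg=15.0, noise_sigma=0.05,
            intensity_scale_range=(0.95, 1.05), modality_dropout_prob=0.0))
    scm_seg_weight: float = 0.5
    latent_fit_weight: float = 0.1
    #: weight of the counterfactual-label supervision of interventional
    #: SCM passes (the hard form of the prior template's expectations)
    cf_seg_weight: float = 1.0
    #: per-intervention label remapping under do(·): the class whose
    #: defining contrast an ablation removes reads as background; classes
    #: not named are expected unchanged (invariance)
    counterfactual_targets: dict = field(default_factory=lambda: {
        "ablate:t1": {1: 0}, "ablate:flair": {2: 0}, "ablate:t1ce": {3: 0}})
    val_every: int = 1

    def __post_init__(self):
        if self.patch_size % 8:
            raise ValueError("patch_size must be divisible by 8")
        if not 0.0 <= self.intervention_prob <= 1.0:
            raise ValueError("intervention_prob must be in [0, 1]")
        # one knob for the interventional strategy: modality-dropout
        # augmentation (the decoder's exposure to ablated inputs) follows
        # the same probability as the SCM interventional passes
        self.augment_params.modality_dropout_prob = self.intervention_prob

    def backbone_config(self) -> BackboneConfig:
        return BackboneConfig(width_scale=self.width_scale,
                              norm_groups=self.norm_groups)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _seg_terms(logits: nn.Tensor, target_onehot: np.ndarray):
    probs = nn.softmax(logits, axis=1)
    return (objective.dice_loss(probs, target_onehot),
            objective.balanced_ce_loss(probs, target_onehot))


def train_step(batch, model: CausalSegModel, optimizer: nn.AdamW,
               config: TrainConfig, rng: np.random.Generator,
               intervention_pool: list[Intervention] | None = None,
               pool_cursor: list[int] | None = None,
               ) -> dict[str, float]:
    """One interventional training iteration.

    ``batch`` is ``(volumes, labels)`` numpy arrays, already preprocessed
    and augmented. An intervention is sampled with probability
    ``config.intervention_prob``; which pool entry fires cycles
    round-robin (``pool_cursor``) so every template gets equal coverage
    over a run. Returns the per-term loss breakdown.
    """
    volumes, labels = batch
    pool = intervention_pool if intervention_pool is not None \
        else default_intervention_pool()
    target = nn.one_hot(labels, model.config.n_classes)

    # factual passes (backbone + SCM)
    state = model.factual(volumes)
    dice_d, ce_d = _seg_terms(state.logits_dec, target)
    dice_s, ce_s = _seg_terms(state.logits_scm, target)

    # Bernoulli gate consumed every step so the stream stays aligned
    # whatever p is; the pool entry advances round-robin when it fires
    sampled = None
    draw = rng.random()
    if pool and draw < config.intervention_prob:
        cursor = pool_cursor if pool_cursor is not None else [0]
        sampled = pool[cursor[0] % len(pool)]
        cursor[0] += 1

    ce_maps = []
    cf_terms = {}
    if sampled is not None:
        modified = apply_intervention(model, state, sampled)
        _, logits_iv = model.scm.forward(modified["feats"], modified["z"])
        delta = nn.softmax(state.logits_scm, axis=1) \
            - nn.softmax(logits_iv, axis=1)
        # anchor the prior's class regions to the batch labels: a
        # prediction-defined region lets the model evade the constraint
        # by shrinking its own factual prediction
        ce_maps.append((sampled.id, delta, labels))
        if config.cf_seg_weight > 0:
            remap = config.counterfactual_targets.get(sampled.id, {})
            cf_labels = labels.copy()
            for old, new in remap.items():
                cf_labels[labels == old] = new
            cf_target = nn.one_hot(cf_labels, model.config.n_classes)
            dice_cf, ce_cf = _seg_terms(logits_iv, cf_target)
            w_cf = config.cf_seg_weight
            cf_terms = {"cf_dice": dice_cf * w_cf,
                        "cf_ce": ce_cf * (w_cf * config.loss_weights.alpha)}

    w = config.loss_weights
    causal_term = objective.causal_loss(model.scm.graph, ce_maps,
                                        config.priors, w.lambda1, w.lambda2)
    smooth_term = objective.smoothness_loss(state.logits_dec, state.volume)
    latent_fit = (state.z_scm - state.z.detach()).square().mean()

    components = {
        "dice": dice_d, "ce": ce_d, "causal": causal_term,
        "smooth": smooth_term,
        "scm_dice": dice_s * config.scm_seg_weight,
        "scm_ce": ce_s * (config.scm_seg_weight * w.alpha),
        "latent_fit": latent_fit * config.latent_fit_weight,
        **cf_terms,
    }
    loss, breakdown = objective.total_loss(components, w)
    if not np.isfinite(loss.data):
        raise FloatingPointError("training loss diverged (NaN/Inf); restore "
                                 "the last saved checkpoint")
    optimizer.zero_grad()
    loss.backward()
    optimizer.step()
    breakdown["intervention"] = 1.0 if sampled is not None else 0.0
    return breakdown


def _prep_cases(cases, config: TrainConfig):
    """Preprocess (z-score on the native grid) a list of PhantomCase-like
    objects into (volume, labels) pairs."""
    out = []
    for case in cases:
        vol, mask = preprocess(case.volume, case.mask,
                               target_shape=(config.patch_size,) * 3)
        out.append((vol, mask))
    return out


def evaluate_dice(model: CausalSegModel, val_pairs,
                  n_classes: int = 4) -> dict:
    """Per-class decoder Dice over a validation set."""
    per_class = np.zeros(n_classes)
    counts = np.zeros(n_classes)
    for vol, mask in val_pairs:
        probs = model.predict(vol.data[None])
        pred = probs.argmax(axis=1)[0]
        for c in range(n_classes):
            per_class[c] += dice_coefficient(pred == c, mask.labels == c)
            counts[c] += 1
    per_class /= np.maximum(counts, 1)
    return {"per_class": per_class.tolist(),
            "mean_foreground": float(per_class[1:].mean())}


def fit(train_cases, val_cases, config: TrainConfig,
        model: CausalSegModel | None = None):
    """Train to ``config.epochs`` with polynomial LR decay and periodic
    validation; the best checkpoint (validation mean foreground Dice) is
    retained and restored before returning.

    Returns ``(model, history)``.
    """
    if not train_cases:
        raise ValueError("empty training set")
    ss = np.random.SeedSequence(config.seed)
    order_rng, aug_rng, iv_rng = [np.random.default_rng(s)
                                  for s in ss.spawn(3)]

    train_pairs = _prep_cases(train_cases, config)
    val_pairs = _prep_cases(val_cases, config) if val_cases else []

    if model is None:
        model = CausalSegModel(config.backbone_config(), seed=config.seed)
    params = model.parameters()
    optimizer = nn.AdamW(params, lr=config.base_lr,
                         weight_decay=config.weight_decay)
    n = len(train_pairs)
    steps_per_epoch = int(np.ceil(n / config.batch_size))
    total_steps = steps_per_epoch * config.epochs

    history = {"steps": [], "epochs": [], "best_epoch": -1, "best_dice": -1.0}
    best_state = None
    step = 0
    pool_cursor = [0]
    for epoch in range(config.epochs):
        order = order_rng.permutation(n)
        t0 = time.time()
        for b in range(steps_per_epoch):
            idx = order[b * config.batch_size:(b + 1) * config.batch_size]
            vols, labs = [], []
            for i in idx:
                vol, mask = train_pairs[i]
                vol_a, mask_a = augment(vol, mask, config.augment_params,
                                        seed=int(aug_rng.integers(2 ** 31 - 1)))
                vols.append(vol_a.data)
                labs.append(mask_a.labels)
            batch = (np.stack(vols), np.stack(labs))
            optimizer.lr = nn.poly_lr(config.base_lr, step, total_steps,
                                      config.poly_power)
            breakdown = train_step(batch, model, optimizer, config, iv_rng,
                                   pool_cursor=pool_cursor)
            breakdown["lr"] = optimizer.lr
            history["steps"].append(breakdown)
            step += 1
        record = {"epoch": epoch, "seconds": time.time() - t0}
        if val_pairs and (epoch + 1) % config.val_every == 0:
            val = evaluate_dice(model, val_pairs)
            record["val"] = val
            if val["mean_foreground"] > history["best_dice"]:
                history["best_dice"] = val["mean_foreground"]
                history["best_epoch"] = epoch
                best_state = model.state_dict()
        history["epochs"].append(record)
    if best_state is not None:
        model.load_state_dict(best_state)
    if config.checkpoint_dir:
        save_checkpoint(model, Path(config.checkpoint_dir) / "best.npz",
                        extra={"history_best_epoch": history["best_epoch"]})
    return model, history


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------

def _tile_starts(full: int, patch: int, overlap: float) -> list[int]:
    if full <= patch:
        return [0]
    stride = max(1, int(patch * (1 - overlap)))
    starts = list(range(0, full - patch + 1, stride))
    if starts[-1] != full - patch:
        starts.append(full - patch)
    return starts


def infer(model: CausalSegModel, volume: MultiModalVolume,
          intervention_set: list[Intervention] | None = None,
          patch_size: int | None = None, overlap: float = 0.5):
    """Standard inference: one factual decoder pass (sliding-window tiled
    with overlap-averaged probabilities when the volume exceeds the patch
    size). Explanations are computed only for requested interventions.

    Returns ``(mask, probs, explanations)``.
    """
    from .causal import explain

    data = volume.data[None]
    sp = data.shape[2:]
    patch = patch_size or min(sp)
    if all(s <= patch for s in sp):
        probs = model.predict(data)
    else:
        acc = np.zeros((1, model.config.n_classes) + sp, dtype=np.float64)
        cnt = np.zeros(sp, dtype=np.float64)
        for sx in _tile_starts(sp[0], patch, overlap):
            for sy in _tile_starts(sp[1], patch, overlap):
                for sz in _tile_starts(sp[2], patch, overlap):
                    sl = (slice(sx, sx + patch), slice(sy, sy + patch),
                          slice(sz, sz + patch))
                    tile = data[(slice(None), slice(None)) + sl]
                    acc[(slice(None), slice(None)) + sl] += \
                        model.predict(tile)
                    cnt[sl] += 1.0
        probs = (acc / cnt).astype(np.float32)
    mask = probs.argmax(axis=1).astype(np.int16)[0]
    explanations: dict = {}
    if intervention_set:
        _, explanations = explain(model, data, intervention_set)
    return mask, probs[0], explanations


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(model: CausalSegModel, path: str | Path,
                    extra: dict | None = None) -> Path:
    """Single-file weights + config (+ learned graph export)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {
        "backbone_config": dataclasses.asdict(model.config),
        "scm_kwargs": model.scm_kwargs,
        "graph": model.scm.graph.export(),
        "extra": extra or {},
    }
    arrays = {f"param/{k}": v for k, v in model.state_dict().items()}
    arrays["__meta__"] = np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8)
    np.savez_compressed(path, **arrays)
    return path


def load_checkpoint(path: str | Path) -> CausalSegModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k[len("param/"):]: data[k] for k in data.files
                 if k.startswith("param/")}
    cfg_kwargs = meta["backbone_config"]
    cfg_kwargs["level_channels"] = tuple(cfg_kwargs["level_channels"])
    config = BackboneConfig(**cfg_kwargs)
    model = CausalSegModel(config, scm_kwargs=meta["scm_kwargs"])
    model.load_state_dict(state)
    g = meta["graph"]
    model.scm.graph.mask_mz = np.asarray(g["mask_mz"], dtype=float)
    model.scm.graph.mask_my = np.asarray(g["mask_my"], dtype=float)
    model.scm.graph.mask_zy = float(g["mask_zy"])
    return model
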