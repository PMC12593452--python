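# causalseg

Causality-guided 3D multi-modal MRI tumor segmentation.

`causalseg` couples a 3D encoder–decoder segmentation network with a
learnable **structural causal model (SCM)** over the variables
{modalities **M** = {T1, T2, FLAIR, T1CE}, latent features **Z**, labels
**Y**}, so that a segmentation model can be *interrogated causally*:
which modality's signal carries which tumor class, what happens under
the intervention do(X^m = 0), and what the counterfactual segmentation
would have been had the imaging been different.

It is aimed at researchers studying interpretable segmentation: the
whole pipeline is verified end-to-end on synthetic multi-modal brain
phantoms whose modality→tissue causal graph is known **by
construction**, so causal-recovery claims can be tested rather than
eyeballed. No external data or GPU is needed; everything runs on one
CPU.

## Model

The backbone is a residual 3D U-Net (double 3×3×3 convs with GroupNorm
and PReLU, strided-conv downsampling, transposed-conv upsampling, skip
concatenation, 1×1×1 softmax head; channel plan 32/64/128/256 with a
320-channel bottleneck, width-scalable). The bottleneck latent grid Z
(1/8 resolution) feeds the SCM layer, whose structural equations with
additive exogenous noise are

    Z = f_Z( Σ_m g[m→Z]·φ_m , C_Z ) + ε_Z
    Y = f_Y( Z , Σ_m g[m→Y,c]·ψ_m , C_Y ) + ε_Y

where φ_m, ψ_m are per-modality embeddings, C_· are 3×3×3 neighbourhood
contexts, and every edge weight is masked by a binary adjacency A
(effective gate A ⊙ softplus(W)), so biologically implausible edges are
structurally absent and the canonical radiological priors (FLAIR→edema,
T1CE→enhancing tumor, T1→necrosis) are first-class citizens.

Training (AdamW, polynomial LR decay) optimises

    L = L_Dice + α·L_CE + β·L_Causal + γ·L_Smooth
    L_Causal = λ₁·‖A ⊙ W‖₁ + λ₂·E_do‖Δ_c − Δ_c^prior‖₁

with interventional minibatches: with probability p = 0.2 a do(·) from a
template pool (the four modality ablations by default) is applied, the
SCM branch is re-run under the intervention, and the causal-effect map
Δ_c(x) = p_factual(c|x) − p_interventional(c|x) is regularised toward
weak domain expectations. Counterfactuals follow
Abduction–Action–Prediction: ε̂ is inferred in closed form (additive
noise), the intervention applied, and the SCM re-run with ε̂ held fixed.

## Worked example

```python
import numpy as np
import causalseg as cs

spec = cs.PhantomSpec()                      # 24³ four-channel phantoms
train = cs.phantom.generate_cases(spec, 32, seed=1000)
val   = cs.phantom.generate_cases(spec, 8,  seed=2000)

model, hist = cs.fit(train, val, cs.TrainConfig(seed=0))
print(f"val mean foreground Dice: {hist['best_dice']:.3f}")

# causal-graph recovery against the generator's ground truth
probe = np.stack([cs.preprocess(c.volume, c.mask,
                                target_shape=(24,)*3)[0].data
                  for c in val[:4]])
scores = cs.edge_importance(model, probe)
auroc, prec = cs.graph_recovery(scores, spec.truth_adjacency)
print(f"edge-recovery AUROC: {auroc:.2f}, precision@k: {prec:.2f}")

# counterfactual: what if there had been no contrast agent?
x = cs.preprocess(val[0].volume, val[0].mask, target_shape=(24,)*3)[0]
state = model.factual(x.data[None])
probs_cf, mask_cf, ce = cs.counterfactual(model, x.data[None],
                                          cs.Intervention.ablate("t1ce"))
print(f"ET voxels factual: {(state.probs_scm.argmax(1) == 3).sum()}, "
      f"counterfactual: {(mask_cf == 3).sum()}")
```

Typical output on one CPU (≈2 min of training):

```
val mean foreground Dice: 0.989
edge-recovery AUROC: 1.00, precision@k: 1.00
ET voxels factual: 673, counterfactual: 116
```

The Dice says the tiny model segments the phantoms almost perfectly;
the AUROC says the learned edge-importance ranking reproduces the
generator's true modality→class graph; and the collapse of the
enhancing-tumor (ET) count under do(X^T1CE = 0) says the model's ET
predictions are causally dependent on contrast enhancement, not on
correlated context.

A CLI mirrors the library: `causalseg simulate | perturb | preprocess |
train | infer | explain | evaluate` (see `causalseg --help`).

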