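# Methods

This note documents the models, the synthetic data, the numerical
choices and the limitations of `causalseg`, at the level of detail a
user needs to judge what the package's tests do and do not demonstrate.

## Problem setting

Multi-modal brain MRI (T1, T2, FLAIR, T1CE) is segmented voxel-wise
into background (0), necrotic core NCR (1), peritumoral edema ED (2)
and enhancing tumor ET (3); the composite regions are TC = NCR ∪ ET and
WT = NCR ∪ ED ∪ ET. Beyond the segmentation itself, the package models
the *causal* relations between modalities and predictions: each
modality carries a characteristic contrast for specific tissue classes
(FLAIR hyperintensity for edema, contrast enhancement on T1CE for
active tumor, T1 hypointensity for necrosis), and the model should rely
on these mechanisms — verifiably, via interventions — rather than on
correlated context.

## Segmentation backbone

A 3D U-Net-style encoder–decoder (`causalseg.backbone`):

- Encoder: four levels of residual double convolutions
  (Conv3×3×3 → GroupNorm → PReLU, twice, with an identity or
  1×1×1-projected additive skip around the pair), separated by stride-2
  3×3×3 convolutions. Channel plan 32/64/128/256, bottleneck 320,
  all scaled by `width_scale` (tests use 0.25 → 8/16/32/64/80).
- The bottleneck double-conv output is the latent grid Z at 1/8 of the
  input resolution — the SCM's interface.
- Decoder: a 1×1×1 projection + skip concatenation at bottleneck
  resolution, then three transposed-conv (2×2×2, stride 2) upsampling
  levels with skip concatenation and double convs, and a 1×1×1 softmax
  head.
- GroupNorm uses 8 groups (4 at tiny widths); PReLU slopes are
  per-channel, initialised at 0.25; weights are He-normal with a seeded
  generator, so models are bit-reproducible per seed.

Input spatial dimensions must be divisible by 8; larger volumes are
handled at inference by sliding-window tiling with overlap-averaged
probabilities.

## Structural causal model layer

The graph has nodes M ∪ {Z, Y} and only forward edges m→Z, m→Y, Z→Y,
so it is acyclic by construction. Each edge weight is
`softplus(raw) × A`, with A a binary adjacency mask; a forbidden edge
contributes exactly zero and its weight is bitwise inert.

- **Default adjacency.** All m→Z edges and Z→Y are allowed. Direct
  m→Y edges are restricted to the canonical domain set T1→NCR,
  FLAIR→ED, T1CE→ET. This masking is load-bearing: with all m→Y edges
  open, a model can represent a class by the *absence* of other
  modalities' signatures (e.g. "enhancing tumor = inside the tumor but
  neither T1-dark nor FLAIR-bright"), a shortcut that survives ablation
  of the class's true modality and defeats counterfactual reasoning.
  Restricting the per-voxel modality paths to plausible edges removes
  that shortcut structurally. The mask is user-configurable.
- **Prior-consistent initialisation.** Allowed prior edges start at
  gate ≈ 1.0, all other edges at ≈ 0.3. Because the per-voxel modality
  maps ψ_m have a free sign, the "inverted" coding (negative response
  with weight on other classes) is a local optimum that scrambles gate
  interpretability; starting prior-shaped selects the direct coding
  basin, and the L1 penalty prunes whatever training does not use.
- **Structural functions.** φ_m are per-modality embeddings of the
  block-average-pooled channel at latent resolution (f_Z input); ψ_m
  are per-modality 1×1×1 voxel embeddings at input resolution,
  tanh-bounded and baseline-subtracted so (a) contribution magnitude
  lives in the gate, not the embedding scale, and (b) a silenced
  modality contributes exactly zero. f_Z and f_Y are shared-weight
  per-voxel MLPs (1×1×1 convs, hidden width 32, PReLU) with 3×3×3
  box-filter context inputs. The Y equation runs at full input
  resolution — the label field is voxel-wise, and at the 24³ test scale
  a latent-resolution label node could not represent the thin enhancing
  rim at all; the latent trunk is compressed (1×1×1 to 16 channels) and
  upsampled trilinearly, so fine spatial detail necessarily routes
  through the gated per-modality voxel paths.
- **Latent mediation.** The Y-trunk consumes
  `z_in = (1−b)·Z_backbone + b·Z_scm`, and the default is b = 1: the Y
  equation sees the SCM's *own* Z node, f_Z(gated pooled features),
  with the backbone latent entering only through the latent-fit term
  that trains f_Z to approximate it. This is the configuration in which
  interventions propagate to the trunk exclusively through a trained,
  controlled path. The alternative (b < 1, mixing in the re-encoding of
  the intervened volume) was measured to make counterfactual behaviour
  seed-chaotic: the encoder's response to an ablated input is a
  nonstationary out-of-distribution signal that the few interventional
  steps per run cannot shape. The blend weight remains exposed for
  experimentation.
- **Exogenous noise** is additive on Z and on the Y logits (adding ε to
  probabilities would break the simplex). Abduction is therefore exact:
  ε̂ = observed − deterministic part, which is what the one-step Newton
  update degenerates to; a zero-noise factual pass abducts ε̂ ≈ 0 and
  injected noise is recovered to machine precision.

## Interventions and counterfactuals

do(V = v) sets the target and recomputes downstream quantities along
*allowed* edges: modality interventions rewrite the channel, re-derive
the modality features, and re-encode the latent (only if the modality
has an allowed m→Z edge — a fully masked modality propagates nothing,
keeping masked-path nullity bitwise); feature clamps set the latent on
a region; ROI edits rewrite post-normalisation intensities (they do not
re-enter preprocessing — re-z-scoring after a hypothetical edit would
entangle the intervention with normalisation statistics).

CE maps difference factual and interventional probabilities from the
same (SCM) branch; differing the decoder's factual output against the
SCM's interventional one (the `alg2_literal` flag) attributes the
branch mismatch to the intervention, which is why it is not the
default. Counterfactual masks are plain argmax; no CRF decoding.

## Objective

`L = L_Dice + α·L_CE + β·L_Causal + γ·L_Smooth` with defaults
α = 1, β = 1, γ = 0.1, λ₁ = 5·10⁻³, λ₂ = 2.

- Soft Dice over foreground classes with ε = 10⁻⁵ (an absent class
  contributes ε/ε = 1, i.e. no loss).
- Class-balanced cross-entropy: per-class weights ∝ inverse batch
  frequency over present classes, normalised to mean 1; probabilities
  floored at 10⁻⁷.
- Causal consistency: λ₁·‖A ⊙ W‖₁ plus λ₂ times the mean (over sampled
  interventions) L1 deviation of the CE map from the prior template,
  evaluated voxel-wise over the batch's ground-truth class regions — the
  voxel-level form gives a dense gradient where a region-mean constraint
  gives a single scalar per (rare) interventional step, and anchoring
  regions to labels (rather than predictions) closes the loophole of
  evading the constraint by shrinking the factual prediction. Template
  entries are (intervention, region class, target class) triples; the
  defaults say: ablating the modality that carries a class removes
  ≈ 0.9 of its probability over its region *and that probability
  reappears as background* (−0.9 on the background class over the same
  region — without naming the takeover class the optimiser has no
  winner to hand the freed probability to), while ablating any other
  modality changes a class by ≈ 0. The zero entries are what turn
  interventional training into a disentanglement constraint rather than
  a pure sensitivity one.
- Counterfactual-label supervision (engine term, weight 1.0): each
  interventional SCM pass is additionally supervised with the
  intervention's expected counterfactual labels — the carried class
  remapped to background under its modality's ablation, the identity
  map (i.e. an invariance constraint) for non-causal ablations. This is
  the same domain expectation as the prior template expressed in
  Dice+cross-entropy geometry, which conditions far better than an L1
  penalty on probabilities: with only ~30 interventional steps per run,
  L1-on-probability pulses either stalled (saturating softmax
  gradients) or destabilised individual runs.
- Smoothness: Σ over 6-neighbour pairs of exp(−ΔI²/2σ_I²)·‖Δlogits‖²
  normalised by pair count, on decoder logits; ΔI is the
  across-modality mean intensity difference and σ_I its batch standard
  deviation.
- The engine adds two auxiliary supervised terms, both logged in the
  breakdown: the SCM branch's own Dice+CE against the labels (the Y
  structural equation is a model *of the label field* and must be fit
  to it for its counterfactual masks to mean anything), and an L2 fit
  of f_Z's prediction to the (detached) encoder latent, which keeps the
  Z equation's abduction residuals small and its interventional
  responses meaningful.

## Training protocol

AdamW (weight decay 10⁻⁵), base LR 2·10⁻³ with polynomial decay
(power 0.9), batch size 2, 10 epochs over 32 training phantoms
(160 steps). With probability p = 0.2 a minibatch carries one
intervention; the pool entry cycles round-robin so all four modality
ablations get equal coverage regardless of seed (uniform sampling makes
the per-modality count a small Binomial and the rarest modality's
training signal seed-dependent). Gradients flow through both factual
and interventional passes. Augmentation: rotations up to ±15° (trilinear
image / nearest labels), per-channel intensity scaling (±5%), additive
Gaussian noise (σ = 0.05); elastic deformation is available but off by
default. Modality-dropout augmentation is tied to the intervention
probability (one knob for the whole interventional strategy): at
p = 0.2 the decoder sees whole-channel-ablated inputs through dropout
while the SCM branch sees them through do(·) passes, and a p = 0
configuration disables both, which is what makes the
interventional-vs-plain robustness comparison mechanistic. Validation
runs every epoch; the best checkpoint by mean foreground Dice is kept.

## Synthetic phantoms

Each case (default 24³ voxels, 1 mm isotropic) is a brain ellipsoid
containing nested tumor compartments: whole tumor ⊃ tumor core ⊃
necrotic core, realised as concentric ellipsoids with randomised
centre, radii and anisotropy; ED = WT∖TC, ET = TC∖NCR. The generative
causal structure is explicit: class c's contrast appears in modality m
iff the ground-truth adjacency has edge m→c (defaults: T1→NCR −0.65,
FLAIR→ED +1.2, T1CE→ET +1.5 on a base signal of 1.0). Contrast fields
are Gaussian-tapered (σ = 0.7) *within* their own class so absent
edges carry no leaked boundary signal. Nuisance structure: a shared
smooth anatomy texture (amplitude 0.02), per-modality smooth
multiplicative bias fields (±1.5%) and Rician noise (σ = 0.10). The
nuisance amplitudes are deliberately small relative to the noise so
that the generator satisfies its own faithfulness property (true edges
separate class from background by > 1 pooled standardised unit, absent
edges by < 0.25); spatially correlated fields shift region means and
would otherwise confound the absent-edge bound.

What the phantoms do **not** emulate: anatomical geometry (no atlas,
no cortex), infiltrative/irregular tumor margins, partial-volume
effects, inter-scanner intensity variation, or any ambiguity about
which modality carries which class. Passing tests therefore show that
the causal machinery behaves as specified when the generative story is
clean — not that the same graph would be recovered from clinical data.
One consequence is worth stating plainly: because the compartments
tile a nested geometry, a class's extent is partially inferable from
the *other* classes' signals, so causal reliance on the correct
modality is enforced by the adjacency mask and the interventional
prior, not guaranteed by the data alone.

Stress perturbations mirror the robustness protocol: Rician corruption
calibrated so mean in-brain signal / σ equals the requested SNR
(re-estimable from the output to within ±10%); smooth multiplicative
bias within [1−ℓ, 1+ℓ]; sub-voxel linear motion blur (a box kernel of
the stated extent with fractional end taps, along a random axis);
single-modality ablation. SNR is defined as mean in-brain signal over
Rician σ; the blur kernel and bias-field construction are package
choices, stated here because the stress protocol names only the
nominal levels.

## Edge importance and graph recovery

For each (modality, class) pair the score averages two max-normalised
components: the learned gate |A ⊙ W|[m, c], and the mean *positive
part* of Δ_c under do(X^m = 0) over the voxels factually predicted as
class c. The positive part matters: softmax renormalisation inflates
|Δ| of unrelated classes (probability mass freed by the ablated class
must land somewhere), whereas a supporting edge specifically *reduces*
its class's probability when removed. Recovery is scored against the
phantom's ground-truth adjacency by tie-aware AUROC and precision at
k = number of true edges. Because the default adjacency mask already
encodes the canonical edges, recovery on the default phantom partly
reflects the prior; the generator accepts arbitrary adjacencies (and
the test suite includes a phantom with the FLAIR→ED edge removed), so
prior-free recovery can be probed by opening the mask and editing the
truth.

## Numerical and engineering choices

- The compute layer is a package-internal reverse-mode autodiff engine
  on numpy (`causalseg.nn`): conv3d as shift-and-accumulate GEMMs,
  transposed conv as tensordot+reshape, GroupNorm/PReLU/softmax/
  box-filter/trilinear primitives with hand-derived adjoints, AdamW,
  polynomial LR. Every primitive's gradient is tested against central
  finite differences (float64) at ≤ 10⁻⁵ relative error; all parameters
  are float32.
- Determinism: every stochastic component (phantoms, augmentation,
  intervention sampling, initialisation) draws from seeded generators;
  fixed seeds reproduce training traces exactly on a given platform.
- Empty-region metric conventions: both masks empty → Dice 1, HD95 0;
  one empty → Dice 0, HD95 = grid diagonal in mm. HD95 is the max of
  the two directed 95th-percentile surface distances (surface = mask
  minus erosion); boundary-F1 tolerance is 2 voxels; calibration uses
  15 equal-width bins; uncertainty is predictive entropy, and both
  case-level and voxel-level Spearman correlations are reported since
  the convention is genuinely ambiguous.
- Degenerate inputs: empty brain masks and constant channels raise
  (the latter guardable with `variance_epsilon`, used when z-scoring
  deliberately ablated channels); NaN in any structural output or loss
  term raises immediately naming the term.
- Problem sizes in the shipped experiments (24³ grids, quarter-width
  model, 32+8 cases, 10 epochs, 3–5 seeds) are chosen so the full
  suite runs on a single CPU in minutes; all conclusions above are
  claimed at that scale only.

## Known limitations

- The SCM's Z equation is an abstraction fitted to the encoder latent,
  not a mechanistic generative model; counterfactual latents are
  first-order (additive-noise) constructions.
- Counterfactual validity is internal to the model: there is no
  image-space counterfactual synthesis, so "what the scan would have
  looked like" is never materialised.
- Structure learning is masked-weight learning only; no DAG search, and
  unobserved confounding beyond additive exogenous noise is out of
  scope.
- The robustness harness evaluates the decoder head; SCM-branch
  robustness is exercised only through the causal criteria.
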