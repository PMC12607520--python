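# Methods

This note records the model as implemented, the choices made where the
design was genuinely open, what the synthetic data does and does not
emulate, and the numerical conventions the tests rely on.

## Architecture

**Stem.** 7×7 convolution, 64 filters, stride 2, TF-style "same" padding →
batch norm → ReLU → 3×3 max pool, stride 2, "same" padding. The pool stride
is not forced by the layer description alone; stride 2 is the standard
choice that yields the canonical 4× stem downsampling (224×224×3 →
56×56×64).

**Expert block.** Attention → conv stack → squeeze-excitation → residual.

* *Attention arity.* The block carries two multiplicative gates: a 7×7-conv
  **spatial** gate producing a single H×W map, and a pooled-bottleneck
  **channel** gate producing a length-C vector. The single-channel reading
  of the 7×7 conv output is a deliberate reconstruction: a triple
  elementwise product `Z ⊗ A ⊗ B` is only dimensionally coherent when one
  factor broadcasts over channels and the other over space, and a C→C 7×7
  conv at 256 channels would by itself blow the parameter budget of this
  model family. Descriptions of this architecture sometimes label the
  7×7-conv stream "channel attention" and the pooled stream "spatial
  attention"; this package names gates by what they modulate.
* *Conv stack.* 1×1 (C→32) + BN + ReLU, 3×3 grouped (4 groups) + BN + ReLU,
  1×1 (32→C) + BN with no activation — the residual sum decides the sign,
  and the block ReLU comes after the sum: `out = ReLU(gate·X₃ + Z_in)`.
  Applying the nonlinearity post-residual is the standard reading of a
  formula that wraps the whole sum.
* *Residual source.* The residual adds the **block's own input**. Any other
  choice (e.g. the stem output) breaks shape compatibility from stage 2 on.
* *Bias convention.* Convolutions immediately followed by batch norm carry
  no bias: BN subtracts the per-channel mean, so such a bias is
  unidentifiable and provably receives zero gradient; BN's shift β plays
  its role. This also keeps the gradient-reach property clean (see below).
  The three pool-bottleneck gates (attention channel stream, SE, global
  context) are likewise bias-free, matching their usual two-weight form.

**Routing.** Scores are `GAP(input) · W_R` with no bias (a config flag can
add one); softmax with detached max-subtraction (exactly shift-invariant,
so numerically stabilized without changing the result). Routing is *soft*:
every expert always runs, outputs are scaled by their weights and
**concatenated** — the channel plan accounts for the N× growth. `W_R`
initializes to small values (std 0.01, seeded) so routing starts near
uniform and specialization emerges through backpropagation; the package
keeps no routing state beyond `W_R`, and per-batch weight traces are
captured for diagnostics.

**Channel plan.** Stem width `base` (64 default); stage *s* experts run at
`base·2^(s-1)`; the stage concat holds `N·base·2^(s-1)` channels and the
following transition compresses to `base·2^s` while halving H and W (floor
division for odd sizes; the default pipeline only produces even sizes).
With 3 experts and base 64 the full model has 845,659 trainable parameters.

**Heads and loss.** Final head: global average pool → linear(512) → ReLU →
dropout 0.5 (training only) → linear. Auxiliary heads (GAP → linear) attach
after the two transitions — attaching post-transition keeps their input
widths small. Classification loss is cross-entropy on logits (the natural
choice for multi-class heads); the composite loss is
`γ_o·L_final + Σ γ_s·L_aux` with defaults `γ_o = 1.0`, `γ_s = 0.3`,
constant over training and exposed both in the model config and the TPE
search space. Auxiliary terms are dropped outside training. Optimizer:
Adam, lr 1e-3 by default (lr, batch size, dropout and γ are in the shipped
tuning space).

## TPE tuner

* Good/bad split: `|good| = max(1, ceil(γ·n))` with ties broken by trial
  index; both sides always nonempty for n ≥ 2. Defaults γ = 0.25, 10
  initial random trials, 24 candidates per iteration, ε = 1e-12.
* Numeric kernels: one truncated Gaussian per observation, bandwidth
  `max(nearest-neighbour distance, 1% of domain width)` (capped at the
  domain width), blended with a uniform prior component of weight
  `1/(k+1)`. Truncation keeps each density properly normalized on its
  domain (verified by trapezoidal integration in the tests). Log-scaled
  parameters are modelled on the log axis; integers on `[low−0.5,
  high+0.5]` with rounding at sampling time.
* Categorical parameters use Laplace-smoothed frequency tables (smoothing
  1). Conditional parameters are fitted only on trials where they were
  active, carry no value when inactive, and fall back to their prior
  density on a side with no active observations.
* The acquisition is `l(z)/(g(z)+ε)` with `l` fitted to the good set — the
  convention where the *ratio is maximized* (notation for which density is
  called *g* varies; the maximize-l/g reading is implemented).
* Failed trials (exceptions, non-finite objectives) are recorded, excluded
  from both density fits, and never become the incumbent.
* Determinism: the per-trial RNG is derived from (seed, trial index), so a
  full run is bit-reproducible and, whenever the warm-up covers the whole
  budget, the trial sequence coincides exactly with the random-search
  baseline under the same seed.

## Synthetic data

The generator emulates the gross statistics of capsule-endoscopy frames:
a Gaussian-smoothed pink/tan mucosa field (correlation length
`texture_scale`, default 16 px), optional radial illumination falloff with
a jittered centre, per-pixel Gaussian noise (`noise_sd`, default 0.02), and
one lesion per frame for lesion classes — irregular bright-red blobs
(bleeding), pale discs with dark rims (ulcer), shaded bumps (polyp), thin
dark-red dendritic streaks (AVM). All colour/shape constants are fixed
module-level values so contrast statistics can be recomputed exactly from
the emitted images and masks; blood red (0.86) deliberately exceeds the
mucosa base red (0.78) so the documented red-channel margin inside bleeding
masks has a closed-form direction. `lesion_contrast` ∈ (0,1] linearly
interpolates lesion colour over background and is the difficulty dial;
radii default to 1/10–1/4 of the frame. Masks are emitted even though the
task is classification-only: they make the attention-overlap check possible
without human annotation. Images live in [0,1]; 8-bit quantization happens
only at PNG boundaries.

What it does **not** emulate: specular highlights, bubbles and debris,
motion blur, inter-patient colour shifts, multiple/partial lesions, or any
anatomical structure. Passing tests therefore demonstrate that the
*mechanisms* (learning, routing specialization, attention localization,
ablation direction) operate as designed — not clinical performance.

## Study problem sizes

* **Learnability run:** 2 classes (non-bleeding/bleeding), 250 images per
  class at 64×64, stratified 80/20 split (400/100), default contrast 0.5;
  model with 2 experts/stage at base 32; Adam lr 1e-3, batch 16, at most 15
  epochs with early exit at 100 % validation accuracy. Reaches ≥ 95 %
  within 15 epochs (typically 100 % by epoch ~5).
* **Ablation benchmark:** same classes at 32×32, contrast 0.35, noise 0.05,
  100/class (160/40 split), base-16 model, 10 epochs, seeds {0,1,2}. This
  sits in the converged-but-unsaturated regime where capacity differences
  are visible; mean validation accuracy over seeds is compared across
  1/2/3 experts and SE on/off.
* **TPE benchmark:** quadratic `(z−0.3)²` on [0,1], budget 60, 10 warm-up
  trials, 24 candidates, medians over 20 paired seeds against matched
  random search.

## Numerical conventions

* Everything is float64. Training, evaluation and generation are
  bit-reproducible on one CPU given the config seeds (model init, dropout,
  batch order, augmentation and data generation each draw from their own
  seeded generator).
* Batch norm: training mode uses biased batch statistics and updates
  running averages (momentum 0.1, eps 1e-5); eval mode uses the running
  averages. Fresh layers have unit variance / zero mean running stats, so
  an untrained layer in eval mode is the identity up to the eps term.
* "Same" padding follows the TensorFlow convention (extra pixel goes to
  the bottom/right); max pooling pads with −∞, so borders never invent
  zeros; average pooling is non-overlapping with floor behaviour.
* Softmax monotonicity is strict mathematically but not representable once
  a weight rounds to exactly 1.0 in float64 (score gaps ≳ 37); tests keep
  scores below that regime.
* The autodiff engine is validated by central-difference gradient checks on
  every op family and by straight-line (loop-based, no im2col) oracle
  re-implementations of every block, which double as the dual-route
  equivalence tests.

## Known limitations

* **Attention polarity is not identified.** The spatial gate reliably
  learns to *segment* the lesion region on the synthetic bleeding task, but
  whether it up-weights or down-weights the lesion depends on the
  initialization seed: the residual bypass lets downstream layers use
  either polarity equally well. The attention-localization check therefore
  holds for its fixed seeded run, and across seeds the in-mask-vs-outside
  fraction is bimodal (near 1 or near 0, rarely near 0.5). Interpreting
  attention overlays on real data should take the gate's sign as
  model-specific.
* Training is CPU-bound numpy; the package is built for mechanism-scale
  experiments (tens of thousands of 64×64 images at most), not for
  full-resolution clinical training runs.
* Soft routing executes every expert, so compute grows linearly with the
  expert count; there is no sparse/top-k path, load-balancing loss or
  capacity factor (none is part of this design).
* Early stopping, LR schedules and pretrained weights are out of scope;
  best-checkpoint selection is by validation accuracy.
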