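# endomoe

An attention-driven, hierarchical **mixture-of-experts CNN with dynamic
routing** for classifying wireless-capsule-endoscopy (WCE) frames, together
with a self-contained **Tree-Structured Parzen Estimator (TPE)**
hyperparameter tuner and a **synthetic WCE data generator** that makes every
part of the pipeline testable without downloading clinical data.

WCE produces thousands of frames per study; pathologies such as bleeding,
ulcers, polyps and arteriovenous malformations appear as small, low-contrast
lesions on highly variable mucosa. The architecture implemented here
addresses that with three ideas working together: multiplicative
spatial/channel attention inside every expert, several parallel experts per
stage whose contributions are weighted per image by a learned router, and
deep supervision so early stages receive a direct training signal.

## The model

For an input frame `x ∈ [0,1]^{224×224×3}`, a stem extracts low-level
features

    Z' = MaxPool₃ₓ₃( ReLU( BN( W₇ₓ₇ * x ) ) )          (stride 2 twice → 56×56×64)

Three stages follow. Stage *s* holds *N* expert blocks at channel width
`C_s` (64, 128, 256 by default). Each expert computes, from its input `Z`:

    spatial gate   A_sp = σ( BN( W₇ₓ₇ * Z ) )                ∈ (0,1)^{H×W}
    channel gate   A_ch = σ( W₂' · ReLU( W₂ · GAP(Z) ) )     ∈ (0,1)^C      (reduction 16)
    Z_f  = Z ⊗ A_sp ⊗ A_ch
    X₃   = BN(W₁ₓ₁ * ReLU(BN(W₃ₓ₃,g=4 * ReLU(BN(W₁ₓ₁ * Z_f)))))   (32-ch bottleneck)
    gate = σ( W_SE2 · ReLU( W_SE1 · GAP(X₃) ) )                    (squeeze-excitation)
    out  = ReLU( gate ⊗ X₃ + Z )                                    (residual)

The router produces a per-image simplex over the stage's experts,

    R = GAP(Z) · W_R,      ∂_j = e^{R_j} / Σ_i e^{R_i},

every expert processes the input (soft routing), each output is scaled by
its weight, and the scaled outputs are **concatenated** (`N·C_s` channels).
A transition block (1×1 conv → BN → ReLU → 2×2 average pool) compresses and
downsamples between stages. After stage 3 a global-context gate (same
pool-bottleneck-sigmoid form) recalibrates the features before the head:
GAP → linear(512) → ReLU → dropout(0.5) → linear(num_classes). Two
auxiliary heads (GAP → linear) after the two transitions contribute to the
training loss only:

    L_total = γ_o · L_final + Σ_s γ_s · L_aux,s        (γ_o = 1, γ_s = 0.3)

The default full model (3 stages × 3 experts) has **0.85 M trainable
parameters**, well inside the published ≤ 11.6 M budget for this
architecture family.

The TPE tuner (`endomoe.tpe`) is independent of the model: it splits past
trials into good/bad sets at the γ-quantile, fits per-parameter Parzen
densities `l` and `g` (truncated-Gaussian mixtures with a uniform prior
component; Laplace-smoothed tables for categoricals; tree-structured
conditional parameters), and proposes the candidate maximizing
`l(z)/(g(z)+ε)`. A seed-matched random-search baseline is included.

Everything runs on a small numpy reverse-mode autodiff engine
(`endomoe.autograd`, `endomoe.nn`) written for this package — double
precision, single CPU, bit-reproducible under a seed, and gradient-checked
against finite differences in the test suite.

## Worked example

```python
from endomoe import (SyntheticSpec, generate_dataset, train_val_split,
                     ModelConfig, build_model, count_parameters,
                     OptimizerConfig, train, evaluate)

spec = SyntheticSpec(classes=("non-bleeding", "bleeding"), n_per_class=60,
                     image_size=32, lesion_contrast=0.8, seed=5)
dataset = generate_dataset(spec)
train_set, val_set = train_val_split(dataset, 0.8, seed=5)

cfg = ModelConfig(num_classes=2, experts_per_stage=2, base_channels=16,
                  bottleneck_channels=16, conv_groups=4,
                  se_reduction=8, attn_reduction=8, seed=3)
model = build_model(cfg)
print(f"trainable parameters: {count_parameters(model):,}")

result = train(model, train_set, val_set,
               OptimizerConfig(learning_rate=1e-3, batch_size=16,
                               epochs=10, seed=3))
print(f"best validation accuracy: {result.best_val_accuracy:.3f} "
      f"(epoch {result.best_epoch})")
print(evaluate(model, val_set).to_table())
```

Output:

```
trainable parameters: 107,106
best validation accuracy: 0.958 (epoch 6)
Class            Precision (%)  Recall (%)  F1-Score (%)  Support
non-bleeding                92         100            96       12
bleeding                   100          92            96       12
Accuracy                                              96       24
Macro Avg                   96          96            96       24
Weighted Avg                96          96            96       24
```

The generator draws mucosa-textured backgrounds under radial illumination
and stamps class-specific lesions (here: irregular bright-red bleeding
blobs) with exact ground-truth masks, so a 96 % validation accuracy means
the model found the lesion signal, not a rendering artefact — the masks let
the test suite verify that trained stage-3 attention concentrates inside
the lesions.

A CLI wraps the same workflow on image folders:

```bash
endomoe generate-data --out data/ --seed 1
endomoe train    --data data/ --out run/ --seed 1
endomoe evaluate --checkpoint run/checkpoint.npz --data data/ --out run/
endomoe explain  --checkpoint run/checkpoint.npz --data data/ --out run/xai/
endomoe tune     --data data/ --out run/tune/ --budget 12 --seed 1
```

`explain` exports per-stage expert-utilization CSVs, 20-sample
routing-pattern matrices, attention overlays (PNG), and — when masks are
present — mean attention inside vs outside the lesion per stage.

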