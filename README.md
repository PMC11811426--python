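# mm-depnet

Multimodal depression screening from facial video and speech audio.

Screening for depression from behavioural signals rests on two robust
clinical observations: depressed speakers tend toward a monotonous, lower
vocal tone, and facial dynamics are damped relative to healthy controls.
`mm-depnet` implements a three-network system that operationalises both
cues and fuses them:

* **TSNet-DD** (video) — a 3-D residual network (ResNet-18/34 stage
  layout) whose residual blocks carry a *temporal-spatial attention
  module* (TSAM) after each convolution sub-module.  The temporal half
  gates channels, `W_t = σ(MLP(avgpool F_v) + MLP(maxpool F_v))`,
  `F_t = F_v ⊙ W_t`; the spatial half gates positions,
  `W_s = σ(conv₁ₓ₇ₓ₇([mean_c F_v, max_c F_v]))`, `F_s = F_v ⊙ W_s`; and
  `F_ts = F_t + F_s`.  With all attention parameters at zero both gates
  are exactly ½ and the network reduces to the plain backbone.
* **GCN-LSTM** (audio) — MFCCs are computed per frame (pre-emphasis →
  framing → window → FFT → power → Mel filterbank → log → DCT-II); each
  frame becomes a node of an undirected graph with an edge whenever the
  similarity `s = 1/(1+d)` of two frames is at least 0.5 (d ≤ 1), weighted
  by the inverse distance `1/d`.  Two graph convolutions with the
  symmetric-normalised rule `Â = D̃^{-1/2}(A_w + I)D̃^{-1/2}` produce node
  embeddings that an LSTM consumes in temporal order.
* **VAFN** (fusion) — the branch feature vectors F_V and F_A are
  zero-padded to a common length, stacked into `H_VA` and concatenated
  into `V_VA`; a fully connected layer with softmax yields two modality
  attention weights `V_VAF`, and `F_VA = V_VAFᵀ·H_VA` is a convex
  per-modality combination, max-pooled and classified.

Every model carries a dual head: a binary depression logit (positive
label = PHQ-8 score above 10) and a continuous PHQ-8 severity estimate
(evaluated with F1 and RMSE/MAE respectively).  Training uses AdamW with
a linear learning-rate decay (1e-4 for the branches, 5e-5 for fusion) and
a joint BCE + MSE objective.

Because the clinical corpus this kind of system is trained on is
restricted-access, the package ships a first-class **synthetic corpus
generator** that reproduces the statistical structure the networks assume:
harmonic voice tones with Ornstein–Uhlenbeck pitch drift (lower, flatter
pitch for positive subjects), moving-blob video with class-dependent
motion amplitude, PHQ-8-like scores coupled to the label by the
threshold-10 rule, a sex attribute for grouped evaluation, and a
163/56/10-proportioned train/val/test split.  Identical configurations
produce byte-identical corpora.

All networks run on a small numpy-based reverse-mode autodiff engine
included in the package (`mmdepnet.autodiff`, `mmdepnet.nn`); no deep
learning framework is required.

## Worked example

```python
import numpy as np
from mmdepnet import GeneratorConfig, generate_corpus, featurize_corpus
from mmdepnet.pipeline import MultimodalDepressionPipeline

cfg = GeneratorConfig(n_subjects=64, effect_size=3.0, frames_per_clip=8,
                      frame_size=(32, 32), clip_seconds=1.0, seed=7)
generate_corpus(cfg, "demo_corpus")
dataset = featurize_corpus("demo_corpus")

pipe = MultimodalDepressionPipeline(modality="fused", seed=0,
                                    video_iterations=300,
                                    audio_iterations=300,
                                    fusion_iterations=200)
pipe.fit(dataset)
report = pipe.evaluate(dataset, split="val")
print(f"val F1={report.f1:.3f}  AUC={report.auc:.3f}  "
      f"RMSE={report.rmse:.2f}  MAE={report.mae:.2f}")
```

On this corpus the run prints

```
val F1=1.000  AUC=1.000  RMSE=6.59  MAE=5.62
```

— at effect size 3 the two class-conditional signal distributions are
far apart, so a correctly wired system should separate the validation
subjects essentially perfectly (F1/AUC near 1), while the PHQ-8 head,
which sees only the binary-coupled synthetic scores, attains errors of a
few score points.  At `effect_size=0` the labels carry no signal and
validation AUC collapses to chance.

The same system is scriptable from the shell:

```bash
mm-depnet generate --config cfg.yaml --out corpus/
mm-depnet train --corpus corpus/ --modality fused --out fused.npz --seed 1
mm-depnet evaluate --corpus corpus/ --ckpt fused.npz --split test --by-sex
mm-depnet ablate --corpus corpus/ --variants no_tsam,gcn_only,lstm_only,video_only,audio_only,fused
mm-depnet attribute --corpus corpus/ --ckpt fused.npz --subject S0003
```

`ablate` retrains the system with components removed (attention stripped,
GCN or LSTM dropped, single modalities) under identical splits and seeds
and tabulates model/F1/RMSE/MAE; `attribute` computes integrated-gradients
attributions (midpoint Riemann sum along the baseline→input path, exact
for linear models, completeness within 1% at 256 steps) aggregated over
fixed-size frame windows.

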