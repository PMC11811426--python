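# Methods

This note records the models implemented in `mm-depnet`, the conventions
and defaults chosen where the design was genuinely open, what the
synthetic data generator does and does not emulate, and the numerical
details a maintainer would need.

## Video branch: TSNet-DD

A 3-D residual network over clip tensors `(batch, channels, T, H, W)`.

* **Stem.** 7×7×7 convolution, stride (1, 2, 2), same-padding 3, followed
  by a 3×3×3 max pool, stride (1, 2, 2), padding 1.  Temporal extent is
  preserved; each spatial dimension is quartered (64 → 16).  Same-padding
  was chosen for the stem (the alternative, valid padding, changes only
  boundary behaviour); inputs need at least 32×32 spatial extent.
* **Stages.** Four stages with (2, 2, 2, 2) residual blocks for the
  ResNet-18 layout (`tsnet32`) or (3, 4, 6, 3) for ResNet-34 (`tsnet64`).
  Channel widths are `base_channels × (1, 2, 4, 8)`; stages 2–4 open with
  a stride-2 block (2×2×2) and a 1×1×1 projection skip.
* **Normalisation.** GroupNorm (≤ 8 groups) after every convolution.  A
  normalisation layer is needed for stable optimisation at depth; GroupNorm
  was picked over BatchNorm because it has no running statistics, so
  evaluation is deterministic and independent of batch composition at the
  small batch sizes (8) used here.
* **Attention (TSAM).** Inserted after each of the two convolution
  sub-modules of every block, before the skip addition.  The temporal
  module is mathematically *channel* attention: global average and max
  pools over (T, H, W) produce two 1×1×C descriptors, a single shared
  two-layer bottleneck MLP (reduction ratio `attention_reduction`,
  default 16; 4 in the desk-scale configs so it divides the small widths)
  maps both, and a sigmoid of their sum gates the channels.  The spatial
  module pools over channels (mean and max), stacks the two maps, and
  applies a (1 × k × k) convolution (k = 7, no temporal extent) plus
  sigmoid to gate positions.  The TSAM output is the sum of the two gated
  maps.  With zero attention parameters each gate is σ(0) = ½, so
  F_ts = ½F_v + ½F_v = F_v exactly and the whole network equals the
  attention-free backbone — this identity is asserted network-wide in the
  tests.
* **Module counting.**  The "32"/"64" network names count the temporal
  and spatial modules separately: 8 blocks × 2 sub-modules × 2 modules
  = 32, and 16 × 2 × 2 = 64.  This is the only counting consistent with
  both totals; it is a naming convention, not an architectural claim.
* **Head.** Global average pool → linear projection to `feature_dim`
  (the exposed visual feature F_V) → dropout → two linear heads (binary
  logit, severity).

## Audio branch: MFCC graph + GCN-LSTM

* **MFCC.** Pre-emphasis (`y[n] = x[n] − 0.97·x[n−1]`, `y[0] = x[0]`),
  25 ms frames with 10 ms hop (no tail padding: the last partial frame is
  dropped), symmetric Hamming window, FFT at the next power of two ≥ the
  frame length, power spectrum `|X|²`, 26 unit-height triangular filters
  on the HTK mel scale (`m = 2595·log10(1 + f/700)`) with bin-snapped
  corners, log with floor 1e-10, orthonormal DCT-II, first 13
  coefficients.  These are standard speech-processing defaults; the test
  suite pins the pipeline to an independently coded O(N²)-DFT oracle at
  1e-6 per coefficient.
* **Graph.** Each frame is a node; similarity `s = 1/(1+d)` with `d` the
  Euclidean distance; an edge joins pairs with `s ≥ 0.5 ⇔ d ≤ 1`; edge
  weight is `1/d`, capped at 1e6 when frames coincide.  The threshold can
  alternatively be applied to the distance directly
  (`threshold_on="distance"`), since a bare "0.5 threshold" is ambiguous
  between the two conventions; the similarity reading is the default
  because one number then expresses both "high enough similarity" and
  "small enough distance".
* **Feature scale for edges.**  Raw cepstra live on a log-energy scale
  where typical inter-frame distances are ≫ 1, which would leave the
  d ≤ 1 rule with empty graphs.  The corpus featurizer therefore builds
  edges from per-clip z-scored coefficients divided by √(2·n_mfcc), so
  two *uncorrelated* frames sit at distance ≈ 1 and the threshold keeps
  pairs more alike than chance; monotonous (low-variability) speech then
  yields denser graphs, which is itself class-informative.  The node
  *attributes* passed to the network keep the absolute cepstra (the mean
  pitch signal lives there); they are corpus-standardised inside the
  estimator.  Both behaviours are configurable (`node_scaling`).
* **GCN.**  The propagation rule is the standard spectral form with
  self-loops, `ReLU(Â X W)`, `Â = D̃^{-1/2}(A_w + I)D̃^{-1/2}` on the
  weighted adjacency; no bias.  Two layers by default.  The rule is not
  uniquely determined by the phrase "GCN"; the symmetric-normalised
  variant is the de-facto default meaning.  GCN and LSTM are *stacked*
  (all graph convolutions, then the sequence model), the simplest
  composition consistent with the architecture's description.
* **Sequence.**  Node embeddings ordered by frame time, optionally
  subsampled with a fixed stride (the "subsampling" step; default stride
  1, stride 4 in the desk-scale experiments to shorten 2-s clips from
  ~200 to ~50 steps), then a single-layer LSTM; the readout is the final
  hidden state (not a mean pool), chosen for its long-range gating and
  kept configurable.  Batched graphs of unequal size are padded and
  masked; masked steps provably leave the state untouched.

## Fusion: VAFN

F_V and F_A are tail-zero-padded to the common length d, stacked into
H_VA (2×d) and concatenated into V_VA (2d).  A fully connected layer maps
V_VA to **two** logits; their softmax V_VAF weights the two rows of H_VA,
so F_VA is a per-modality convex combination — the only reading of
"multiply H_VA by the attention vector" that is dimensionally coherent
with per-modality attention.  An alternative length-d sigmoid gate
(elementwise convex combination) is retained behind
`attention_mode="elementwise"`.  The fused vector is max-pooled (window =
stride = 4 by default; a trailing remainder is dropped) and classified by
the dual head.  Fusion trains with the branch backbones frozen (staged
training at the smaller fusion learning rate); joint fine-tuning is
deliberately out of scope of the fusion estimator.

## Training and evaluation

* AdamW (β = 0.9/0.999, decoupled weight decay 1e-2), linear decay of the
  learning rate to zero; branch lr 1e-4, fusion lr 5e-5; dropout 0.5
  (valid band [0.4, 0.6]); nominal 5000 iterations with desk-scale runs
  using 200–500 (see below).
* Joint objective: `λ_cls·BCE + λ_reg·MSE`, λ = (1, 1).  Inside the
  estimators the severity target is z-scored with training statistics
  (and un-scaled at prediction), so the MSE term is commensurate with the
  BCE term; without this the raw 0–24 squared error dominates early
  optimisation.
* Classification threshold for F1 is logit 0 (probability ½); the labels
  are never re-derived from the severity head.
* Metrics: precision, recall, F1 (harmonic mean), RMSE, MAE, ROC by
  threshold sweep with AUC by the trapezoid rule.  A single-class truth
  vector makes AUC (and F1 when undefined) *missing*, never zero.
  Synthetic benchmarks report means over 3 seeds.
* Ablation variants: `no_tsam` (attention stripped), `gcn_only` (mean
  pool instead of the LSTM), `lstm_only` (raw cepstra to the LSTM),
  `video_only`, `audio_only`, `fused`; all variants share splits and
  seeds, and branch models common to several variants are trained once.
* Attribution: integrated gradients as a midpoint Riemann sum; exact on
  linear models for any step count, completeness (Σ attributions =
  f(x) − f(baseline)) within 1% at 256 steps on a smooth toy network.
  Frame-wise attributions can be aggregated over fixed windows (default
  100 frames); totals are preserved, including a trailing partial window.

## Synthetic corpus

The generator emulates exactly the structure the networks assume and
nothing more:

* **Audio**: fundamental + two harmonics (amplitudes 1, 0.5, 0.25) with
  additive Gaussian noise (σ = 0.02); pitch follows an exactly
  discretised Ornstein–Uhlenbeck process (θ = 3 s⁻¹).  Class means of the
  fundamental are 165 ± 7.5·effect Hz (positive label lower), subject SD
  8 Hz; OU stationary SD is 6·(1 + 0.3·effect) Hz for controls and
  6/(1 + 0.6·effect) Hz for positives (more monotonous).  At effect 0 the
  class distributions coincide.
* **Video**: a Gaussian blob (σ = 0.15·min(H, W)) oscillating around a
  jittered centre; oscillation amplitude 0.12·(1 + 0.5·effect) of the
  frame for controls versus 0.12/(1 + 0.5·effect) for positives, with an
  analogous factor on the oscillation frequency; pixel noise σ = 0.02,
  values clipped to [0, 1].
* **Metadata**: label 1 iff the PHQ-8-like score exceeds 10 (the score is
  drawn uniformly from the side of the threshold the label dictates; the
  boundary value 10 maps to label 0, and the threshold is configurable);
  sex is an independent Bernoulli(½); the train/val/test split is
  stratified by label with largest-remainder allocation at proportions
  163/229, 56/229, 10/229, so a 229-subject corpus lands within ±1 of a
  163/56/10 partition.
* Every per-subject stream is seeded from (config seed, CRC32 of the
  subject id, modality), so corpora are byte-identical across
  regenerations and insensitive to generation order.

What the generator does **not** emulate: phonetic content or prosody
beyond pitch, photorealistic faces, occlusion and head pose, recording
artefacts, label noise, or realistic PHQ-8 score distributions.  Passing
the synthetic benchmarks therefore demonstrates that the architecture,
optimisation and evaluation machinery are wired correctly and can
recover class-conditional pitch/motion structure from raw signals — not
that the system attains any particular accuracy on clinical interviews.

## Benchmark problem sizes

The canned experiments (`mmdepnet.experiments`) use 8-frame 32×32 clips
and 2-s audio at 16 kHz — the smallest geometry that exercises the full
stem and all four stages: the overfit check trains the fused system on
32 subjects for 500 iterations and must reach training F1 ≥ 0.95; signal
recovery trains on 200-subject corpora (300 branch / 200 fusion
iterations, three seeds) and expects mean validation AUC ≥ 0.9 at effect
size 3 and chance-level AUC at effect size 0.  The desk-scale video
network uses `base_channels=4` with `attention_reduction=4` (so the
bottleneck is well defined at every width); audio uses 16 GCN channels
and a 32-unit LSTM; these sizes were chosen once as the smallest that
memorise the overfit corpus reliably.

## Known limitations

* The in-package autodiff engine is single-threaded numpy; it is exact
  but not fast, which is why the benchmark geometries are small.
* `BatchNorm` is not implemented; GroupNorm is the only normalisation.
* Graph construction is O(n²) in frames; use the frame stride for long
  recordings.
* The E-DAIC-style feature-table reader feeds only the attribution
  workflow; no claim is made about clinical-data performance.
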