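# Methods

## The problem and the model

Segmenting lesion regions in gastroscopy frames is hard for purely
convolutional encoders (limited long-range context; gastric folds mimic
lesion boundaries) and for purely attention-based encoders (weak low-level
detail on small datasets). The network implemented here attacks both
failure modes at once: a convolutional encoder and a hierarchical windowed
self-attention encoder consume the same 224×224 RGB frame in parallel; a
per-scale fusion module lets their evidence interact; and an attention-gated
decoder produces the final mask, with each branch additionally supervised
through its own lightweight aggregation decoder.

Both encoders obey one pyramid contract: four feature maps at 1/4, 1/8,
1/16 and 1/32 of the input resolution with C, 2C, 4C, 8C channels. C = 96
everywhere by default; the convolutional branch's first unit runs at
C/2 = 48 channels so its later units land exactly on the contract.

### Attention branch

Standard shifted-window design: 4×4 patch embedding (flatten + linear +
layer norm), four stages of blocks

    ẑ^l = (S)W-MSA(LN(z^{l-1})) + z^{l-1}
    z^l = MLP(LN(ẑ^l)) + ẑ^l

with patch merging (2×2 concat, linear 4D→2D) between stages. Attention is
computed densely inside non-overlapping w×w token windows with a learned
relative position bias; odd-indexed blocks cyclically shift the grid by
⌊w/2⌋ and mask attention across the wrap-around boundary (additive −1e9 on
cross-group pairs). Defaults (depths [2,2,6,2], heads [3,6,12,24], window 7,
MLP ratio 4, LN ε = 1e-5, GELU) are the published tiny configuration, chosen
for checkpoint compatibility; the depth order [2,2,2,6] is selectable via
`model.swin.depths`. Shift size is the ⌊w/2⌋ convention. Since no GPU
framework is a dependency, the optional ImageNet checkpoint import takes a
dict/`.npz` of arrays keyed by the published parameter names; the loader
reshapes the 4×4 conv kernel onto the linear embedding and reports
missing/unexpected/mismatched keys.

### Convolutional branch

Five units of (3×3 conv + BN + ReLU) ×2 followed by a 2×2 max-pool. The
pool placed after the convolutions is the only ordering consistent with the
pyramid contract (five halvings ending at 1/32 with the last four unit
outputs at 1/4…1/32). The stand-alone baseline adds a classic symmetric
decoder: bilinear ×2, skip concatenation, two conv units per level.

### DFA decoder

Only the three deepest levels are decoded (low-level features contribute
little to salient-region localization but dominate compute). Each level is
refined to 48 channels by a receptive-field block: four parallel branches
with a 1×1 bottleneck to in/8 channels, rates {3,5,7} adding a 3×3 conv and
a dilated 3×3 at that rate, concat + 1×1 merge + 1×1 shortcut. The refined
maps combine as

    AD1 = concat[ Up2( Up2(F3') ⊙ F2' ), Up4(F3') ]     (1/8, 96 ch)
    AD2 = concat[ Up2(F2') ⊙ F1', AD1 ]                 (1/8, 144 ch)

then a 3×3 conv+BN+ReLU to 48 channels, a 3×3 conv to logits, and bilinear
×8. As printed, the two AD1 terms would sit at different scales; the product
term is upsampled ×2 before concatenation, the only placement under which
the chain composes and ×8 restores full resolution.

### Feature fusion

Per scale i: both branch maps are refined by one shared 3×3 conv ω (one
conv per scale — the two inputs have identical shapes); from scale 2 the
previous fusion output is max-pooled 3×3/stride 2 and aligned by a 1×1 conv;
the refined maps multiply elementwise into the interaction map b_i, which is
concatenated with the raw branch maps and merged by a residual block (1×1
projection 3c→c + 3×3 conv, identity shortcut, BN+ReLU) back to c channels.
Threading ff_{i-1} forward is the multi-modal mechanism that propagates
cross-branch agreement down the pyramid. The "Hadamard product" is read
elementwise (all factors are brought to the same channel count); the
outer-product reading is dimensionally inconsistent with same-shape fusion
and is not implemented.

The residual block's width and the ω sharing are not pinned down by the
architecture description; the choices above were fixed so that the
fused-model parameter budgets bracket the published ablation table (see
"Parameter accounting").

### Gated decoder

The decoder state starts at ff_4 (1/32). Each of three gates upsamples the
state ×2 (bilinear, align_corners=false — as everywhere), 1×1-projects it to
the skip's width, and computes

    T = ReLU(W_f·ff_i + W_up·up)        gate = Sigmoid(BN(1×1 conv(T)))
    up_i = up ⊙ gate

with a single-channel gate broadcast over channels (per-channel gating via
`model.att.per_channel_gate`). Sigmoid is the operative activation (its
(0,1) range is what makes the gate an attenuator; a {−1,1}-style mapping
would contradict the gate equations). After the last gate (1/4 scale, 96
channels) a 96→48→48→2 conv head and bilinear ×4 produce the logits. The
first gate's internal upsample *is* the ff_4 interpolation: three internal
×2 steps are exactly what takes 1/32 to 1/4.

### Loss and metrics

Two-class softmax pixel cross-entropy per head,
`L = α·L_ff + β·L_st + γ·L_u`, weights validated to be convex; defaults
(0.5, 0.2, 0.3). A printed logistic form with an inverted orientation and a
sign slip is normalized to the standard orientation — as written the loss
would be unbounded below and decrease with confidence in the wrong class.

All seven metrics derive from pixel confusion counts. Zero denominators
return 1 when the condition is vacuously met (empty truth, empty
prediction) else 0. Summaries report per-image mean ± population std
(divisor n); dataset-level F1 is the harmonic mean of mean precision and
mean recall, the convention that reproduces tabled per-cohort F1 columns
(it is *not* the mean per-image Dice).

## Synthetic data

`SyntheticConfig` defaults: 224×224 frames, 1–3 lesions, total lesion area
2–35 % of the frame, fold frequency 2–5 cycles/frame with amplitude 0.08,
speckle σ = 0.03 (all in [0,1] intensity units). Backgrounds are a
low-frequency random color field around a mucosa tone plus an oriented
sinusoidal fold pattern; lesions are star-convex blobs whose boundary radius
is modulated by 2–5 random harmonics (3–18 % amplitude), colored with a
shifted tone and finer texture, alpha-blended at the rim for a soft
transition while the mask stays the exact geometric support. Area
constraints are enforced with bounded retries. Augmentation: flips,
rotation uniform in [0,360) (reflect-pad image, zero-fill mask,
nearest-neighbour mask resampling), ±10 % translation, 0.85–1.15 zoom,
hue ±0.03, saturation/brightness ×0.8–1.2. The study-scale ×17.7
augmentation multiplier is a config knob (`aug_factor`), default 4 at desk
scale; 5 % of the augmented pool becomes the validation split.

What passing tests on this generator do show: shape/scale contracts,
gradient flow through every branch, optimizer wiring, metric arithmetic,
loss behaviour, end-to-end train/eval/predict plumbing. What they do not
show: segmentation quality on real mucosa — the generator has none of the
specular highlights, depth-of-field blur, instrument shadows or label noise
of clinical data, so no accuracy claim transfers.

## Numerical engine and choices

All layers run on `dbhnet.nn`, a reverse-mode autodiff over NumPy written
for this package: convolution as a strided-view contraction (gradients via
transposed convolution), max-pool with argmax scatter, bilinear resizing as
two cached 1-D interpolation matrices (exact transpose in the backward
pass), attention/norm layers composed from broadcasting primitives, and
Adam with L2 weight decay (lr 1e-3, wd 1e-4, no schedule — none is
specified). Every op is verified against central finite differences in the
test suite (tolerance 1e-6 relative). Evaluation-mode forwards are
bitwise deterministic; training is deterministic given the seed (one global
generator for initialization, per-call generators for data).

Other conventions: BN ε 1e-5, momentum 0.1; logits carry 2 channels
(softmax formulation; a 1-channel sigmoid mode with threshold 0.5 follows
the same confusion-count path); masks are stored as {0,255} single-channel
PNG; checkpoints are `.npz` state dicts with a JSON sidecar (variant,
config echo, seed); best-validation-Dice checkpoint is retained.

## Parameter accounting

Closed-form layer sums (tested) give, at C=96: conv baseline 17.66 M,
attention baseline 28.23 M, conv+DFA 11.81 M, attention+DFA 28.73 M, fused
without DFA heads 55.81 M, full model 58.23 M. The published ablation
figures are bracketed within ~3 % (single-branch baselines) to ~8–10 %
(fused models) — except attention+DFA, whose published 21.97 M lies below
the published tiny encoder alone (~27.5 M) and cannot be reached by any
composition of the described parts; that row is reported as the
architecture dictates. The published fused-model figures are themselves
mutually inconsistent (adding two DFA heads cannot reduce the total), which
bounds how closely any single fusion design can match both.

## Desk-scale test configuration

Property and smoke tests run a reduced instance chosen to exercise every
code path: 64×64 images, C=16, one attention block per stage, heads
(1,2,4,8), window 2 (the window must divide every stage's token grid; at
64×64 the deepest grid is 2×2). The overfit probe — four synthetic pairs,
≤200 Adam steps — checks that the three-head model can memorize its batch
(train Dice > 0.95), the strongest cheap test of correct wiring and
gradient flow through both encoders, the fusion chain and all heads.

## Known limitations

No boundary-aware loss terms; no attention-based fusion variants; no
Swin-V2/variable windows; gradient checkpointing and GPU execution are out
of scope. The NumPy engine favours transparency over speed: full-size
(224×224, C=96) training is impractical — the package targets architectural
study, unit-verifiable correctness and desk-scale experiments, not clinical
throughput.
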