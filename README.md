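# dbhnet

Dual-branch hybrid network for binary lesion segmentation of endoscopic
images — a windowed self-attention encoder and a convolutional (U-Net style)
encoder run in parallel over the same frame, exchange information through a
Hadamard-product feature-fusion module at four scales, and are decoded by an
attention-gated decoder under a jointly weighted three-head loss.

The package is aimed at researchers studying encoder-fusion architectures
for gastrointestinal endoscopy (gastric lesions, polyps in Kvasir-SEG /
CVC-ClinicDB style datasets) who want a fully inspectable, desk-scale
implementation: every layer runs on a small NumPy autodiff engine that ships
with the package (`dbhnet.nn`), so the whole forward/backward pass is plain
array code with finite-difference-verified gradients — no GPU framework
required.

## Model

Both branches emit a four-scale feature pyramid (1/4 … 1/32 resolution,
C … 8C channels, C = 96 by default):

* **Attention branch** — 4×4 patch embedding, then four stages of
  (shifted-)window multi-head self-attention blocks
  (`ẑ = (S)W-MSA(LN(z)) + z`, `z' = MLP(LN(ẑ)) + ẑ`) with patch-merging
  downsamples; defaults match the published tiny configuration
  (depths [2,2,6,2], heads [3,6,12,24], window 7) so its ImageNet
  checkpoint can be mapped in.
* **Convolutional branch** — five conv units (two 3×3 conv+BN+ReLU, 2×2
  max-pool each); the deepest four unit outputs form the pyramid.
* **DFA decoder** (per branch) — the three deepest levels are reduced to 48
  channels by receptive-field blocks with dilation rates {1,3,5,7}, fused by
  elementwise products and concatenation at 1/8 scale, and upsampled ×8 to
  logits: `AD1 = [Up2(Up2(F3')⊙F2'), Up4(F3')]`, `AD2 = [Up2(F2')⊙F1', AD1]`.
* **FF module** (per scale) — `b_i = ω(st_i) ⊙ ω(u_i) ⊙ ω_ff(φ(ff_{i-1}))`,
  `ff_i = Residual([st_i, u_i, b_i])`, threading each fused output into the
  next scale.
* **Gated decoder** — three additive attention gates
  (`T = ReLU(W_f ff + W_up up)`, `gate = σ(BN(conv T))`, `up_i = up·gate`)
  from 1/32 up to 1/4, then a three-conv head and bilinear ×4.
* **Loss** — `L = α·L_ff + β·L_st + γ·L_u` with (α,β,γ) = (0.5, 0.2, 0.3),
  each term a 2-class softmax pixel cross-entropy.

Evaluation reports IOU, Dice, Accuracy, Recall, Precision, Specificity and
F1 from pixel confusion counts, per image (mean ± std) and at dataset level
(F1 as the harmonic mean of mean precision and mean recall).

Because the study's gastric dataset is private, the package includes a
seeded synthetic generator of endoscopy-like image/mask pairs (textured
mucosa background with fold structure, star-convex lesion blobs with exact
masks) so everything — training included — runs without any download.

## Worked example

```
$ dbhnet synth --out data --n-train 8 --n-test 4 --image-size 64 --seed 0
wrote {'train': 30, 'val': 2, 'test': 4} to data

$ dbhnet params --variant ours
ours         58,227,225  (58.23 M)
```

A desk-scale overfit probe (the same computation
`scripts/acceptance.py` runs; tiny configuration C=16, one block per stage,
window 2, four 64×64 synthetic pairs):

```python
>>> from dbhnet import build_model, SyntheticConfig, generate_sample
>>> from dbhnet.data import to_batch
>>> from dbhnet.swin_encoder import SwinConfig
>>> from dbhnet.train import fit_batch
>>> cfg = SwinConfig(embed_dim=16, depths=(1,1,1,1), heads=(1,2,4,8), window=2)
>>> imgs, masks = to_batch([generate_sample(SyntheticConfig(image_size=64, seed=1), s)
...                         for s in range(4)])
>>> res = fit_batch(build_model("ours", swin_config=cfg, seed=1),
...                 imgs, masks, steps=200, lr=1e-3, target_dice=0.95)
>>> round(res["dice"], 4), res["steps"]
(0.9573, 70)
```

i.e. the three-head model memorizes the four images (train Dice 0.957)
within 70 optimization steps — the end-to-end wiring/gradient-flow check.
Full training/evaluation/prediction run through `dbhnet train`,
`dbhnet eval` (per-image CSV + "mean ± std" summary) and `dbhnet predict`
(mask PNG plus a red/yellow/green ground-truth overlay).

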