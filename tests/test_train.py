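"""Training loop: gradient flow, determinism, end-to-end run, prediction."""

import json

import numpy as np
import pytest

from dbhnet.data import to_batch, write_image, write_mask
from dbhnet.losses import LossWeights
from dbhnet.metrics import confusion
from dbhnet.models import VARIANTS, build_model
from dbhnet.swin_encoder import SwinConfig
from dbhnet.synthetic import SyntheticConfig, build_dataset, generate_sample
from dbhnet.train import (DivergenceError, ManifestDataset, _model_loss,
                          evaluate, fit_batch, overlay, predict, train)

TINY = SwinConfig(embed_dim=16, depths=(1, 1, 1, 1), heads=(1, 2, 4, 8),
                  window=2)
DATA_CFG = SyntheticConfig(image_size=64)


def small_batch(n=2):
    return to_batch([generate_sample(DATA_CFG, s) for s in range(n)])


@pytest.mark.parametrize("variant", VARIANTS)
def test_every_parameter_group_receives_gradient(variant):
    """After one step each top-level submodule has nonzero gradient norm —
    the wiring check that catches detached branches in a multi-head model."""
    model = build_model(variant, swin_config=TINY, seed=0)
    images, masks = small_batch()
    model.train()
    loss = _model_loss(model, images, masks, LossWeights())
    loss.backward()
    for name, child in model._modules.items():
        norms = [np.linalg.norm(p.grad) for _, p in
                 child.named_parameters() if p.grad is not None]
        missing = [pn for pn, p in child.named_parameters() if p.grad is None]
        assert not missing, f"{variant}.{name}: no grad for {missing}"
        assert sum(norms) > 0, f"{variant}.{name} received zero gradient"


def test_fixed_seed_reproduces_loss_trajectory():
    images, masks = small_batch()
    runs = []
    for _ in range(2):
        model = build_model("ours", swin_config=TINY, seed=3)
        res = fit_batch(model, images, masks, steps=3, lr=1e-3)
        runs.append(res["losses"])
    assert runs[0] == runs[1]


def test_overfit_probe_reduces_loss():
    images, masks = small_batch()
    model = build_model("unet_dfa", swin_config=TINY, seed=0)
    res = fit_batch(model, images, masks, steps=15, lr=1e-3)
    assert res["losses"][-1] < res["losses"][0]


def test_divergence_raises_with_diagnostic():
    images, masks = small_batch()
    model = build_model("unet_dfa", swin_config=TINY, seed=0)
    for p in model.parameters():
        p.data = p.data + np.nan
    with pytest.raises(DivergenceError, match="step 0"):
        fit_batch(model, images, masks, steps=2)


@pytest.fixture(scope="module")
def micro_run(tmp_path_factory):
    """A two-epoch training run on a micro synthetic dataset."""
    root = tmp_path_factory.mktemp("run")
    data = root / "data"
    build_dataset(DATA_CFG, 4, 2, data, aug_factor=2, val_fraction=0.25)
    cfg = {
        "model": {"C": 16,
                  "swin": {"depths": [1, 1, 1, 1], "heads": [1, 2, 4, 8],
                           "window": 2, "mlp_ratio": 4.0},
                  "num_classes": 2, "att": {"per_channel_gate": False},
                  "dfa": {"channels": 48, "dilations": [1, 3, 5, 7]},
                  "ff": {"residual_depth": 2},
                  "unet": {"base_channels": None}},
        "train": {"epochs": 2, "batch_size": 4, "learning_rate": 1e-3,
                  "weight_decay": 1e-4, "image_size": 64, "seed": 0,
                  "loss_weights": [0.5, 0.2, 0.3]},
    }
    result = train(data, "unet_dfa", root / "out", cfg, log=lambda *_: None)
    return root, data, result


def test_training_writes_history_and_best_checkpoint(micro_run):
    root, _, result = micro_run
    assert len(result["history"]) == 2
    assert (root / "out" / "best.npz").exists()
    meta = json.loads((root / "out" / "best.json").read_text())
    assert meta["variant"] == "unet_dfa" and meta["seed"] == 0
    history = json.loads((root / "out" / "history.json").read_text())
    assert all(np.isfinite(h["train_loss"]) for h in history)


def test_evaluation_produces_metric_summary_and_csv(micro_run, tmp_path):
    root, data, result = micro_run
    csv_path = tmp_path / "report.csv"
    summary = evaluate(result["checkpoint"], data, csv_path)
    assert summary["n"] == 2
    assert 0.0 <= summary["mean"]["dice"] <= 1.0
    lines = csv_path.read_text().strip().splitlines()
    assert len(lines) == 4          # header + 2 rows + summary


def test_prediction_writes_mask_and_overlay(micro_run, tmp_path):
    root, data, result = micro_run
    ds = ManifestDataset(data, "test", 64)
    pair = ds.pair(0)
    img_path = tmp_path / "img.png"
    msk_path = tmp_path / "msk.png"
    write_image(img_path, pair.image)
    write_mask(msk_path, pair.mask)
    pred = predict(result["checkpoint"], img_path, tmp_path / "pred.png",
                   msk_path)
    assert pred.shape == (64, 64)
    assert (tmp_path / "pred.png").exists()
    assert (tmp_path / "pred_overlay.png").exists()


def test_overlay_color_semantics(rng):
    truth = rng.integers(0, 2, (8, 8))
    img = overlay(truth, truth)
    green = (img == (0, 255, 0)).all(axis=-1)
    assert green.sum() == truth.sum()          # identical masks: pure green
    assert not ((img == (255, 0, 0)).all(axis=-1)).any()

    pred = np.zeros_like(truth)
    pred[0, 0] = 1
    truth2 = np.zeros_like(truth)
    truth2[7, 7] = 1
    img2 = overlay(pred, truth2)
    assert not ((img2 == (0, 255, 0)).all(axis=-1)).any()   # disjoint: none

    c = confusion(pred, truth2)
    yellow = (img2 == (255, 255, 0)).all(axis=-1).sum()
    red = (img2 == (255, 0, 0)).all(axis=-1).sum()
    assert (yellow, red) == (c.fp, c.fn)
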