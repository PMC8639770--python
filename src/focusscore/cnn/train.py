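"""Training protocol for the residual-network focus classifier.

The protocol: resize images to the network input size, augment during
training (rotation, translation, shear, flips), train for a fixed number of
epochs with binary cross-entropy, Adam at initial learning rate 1e-4 decayed
by cosine annealing, minibatch size 32; after every epoch record train and
validation loss/accuracy, and finally evaluate the checkpoint from the epoch
with maximal validation accuracy (earliest epoch on ties).  Because training
is stochastic, the experiment is repeated over several seeds (five in the
full protocol) and metrics are reported as mean +/- sample SD.

All randomness (initialization, shuffling, augmentation) derives from one
master seed per trial, so runs are bit-reproducible.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.transform import resize as _resize

from ..evalstat import EvalReport, evaluate_scores, summarize_trials
from ..synthgen import DatasetManifest, FocusImage, images_for
from .augmentation import apply_params as _aug_apply
from .augmentation import draw_params as _aug_draw
from .nn import Adam, bce_with_logits, cosine_lr, sigmoid
from .resnet import ResNet18, build_model

__all__ = ["TrainConfig", "TrainRun", "TrialSet", "train", "predict",
           "run_trials", "load_checkpoint"]


@dataclass(frozen=True)
class TrainConfig:
    """Hyper-parameters of one training run.

    Defaults are the full protocol: 50 epochs, batch 32, Adam at 1e-4 with
    cosine annealing to 0, 224x224 input, rotation +/-90 deg, translation
    +/-44 px (at 224; scaled for other input sizes), shear +/-15 deg, flips
    at p=0.5, no pretraining.  ``base_width=64`` is the canonical network
    width; reduce it (with ``input_size``) for CPU-scale runs.
    """

    epochs: int = 50
    batch_size: int = 32
    lr_init: float = 1e-4
    lr_min: float = 0.0
    input_size: tuple[int, int] = (224, 224)
    rotation: float = 90.0
    translate: float = 44.0
    shear: float = 15.0
    flip_p: float = 0.5
    seed: int = 0
    pretrained: bool = False
    base_width: int = 64

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")
        if self.lr_init <= 0 or self.lr_min < 0:
            raise ValueError("learning rates must be positive / nonnegative")
        if min(self.input_size) < 8:
            raise ValueError("input_size too small")


@dataclass
class TrainRun:
    """History and selected checkpoint of one training run."""

    config: TrainConfig
    history: pd.DataFrame      # epoch, lr, train_loss, train_acc, val_loss, val_acc
    selected_epoch: int        # argmax val_acc, earliest on ties (0-based)
    checkpoint: dict           # model state_dict at selected_epoch

    def save_checkpoint(self, path: str | Path) -> None:
        payload = {"config": self.config.__dict__ | {"input_size": list(self.config.input_size)},
                   "state": self.checkpoint,
                   "selected_epoch": self.selected_epoch}
        with open(path, "wb") as fh:
            pickle.dump(payload, fh)

    def history_to_csv(self, path: str | Path) -> None:
        self.history.to_csv(path, index=False)


def load_checkpoint(path: str | Path) -> tuple[ResNet18, TrainConfig]:
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    cfgd = dict(payload["config"])
    cfgd["input_size"] = tuple(cfgd["input_size"])
    config = TrainConfig(**cfgd)
    return ResNet18.from_state(payload["state"]), config


@dataclass
class TrialSet:
    """Several seeded runs plus their test-set reports and mean +/- SD summary."""

    runs: list[TrainRun]
    reports: list[EvalReport]
    summary: dict

    def summary_frame(self) -> pd.DataFrame:
        rows = [{"metric": k, **v} for k, v in self.summary.items()]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# data plumbing

def _prepare(images: list[FocusImage], input_size) -> np.ndarray:
    """Resize to input size; float64 HWC in [0, 1] (augmentation space)."""
    out = np.empty((len(images), *input_size, 3))
    for i, im in enumerate(images):
        px = im.pixels
        if px.shape[:2] == tuple(input_size):
            out[i] = px / 255.0
        else:
            out[i] = _resize(px, input_size, anti_aliasing=True, preserve_range=True) / 255.0
    return out


def _to_net(batch_hwc: np.ndarray) -> np.ndarray:
    """[0,1] HWC -> normalized float32 NCHW (mean 0.5, sd 0.5 per channel)."""
    x = (batch_hwc - 0.5) / 0.5
    return np.ascontiguousarray(x.transpose(0, 3, 1, 2)).astype(np.float32)


def _split_rows(manifest: DatasetManifest, name: str) -> pd.DataFrame:
    rows = manifest.records[manifest.records["split"] == name]
    if len(rows) == 0:
        raise ValueError(f"split {name!r} is empty")
    if rows["label"].nunique() < 2:
        raise ValueError(f"split {name!r} contains a single class")
    return rows


# ---------------------------------------------------------------------------
# training

def train(manifest: DatasetManifest, config: TrainConfig) -> TrainRun:
    """Run the training protocol on the manifest's train/val splits.

    Checkpoint selection: parameters from the epoch with maximal validation
    accuracy (earliest on ties).  Fully seeded end-to-end.
    """
    tr_rows = _split_rows(manifest, "train")
    va_rows = _split_rows(manifest, "val")
    X_tr = _prepare(images_for(manifest, tr_rows), config.input_size)
    y_tr = tr_rows["label"].to_numpy()
    X_va = _to_net(_prepare(images_for(manifest, va_rows), config.input_size))
    y_va = va_rows["label"].to_numpy()

    master = np.random.SeedSequence(config.seed)
    init_seed, shuffle_seed, aug_seed = (int(s.generate_state(1)[0] % (2**31))
                                         for s in master.spawn(3))
    model = build_model(pretrained=config.pretrained, base_width=config.base_width,
                        seed=init_seed)
    opt = Adam(model.params(), lr=config.lr_init)
    shuffle_rng = np.random.default_rng(shuffle_seed)
    aug_rng = np.random.default_rng(aug_seed)

    hist = []
    best_acc, best_epoch, best_state = -1.0, -1, None
    n = len(X_tr)
    for epoch in range(config.epochs):
        lr = cosine_lr(epoch, config.epochs, config.lr_init, config.lr_min)
        opt.lr = lr
        order = shuffle_rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            batch = np.stack([
                _aug_apply(X_tr[i], _aug_draw(config, aug_rng, config.input_size))
                for i in idx])
            xb = _to_net(batch)
            yb = y_tr[idx]
            logits = model.forward(xb, training=True).ravel()
            loss, dlogits = bce_with_logits(logits, yb)
            opt.zero_grad()
            model.backward(dlogits.reshape(-1, 1))
            opt.step()
            losses.append(loss * len(idx))
            correct += int(np.sum((sigmoid(logits) >= 0.5) == (yb == 1)))
        train_loss = float(np.sum(losses) / n)
        train_acc = correct / n

        val_logits = _forward_eval(model, X_va, config.batch_size)
        val_loss, _ = bce_with_logits(val_logits, y_va)
        val_acc = float(np.mean((sigmoid(val_logits) >= 0.5) == (y_va == 1)))
        hist.append({"epoch": epoch, "lr": lr, "train_loss": train_loss,
                     "train_acc": train_acc, "val_loss": val_loss,
                     "val_acc": val_acc})
        if val_acc > best_acc:      # strict: earliest epoch wins ties
            best_acc, best_epoch = val_acc, epoch
            best_state = model.state_dict()

    return TrainRun(config=config, history=pd.DataFrame(hist),
                    selected_epoch=best_epoch, checkpoint=best_state)


def _forward_eval(model: ResNet18, X: np.ndarray, batch_size: int) -> np.ndarray:
    out = []
    for start in range(0, len(X), batch_size):
        out.append(model.forward(X[start:start + batch_size], training=False).ravel())
    return np.concatenate(out) if out else np.empty(0)


def predict(checkpoint: dict | ResNet18, images: list[FocusImage],
            config: TrainConfig) -> np.ndarray:
    """Sigmoid probabilities for a list of images (no augmentation), order-
    preserving; empty input yields empty output."""
    if not images:
        return np.empty(0)
    model = checkpoint if isinstance(checkpoint, ResNet18) else ResNet18.from_state(checkpoint)
    X = _to_net(_prepare(images, config.input_size))
    logits = _forward_eval(model, X, config.batch_size)
    return sigmoid(logits)


def run_trials(manifest: DatasetManifest, config: TrainConfig,
               seeds: list[int], test_manifest: DatasetManifest | None = None) -> TrialSet:
    """One training run per seed, each evaluated on the test data.

    Test images come from the manifest's ``test`` split, or — in transfer
    mode — from ``test_manifest`` (e.g. foci induced by a chemical never seen
    in training).  Summary is mean +/- sample SD (ddof=1) per metric.
    """
    if not seeds:
        raise ValueError("need at least one seed")
    if test_manifest is not None:
        test_rows = test_manifest.records
        overlap = set(test_rows["id"]) & set(manifest.records["id"])
        if overlap:
            raise ValueError(f"transfer test ids overlap training manifest: "
                             f"{sorted(overlap)[:5]}...")
        test_images = images_for(test_manifest, test_rows)
    else:
        test_rows = _split_rows(manifest, "test")
        test_images = images_for(manifest, test_rows)
    y_test = test_rows["label"].to_numpy()

    runs, reports = [], []
    for seed in seeds:
        try:
            run = train(manifest, replace(config, seed=int(seed)))
        except Exception as exc:
            raise RuntimeError(f"trial with seed {seed} failed: {exc}") from exc
        scores = predict(run.checkpoint, test_images, config)
        runs.append(run)
        reports.append(evaluate_scores(scores, y_test))
    return TrialSet(runs=runs, reports=reports, summary=summarize_trials(reports))
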