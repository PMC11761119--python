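"""Training harness: AdamW + cross-entropy with full seeding and history.

Default hyperparameters follow the reference protocol for the 224-px
model: 60 epochs, learning rate 1e-4, batch size 32.  The `tiny` model
preset pairs with a shorter schedule (see ModelConfig.tiny) for CPU-scale
experiments; its preset learning rate is 1e-3.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .model import FusedSwinClassifier, ModelConfig, build_model, normalize_batch
from .nn import AdamW, cross_entropy
from .preprocess import resize_image

__all__ = ["TrainConfig", "TrainHistory", "train", "predict",
           "save_checkpoint", "load_checkpoint", "dataset_to_arrays"]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 60
    learning_rate: float = 1e-4
    batch_size: int = 32
    optimizer: str = "adamw"
    betas: tuple[float, float] = (0.9, 0.999)
    weight_decay: float = 0.05
    loss: str = "cross_entropy"
    seed: int = 0
    eval_every: int = 1

    def validate(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.optimizer != "adamw" or self.loss != "cross_entropy":
            raise ValueError("supported: optimizer='adamw', loss='cross_entropy'")


def tiny_train_config(seed: int = 0, epochs: int = 5) -> "TrainConfig":
    """Schedule paired with ModelConfig.tiny for CPU-scale runs.

    Short from-scratch schedules favour a slightly larger step and a
    faster-adapting second moment than the full 60-epoch protocol.
    """
    return TrainConfig(epochs=epochs, learning_rate=1e-3, batch_size=16,
                       betas=(0.9, 0.95), seed=seed, eval_every=epochs)


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    epoch_seconds: list[float] = field(default_factory=list)
    seed: int = 0
    config_hash: str = ""

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({
            "epoch": np.arange(1, len(self.train_loss) + 1),
            "loss": self.train_loss,
            "train_acc": self.train_accuracy,
            "val_acc": self.val_accuracy,
        }).to_csv(path, index=False)


def dataset_to_arrays(dataset, img_size: int,
                      classes: tuple[str, ...] | None = None):
    """Stack a labelled-image list into (N,H,W,3) uint8 + int labels."""
    def unpack(item):
        if hasattr(item, "image"):
            return item.image, item.label
        return item

    pairs = [unpack(it) for it in dataset]
    if classes is None:
        classes = tuple(sorted({lab for _, lab in pairs}))
    lut = {lab: i for i, lab in enumerate(classes)}
    imgs = np.stack([
        img if img.shape[0] == img_size else resize_image(img, img_size)
        for img, _ in pairs
    ])
    labels = np.array([lut[lab] for _, lab in pairs], dtype=int)
    return imgs, labels, classes


def _accuracy(model: FusedSwinClassifier, images: np.ndarray, labels: np.ndarray,
              batch_size: int) -> float:
    probs = model.predict_proba(images, batch_size=batch_size)
    return float((probs.argmax(axis=1) == labels).mean())


def train(model: FusedSwinClassifier, train_set, val_set,
          config: TrainConfig | None = None,
          out_dir: str | Path | None = None) -> tuple[FusedSwinClassifier, TrainHistory]:
    """Train in place; returns the model and its per-epoch history.

    Reproducible for a fixed (model seed, config.seed) pair on CPU; the
    best-validation checkpoint is written under out_dir when given.
    """
    config = config or TrainConfig()
    config.validate()
    if not train_set or not val_set:
        raise ValueError("datasets must be non-empty")
    cfg = model.cfg
    classes = tuple(sorted({it.label if hasattr(it, "label") else it[1]
                            for it in list(train_set) + list(val_set)}))
    if len(classes) > cfg.num_classes:
        raise ValueError(f"{len(classes)} labels but model has {cfg.num_classes} classes")
    x_train, y_train, _ = dataset_to_arrays(train_set, cfg.img_size, classes)
    x_val, y_val, _ = dataset_to_arrays(val_set, cfg.img_size, classes)
    x_train_n = normalize_batch(x_train)

    rng = np.random.default_rng(config.seed)
    opt = AdamW(model.parameters(), lr=config.learning_rate, betas=config.betas,
                weight_decay=config.weight_decay)
    import zlib

    cfg_blob = json.dumps(asdict(config), sort_keys=True).encode()
    hist = TrainHistory(seed=config.seed, config_hash=f"{zlib.crc32(cfg_blob):08x}")
    best_val = -1.0
    n = len(x_train_n)
    for epoch in range(config.epochs):
        t0 = time.time()
        model.train()
        order = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            logits, _ = model.logits(x_train_n[idx])
            loss = cross_entropy(logits, y_train[idx])
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch + 1}, step {start // config.batch_size}: "
                    f"loss={loss.data!r}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            correct += int((logits.data.argmax(axis=1) == y_train[idx]).sum())
        hist.train_loss.append(float(np.mean(losses)))
        hist.train_accuracy.append(correct / n)
        if (epoch + 1) % config.eval_every == 0 or epoch == config.epochs - 1:
            val_acc = _accuracy(model, x_val, y_val, config.batch_size)
        else:
            val_acc = hist.val_accuracy[-1] if hist.val_accuracy else float("nan")
        hist.val_accuracy.append(val_acc)
        hist.epoch_seconds.append(time.time() - t0)
        if out_dir is not None and val_acc >= best_val:
            best_val = val_acc
            save_checkpoint(model, Path(out_dir) / "best.npz", classes=classes,
                            seed=config.seed)
    if out_dir is not None:
        hist.to_csv(Path(out_dir) / "history.csv")
    return model, hist


def predict(model: FusedSwinClassifier, images: np.ndarray,
            classes: tuple[str, ...] | None = None):
    """Eval-mode labels + probabilities; per-item results are batch-order
    independent."""
    imgs = np.asarray(images)
    if imgs.ndim == 3:
        imgs = imgs[None]
    if imgs.shape[1] != model.cfg.img_size:
        imgs = np.stack([resize_image(im, model.cfg.img_size) for im in imgs])
    probs = model.predict_proba(imgs)
    idx = probs.argmax(axis=1)
    labels = [classes[i] for i in idx] if classes else list(idx)
    return labels, probs


def save_checkpoint(model: FusedSwinClassifier, path,
                    classes: tuple[str, ...] | None = None, seed: int = 0) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {"config": asdict(model.cfg), "classes": list(classes or ()), "seed": seed}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **model.state_dict())


def load_checkpoint(path) -> tuple[FusedSwinClassifier, dict]:
    with np.load(Path(path)) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        cfg_d = meta["config"]
        for k in ("depths", "heads"):
            cfg_d[k] = tuple(cfg_d[k])
        cfg = ModelConfig(**cfg_d)
        model = build_model(cfg, seed=meta["seed"])
        state = {k: z[k] for k in z.files if k != "__meta__"}
    model.load_state_dict(state)
    return model, meta
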