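"""End-to-end study protocols used by the test-bench and reporting scripts.

These compose the library the way a study would: generate ground-truthed
kernels, run the isolation pipeline, train the CPU-scale (tiny) model,
and measure recovery/accuracy.  Problem sizes are chosen for single-CPU
runs and stated in each docstring.
"""

from __future__ import annotations

import numpy as np

from . import fixtures as fx
from .model import ModelConfig, build_model
from .preprocess import (
    AugmentationConfig, LabeledImage, balance_and_expand, segment_kernels,
)
from .train import dataset_to_arrays, tiny_train_config, train

__all__ = ["segmentation_recovery", "smoke_training", "ablation_accuracies"]


def segmentation_recovery(n_trays: int = 20, seed: int = 0,
                          canvas: tuple[int, int] = (320, 320)):
    """Kernel recovery over seeded trays with 8-16 non-overlapping kernels.

    Returns (fraction of trays with exact count, matched centroid errors).
    """
    exact = 0
    errors: list[float] = []
    for i in range(n_trays):
        tray_seed = fx.derive_seed(seed, i)
        n = 8 + int(np.random.default_rng(tray_seed).integers(0, 9))
        tray = fx.generate_tray(n, canvas=canvas, seed=tray_seed)
        crops = segment_kernels(tray.pixels)
        if len(crops) == len(tray.kernels):
            exact += 1
            gt = np.array([k.center for k in tray.kernels])
            for c in crops:
                errors.append(float(np.hypot(gt[:, 0] - c.centroid[0],
                                             gt[:, 1] - c.centroid[1]).min()))
    return exact / n_trays, errors


def _expanded_training_set(n_per_class: int, target_per_class: int, seed: int):
    data = fx.generate_dataset(n_per_class, seed=seed)
    labeled = [LabeledImage(image=img, label=lab) for img, lab in data]
    expanded = balance_and_expand(labeled, target_per_class,
                                  AugmentationConfig(), seed=fx.derive_seed(seed, 77))
    return data, expanded


def smoke_training(seeds=(0, 1, 2), n_per_class: int = 100, epochs: int = 5,
                   data_seed: int = 11):
    """Tiny-preset training on 300 generated kernels (100 per class).

    The training set is the package's standard balance-augmented expansion
    (to 300 per class); accuracy is measured on the 300 original kernels.
    Returns a list of per-seed dicts with final accuracy and the attention
    weights observed on the originals.
    """
    originals, expanded = _expanded_training_set(n_per_class, 3 * n_per_class,
                                                 data_seed)
    x, y, classes = dataset_to_arrays(originals, 64)
    results = []
    for seed in seeds:
        model = build_model(ModelConfig.tiny(), seed=seed)
        _, hist = train(model, expanded, originals[:: max(len(originals) // 30, 1)],
                        tiny_train_config(seed=seed, epochs=epochs))
        probs = model.predict_proba(x)
        acc = float((probs.argmax(axis=1) == y).mean())
        model.eval()
        from .model import normalize_batch

        _, inter = model.forward(normalize_batch(x[:16]), collect=True)
        results.append({
            "seed": seed,
            "train_accuracy": acc,
            "loss_curve": hist.train_loss,
            "attention_weights": inter["weights"],
        })
    return results


def ablation_accuracies(seeds=(0, 1, 2), n_per_class: int = 60, epochs: int = 4,
                        data_seed: int = 23):
    """Mean fixture test accuracy for baseline / +fusion / +fusion+attention.

    Small-scale ablation: 60 kernels per class, 4:1 split, training set
    balance-augmented to 150 per class, tiny preset, 4 epochs, averaged
    over the given seeds.
    """
    from .preprocess import SplitSpec, split_dataset

    data = fx.generate_dataset(n_per_class, seed=data_seed)
    labeled = [LabeledImage(image=img, label=lab) for img, lab in data]
    train_set, test_set = split_dataset(labeled, SplitSpec(0.8, True, data_seed))
    expanded = balance_and_expand(train_set, 150, AugmentationConfig(),
                                  seed=fx.derive_seed(data_seed, 77))
    x, y, classes = dataset_to_arrays(test_set, 64)
    out: dict[str, float] = {}
    for variant in ("baseline", "tf", "tf_fa"):
        accs = []
        for seed in seeds:
            model = build_model(ModelConfig.tiny(variant=variant), seed=seed)
            train(model, expanded, test_set, tiny_train_config(seed=seed, epochs=epochs))
            probs = model.predict_proba(x)
            accs.append(float((probs.argmax(axis=1) == y).mean()))
        out[variant] = float(np.mean(accs))
    return out
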