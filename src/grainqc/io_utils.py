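"""Directory-per-class dataset I/O (root/{good,moldy,broken}/*.png)."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .preprocess import LabeledImage

__all__ = ["read_class_dir", "write_class_dir", "list_class_dir"]


def list_class_dir(root: str | Path) -> list[tuple[str, str]]:
    """(relative filename, label) pairs, sorted for determinism."""
    root = Path(root)
    out = []
    for class_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        for f in sorted(class_dir.glob("*")):
            if f.suffix.lower() in (".png", ".jpg", ".jpeg"):
                out.append((f"{class_dir.name}/{f.name}", class_dir.name))
    return out


def read_class_dir(root: str | Path) -> list[LabeledImage]:
    from PIL import Image

    root = Path(root)
    out = []
    for name, lab in list_class_dir(root):
        img = np.asarray(Image.open(root / name).convert("RGB"))
        out.append(LabeledImage(image=img, label=lab))
    return out


def write_class_dir(dataset: list[LabeledImage], root: str | Path) -> Path:
    from PIL import Image

    root = Path(root)
    counters: dict[str, int] = {}
    for item in dataset:
        d = root / item.label
        d.mkdir(parents=True, exist_ok=True)
        i = counters.get(item.label, 0)
        counters[item.label] = i + 1
        Image.fromarray(item.image).save(d / f"{i:05d}.png")
    return root
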