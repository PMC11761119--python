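"""Synthetic grain-kernel image generator with exact ground truth.

Real kernel photographs of the three quality classes (good / moldy /
broken) are emulated with parametric renders: a good kernel is a smooth,
convex, bright ellipse; a moldy kernel carries dark blotches inside the
same outline; a broken kernel has a concave bite taken out of the
ellipse.  Kernels sit darker-saturated on a light background (light-box
polarity), with multiplicative radial shading, anti-aliased edges and
additive Gaussian sensor noise (sigma 4 gray levels) so that denoising and
thresholding are exercised non-trivially.

Every render is a pure function of (spec, seed); the declared kernel
centre is the centroid of the rendered mask (to sub-pixel accuracy), and
per-item seeds are derived from a master seed with a splitmix64-style
mixer so datasets are reproducible bit for bit.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "KernelSpec", "TrayImage", "SizingError", "CapacityError",
    "generate_kernel", "generate_tray", "generate_dataset",
    "derive_seed", "random_kernel_spec", "write_dataset", "write_tray",
    "LABELS",
]

LABELS = ("good", "moldy", "broken")

_BACKGROUND = 235.0
_NOISE_SIGMA = 4.0
_SUPERSAMPLE = 4


class SizingError(ValueError):
    """Kernel axes do not fit the requested canvas."""


class CapacityError(ValueError):
    """Non-overlapping placement failed; canvas too small for the request."""


def derive_seed(master: int, index: int) -> int:
    """splitmix64-style per-item seed derivation (parallel-safe, documented here).

    z = (master * 2^32 + index + golden) mixed through two xor-shift/multiply
    rounds; result truncated to 31 bits so it stays a valid small seed.
    """
    z = (int(master) * (1 << 32) + int(index) + 0x9E3779B97F4A7C15) % (1 << 64)
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) % (1 << 64)
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) % (1 << 64)
    return int((z ^ (z >> 31)) % (1 << 31))


@dataclass(frozen=True)
class KernelSpec:
    """Geometry + appearance of one kernel; axes are semi-axes in pixels."""

    label: str
    center: tuple[float, float]  # (x, y) = (column, row)
    axes: tuple[float, float]  # (major, minor) semi-axes
    angle: float = 0.0  # degrees, counter-clockwise
    base_intensity: tuple[float, float, float] = (210.0, 172.0, 84.0)
    blemish_count: int = 0
    notch_fraction: float = 0.0

    def validate(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        if min(self.axes) <= 0:
            raise ValueError("axes must be positive")
        if self.label != "moldy" and self.blemish_count != 0:
            raise ValueError("blemish_count must be 0 unless label is 'moldy'")
        if (self.label == "broken") != (self.notch_fraction > 0):
            raise ValueError("notch_fraction must be > 0 iff label is 'broken'")
        if not 0 <= self.notch_fraction <= 1:
            raise ValueError("notch_fraction must lie in [0, 1]")


@dataclass
class TrayImage:
    """Multi-kernel scene with per-kernel ground truth."""

    pixels: np.ndarray  # H x W x 3 uint8
    background_intensity: float
    kernels: list[KernelSpec]
    overlap_allowed: bool = False
    masks: list[np.ndarray] = field(default_factory=list)  # full-canvas booleans

    def foreground_mask(self) -> np.ndarray:
        out = np.zeros(self.pixels.shape[:2], dtype=bool)
        for m in self.masks:
            out |= m
        return out


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------

def _kernel_geometry(spec: KernelSpec, rng: np.random.Generator):
    """Bite position/radius for broken kernels (consumed from rng even when
    unused so the draw sequence is label-independent)."""
    theta = rng.uniform(0.0, 2 * np.pi)
    a, b = spec.axes
    bite_r = spec.notch_fraction * a
    # bite centre sits slightly inside the outline so the cut is a deep
    # concavity (still crossing the boundary) rather than a shallow nick
    f = 1.0 - 0.45 * spec.notch_fraction
    bite_c = np.array([f * a * np.cos(theta), f * b * np.sin(theta)])
    return bite_c, bite_r


def _alpha_supersampled(shape, center, spec, bite_c, bite_r):
    H, W = shape
    ss = _SUPERSAMPLE
    ys = (np.arange(H * ss) + 0.5) / ss - 0.5 - center[1]
    xs = (np.arange(W * ss) + 0.5) / ss - 0.5 - center[0]
    X, Y = np.meshgrid(xs, ys)
    ang = np.deg2rad(spec.angle)
    ca, sa = np.cos(ang), np.sin(ang)
    xr = ca * X + sa * Y
    yr = -sa * X + ca * Y
    a, b = spec.axes
    inside = (xr / a) ** 2 + (yr / b) ** 2 <= 1.0
    if bite_r > 0:
        inside &= (xr - bite_c[0]) ** 2 + (yr - bite_c[1]) ** 2 > bite_r**2
    # block-average ss x ss sub-pixels -> per-pixel coverage
    return inside.reshape(H, ss, W, ss).mean(axis=(1, 3))


def _render_kernel_layer(shape, spec: KernelSpec, rng: np.random.Generator):
    """Return (alpha, rgb) for one kernel on a canvas of `shape`.

    The render is centroid-corrected: the binary (alpha > 0.5) centroid
    lands on spec.center even for bitten (asymmetric) shapes.
    """
    bite_c, bite_r = _kernel_geometry(spec, rng)
    center = np.asarray(spec.center, dtype=float)
    alpha = _alpha_supersampled(shape, center, spec, bite_c, bite_r)
    m = alpha > 0.5
    if not m.any():
        raise SizingError("kernel renders to an empty mask on this canvas")
    ys, xs = np.nonzero(m)
    c1 = np.array([xs.mean(), ys.mean()])
    shift = center - c1
    if np.abs(shift).max() > 1e-3:  # second pass with centroid correction
        alpha = _alpha_supersampled(shape, center + shift, spec, bite_c, bite_r)
        m = alpha > 0.5
        center = center + shift

    H, W = shape
    Y, X = np.mgrid[0:H, 0:W].astype(float)
    ang = np.deg2rad(spec.angle)
    ca, sa = np.cos(ang), np.sin(ang)
    xr = ca * (X - center[0]) + sa * (Y - center[1])
    yr = -sa * (X - center[0]) + ca * (Y - center[1])
    a, b = spec.axes
    er2 = np.clip((xr / a) ** 2 + (yr / b) ** 2, 0.0, 1.0)
    shading = 1.0 - 0.18 * er2  # multiplicative radial shading

    mult = np.ones((H, W))
    for _ in range(spec.blemish_count):
        # blotch centre in ellipse coordinates, kept inside the outline
        u = rng.uniform(0, 0.72)
        th = rng.uniform(0, 2 * np.pi)
        bx, by = np.sqrt(u) * a * np.cos(th), np.sqrt(u) * b * np.sin(th)
        r = rng.uniform(0.16, 0.26) * b
        d2 = (xr - bx) ** 2 + (yr - by) ** 2
        blotch = np.exp(-0.5 * d2 / (r * r))
        mult *= 1.0 - 0.7 * blotch  # dark mold blotches

    base = np.asarray(spec.base_intensity, dtype=float)
    rgb = base[None, None, :] * (shading * mult)[:, :, None]
    return alpha, rgb


def generate_kernel(spec: KernelSpec, seed: int,
                    canvas: tuple[int, int] | None = None
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Render one kernel; returns (H x W x 3 uint8 image, boolean mask)."""
    spec.validate()
    a = spec.axes[0]
    if canvas is None:
        side = int(np.ceil(2 * a)) + 16
        canvas = (side, side)
    H, W = canvas
    if 2 * a + 6 > min(H, W):
        raise SizingError(f"axes {spec.axes} exceed canvas {canvas}")
    if spec.center == (0.0, 0.0):
        spec = KernelSpec(**{**spec.__dict__, "center": (W / 2.0, H / 2.0)})
    rng = np.random.default_rng(seed)
    alpha, rgb = _render_kernel_layer((H, W), spec, rng)
    img = _BACKGROUND * (1 - alpha[:, :, None]) + rgb * alpha[:, :, None]
    img = img + rng.normal(0.0, _NOISE_SIGMA, size=img.shape)
    return np.clip(img, 0, 255).astype(np.uint8), alpha > 0.5


def random_kernel_spec(label: str, rng: np.random.Generator,
                       center: tuple[float, float] = (0.0, 0.0),
                       scale: float = 16.0) -> KernelSpec:
    """Draw a plausible kernel of the given class; `scale` is the mean
    major semi-axis in pixels."""
    major = rng.uniform(0.85, 1.15) * scale
    minor = major * rng.uniform(0.6, 0.8)
    angle = rng.uniform(0.0, 180.0)
    base = np.array([210.0, 172.0, 84.0]) + rng.uniform(-6, 6, size=3)
    blemishes = int(rng.integers(4, 8)) if label == "moldy" else 0
    notch = float(rng.uniform(0.35, 0.5)) if label == "broken" else 0.0
    return KernelSpec(label=label, center=center, axes=(major, minor),
                      angle=angle, base_intensity=tuple(base),
                      blemish_count=blemishes, notch_fraction=notch)


def _class_counts(n: int, mix: dict[str, float] | None) -> dict[str, int]:
    if mix is None:
        mix = {lab: 1 / 3 for lab in LABELS}
    total = sum(mix.values())
    if abs(total - 1.0) > 1e-6:
        raise ValueError("class_mix proportions must sum to 1")
    raw = {lab: n * p for lab, p in mix.items()}
    counts = {lab: int(np.floor(v)) for lab, v in raw.items()}
    rem = n - sum(counts.values())
    for lab in sorted(raw, key=lambda l: raw[l] - counts[l], reverse=True)[:rem]:
        counts[lab] += 1
    return counts


def generate_tray(n_kernels: int, canvas: tuple[int, int] = (256, 256),
                  class_mix: dict[str, float] | None = None, seed: int = 0,
                  scale: float = 16.0, overlap_allowed: bool = False) -> TrayImage:
    """Compose `n_kernels` kernels on a light tray with >= 2 px separation."""
    if n_kernels < 0:
        raise ValueError("n_kernels must be >= 0")
    H, W = canvas
    rng = np.random.default_rng(derive_seed(seed, 0))
    counts = _class_counts(n_kernels, class_mix)
    labels = [lab for lab in LABELS for _ in range(counts[lab])]
    rng.shuffle(labels)

    specs: list[KernelSpec] = []
    radii: list[float] = []
    centers: list[np.ndarray] = []
    for i, lab in enumerate(labels):
        spec0 = random_kernel_spec(lab, np.random.default_rng(derive_seed(seed, 1 + i)),
                                   scale=scale)
        r = spec0.axes[0] + 6.0
        placed = False
        for _ in range(400):
            c = np.array([rng.uniform(r + 2, W - r - 2), rng.uniform(r + 2, H - r - 2)])
            if overlap_allowed or all(
                np.hypot(*(c - c2)) > r + r2 + 2.0 for c2, r2 in zip(centers, radii)
            ):
                placed = True
                break
        if not placed:
            raise CapacityError(
                f"could not place kernel {i + 1}/{n_kernels} on canvas {canvas}")
        centers.append(c)
        radii.append(r)
        specs.append(KernelSpec(**{**spec0.__dict__, "center": (float(c[0]), float(c[1]))}))

    img = np.full((H, W, 3), _BACKGROUND, dtype=float)
    masks: list[np.ndarray] = []
    for i, spec in enumerate(specs):
        layer_rng = np.random.default_rng(derive_seed(seed, 1000 + i))
        alpha, rgb = _render_kernel_layer((H, W), spec, layer_rng)
        img = img * (1 - alpha[:, :, None]) + rgb * alpha[:, :, None]
        masks.append(alpha > 0.5)
    noise_rng = np.random.default_rng(derive_seed(seed, 2))
    img = img + noise_rng.normal(0.0, _NOISE_SIGMA, size=img.shape)
    return TrayImage(pixels=np.clip(img, 0, 255).astype(np.uint8),
                     background_intensity=_BACKGROUND, kernels=specs,
                     overlap_allowed=overlap_allowed, masks=masks)


def generate_dataset(n_per_class: int, seed: int = 0,
                     canvas: tuple[int, int] = (96, 96),
                     scale: float | None = None) -> list[tuple[np.ndarray, str]]:
    """Balanced list of 3 * n_per_class single-kernel (image, label) pairs."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if scale is None:
        scale = 0.26 * min(canvas)
    out: list[tuple[np.ndarray, str]] = []
    idx = 0
    for lab in LABELS:
        for _ in range(n_per_class):
            s = derive_seed(seed, idx)
            rng = np.random.default_rng(s)
            H, W = canvas
            jitter = rng.uniform(-2, 2, size=2)
            spec = random_kernel_spec(
                lab, rng, center=(W / 2.0 + jitter[0], H / 2.0 + jitter[1]),
                scale=scale)
            img, _ = generate_kernel(spec, derive_seed(s, 1), canvas=canvas)
            out.append((img, lab))
            idx += 1
    return out


# --------------------------------------------------------------------------
# on-disk interface (PNG + ground-truth sidecar CSV)
# --------------------------------------------------------------------------

def write_tray(tray: TrayImage, out_dir: str | Path, stem: str = "tray") -> Path:
    from PIL import Image

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    png = out_dir / f"{stem}.png"
    Image.fromarray(tray.pixels).save(png)
    with open(out_dir / f"{stem}.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["filename", "label", "cx", "cy",
                    "box_x", "box_y", "box_w", "box_h", "angle"])
        for spec, mask in zip(tray.kernels, tray.masks):
            ys, xs = np.nonzero(mask)
            w.writerow([png.name, spec.label,
                        f"{spec.center[0]:.2f}", f"{spec.center[1]:.2f}",
                        int(xs.min()), int(ys.min()),
                        int(xs.max() - xs.min() + 1), int(ys.max() - ys.min() + 1),
                        f"{spec.angle:.2f}"])
    return png


def write_dataset(dataset: list[tuple[np.ndarray, str]], out_dir: str | Path) -> Path:
    """Directory-per-class layout root/{good,moldy,broken}/NNN.png + manifest."""
    from PIL import Image

    out_dir = Path(out_dir)
    rows = []
    counters = {lab: 0 for lab in LABELS}
    for img, lab in dataset:
        d = out_dir / lab
        d.mkdir(parents=True, exist_ok=True)
        name = f"{counters[lab]:04d}.png"
        counters[lab] += 1
        Image.fromarray(img).save(d / name)
        rows.append([f"{lab}/{name}", lab])
    with open(out_dir / "manifest.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["filename", "label"])
        w.writerows(rows)
    return out_dir
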