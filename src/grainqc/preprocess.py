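"""Kernel isolation, augmentation, class balancing and the 4:1 split.

The isolation pipeline mirrors standard tray-photograph processing:
grayscale conversion, Gaussian denoising, automatic (Otsu) thresholding
with polarity detection, connected-component contour extraction with
centroids from first image moments, and a minimum-area rotated-rectangle
crop per kernel, rectified to axis-aligned.

Augmentation covers random rotation, brightness scaling, salt-and-pepper
noise, additive Gaussian noise, Gaussian blur and exact 180-degree
rotation; `balance_and_expand` uses them to equalise class counts with
full provenance, and `split_dataset` performs a single stratified
train/test split (default 4:1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.ndimage as ndi
from skimage import measure, transform
from skimage.filters import threshold_otsu
from shapely import MultiPoint

__all__ = [
    "BinaryMask", "KernelCrop", "AugmentationConfig", "SplitSpec", "LabeledImage",
    "to_grayscale", "gaussian_denoise", "binarize", "extract_contours",
    "crop_min_rect", "segment_kernels", "augment_image", "balance_and_expand",
    "split_dataset", "resize_image", "AUGMENT_OPS",
]

# Rec.601 luminance weights
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class BinaryMask:
    pixels: np.ndarray  # H x W bool
    polarity: str  # "foreground_high" | "foreground_low"
    threshold: float | None = None


@dataclass
class Contour:
    points: np.ndarray  # (N, 2) float, (x, y) order
    centroid: tuple[float, float]  # (cx, cy)
    area: float


@dataclass
class KernelCrop:
    image: np.ndarray  # h x w x 3 uint8
    source_box: tuple[float, float, float, float, float]  # (x, y, w, h, angle deg)
    centroid: tuple[float, float]
    label: str | None = None


@dataclass(frozen=True)
class AugmentationConfig:
    """Parameter ranges for the six augmentation operators."""

    rotation_range: tuple[float, float] = (-180.0, 180.0)
    brightness_range: tuple[float, float] = (0.7, 1.3)
    sp_amount: float = 0.02
    gaussian_sigma: tuple[float, float] = (0.5, 1.5)  # blur sigma range, px
    noise_sigma: float = 10.0  # additive noise, gray levels
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.sp_amount <= 1:
            raise ValueError("sp_amount must lie in [0, 1]")
        if min(self.brightness_range) <= 0:
            raise ValueError("brightness factors must be > 0")


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.8  # the 4:1 protocol
    stratified: bool = True
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")


@dataclass
class LabeledImage:
    image: np.ndarray
    label: str
    provenance: list = field(default_factory=list)  # [(op, seed), ...] applied to source
    source: int | None = None  # index of the original this was derived from


# --------------------------------------------------------------------------
# isolation pipeline
# --------------------------------------------------------------------------

def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Rec.601 luminance; preserves the 0-255 range."""
    image = np.asarray(image)
    if image.ndim == 2:
        return image.astype(float)
    if image.ndim != 3 or image.shape[-1] != 3:
        raise ValueError(f"expected H x W x 3 image, got shape {image.shape}")
    return image.astype(float) @ _LUMA


def gaussian_denoise(gray: np.ndarray, sigma: float = 1.0) -> np.ndarray:
    """Gaussian filter, kernel truncated at 3 sigma."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    return ndi.gaussian_filter(np.asarray(gray, dtype=float), sigma=sigma, truncate=3.0)


def binarize(gray: np.ndarray, method: str = "otsu",
             threshold: float | None = None) -> BinaryMask:
    """Threshold with kernels-as-foreground polarity.

    Polarity is auto-detected: the side of the threshold with fewer pixels
    is taken as foreground (kernels occupy the minority of a tray).
    """
    gray = np.asarray(gray, dtype=float)
    if method == "otsu":
        if np.ptp(gray) == 0:
            raise ValueError("degenerate histogram: image is constant")
        t = float(threshold_otsu(gray))
    elif method == "fixed":
        if threshold is None:
            raise ValueError("fixed method requires a threshold")
        t = float(threshold)
    else:
        raise ValueError(f"unknown method {method!r}")
    high = gray >= t
    if high.sum() <= high.size / 2:
        return BinaryMask(high, "foreground_high", t)
    return BinaryMask(~high, "foreground_low", t)


def extract_contours(mask: BinaryMask, min_area: float = 0.0) -> list[Contour]:
    """One contour per connected component with area >= min_area.

    Centroids are first image moments of the filled component, reported in
    (x, y) = (column, row) pixel-centred coordinates.
    """
    lab = measure.label(mask.pixels)
    out: list[Contour] = []
    for region in measure.regionprops(lab):
        if region.area < min_area:
            continue
        cy, cx = region.centroid
        comp = lab == region.label
        cs = measure.find_contours(comp.astype(float), 0.5)
        pts = max(cs, key=len)[:, ::-1] if cs else np.empty((0, 2))  # (row,col)->(x,y)
        out.append(Contour(points=pts, centroid=(float(cx), float(cy)),
                           area=float(region.area)))
    out.sort(key=lambda c: (c.centroid[1], c.centroid[0]))
    return out


def _min_area_rect(points: np.ndarray) -> tuple[np.ndarray, float, float, float]:
    """(center, width, height, angle_deg) of the minimum-area enclosing rectangle."""
    rect = MultiPoint([tuple(p) for p in points]).minimum_rotated_rectangle
    if rect.geom_type != "Polygon":  # degenerate (collinear) contour
        raise ValueError("contour is degenerate; no enclosing rectangle")
    corners = np.asarray(rect.exterior.coords)[:4]
    e1 = corners[1] - corners[0]
    e2 = corners[2] - corners[1]
    w, h = np.linalg.norm(e1), np.linalg.norm(e2)
    angle = np.degrees(np.arctan2(e1[1], e1[0]))
    center = corners[:4].mean(axis=0)
    return center, float(w), float(h), float(angle)


def crop_min_rect(image: np.ndarray, contour: Contour, padding: int = 2,
                  label: str | None = None) -> KernelCrop:
    """Rectified crop of the minimum-area rotated rectangle around a contour."""
    if len(contour.points) < 3:
        raise ValueError("contour needs at least 3 points")
    center, w, h, angle = _min_area_rect(contour.points)
    H, W = image.shape[:2]
    w_out = int(np.ceil(w)) + 2 * padding
    h_out = int(np.ceil(h)) + 2 * padding
    # sample the rotated rectangle on an axis-aligned grid (bilinear)
    ang = np.deg2rad(angle)
    ca, sa = np.cos(ang), np.sin(ang)
    xs = np.arange(w_out) - (w_out - 1) / 2
    ys = np.arange(h_out) - (h_out - 1) / 2
    Xg, Yg = np.meshgrid(xs, ys)
    src_x = center[0] + ca * Xg - sa * Yg
    src_y = center[1] + sa * Xg + ca * Yg
    if src_x.min() < -0.5 or src_y.min() < -0.5 or src_x.max() > W - 0.5 or src_y.max() > H - 0.5:
        warnings.warn("crop rectangle exceeds image bounds; clipping", stacklevel=2)
    coords = np.stack([np.clip(src_y, 0, H - 1), np.clip(src_x, 0, W - 1)])
    chans = [ndi.map_coordinates(image[..., c].astype(float), coords, order=1)
             for c in range(image.shape[-1])]
    crop = np.clip(np.stack(chans, axis=-1), 0, 255).astype(np.uint8)
    return KernelCrop(
        image=crop,
        source_box=(float(center[0] - w / 2), float(center[1] - h / 2),
                    float(w), float(h), angle),
        centroid=contour.centroid, label=label,
    )


def segment_kernels(image: np.ndarray, sigma: float = 1.0, method: str = "otsu",
                    threshold: float | None = None, min_area_frac: float = 0.001,
                    padding: int = 2) -> list[KernelCrop]:
    """Full isolation pipeline; crops ordered row-major by centroid.

    A blank (constant) image yields an empty list rather than a
    thresholding error.
    """
    gray = to_grayscale(image)
    den = gaussian_denoise(gray, sigma)
    if np.ptp(den) < 1.0:  # flat tray: nothing to segment
        return []
    mask = binarize(den, method=method, threshold=threshold)
    min_area = min_area_frac * mask.pixels.size
    contours = extract_contours(mask, min_area=min_area)
    return [crop_min_rect(image, c, padding=padding) for c in contours]


def resize_image(image: np.ndarray, size: int) -> np.ndarray:
    """Bilinear resize to size x size (the model's input resolution)."""
    out = transform.resize(image.astype(float), (size, size), order=1,
                           preserve_range=True, anti_aliasing=True)
    return np.clip(out, 0, 255).astype(np.uint8)


# --------------------------------------------------------------------------
# augmentation
# --------------------------------------------------------------------------

AUGMENT_OPS = ("rotate_random", "rotate_180", "brightness", "salt_pepper",
               "gaussian_noise", "gaussian_blur")


def augment_image(image: np.ndarray, op: str, config: AugmentationConfig,
                  seed: int) -> np.ndarray:
    """Apply one augmentation operator; deterministic per (op, config, seed)."""
    config.validate()
    rng = np.random.default_rng(seed)
    img = np.asarray(image)
    if op == "rotate_random":
        angle = rng.uniform(*config.rotation_range)
        out = transform.rotate(img.astype(float), angle, order=1, mode="edge",
                               preserve_range=True)
    elif op == "rotate_180":
        out = img[::-1, ::-1]  # exact involution, no resampling
    elif op == "brightness":
        factor = rng.uniform(*config.brightness_range)
        out = img.astype(float) * factor
    elif op == "salt_pepper":
        out = img.astype(float).copy()
        hit = rng.random(img.shape[:2]) < config.sp_amount
        salt = rng.random(img.shape[:2]) < 0.5
        out[hit & salt] = 255
        out[hit & ~salt] = 0
    elif op == "gaussian_noise":
        out = img.astype(float) + rng.normal(0, config.noise_sigma, size=img.shape)
    elif op == "gaussian_blur":
        sigma = rng.uniform(*config.gaussian_sigma)
        out = ndi.gaussian_filter(img.astype(float), sigma=(sigma, sigma, 0))
    else:
        raise ValueError(f"unknown augmentation op {op!r}")
    return np.clip(out, 0, 255).astype(img.dtype)


def balance_and_expand(dataset: list[LabeledImage], target_per_class: int,
                       config: AugmentationConfig | None = None,
                       seed: int = 0) -> list[LabeledImage]:
    """Grow every class to exactly target_per_class with augmented copies.

    Originals are retained untouched; each synthetic image records the
    index of its source and the (op, seed) chain so it can be replayed.
    """
    from .fixtures import derive_seed

    config = config or AugmentationConfig()
    by_class: dict[str, list[int]] = {}
    for i, item in enumerate(dataset):
        by_class.setdefault(item.label, []).append(i)
    if any(len(v) == 0 for v in by_class.values()):
        raise ValueError("every class must be non-empty")
    for lab, idxs in by_class.items():
        if target_per_class < len(idxs):
            raise ValueError(
                f"target {target_per_class} below original count {len(idxs)} for {lab!r}")

    out = [replace(it, provenance=list(it.provenance)) for it in dataset]
    counter = 0
    for lab in sorted(by_class):
        idxs = by_class[lab]
        need = target_per_class - len(idxs)
        lab_tag = int.from_bytes(lab.encode(), "little") % (1 << 16)  # stable across runs
        rng = np.random.default_rng(derive_seed(seed, lab_tag))
        for _ in range(need):
            src = int(rng.choice(idxs))
            op = AUGMENT_OPS[int(rng.integers(len(AUGMENT_OPS)))]
            op_seed = derive_seed(seed, counter)
            counter += 1
            img = augment_image(dataset[src].image, op, config, op_seed)
            out.append(LabeledImage(image=img, label=lab,
                                    provenance=[(op, op_seed)], source=src))
    return out


def replay_provenance(dataset: list[LabeledImage], item: LabeledImage,
                      config: AugmentationConfig | None = None) -> np.ndarray:
    """Re-derive a synthetic image from its source and op chain."""
    config = config or AugmentationConfig()
    img = dataset[item.source].image
    for op, op_seed in item.provenance:
        img = augment_image(img, op, config, op_seed)
    return img


def split_dataset(dataset: list, spec: SplitSpec) -> tuple[list, list]:
    """Single stratified train/test split; per-class counts round to the
    train fraction within one item."""
    spec.validate()
    if not dataset:
        raise ValueError("dataset is empty")
    rng = np.random.default_rng(spec.seed)

    def label_of(item):
        return item.label if hasattr(item, "label") else item[1]

    if spec.stratified:
        groups: dict[str, list[int]] = {}
        for i, item in enumerate(dataset):
            groups.setdefault(label_of(item), []).append(i)
        train_idx: list[int] = []
        test_idx: list[int] = []
        for lab in sorted(groups):
            idxs = np.array(groups[lab])
            if len(idxs) < 2:
                raise ValueError(f"class {lab!r} has fewer than 2 items")
            rng.shuffle(idxs)
            n_train = int(round(spec.train_fraction * len(idxs)))
            n_train = min(max(n_train, 1), len(idxs) - 1)
            train_idx.extend(idxs[:n_train])
            test_idx.extend(idxs[n_train:])
    else:
        idxs = np.arange(len(dataset))
        rng.shuffle(idxs)
        n_train = int(round(spec.train_fraction * len(idxs)))
        train_idx, test_idx = list(idxs[:n_train]), list(idxs[n_train:])
    return [dataset[i] for i in sorted(train_idx)], [dataset[i] for i in sorted(test_idx)]
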