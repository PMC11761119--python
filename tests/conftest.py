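import numpy as np
import pytest

from grainqc import fixtures as fx


@pytest.fixture(scope="session")
def small_dataset():
    """60 single-kernel images (20 per class) at the generator default canvas."""
    return fx.generate_dataset(20, seed=11)


@pytest.fixture(scope="session")
def tray_12():
    """A 12-kernel non-overlapping tray with ground truth."""
    return fx.generate_tray(12, canvas=(320, 320), seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def solidity(mask: np.ndarray) -> float:
    """Area over convex-hull area (the geometric oracle used throughout)."""
    from skimage.morphology import convex_hull_image

    return float(mask.sum() / convex_hull_image(mask).sum())


def gray_mean(image: np.ndarray, mask: np.ndarray) -> float:
    g = image.astype(float) @ np.array([0.299, 0.587, 0.114])
    return float(g[mask].mean())
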