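"""Generate synthetic kernels of the three quality classes.

Renders one kernel per class plus a 9-kernel tray, prints each kernel's
ground truth and the class-discriminative statistics (solidity for shape,
mean interior intensity for mold).
"""

import numpy as np
from skimage.morphology import convex_hull_image

from grainqc import fixtures as fx

specs = {
    "good": fx.KernelSpec("good", (48.0, 48.0), (18.0, 12.0), angle=25.0),
    "moldy": fx.KernelSpec("moldy", (48.0, 48.0), (18.0, 12.0), angle=25.0,
                           blemish_count=5),
    "broken": fx.KernelSpec("broken", (48.0, 48.0), (18.0, 12.0), angle=25.0,
                            notch_fraction=0.4),
}

print("single kernels (96x96 canvas):")
for label, spec in specs.items():
    img, mask = fx.generate_kernel(spec, seed=1, canvas=(96, 96))
    sol = mask.sum() / convex_hull_image(mask).sum()
    gray = img.astype(float) @ np.array([0.299, 0.587, 0.114])
    print(f"  {label:7s} solidity={sol:.3f}  mean intensity={gray[mask].mean():6.1f}")

tray = fx.generate_tray(9, canvas=(300, 300), seed=7)
print(f"\ntray: {len(tray.kernels)} kernels on a "
      f"{tray.pixels.shape[0]}x{tray.pixels.shape[1]} canvas")
for k in tray.kernels:
    print(f"  {k.label:7s} centre=({k.center[0]:6.1f},{k.center[1]:6.1f}) "
          f"axes=({k.axes[0]:.1f},{k.axes[1]:.1f}) angle={k.angle:5.1f}")

# Good kernels are convex (solidity near 1), broken ones concave (< 0.9),
# moldy ones darker inside the outline — these gaps are what both the
# segmentation thresholds and the classifier rely on.
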