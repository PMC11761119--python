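"""Audit the 224-px architecture: stage shapes, fusion trace, parameters.

Prints every dimension the design fixes: stage outputs 56x56x96 /
28x28x192 / 14x14x384, unified 1x1x384 pooled vectors, the convolution
block's 384->128->256->1152 schedule, and the 1x3x384 fusion tensors.
"""

import numpy as np

from grainqc.model import ModelConfig, build_model, build_swin_baseline, count_parameters

model = build_model(ModelConfig(), seed=0)
model.eval()
x = np.zeros((1, 224, 224, 3), dtype=np.float32)
_, inter = model.forward(x, collect=True)

for key in ("F1", "F2", "F3", "pooled", "F4", "F5", "F6", "F7"):
    print(f"{key}: {inter[key]}")
print("conv block trace:", inter["conv_trace"])
print("attention weights:", inter["weights"].round(4))

n_trunc = count_parameters(model)
n_full = count_parameters(build_swin_baseline(seed=0))
print(f"\nstages: {len(model.backbone.stages)} (stage 4 removed), "
      f"stage-3 blocks: {len(model.backbone.stages[2])}")
print(f"parameters: {n_trunc:,} vs {n_full:,} for the untruncated 4-stage "
      f"backbone ({100 * (1 - n_trunc / n_full):.1f}% fewer)")
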