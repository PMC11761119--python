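"""Balance an imbalanced kernel set by augmentation, then split 4:1.

Shows the provenance records that make every synthetic image replayable,
and the stratified one-off train/test split.
"""

from grainqc import fixtures as fx
from grainqc.preprocess import (
    AugmentationConfig, LabeledImage, SplitSpec, balance_and_expand,
    replay_provenance, split_dataset,
)

# imbalanced starting point: 12 good, 6 moldy, 9 broken
pool = fx.generate_dataset(12, seed=1)  # 12 per class, balanced
keep = {"good": 12, "moldy": 6, "broken": 9}
data = []
for img, lab in pool:
    if keep[lab] > 0:
        keep[lab] -= 1
        data.append(LabeledImage(image=img, label=lab))

counts = {lab: sum(1 for it in data if it.label == lab) for lab in fx.LABELS}
print("before:", counts)

expanded = balance_and_expand(data, 15, AugmentationConfig(), seed=4)
counts = {lab: sum(1 for it in expanded if it.label == lab) for lab in fx.LABELS}
print("after balancing to 15/class:", counts)

synth = [it for it in expanded if it.provenance]
ok = all((replay_provenance(expanded, it) == it.image).all() for it in synth)
print(f"{len(synth)} synthetic images; provenance replays exactly: {ok}")
print("example op chain:", synth[0].provenance, "from source", synth[0].source)

train_set, test_set = split_dataset(expanded, SplitSpec(0.8, True, seed=0))
print(f"split 4:1 -> {len(train_set)} train / {len(test_set)} test (stratified)")
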