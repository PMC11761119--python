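"""Train the CPU-scale (tiny) classifier on synthetic kernels.

A shortened run: 90 kernels, 3 epochs — enough to watch the loss fall and
the validation accuracy move off chance (1/3).  The full smoke protocol
(300 kernels, balance-augmented, 5 epochs) lives in
grainqc.protocols.smoke_training.
"""

from dataclasses import replace

from grainqc import fixtures as fx
from grainqc.model import ModelConfig, build_model
from grainqc.preprocess import SplitSpec, split_dataset
from grainqc.train import tiny_train_config, train

data = fx.generate_dataset(30, seed=11)  # 90 kernels, 30 per class
train_set, val_set = split_dataset(data, SplitSpec(0.8, True, seed=0))

model = build_model(ModelConfig.tiny(), seed=0)
cfg = replace(tiny_train_config(seed=0, epochs=3), eval_every=1)
_, hist = train(model, train_set, val_set, cfg)

for e, (loss, tr, va) in enumerate(zip(hist.train_loss, hist.train_accuracy,
                                       hist.val_accuracy), 1):
    print(f"epoch {e}: loss={loss:.3f} train_acc={tr:.3f} val_acc={va:.3f}")
print("chance level is 0.333; the loss should drop well below ln(3)=1.099")
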