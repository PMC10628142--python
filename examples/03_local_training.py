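"""One client's local SGD: cross-entropy loss over epochs on its partition.

The desk-scale tiny_cnn (two conv blocks + global average pooling + linear
head) trains with plain mini-batch SGD; the printed per-epoch losses are the
mean per-sample training loss and should trend downward.
"""

import numpy as np

import fedleaf as fl
from fedleaf.model_core import build_model

data = fl.make_dataset(fl.SyntheticDatasetSpec(
    n_classes=4, images_per_class=40, image_size=(32, 32),
    noise_level=0.1, seed=3,
))
stats = fl.compute_channel_stats(data)
data = fl.normalize(data, stats)

spec = fl.ModelSpec("tiny_cnn", n_classes=4, input_size=(32, 32), init_seed=0)
model = build_model(spec)
print(f"tiny_cnn with {len(model.get_weights())} parameters")

weights, losses = fl.local_train(
    model, data, epochs=5, batch_size=16, lr=0.01, seed=0
)
for e, loss in enumerate(losses, 1):
    print(f"epoch {e}: mean training loss {loss:.4f}")
acc = float(np.mean(model.predict(data.images) == data.labels))
print(f"training accuracy after 5 epochs: {acc:.3f}")
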