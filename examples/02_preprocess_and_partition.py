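"""Stratified split, channel standardization, and IID client partitioning.

Channel stats (mean m, population std sigma) are computed on the training
split only and applied as Z = (X - m) / sigma to both splits; the training
pool is then dealt equally and at random to the clients.
"""

import numpy as np

import fedleaf as fl

data = fl.make_dataset(fl.SyntheticDatasetSpec(
    n_classes=4, images_per_class=50, image_size=(32, 32),
    noise_level=0.1, seed=1,
))
train, test = fl.stratified_split(data, test_fraction=0.2, seed=0)
print(f"split: {len(train)} train / {len(test)} test "
      f"(per-class test counts {np.bincount(test.labels).tolist()})")

stats = fl.compute_channel_stats(train)
print("channel means:", np.round(stats.mean, 4).tolist())
print("channel stds: ", np.round(stats.std, 4).tolist())
z = fl.normalize(train, stats)
flat = z.images.reshape(-1, 3)
print("after normalize: per-channel mean ~", np.round(flat.mean(0), 10).tolist(),
      "std ~", np.round(flat.std(0), 10).tolist())

parts = fl.iid_partition(len(train), n_clients=3, seed=42)
print("client partition sizes:", [len(p) for p in parts],
      "(sizes differ by at most 1; disjoint cover of the training pool)")
print(fl.partition_table(parts).head(5).to_string(index=False))
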