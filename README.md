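# fedleaf

Federated-learning simulation for plant-leaf disease image classification.

Crop-disease classifiers are usually trained centrally, which requires
collecting growers' images in one place. Federated learning (FL) avoids
that: each participant ("client") trains on its own private leaf images and
shares only model parameters with a central server. `fedleaf` implements
this setting end to end as a reusable, fully deterministic library:

- **IID partitioning** — the training pool `D = Σₖ Pₖ` is dealt equally and
  at random to `C` clients (`P₁ ≈ … ≈ P_C`, sizes within one item).
- **Local training** — per communication round, each client runs `E_c`
  epochs of mini-batch SGD (batch `B_c`, learning rate `L_R`) on
  cross-entropy loss, starting from the broadcast global weights `W`.
- **FedAvg aggregation** — the server replaces `W` with the sample-size
  weighted average `W ← Σₖ (nₖ / n) Wₖ` of the returned client weights.
- **Per-round evaluation** — every client scores the new global model on
  its private test shard; confusion matrices are pooled and summarized with
  accuracy, macro precision, macro recall and macro F1
  (`Accuracy = (TP+TN)/(TP+FP+TN+FN)`, `Precision = TP/(TP+FP)`,
  `Recall = TP/(TP+FN)`, `F1 = 2PR/(P+R)` per class, one-vs-rest).
- **Sweeps** — config-driven experiments over the number of clients,
  rounds, local epochs, or datasets, with summary tables and
  accuracy-versus-round figures.

Because public leaf-image archives are external downloads, the package
ships a deterministic synthetic generator that renders PlantVillage-style
datasets (class-per-directory PNG layout, one healthy class, per-class
lesion motifs, adjustable noise), so every stage is testable offline.
Training runs on a small native-numpy CNN (`tiny_cnn`, two conv blocks +
global average pooling + linear head); the seven standard full-size
backbones (ResNet50, DenseNet121, VGG16, MobileNetV2, InceptionV3,
ViT-B/16, ViT-B/32) are registered as optional backends that require a
deep-learning framework.

## Worked example

A 3-client run on a synthetic 4-class leaf dataset (150 images per class,
32×32, noise 0.1), 10 rounds, 1 local epoch, batch 16, learning rate 0.01
(`examples/04_federated_run.py`):

```python
import fedleaf as fl

config = fl.ExperimentConfig(
    dataset=fl.SyntheticDatasetSpec(n_classes=4, images_per_class=150,
                                    image_size=(32, 32), noise_level=0.1, seed=1),
    model=fl.ModelSpec("tiny_cnn", n_classes=4, input_size=(32, 32)),
    n_clients=3, rounds=10, local_epochs=1, batch_size=16,
    learning_rate=0.01, test_fraction=0.2, base_seed=1,
)
result = fl.run_experiment(config)
```

prints

```
round  pooled_acc  pooled_f1  mean_acc
    1      0.9833     0.9833    0.9833
    2      1.0000     1.0000    1.0000
    ...
   10      1.0000     1.0000    1.0000

final round: accuracy 100.00%, F1 100.00% (120 pooled test images)
```

`pooled_acc`/`pooled_f1` are computed on the confusion matrix summed over
all clients' private test shards (the headline value); `mean_acc` averages
the per-client accuracies. The synthetic classes are color/lesion
separable, so the tiny CNN converges within a few rounds.

The other scripts in `examples/` walk through dataset generation and disk
round-trip, preprocessing + partitioning, a single client's local SGD, and
a client-count sweep. The same capabilities are available from the shell:

```sh
fedleaf generate --out data/grape --seed 7
fedleaf run   --config config.yaml --out results/run1
fedleaf sweep --config sweep.yaml  --out results/sweep
fedleaf report --results results/
```

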