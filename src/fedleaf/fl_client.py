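"""The client role: local training on a private partition, local evaluation.

A client receives the global weight vector, loads it into a freshly built
model, runs local SGD on its own data and returns only the updated weights,
its sample count and per-epoch losses — raw images never cross the
interface.  Evaluation accumulates argmax predictions on the client's
private test shard into a confusion matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .metrics import ConfusionMatrix
from .model_core import ModelSpec, WeightVector, build_model, check_layouts, local_train
from .synthetic_data import LabeledImageSet


@dataclass(frozen=True)
class ClientUpdateResult:
    """What a client sends back to the server after one round."""

    client_id: int
    weights: WeightVector
    n_samples: int
    epoch_losses: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError(f"n_samples must be >= 1, got {self.n_samples}")


def client_update(
    model_spec: ModelSpec,
    global_weights: WeightVector,
    partition_data: LabeledImageSet,
    epochs: int,
    batch_size: int,
    lr: float,
    seed: int,
    client_id: int = 0,
) -> ClientUpdateResult:
    """One round of local training starting from the global weights."""
    if len(partition_data) == 0:
        raise ValueError("client partition is empty")
    model = build_model(model_spec)
    check_layouts(model.get_weights(), global_weights)
    model.set_weights(global_weights)
    weights, losses = local_train(
        model, partition_data, epochs=epochs, batch_size=batch_size, lr=lr, seed=seed
    )
    return ClientUpdateResult(
        client_id=client_id,
        weights=weights,
        n_samples=len(partition_data),
        epoch_losses=tuple(losses),
    )


def client_evaluate(
    model_spec: ModelSpec,
    global_weights: WeightVector,
    test_data: LabeledImageSet,
) -> ConfusionMatrix:
    """Evaluate the global model on the client's private test shard."""
    if len(test_data) == 0:
        raise ValueError("client test shard is empty")
    k = model_spec.n_classes
    if test_data.labels.min() < 0 or test_data.labels.max() >= k:
        raise ValueError(f"test labels must lie in [0, {k})")
    model = build_model(model_spec)
    model.set_weights(global_weights)
    predicted = model.predict(test_data.images)
    return ConfusionMatrix.from_labels(
        test_data.labels,
        predicted,
        n_classes=k,
        class_names=(
            test_data.class_names if len(test_data.class_names) == k else None
        ),
    )
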