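"""The server role: FedAvg aggregation and the communication-round loop.

Each round: broadcast the global weights, run every client's local update,
aggregate the returned weight vectors by sample-size-weighted averaging
(FedAvg), then have every client evaluate the freshly aggregated global
model on its private test shard.  Both the mean of per-client metrics and
the metrics of the pooled (summed) confusion matrix are recorded; the
pooled values are the headline numbers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from ._seeds import (
    client_round_seed,
    model_init_seed,
    test_partition_seed,
    train_partition_seed,
)
from .config import ExperimentConfig
from .fl_client import ClientUpdateResult, client_evaluate, client_update
from .metrics import ConfusionMatrix, all_metrics
from .model_core import ModelSpec, WeightVector, build_model, check_layouts
from .partitioning import iid_partition
from .preprocessing import ChannelStats
from .synthetic_data import LabeledImageSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RoundRecord:
    """Evaluation of the global model after one communication round."""

    round_index: int
    per_client_metrics: tuple  # of (client_id, accuracy, precision, recall, f1)
    mean_metrics: dict
    pooled_metrics: dict
    pooled_confusion: ConfusionMatrix
    client_losses: tuple  # of (client_id, mean loss of last local epoch)


@dataclass
class ExperimentResult:
    """Everything one federated run produces."""

    config: ExperimentConfig
    rounds: list[RoundRecord]
    final_weights: WeightVector
    channel_stats: ChannelStats | None = None
    runtime_seconds: float | None = None

    @property
    def final_round(self) -> RoundRecord:
        return self.rounds[-1]

    def best_round(self, metric: str = "accuracy") -> RoundRecord:
        return max(self.rounds, key=lambda r: r.pooled_metrics[metric])


def fedavg(updates: list[ClientUpdateResult]) -> WeightVector:
    """Sample-size-weighted average of client weight vectors.

    Coordinate-wise ``sum_k (n_k / n) * w_k`` with ``n = sum_k n_k``; with
    equal partition sizes this is the arithmetic mean, and a single update
    is returned unchanged.
    """
    if not updates:
        raise ValueError("fedavg needs at least one client update")
    ref = updates[0].weights
    for u in updates[1:]:
        check_layouts(ref, u.weights)
    if len(updates) == 1:
        return WeightVector(ref.values.copy(), ref.layout)
    n_total = sum(u.n_samples for u in updates)
    acc = np.zeros_like(ref.values)
    for u in updates:
        acc += (u.n_samples / n_total) * u.weights.values
    return WeightVector(acc, ref.layout)


def run_federated_training(
    config: ExperimentConfig,
    train: LabeledImageSet,
    test: LabeledImageSet,
) -> ExperimentResult:
    """Run the full R-round federated loop on already-preprocessed data.

    The training pool is partitioned IID across ``config.n_clients``; the
    test set is sharded the same way so each client evaluates on its own
    private shard.  Per-round, per-client seeds derive from
    ``config.base_seed`` so the run is bit-reproducible.
    """
    config.validate()
    if len(train) < config.n_clients:
        raise ValueError(
            f"{len(train)} training items cannot cover {config.n_clients} clients"
        )
    spec: ModelSpec = replace(
        config.model,
        init_seed=model_init_seed(config.base_seed, config.model.init_seed),
    )
    global_model = build_model(spec)
    global_weights = global_model.get_weights()

    train_parts = iid_partition(
        len(train), config.n_clients, train_partition_seed(config.base_seed)
    )
    test_parts = iid_partition(
        len(test), config.n_clients, test_partition_seed(config.base_seed)
    )
    client_train = [train.subset(p.indices) for p in train_parts]
    client_test = [test.subset(p.indices) for p in test_parts]

    records: list[RoundRecord] = []
    for r in range(1, config.rounds + 1):
        updates = []
        for k in range(config.n_clients):
            try:
                updates.append(
                    client_update(
                        spec,
                        global_weights,
                        client_train[k],
                        epochs=config.local_epochs,
                        batch_size=config.batch_size,
                        lr=config.learning_rate,
                        seed=client_round_seed(config.base_seed, r, k),
                        client_id=k,
                    )
                )
            except Exception as exc:
                raise RuntimeError(
                    f"client {k} failed in round {r}: {exc}"
                ) from exc
        global_weights = fedavg(updates)

        per_client = []
        pooled_cm: ConfusionMatrix | None = None
        for k in range(config.n_clients):
            cm = client_evaluate(spec, global_weights, client_test[k])
            m = all_metrics(cm, config.averaging)
            per_client.append(
                (k, m["accuracy"], m["precision"], m["recall"], m["f1"])
            )
            pooled_cm = cm if pooled_cm is None else pooled_cm + cm
        assert pooled_cm is not None
        mean_metrics = {
            name: float(np.mean([pc[i + 1] for pc in per_client]))
            for i, name in enumerate(("accuracy", "precision", "recall", "f1"))
        }
        pooled_metrics = all_metrics(pooled_cm, config.averaging)
        record = RoundRecord(
            round_index=r,
            per_client_metrics=tuple(per_client),
            mean_metrics=mean_metrics,
            pooled_metrics=pooled_metrics,
            pooled_confusion=pooled_cm,
            client_losses=tuple(
                (u.client_id, u.epoch_losses[-1]) for u in updates
            ),
        )
        records.append(record)
        logger.info(
            "round %d/%d: pooled acc=%.4f f1=%.4f",
            r,
            config.rounds,
            pooled_metrics["accuracy"],
            pooled_metrics["f1"],
        )
    return ExperimentResult(
        config=config, rounds=records, final_weights=global_weights
    )
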