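"""A complete federated run: 3 clients, 10 communication rounds.

Every round the server broadcasts the global weights, each client trains
locally for one epoch, the server aggregates with sample-size-weighted
FedAvg, and every client evaluates the new global model on its private test
shard.  The printed pooled metrics come from the summed confusion matrix
over all clients.
"""

import fedleaf as fl

config = fl.ExperimentConfig(
    dataset=fl.SyntheticDatasetSpec(
        n_classes=4, images_per_class=150, image_size=(32, 32),
        noise_level=0.1, seed=1,
    ),
    model=fl.ModelSpec("tiny_cnn", n_classes=4, input_size=(32, 32)),
    n_clients=3, rounds=10, local_epochs=1, batch_size=16,
    learning_rate=0.01, test_fraction=0.2, base_seed=1,
)
result = fl.run_experiment(config)

print("round  pooled_acc  pooled_f1  mean_acc")
for rec in result.rounds:
    print(f"{rec.round_index:5d}  {rec.pooled_metrics['accuracy']:10.4f}"
          f"  {rec.pooled_metrics['f1']:9.4f}"
          f"  {rec.mean_metrics['accuracy']:8.4f}")
final = result.final_round.pooled_metrics
print(f"\nfinal round: accuracy {100 * final['accuracy']:.2f}%, "
      f"F1 {100 * final['f1']:.2f}% "
      f"({result.final_round.pooled_confusion.total} pooled test images)")
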