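"""Sweep the number of clients with total data fixed.

With the same pool spread over more clients, each client sees less data per
round, so accuracy at a given round count should not improve as clients are
added — the qualitative client-scaling effect.  Writes the summary CSV and
an accuracy-versus-rounds figure to ./sweep_out/.
"""

import fedleaf as fl

base = fl.ExperimentConfig(
    dataset=fl.SyntheticDatasetSpec(
        n_classes=4, images_per_class=100, image_size=(32, 32),
        noise_level=0.1, seed=5,
    ),
    model=fl.ModelSpec("tiny_cnn", n_classes=4, input_size=(32, 32)),
    n_clients=3, rounds=8, local_epochs=1, batch_size=16,
    learning_rate=0.01, base_seed=5,
)
sweep = fl.SweepSpec(base=base, axis="n_clients", values=(3, 5, 7))
results = fl.run_sweep(sweep, out_dir="sweep_out")
table = fl.summarize(results, axis="n_clients")
print(table.to_string(index=False))
fig = fl.plot_round_curves(results, "accuracy",
                           "sweep_out/accuracy_vs_rounds.png",
                           axis="n_clients")
print(f"\nfigure written to {fig}")
print("columns are percent (final and best pooled metrics per run)")
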