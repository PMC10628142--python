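"""Config-driven experiments and sweeps, with table and figure reporting.

``run_experiment`` takes one :class:`ExperimentConfig` end to end: build or
load the dataset, stratified train/test split, resize to the model's input
size, standardize with training-split channel stats, then run the federated
round loop.  ``run_sweep`` repeats that along one axis (number of clients,
rounds, local epochs, or dataset) holding everything else at the base
configuration, the four scenario axes typically studied.  ``summarize``
renders one row per run (final and best pooled accuracy/F1, percent, two
decimals) and ``plot_round_curves`` draws metric-versus-round curves.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import replace
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from ._seeds import derive_seed
from .config import ExperimentConfig, SweepSpec, SWEEP_AXES
from .fl_server import ExperimentResult, run_federated_training
from .preprocessing import ChannelStats, compute_channel_stats, normalize, resize_images
from .synthetic_data import (
    DATASET_PRESETS,
    LabeledImageSet,
    SyntheticDatasetSpec,
    make_dataset,
    read_dataset,
    stratified_split,
)

logger = logging.getLogger(__name__)

#: Canonical ImageNet channel statistics, used when ``stats_source='preset'``
#: (the convention when fine-tuning pretrained backbones).
PRESET_CHANNEL_STATS = ChannelStats(
    mean=np.array([0.485, 0.456, 0.406]),
    std=np.array([0.229, 0.224, 0.225]),
)

VALID_METRICS = ("accuracy", "precision", "recall", "f1")


def _resolve_dataset(config: ExperimentConfig) -> LabeledImageSet:
    ds = config.dataset
    if isinstance(ds, SyntheticDatasetSpec):
        return make_dataset(ds)
    if isinstance(ds, str):
        if ds in DATASET_PRESETS:
            spec = SyntheticDatasetSpec(
                name=ds,
                n_classes=len(DATASET_PRESETS[ds]),
                seed=derive_seed(config.base_seed, "dataset", ds),
            )
            return make_dataset(spec)
        path = Path(ds)
        if path.exists():
            return read_dataset(path)
        raise ValueError(
            f"dataset {ds!r} is neither a preset ({', '.join(DATASET_PRESETS)}) "
            "nor an existing directory"
        )
    raise TypeError(f"dataset must be a name, path or spec, got {type(ds)!r}")


def prepare_data(
    config: ExperimentConfig,
) -> tuple[LabeledImageSet, LabeledImageSet, ChannelStats]:
    """Dataset -> split -> resize -> standardize, returning (train, test, stats).

    Channel stats come from the training split only (or the ImageNet preset)
    and are applied unchanged to the test split.
    """
    data = _resolve_dataset(config)
    train, test = stratified_split(
        data, config.test_fraction, derive_seed(config.base_seed, "split")
    )
    target = config.model.input_size
    train = resize_images(train, target)
    test = resize_images(test, target)
    if config.stats_source == "preset":
        stats = PRESET_CHANNEL_STATS
    else:
        stats = compute_channel_stats(train)
    return normalize(train, stats), normalize(test, stats), stats


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """One complete federated run from a configuration."""
    config.validate()
    t0 = time.perf_counter()
    train, test, stats = prepare_data(config)
    result = run_federated_training(config, train, test)
    result.channel_stats = stats
    result.runtime_seconds = time.perf_counter() - t0
    return result


def run_sweep(sweep: SweepSpec, out_dir=None) -> list[ExperimentResult | None]:
    """One complete run per axis value; failures are recorded, not fatal.

    Each run's base seed is derived from the sweep's base seed and the axis
    value, so runs are decorrelated but individually reproducible.  When
    ``out_dir`` is given, each run is persisted as it completes.
    """
    sweep.validate()
    results: list[ExperimentResult | None] = []
    for value in sweep.values:
        config = sweep.base.with_value(sweep.axis, value)
        config = replace(
            config,
            base_seed=derive_seed(sweep.base.base_seed, "sweep", sweep.axis, str(value)),
        )
        try:
            result = run_experiment(config)
        except Exception:
            logger.exception("sweep run %s=%r failed", sweep.axis, value)
            results.append(None)
            continue
        results.append(result)
        if out_dir is not None:
            save_result(result, Path(out_dir) / f"{sweep.axis}_{value}")
    return results


def _axis_value(result: ExperimentResult, axis: str):
    v = getattr(result.config, axis)
    if axis == "dataset" and isinstance(v, SyntheticDatasetSpec):
        return v.name
    return v


def rounds_to_dataframe(result: ExperimentResult) -> pd.DataFrame:
    """Per-round metrics, one row per client plus POOLED and MEAN rows."""
    rows = []
    for rec in result.rounds:
        for cid, acc, prec, rec_, f1 in rec.per_client_metrics:
            rows.append((rec.round_index, str(cid), acc, prec, rec_, f1))
        mm, pm = rec.mean_metrics, rec.pooled_metrics
        rows.append(
            (rec.round_index, "MEAN", mm["accuracy"], mm["precision"],
             mm["recall"], mm["f1"])
        )
        rows.append(
            (rec.round_index, "POOLED", pm["accuracy"], pm["precision"],
             pm["recall"], pm["f1"])
        )
    return pd.DataFrame(
        rows,
        columns=["round", "client_id", "accuracy", "precision", "recall", "f1"],
    )


def summarize(
    results: list[ExperimentResult | None], axis: str | None = None
) -> pd.DataFrame:
    """One row per run: final-round and best-round pooled metrics.

    Accuracy and F1 are reported in percent with two decimals, mirroring the
    usual presentation of federated sweep tables.  Rows sort ascending by
    axis value when an axis is given.
    """
    kept = [r for r in results if r is not None]
    if not kept:
        raise ValueError("no successful results to summarize")
    if axis is not None and axis not in SWEEP_AXES:
        raise ValueError(f"axis must be one of {SWEEP_AXES}, got {axis!r}")
    rows = []
    for r in kept:
        final = r.final_round.pooled_metrics
        best = r.best_round("f1").pooled_metrics
        rows.append(
            {
                "axis_value": _axis_value(r, axis) if axis else "",
                "final_accuracy_pct": round(100 * final["accuracy"], 2),
                "final_f1_pct": round(100 * final["f1"], 2),
                "best_accuracy_pct": round(100 * best["accuracy"], 2),
                "best_f1_pct": round(100 * best["f1"], 2),
                "rounds": len(r.rounds),
                "runtime_s": (
                    round(r.runtime_seconds, 2) if r.runtime_seconds else None
                ),
            }
        )
    df = pd.DataFrame(rows)
    if axis is not None:
        try:
            df = df.sort_values("axis_value", ignore_index=True)
        except TypeError:
            pass
    return df


def plot_round_curves(
    results: list[ExperimentResult | None],
    metric: str,
    out_path,
    axis: str | None = None,
) -> Path:
    """Pooled ``metric`` versus communication round, one line per run."""
    if metric not in VALID_METRICS:
        raise ValueError(
            f"unknown metric {metric!r}; valid options: {', '.join(VALID_METRICS)}"
        )
    kept = [r for r in results if r is not None]
    if not kept:
        raise ValueError("no successful results to plot")
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for r in kept:
        xs = [rec.round_index for rec in r.rounds]
        ys = [rec.pooled_metrics[metric] for rec in r.rounds]
        label = f"{axis}={_axis_value(r, axis)}" if axis else None
        ax.plot(xs, ys, marker="o", markersize=3, label=label)
    ax.set_xlabel("communication round")
    ax.set_ylabel(f"pooled {metric}")
    ax.set_ylim(0.0, 1.02)
    if axis:
        ax.legend()
    ax.grid(True, alpha=0.3)
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out_path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return out_path


def save_result(result: ExperimentResult, out_dir) -> Path:
    """Persist one run: config snapshot, channel stats, per-round CSV, summary."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    result.config.to_yaml(out_dir / "config.yaml")
    if result.channel_stats is not None:
        with open(out_dir / "channel_stats.json", "w") as fh:
            json.dump(result.channel_stats.to_dict(), fh, indent=2)
    rounds_to_dataframe(result).to_csv(out_dir / "rounds.csv", index=False)
    summarize([result]).to_csv(out_dir / "summary.csv", index=False)
    return out_dir
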