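"""Desk-scale experiment harnesses built on the pipeline primitives.

These functions run the full chain — generate, filter, cross-validated
training, key selection, key-position-only evaluation — on synthetic pools
and report recovery and classification summaries.  They back both the
analysis drivers and the reproducibility script.
"""

from __future__ import annotations

from dataclasses import asdict

import numpy as np
import pandas as pd

from .classifier import ConfusionCounts, classify, confusion, metrics, score_sequence
from .diad_profile import DiadPartition, get_partition
from .key_positions import select_key_positions
from .oligo_io import filter_by_affinity
from .position_weights import TrainingConfig, cv_position_weights, make_folds
from .synthetic import SyntheticSpec, generate_pool

__all__ = ["key_recovery_trial", "recovery_study"]


def key_recovery_trial(
    seed: int,
    effect_size: float = 0.30,
    n_sequences: int = 2000,
    partition: str | DiadPartition = "4-4",
    n_keys: int = 10,
    K: int = 10,
) -> dict:
    """One seeded end-to-end run on a synthetic pool.

    Returns the number of planted positions recovered among the top
    ``n_keys`` selected positions, the key-position-only classification
    metrics (from the mean of the K held-out confusion counts), and the
    majority-class baseline accuracy of the filtered pool.
    """
    part = get_partition(partition) if isinstance(partition, str) else partition
    spec = SyntheticSpec(
        n_sequences=n_sequences, effect_size=effect_size, seed=seed
    )
    pool, classes, planted = generate_pool(spec, part)
    labeled = filter_by_affinity(pool)
    folds = make_folds(labeled, K, seed=seed + 10_000)
    config = TrainingConfig(seed=seed + 20_000)
    mean_w, _ = cv_position_weights(labeled, part, folds, config)
    keys = select_key_positions(mean_w, n_keys)
    recovered = len(set(keys.positions) & set(planted))

    rows = []
    for k in range(1, folds.K + 1):
        _, te = folds.indices(k)
        preds = [
            classify(score_sequence(labeled.pool.records[i], mean_w, keys, part))
            for i in te
        ]
        c = confusion(preds, labeled.labels[te])
        rows.append((c.TP, c.FP, c.TN, c.FN))
    mean_counts = ConfusionCounts(*np.mean(rows, axis=0))
    report = metrics(mean_counts)

    n_pos = int((labeled.labels == 1).sum())
    baseline_acc = 100.0 * max(n_pos, len(labeled) - n_pos) / len(labeled)
    return {
        "seed": seed,
        "n_filtered": len(labeled),
        "recovered": recovered,
        "n_keys": n_keys,
        "planted": planted,
        "key_positions": keys.positions,
        "mean_counts": mean_counts,
        "metrics": report,
        "baseline_acc": baseline_acc,
    }


def recovery_study(
    seeds: range,
    effect_size: float = 0.30,
    n_sequences: int = 2000,
    partition: str = "4-4",
    n_keys: int = 10,
) -> pd.DataFrame:
    """key_recovery_trial over many seeds, one row per seed."""
    rows = []
    for seed in seeds:
        trial = key_recovery_trial(
            seed, effect_size=effect_size, n_sequences=n_sequences,
            partition=partition, n_keys=n_keys,
        )
        rows.append(
            {
                "seed": seed,
                "recovered": trial["recovered"],
                "acc": trial["metrics"].acc,
                "sen": trial["metrics"].sen,
                "ppv": trial["metrics"].ppv,
                "mcc": trial["metrics"].mcc,
                "baseline_acc": round(trial["baseline_acc"], 1),
            }
        )
    return pd.DataFrame(rows)
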