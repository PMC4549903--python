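"""End-to-end orchestration: generate/read -> filter -> profile -> train ->
select keys -> classify -> metrics, with a reproducible run directory.

All randomness flows from the single config seed: fold assignment, training
initialisation and synthetic generation each receive a child seed spawned
deterministically from it.  A completed run directory is self-describing —
config, manifest (with content hashes) and output tables suffice to re-run
bit-identically.  Log lines go to ``run.log``, which is excluded from the
manifest hashes because it carries timestamps.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from . import classifier, diad_profile, key_positions, position_weights, synthetic
from .classifier import ConfusionCounts, MetricReport
from .diad_profile import DiadPartition, get_partition, standard_partitions
from .oligo_io import LabeledPool, filter_by_affinity, read_pool, write_labeled_pool
from .position_weights import TrainingConfig
from .synthetic import SyntheticSpec, generate_pool

__all__ = ["RunConfig", "run_experiment", "run_all_partitions", "metrics_only"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""


@dataclass
class RunConfig:
    """One experiment: one partition, one pool source, one seed.

    Exactly one of (``fasta`` + ``affinity``) or ``synthetic`` must be set.
    ``partition`` is a standard name (4-4, 4-3, 5-4) or a custom
    DiadPartition.  ``n_keys`` is the number of key positions (10 or 20 in
    the reference experiments).
    """

    out_dir: Union[str, Path]
    partition: Union[str, DiadPartition] = "4-4"
    fasta: Optional[Union[str, Path]] = None
    affinity: Optional[Union[str, Path]] = None
    synthetic: Optional[SyntheticSpec] = None
    upper: float = 1.0
    lower: float = 0.0
    K: int = 10
    n_keys: int = 10
    threshold: float = 0.0
    seed: int = 0
    learning_rate: float = 0.5
    epochs: int = 400

    def __post_init__(self) -> None:
        has_files = self.fasta is not None and self.affinity is not None
        if has_files == (self.synthetic is not None):
            raise ValueError(
                "exactly one of (fasta+affinity) or synthetic must be given"
            )

    def resolve_partition(self) -> DiadPartition:
        if isinstance(self.partition, DiadPartition):
            return self.partition
        return get_partition(self.partition)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "synthetic" in raw and raw["synthetic"] is not None:
            syn = raw["synthetic"]
            if "planted_positions" in syn:
                syn["planted_positions"] = tuple(syn["planted_positions"])
            raw["synthetic"] = SyntheticSpec(**syn)
        if isinstance(raw.get("partition"), dict):
            p = raw["partition"]
            raw["partition"] = DiadPartition(
                p.get("name", "custom"),
                frozenset(p["positive"]),
                frozenset(p["negative"]),
            )
        return cls(**raw)

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["out_dir"] = str(d["out_dir"])
        for k in ("fasta", "affinity"):
            if d[k] is not None:
                d[k] = str(d[k])
        part = self.resolve_partition()
        d["partition"] = {
            "name": part.name,
            "positive": sorted(part.positive),
            "negative": sorted(part.negative),
        }
        return d


def _child_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-stage seeds below 2**31 derived from one root seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_experiment(config: RunConfig) -> Path:
    """Execute one full experiment; returns the run directory.

    Writes: filtered pool table, per-subset diad frequency profiles, the
    mean position-weight vector, the key-position set (TSV + BED), per-fold
    confusion counts, the metric report, and ``manifest.json`` recording the
    config, seed and content hashes of all outputs.  On stage failure, a
    ``INCOMPLETE`` marker naming the failed stage is left in the directory.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    log_lines: list[str] = []
    t0 = time.time()

    def log(stage: str, msg: str) -> None:
        log_lines.append(f"[{time.time() - t0:8.2f}s] {stage}: {msg}")

    gen_seed, fold_seed, train_seed = _child_seeds(config.seed, 3)
    partition = config.resolve_partition()
    stage = "setup"
    try:
        # --- acquire pool -------------------------------------------------
        stage = "input"
        input_hashes = {}
        if config.synthetic is not None:
            spec = config.synthetic
            if spec.seed != gen_seed:
                spec = SyntheticSpec(**{**asdict(spec), "seed": gen_seed})
            pool, true_labels, planted = generate_pool(spec, partition)
            log(stage, f"generated {len(pool)} synthetic oligos, L={pool.length}")
        else:
            pool = read_pool(config.fasta, config.affinity)
            planted = ()
            input_hashes = {
                "fasta": _sha256(Path(config.fasta)),
                "affinity": _sha256(Path(config.affinity)),
            }
            log(stage, f"read {len(pool)} oligos, L={pool.length}")

        # --- filter -------------------------------------------------------
        stage = "filter"
        labeled = filter_by_affinity(pool, config.upper, config.lower)
        n_pos = int(np.sum(labeled.labels == 1))
        n_neg = int(np.sum(labeled.labels == -1))
        log(stage, f"in={len(pool)} kept={len(labeled)} (pos={n_pos}, neg={n_neg})")
        write_labeled_pool(labeled, out / "filtered_pool.tsv")

        # --- profiles -----------------------------------------------------
        stage = "profile"
        profiles = []
        for subset in ("all", "positive", "negative"):
            prof = diad_profile.position_frequency(labeled, subset)
            profiles.append(prof.to_long())
            log(stage, f"subset={subset} n={prof.n_sequences}")
        pd.concat(profiles).to_csv(out / "diad_profiles.tsv", sep="\t", index=False)

        # --- cross-validated training --------------------------------------
        stage = "train"
        folds = position_weights.make_folds(labeled, config.K, fold_seed)
        tc = TrainingConfig(
            learning_rate=config.learning_rate,
            epochs=config.epochs,
            seed=train_seed,
        )
        mean_w, fold_counts = position_weights.cv_position_weights(
            labeled, partition, folds, tc, config.threshold
        )
        mean_w.write_tsv(out / "position_weights.tsv")
        fold_counts.to_csv(out / "fold_confusion.tsv", sep="\t", index=False)
        log(stage, f"K={config.K} folds trained, {len(mean_w.weights)} positions")

        # --- key positions --------------------------------------------------
        stage = "keys"
        keys = key_positions.select_key_positions(mean_w, config.n_keys)
        keys.write_tsv(out / "key_positions.tsv")
        keys.write_bed(out / "key_positions.bed")
        log(stage, f"selected top-{config.n_keys}: {keys.positions}")

        # --- key-position-only evaluation ----------------------------------
        stage = "classify"
        rows = []
        for k in range(1, folds.K + 1):
            _, te = folds.indices(k)
            preds = [
                classifier.classify(
                    classifier.score_sequence(
                        labeled.pool.records[i], mean_w, keys, partition
                    ),
                    config.threshold,
                )
                for i in te
            ]
            c = classifier.confusion(preds, labeled.labels[te])
            rows.append({"fold": k, "TP": c.TP, "FP": c.FP, "TN": c.TN, "FN": c.FN})
        key_fold = pd.DataFrame(rows)
        key_fold.to_csv(out / "keypos_fold_confusion.tsv", sep="\t", index=False)
        mean_counts = ConfusionCounts(
            *(float(key_fold[c].mean()) for c in ("TP", "FP", "TN", "FN"))
        )
        report = classifier.metrics(mean_counts)
        summary = pd.DataFrame(
            [
                {
                    "partition": partition.name,
                    "key_positions": ",".join(map(str, keys.positions)),
                    "TP": round(mean_counts.TP, 1),
                    "FP": round(mean_counts.FP, 1),
                    "TN": round(mean_counts.TN, 1),
                    "FN": round(mean_counts.FN, 1),
                    **report.as_dict(),
                }
            ]
        )
        summary.to_csv(out / "metrics.tsv", sep="\t", index=False)
        log(
            stage,
            f"mean counts TP={mean_counts.TP:.1f} FP={mean_counts.FP:.1f} "
            f"TN={mean_counts.TN:.1f} FN={mean_counts.FN:.1f} -> "
            f"Acc={report.acc} Sen={report.sen} PPV={report.ppv} MCC={report.mcc}",
        )

        # --- manifest -------------------------------------------------------
        stage = "manifest"
        outputs = sorted(
            p.name
            for p in out.iterdir()
            if p.is_file() and p.name not in ("run.log", "manifest.json", "INCOMPLETE")
        )
        manifest = {
            "config": config.to_jsonable(),
            "seed": config.seed,
            "stage_seeds": {
                "generate": gen_seed,
                "folds": fold_seed,
                "train": train_seed,
            },
            "planted_positions": list(planted),
            "input_hashes": input_hashes,
            "output_hashes": {name: _sha256(out / name) for name in outputs},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        marker = out / "INCOMPLETE"
        if marker.exists():
            marker.unlink()
    except Exception as exc:
        (out / "INCOMPLETE").write_text(f"failed at stage {stage}: {exc}\n")
        log_path.write_text("\n".join(log_lines) + "\n")
        raise StageError(f"stage {stage!r} failed: {exc}") from exc

    log_path.write_text("\n".join(log_lines) + "\n")
    return out


def run_all_partitions(base_config: RunConfig) -> pd.DataFrame:
    """Run the three standard experiments (4-4, 4-3, 5-4) and compare keys.

    Each partition runs in a subdirectory of the base output directory; a
    ``key_position_comparison.tsv`` with pairwise overlaps is written at the
    top level.  Returns the concatenated metric summaries.
    """
    base = Path(base_config.out_dir)
    summaries = []
    key_sets = []
    for part in standard_partitions():
        cfg_kwargs = {**asdict(base_config)}
        if cfg_kwargs.get("synthetic") is not None:
            cfg_kwargs["synthetic"] = base_config.synthetic
        cfg_kwargs["partition"] = part
        cfg_kwargs["out_dir"] = base / part.name.replace("-", "_")
        run_dir = run_experiment(RunConfig(**cfg_kwargs))
        summaries.append(pd.read_csv(run_dir / "metrics.tsv", sep="\t"))
        kp = pd.read_csv(run_dir / "key_positions.tsv", sep="\t")
        key_sets.append(
            key_positions.KeyPositionSet(
                tuple(int(p) for p in kp["position"]), len(kp), part.name
            )
        )
    comparison = key_positions.compare_key_sets(key_sets, tolerance=1)
    base.mkdir(parents=True, exist_ok=True)
    comparison.to_csv(base / "key_position_comparison.tsv", sep="\t", index=False)
    combined = pd.concat(summaries, ignore_index=True)
    combined.to_csv(base / "metrics_all.tsv", sep="\t", index=False)
    return combined


def metrics_only(counts: ConfusionCounts) -> MetricReport:
    """Metric report straight from confusion counts (shared implementation)."""
    return classifier.metrics(counts)
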