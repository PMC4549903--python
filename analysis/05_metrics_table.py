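"""Assemble the final metrics table.

Combines (a) the Acc/Sen/PPV/MCC rows recomputed from the published
per-fold mean confusion counts of the three reference experiments and
(b) the synthetic-pool rows produced by 03_learn_position_weights.py.
Writes results/metrics_table.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from nucleokey import ConfusionCounts, metrics

ROOT = Path(__file__).resolve().parents[1]

REFERENCE_COUNTS = {
    "4-4": (786.3, 367.5, 1763.1, 105.6),
    "4-3": (852.6, 301.2, 1678.2, 190.5),
    "5-4": (859.8, 294.0, 1673.7, 195.0),
}


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--experiments", type=Path, default=ROOT / "results" / "experiments")
    parser.add_argument("--out", type=Path, default=ROOT / "results" / "metrics_table.tsv")
    args = parser.parse_args()

    rows = []
    for name, counts in REFERENCE_COUNTS.items():
        rep = metrics(ConfusionCounts(*counts))
        rows.append({"source": "reference", "partition": name, **rep.as_dict()})

    synth = args.experiments / "metrics_all.tsv"
    if synth.exists():
        df = pd.read_csv(synth, sep="\t")
        for _, r in df.iterrows():
            rows.append(
                {
                    "source": "synthetic",
                    "partition": r["partition"],
                    "acc": r["acc"],
                    "sen": r["sen"],
                    "ppv": r["ppv"],
                    "mcc": r["mcc"],
                }
            )
    else:
        print(f"note: {synth} not found; run 03_learn_position_weights.py first")

    table = pd.DataFrame(rows)
    table.to_csv(args.out, sep="\t", index=False)
    print(table.to_string(index=False))
    print(f"\nwrote {args.out}")


if __name__ == "__main__":
    main()
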