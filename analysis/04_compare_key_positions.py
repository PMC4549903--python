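"""Compare the selected key positions across experiments and against truth.

Reads the key-position sets written by 03_learn_position_weights.py and the
planted positions recorded in the pool fixture, reports pairwise overlap
between the three experiments (tolerance +-1), and counts how many planted
positions each experiment recovered.
"""

import argparse
from pathlib import Path

import pandas as pd

from nucleokey import KeyPositionSet, compare_key_sets

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--experiments", type=Path, default=ROOT / "results" / "experiments")
    parser.add_argument("--pool", type=Path, default=ROOT / "results" / "pool")
    args = parser.parse_args()

    truth_header = (args.pool / "truth.tsv").read_text().splitlines()[0]
    planted = set(
        int(p) for p in truth_header.split("=", 1)[1].split(",") if p
    )

    sets = []
    for sub in ("4_4", "4_3", "5_4"):
        df = pd.read_csv(args.experiments / sub / "key_positions.tsv", sep="\t")
        name = sub.replace("_", "-")
        ks = KeyPositionSet(tuple(int(p) for p in df["position"]), len(df), name)
        sets.append(ks)
        hit = len(set(ks.positions) & planted)
        print(f"{name}: keys {','.join(map(str, ks.positions))}  "
              f"({hit}/{len(planted)} planted recovered)")

    print("\npairwise overlap (tolerance 1):")
    print(compare_key_sets(sets, tolerance=1).to_string(index=False))


if __name__ == "__main__":
    main()
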