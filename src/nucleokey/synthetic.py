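"""Synthetic oligo pools with planted position-specific diad biases.

The generator emulates the statistical structure of a competitive
nucleosome-reconstitution experiment: a pool of fixed-length oligos, each
with a real-valued affinity (log-ratio, class-conditionally Gaussian), in
which nucleosome-favouring (G/C-rich) diads are enriched at a chosen set of
"key" positions in positive-affinity sequences and disfavouring (A/T-rich)
diads at the same positions in negative-affinity sequences.

Generation per record: draw the class from the class balance; draw the
affinity from that class's Gaussian; draw all bases independently from the
background composition; then at each planted position (ascending order),
with probability ``effect_size`` overwrite the diad there with one drawn
uniformly from the class-consistent diad set.  Planted positions closer
than 2 apart are legal and resolved left-to-right: a later overwrite may
clobber the second base of an earlier one.  Everything is deterministic
given the seed.

Affinity is modelled as a class-conditional Gaussian rather than derived
mechanistically from the sequence: the analysis treats affinity as a
measured label, and this is the simplest model that makes the >1 / <0
filter and the affinity-weighted diad score meaningful.  Generation is
single-strand; no reverse-complement augmentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .diad_profile import BASES, DIADS, DiadPartition
from .oligo_io import OligoPool, OligoRecord

__all__ = ["SyntheticSpec", "generate_pool", "write_fixture"]

#: default planted key positions: ten diad starts spread over the 150 bp frame
DEFAULT_PLANTED: tuple[int, ...] = (10, 25, 40, 55, 70, 85, 100, 115, 130, 145)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic pool.

    Defaults give the desk-scale recovery setting: 2000 oligos of 150 bp,
    ten planted positions with effect size 0.30, positive fraction 0.69
    (matching an affinity-filtered reconstitution pool), and affinity
    Gaussians N(1.5, 0.5) / N(-0.75, 0.5) so the strict >1 / <0 filter
    keeps most records.
    """

    n_sequences: int = 2000
    L: int = 150
    planted_positions: tuple[int, ...] = DEFAULT_PLANTED
    effect_size: float = 0.30
    class_balance: float = 0.69
    mean_pos: float = 1.5
    mean_neg: float = -0.75
    sd: float = 0.5
    base_frequencies: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sequences < 1 or self.L < 2:
            raise ValueError("need n_sequences >= 1 and L >= 2")
        pp = tuple(sorted(int(p) for p in self.planted_positions))
        object.__setattr__(self, "planted_positions", pp)
        if pp and not (1 <= pp[0] and pp[-1] <= self.L - 1):
            raise ValueError(f"planted positions must lie in 1..{self.L - 1}")
        if not 0.0 <= self.effect_size <= 1.0:
            raise ValueError("effect_size must be in [0, 1]")
        if not 0.0 < self.class_balance < 1.0:
            raise ValueError("class_balance must be in (0, 1)")
        if self.sd <= 0:
            raise ValueError("sd must be positive")
        bf = np.asarray(self.base_frequencies, dtype=float)
        if bf.shape != (4,) or not np.isclose(bf.sum(), 1.0) or (bf < 0).any():
            raise ValueError("base_frequencies must be 4 non-negative values summing to 1")


def generate_pool(
    spec: SyntheticSpec, partition: DiadPartition
) -> tuple[OligoPool, np.ndarray, tuple[int, ...]]:
    """Generate a pool with planted class-consistent diads.

    Returns (pool, true class labels as +1/-1, planted positions).  The
    labels are the generating classes; the drawn affinities agree with them
    in sign except in the Gaussian tails.
    """
    rng = np.random.default_rng(spec.seed)
    n, L = spec.n_sequences, spec.L

    classes = np.where(rng.random(n) < spec.class_balance, 1, -1).astype(np.int8)
    means = np.where(classes == 1, spec.mean_pos, spec.mean_neg)
    affinities = rng.normal(means, spec.sd)

    codes = rng.choice(4, size=(n, L), p=np.asarray(spec.base_frequencies))

    pos_diads = sorted(partition.positive)
    neg_diads = sorted(partition.negative)
    diad_code = {d: (BASES.index(d[0]), BASES.index(d[1])) for d in DIADS}
    for p in spec.planted_positions:  # ascending: overlaps resolve left-to-right
        hit = rng.random(n) < spec.effect_size
        # draw a diad index per record even where unused, to keep the stream
        # layout independent of the hit pattern of earlier positions
        pos_pick = rng.integers(len(pos_diads), size=n)
        neg_pick = rng.integers(len(neg_diads), size=n)
        for i in np.flatnonzero(hit):
            d = (
                pos_diads[pos_pick[i]]
                if classes[i] == 1
                else neg_diads[neg_pick[i]]
            )
            c0, c1 = diad_code[d]
            codes[i, p - 1] = c0
            codes[i, p] = c1

    base_arr = np.frombuffer(BASES.encode(), dtype=np.uint8)
    seq_bytes = base_arr[codes]
    records = [
        OligoRecord(f"syn{i:05d}", seq_bytes[i].tobytes().decode(), float(affinities[i]))
        for i in range(n)
    ]
    return OligoPool(records, L), classes, spec.planted_positions


def write_fixture(
    pool: OligoPool,
    labels: np.ndarray,
    planted: tuple[int, ...],
    directory: Union[str, Path],
) -> dict[str, Path]:
    """Write FASTA + affinity TSV + ground-truth TSV; returns the paths.

    The truth file carries the planted positions in a header comment and one
    (id, class) row per record; byte-identical across runs with equal seed.
    """
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
        fasta = directory / "pool.fasta"
        aff = directory / "affinity.tsv"
        truth = directory / "truth.tsv"
        with open(fasta, "w") as fh:
            for rec in pool:
                fh.write(f">{rec.id}\n{rec.sequence}\n")
        with open(aff, "w") as fh:
            fh.write("id\taffinity\n")
            for rec in pool:
                fh.write(f"{rec.id}\t{rec.affinity:.10g}\n")
        with open(truth, "w") as fh:
            fh.write(f"# planted_positions={','.join(map(str, planted))}\n")
            fh.write("id\tclass\n")
            for rec, lab in zip(pool, labels):
                fh.write(f"{rec.id}\t{'pos' if lab == 1 else 'neg'}\n")
    except OSError as exc:
        raise OSError(f"cannot write fixture under {directory}: {exc}") from exc
    return {"fasta": fasta, "affinity": aff, "truth": truth}
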