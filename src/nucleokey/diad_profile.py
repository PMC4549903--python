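"""Diad (dinucleotide) partitions, position-wise frequency profiles, and the
affinity-weighted diad score.

A "diad" is a 2-mer over {A,C,G,T}; a diad at position p (1-based) starts at
base p, so a length-L oligo has L-1 diad positions.  Overlapping occurrences
count: "CCC" contains CC at positions 1 and 2.

An experiment is defined by a *diad partition*: a nucleosome-favouring
("positive", G/C-rich) diad set versus a disfavouring ("negative", A/T-rich)
set.  The three standard experiments are

* 4-4:  {CC,CG,GC,GG} vs {AA,AT,TA,TT}
* 4-3:  {CC,CG,GC,GG} vs {AA,AT,TT}   (TA dropped: no class contrast)
* 5-4:  {AC,CC,CG,GC,GG} vs {AA,AT,TA,TT}  (AC added: shows class contrast)

The per-sequence score is w = af*(n1-n2) for affinity af >= 0 and
w = af*(n2-n1) for af < 0, where n1/n2 count positive/negative diads in the
sequence; both branches collapse to |af|*(n1-n2).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Union

import numpy as np
import pandas as pd

from .oligo_io import LabeledPool, OligoPool

__all__ = [
    "DIADS",
    "DiadPartition",
    "DiadFrequencyProfile",
    "DiadScore",
    "standard_partitions",
    "position_frequency",
    "count_diads",
    "eq1_weight",
    "sequences_to_codes",
    "diad_codes",
]

BASES = "ACGT"
#: the 16 diads in lexicographic order (AA, AC, ..., TT)
DIADS: tuple[str, ...] = tuple(a + b for a in BASES for b in BASES)
_BASE_CODE = {b: i for i, b in enumerate(BASES)}
_DIAD_INDEX = {d: i for i, d in enumerate(DIADS)}


@dataclass(frozen=True)
class DiadPartition:
    """Disjoint positive/negative diad sets defining one experiment."""

    name: str
    positive: frozenset[str]
    negative: frozenset[str]

    def __post_init__(self) -> None:
        pos, neg = frozenset(self.positive), frozenset(self.negative)
        object.__setattr__(self, "positive", pos)
        object.__setattr__(self, "negative", neg)
        if not pos or not neg:
            raise ValueError("both diad sets must be non-empty")
        if pos & neg:
            raise ValueError(f"overlapping diad sets: {sorted(pos & neg)}")
        bad = (pos | neg) - set(DIADS)
        if bad:
            raise ValueError(f"not diads: {sorted(bad)}")

    def class_table(self) -> np.ndarray:
        """Length-16 int8 lookup: +1 for positive diads, -1 negative, 0 else."""
        table = np.zeros(16, dtype=np.int8)
        for d in self.positive:
            table[_DIAD_INDEX[d]] = 1
        for d in self.negative:
            table[_DIAD_INDEX[d]] = -1
        return table


def standard_partitions() -> tuple[DiadPartition, DiadPartition, DiadPartition]:
    """The 4-4, 4-3 and 5-4 experiment partitions, in that order."""
    gc = frozenset({"CC", "CG", "GC", "GG"})
    at = frozenset({"AA", "AT", "TA", "TT"})
    return (
        DiadPartition("4-4", gc, at),
        DiadPartition("4-3", gc, at - {"TA"}),
        DiadPartition("5-4", gc | {"AC"}, at),
    )


def get_partition(name: str) -> DiadPartition:
    for p in standard_partitions():
        if p.name == name:
            return p
    raise KeyError(f"no standard partition named {name!r} (use 4-4, 4-3 or 5-4)")


def sequences_to_codes(sequences: Iterable[str]) -> np.ndarray:
    """Encode equal-length ACGT strings as an (n, L) uint8 matrix (A=0..T=3)."""
    seqs = list(sequences)
    arr = np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(
        len(seqs), -1
    )
    codes = np.full(256, 255, dtype=np.uint8)
    for b, i in _BASE_CODE.items():
        codes[ord(b)] = i
    out = codes[arr]
    if (out == 255).any():
        raise ValueError("non-ACGT character in sequence")
    return out


def diad_codes(codes: np.ndarray) -> np.ndarray:
    """(n, L) base codes -> (n, L-1) diad codes in 0..15 (row-major AA..TT)."""
    return (codes[:, :-1] * 4 + codes[:, 1:]).astype(np.uint8)


@dataclass
class DiadFrequencyProfile:
    """16 x (L-1) matrix of per-position diad proportions over a pool subset.

    ``frequencies`` is a DataFrame indexed by diad with 1-based position
    columns; each column sums to 1.
    """

    frequencies: pd.DataFrame
    n_sequences: int
    subset_tag: str

    def to_long(self) -> pd.DataFrame:
        long = (
            self.frequencies.rename_axis("diad")
            .reset_index()
            .melt(id_vars="diad", var_name="position", value_name="frequency")
        )
        long["subset"] = self.subset_tag
        return long[["diad", "position", "subset", "frequency"]]

    def write_tsv(self, path: Union[str, Path]) -> None:
        self.to_long().to_csv(path, sep="\t", index=False)


def position_frequency(
    pool: Union[OligoPool, LabeledPool], subset: str = "all"
) -> DiadFrequencyProfile:
    """Per-position diad proportions over the requested subset of a pool.

    frequencies[d, p] is the fraction of subset sequences whose diad starting
    at position p equals d; every position's 16 proportions sum to 1.
    Profiles are computed on the given strand only.
    """
    if isinstance(pool, LabeledPool):
        sub = pool.subset(subset)
        seqs = sub.pool.sequences
        length = sub.pool.length
    else:
        if subset != "all":
            raise ValueError("class subsets require a LabeledPool")
        seqs = pool.sequences
        length = pool.length
    if not seqs:
        raise ValueError(f"subset {subset!r} is empty; no profile defined")

    dc = diad_codes(sequences_to_codes(seqs))
    n = dc.shape[0]
    counts = np.zeros((16, length - 1), dtype=np.int64)
    for p in range(length - 1):
        counts[:, p] = np.bincount(dc[:, p], minlength=16)
    freq = counts / n
    df = pd.DataFrame(freq, index=list(DIADS), columns=range(1, length))
    return DiadFrequencyProfile(df, n, subset)


@dataclass(frozen=True)
class DiadScore:
    """Positive/negative diad counts and the affinity-weighted score of one oligo."""

    n1: int
    n2: int
    w: float


def count_diads(sequence: str, partition: DiadPartition) -> tuple[int, int]:
    """Count positive (n1) and negative (n2) diads, overlapping occurrences
    included, over start positions 1..L-1."""
    if len(sequence) < 2:
        raise ValueError("sequence must have length >= 2")
    table = partition.class_table()
    dc = diad_codes(sequences_to_codes([sequence]))[0]
    cls = table[dc]
    return int(np.sum(cls == 1)), int(np.sum(cls == -1))


def eq1_weight(affinity, n1, n2):
    """Affinity-weighted diad score: af*(n1-n2) for af >= 0, af*(n2-n1) for
    af < 0; algebraically |af|*(n1-n2).  Vectorizes over array inputs."""
    af = np.asarray(affinity, dtype=float)
    if not np.all(np.isfinite(af)):
        raise ValueError("non-finite affinity")
    n1 = np.asarray(n1)
    n2 = np.asarray(n2)
    w = np.where(af >= 0, af * (n1 - n2), af * (n2 - n1))
    if w.ndim == 0:
        return float(w)
    return w


def score_pool(
    labeled: LabeledPool, partition: DiadPartition
) -> list[DiadScore]:
    """DiadScore for every record of a labelled pool."""
    table = partition.class_table()
    dc = diad_codes(sequences_to_codes(labeled.pool.sequences))
    cls = table[dc]
    n1 = (cls == 1).sum(axis=1)
    n2 = (cls == -1).sum(axis=1)
    w = eq1_weight(labeled.pool.affinities, n1, n2)
    return [DiadScore(int(a), int(b), float(c)) for a, b, c in zip(n1, n2, w)]
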