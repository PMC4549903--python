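"""Reading, validating, filtering and segmenting fixed-length oligo pools.

The unit of analysis is a pool of equal-length DNA oligos (150 bp in the
reference experiment), each carrying a real-valued nucleosome-formation
affinity: the log-ratio of a sequence's abundance in the reconstituted
(nucleosome-bound) fraction versus the initial pool.  Positive affinity
means the sequence preferentially forms nucleosomes.

All user-facing coordinates are 1-based inclusive; internal 0-based
indexing is a private detail.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, TextIO, Union

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "OligoRecord",
    "OligoPool",
    "LabeledPool",
    "SegmentBounds",
    "read_pool",
    "read_affinity_table",
    "filter_by_affinity",
    "segment",
    "write_labeled_pool",
]

_VALID_BASES = frozenset("ACGT")


class PoolValidationError(ValueError):
    """Raised when a pool violates its structural invariants."""


@dataclass(frozen=True)
class OligoRecord:
    """One oligo: identifier, fixed-length ACGT sequence, affinity log-ratio."""

    id: str
    sequence: str
    affinity: float

    def validate(self, length: int | None = None) -> None:
        if length is not None and len(self.sequence) != length:
            raise PoolValidationError(
                f"record {self.id!r}: length {len(self.sequence)} != declared {length}"
            )
        for offset, base in enumerate(self.sequence, start=1):
            if base not in _VALID_BASES:
                raise PoolValidationError(
                    f"record {self.id!r}: invalid base {base!r} at position {offset}"
                )
        if not np.isfinite(self.affinity):
            raise PoolValidationError(f"record {self.id!r}: non-finite affinity")


@dataclass
class OligoPool:
    """Ordered collection of equal-length oligo records with unique ids."""

    records: list[OligoRecord]
    length: int

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise PoolValidationError(f"duplicate record ids: {dupes[:5]}")
        for rec in self.records:
            rec.validate(self.length)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def affinities(self) -> np.ndarray:
        return np.array([r.affinity for r in self.records], dtype=float)

    @property
    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]


@dataclass
class LabeledPool:
    """A pool with a +1/-1 class per record (sign of affinity after filtering)."""

    pool: OligoPool
    labels: np.ndarray  # int8, +1 positive / -1 negative

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if len(self.labels) != len(self.pool):
            raise PoolValidationError("labels length != pool size")
        if not np.all(np.isin(self.labels, (-1, 1))):
            raise PoolValidationError("labels must be +1 or -1")

    def __len__(self) -> int:
        return len(self.pool)

    def subset(self, which: str) -> "LabeledPool":
        """Restrict to 'positive', 'negative' or 'all' records."""
        if which == "all":
            return self
        if which not in ("positive", "negative"):
            raise ValueError(f"unknown subset {which!r}")
        want = 1 if which == "positive" else -1
        keep = [i for i, lab in enumerate(self.labels) if lab == want]
        return LabeledPool(
            OligoPool([self.pool.records[i] for i in keep], self.pool.length),
            self.labels[keep],
        )


@dataclass(frozen=True)
class SegmentBounds:
    """Front/mid/last partition of 1..L, 1-based inclusive intervals."""

    front: tuple[int, int] = (1, 30)
    mid: tuple[int, int] = (31, 120)
    last: tuple[int, int] = (121, 150)

    def validate(self, length: int) -> None:
        f, m, l = self.front, self.mid, self.last
        ok = (
            f[0] == 1
            and m[0] == f[1] + 1
            and l[0] == m[1] + 1
            and l[1] == length
            and f[0] <= f[1]
            and m[0] <= m[1]
            and l[0] <= l[1]
        )
        if not ok:
            raise ValueError(
                f"segment bounds {f}/{m}/{l} do not tile 1..{length} contiguously"
            )


def read_affinity_table(source: Union[str, Path, TextIO]) -> pd.DataFrame:
    """Read a two-column (id, affinity) TSV; a header row is auto-detected.

    The first row is treated as a header iff its second field does not
    parse as a number.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = source.read()
    df = pd.read_csv(io.StringIO(text), sep="\t", header=None, dtype=str)
    if df.shape[1] < 2:
        raise PoolValidationError("affinity table needs >= 2 tab-separated columns")
    try:
        float(df.iloc[0, 1])
    except (TypeError, ValueError):
        df = df.iloc[1:].reset_index(drop=True)
    out = pd.DataFrame(
        {"id": df.iloc[:, 0].astype(str), "affinity": df.iloc[:, 1].astype(float)}
    )
    if out["id"].duplicated().any():
        raise PoolValidationError("duplicate ids in affinity table")
    return out


def read_pool(
    sequence_source: Union[str, Path, TextIO],
    affinity_source: Union[str, Path, TextIO],
    length: int | None = None,
) -> OligoPool:
    """Join a FASTA stream with an (id, affinity) table into a validated pool.

    Records keep FASTA order.  ``length`` defaults to the first record's
    length; every record must match it.  Lowercase bases are accepted and
    uppercased; ambiguity codes are rejected.
    """
    if isinstance(sequence_source, (str, Path)):
        handle: TextIO = open(sequence_source)
        close = True
    else:
        handle, close = sequence_source, False
    try:
        fasta = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(handle, "fasta")]
    finally:
        if close:
            handle.close()
    if not fasta:
        raise PoolValidationError("no FASTA records found")

    table = read_affinity_table(affinity_source)
    aff = dict(zip(table["id"], table["affinity"]))

    fasta_ids = {fid for fid, _ in fasta}
    missing_aff = [fid for fid, _ in fasta if fid not in aff]
    if missing_aff:
        raise PoolValidationError(
            f"ids in FASTA but not in affinity table: {missing_aff[:5]}"
        )
    extra = sorted(set(aff) - fasta_ids)
    if extra:
        raise PoolValidationError(f"ids in affinity table but not in FASTA: {extra[:5]}")

    if length is None:
        length = len(fasta[0][1])
    records = [OligoRecord(fid, seq, float(aff[fid])) for fid, seq in fasta]
    return OligoPool(records, length)


def filter_by_affinity(
    pool: OligoPool, upper: float = 1.0, lower: float = 0.0
) -> LabeledPool:
    """Keep records with affinity strictly above ``upper`` (labelled +1) or
    strictly below ``lower`` (labelled -1); everything in [lower, upper] is
    dropped.  Order is preserved.  Idempotent on its own output pool.
    """
    if not upper > lower:
        raise ValueError(f"upper ({upper}) must exceed lower ({lower})")
    kept: list[OligoRecord] = []
    labels: list[int] = []
    for rec in pool:
        if rec.affinity > upper:
            kept.append(rec)
            labels.append(1)
        elif rec.affinity < lower:
            kept.append(rec)
            labels.append(-1)
    return LabeledPool(OligoPool(kept, pool.length), np.array(labels, dtype=np.int8))


def segment(
    record: OligoRecord, bounds: SegmentBounds | None = None
) -> tuple[str, str, str]:
    """Split a record's sequence into front/mid/last sub-sequences.

    Bounds are 1-based inclusive; the concatenation of the three pieces
    equals the input sequence.  Default bounds (1-30, 31-120, 121-150)
    apply to 150 bp oligos.
    """
    if bounds is None:
        bounds = SegmentBounds()
    bounds.validate(len(record.sequence))
    s = record.sequence
    cut = lambda iv: s[iv[0] - 1 : iv[1]]
    return cut(bounds.front), cut(bounds.mid), cut(bounds.last)


def write_labeled_pool(labeled: LabeledPool, path: Union[str, Path]) -> None:
    """Write a LabeledPool as TSV (id, affinity, label) with label in {pos,neg}."""
    rows = [
        (r.id, r.affinity, "pos" if lab == 1 else "neg")
        for r, lab in zip(labeled.pool, labeled.labels)
    ]
    pd.DataFrame(rows, columns=["id", "affinity", "label"]).to_csv(
        path, sep="\t", index=False
    )
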