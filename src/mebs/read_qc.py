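"""Three-rule quality filter producing "clean reads" from raw FASTQ.

A read is dropped when it (i) contains the adapter sequence, (ii) has more
than ``max_uncalled_frac`` uncalled bases (N), or (iii) has more than
``max_lowqual_frac`` of its bases below the Phred cutoff.  Both fraction
thresholds are strict ("more than"), so a read sitting exactly on the
boundary is kept.  Rules are tested in order (i), (ii), (iii) and the first
failure is the reported reason.

Adapter-containing reads are dropped whole (exact substring match, no
mismatches); no trimming of any kind is performed.
"""
from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from typing import Iterable, Iterator

from .io_formats import FastqRead

KEEP = "keep"
DROP_ADAPTER = "adapter"
DROP_UNCALLED = "uncalled"
DROP_QUALITY = "quality"


@dataclass
class QcThresholds:
    """Filter parameters.  An empty ``adapter_seq`` disables rule (i)."""

    adapter_seq: str = ""
    max_uncalled_frac: float = 0.10
    low_qual_cutoff: int = 20
    max_lowqual_frac: float = 0.10

    def __post_init__(self) -> None:
        for frac in (self.max_uncalled_frac, self.max_lowqual_frac):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"fraction threshold {frac} outside [0, 1]")
        if self.low_qual_cutoff < 0:
            raise ValueError("low_qual_cutoff must be >= 0")


@dataclass
class QcReport:
    input_reads: int = 0
    kept_reads: int = 0
    dropped_by_adapter: int = 0
    dropped_by_n: int = 0
    dropped_by_quality: int = 0
    dropped_as_orphan: int = 0

    @property
    def dropped_total(self) -> int:
        return (
            self.dropped_by_adapter
            + self.dropped_by_n
            + self.dropped_by_quality
            + self.dropped_as_orphan
        )

    def check(self) -> None:
        if self.input_reads != self.kept_reads + self.dropped_total:
            raise AssertionError("QcReport counts do not conserve reads")

    def to_tsv(self) -> str:
        rows = [
            ("input_reads", self.input_reads),
            ("kept_reads", self.kept_reads),
            ("dropped_by_adapter", self.dropped_by_adapter),
            ("dropped_by_n", self.dropped_by_n),
            ("dropped_by_quality", self.dropped_by_quality),
            ("dropped_as_orphan", self.dropped_as_orphan),
        ]
        return "".join(f"{k}\t{v}\n" for k, v in rows)


def assess_read(read: FastqRead, t: QcThresholds) -> str:
    """Return ``keep`` or the first failing rule (adapter/uncalled/quality)."""
    n = len(read)
    if t.adapter_seq and t.adapter_seq in read.seq:
        return DROP_ADAPTER
    if read.seq.count("N") / n > t.max_uncalled_frac:
        return DROP_UNCALLED
    if sum(1 for q in read.quals if q < t.low_qual_cutoff) / n > t.max_lowqual_frac:
        return DROP_QUALITY
    return KEEP


_MATE_SUFFIX = re.compile(r"/[12]$")


def _pair_key(read_id: str) -> str:
    return _MATE_SUFFIX.sub("", read_id)


_REASON_FIELD = {
    DROP_ADAPTER: "dropped_by_adapter",
    DROP_UNCALLED: "dropped_by_n",
    DROP_QUALITY: "dropped_by_quality",
}


def filter_pairs(
    r1: Iterable[FastqRead],
    r2: Iterable[FastqRead],
    t: QcThresholds,
    mode: str = "drop-pair",
) -> tuple[list[tuple[FastqRead, FastqRead]], list[FastqRead], QcReport]:
    """Filter a paired-end library.

    In ``drop-pair`` mode a pair survives only when both mates pass; the
    passing mate of a half-failed pair is counted as ``dropped_as_orphan``.
    In ``keep-orphans`` mode that mate is emitted in the orphan list and
    counted as kept.
    """
    if mode not in ("drop-pair", "keep-orphans"):
        raise ValueError(f"unknown pair mode {mode!r}")
    pairs: list[tuple[FastqRead, FastqRead]] = []
    orphans: list[FastqRead] = []
    report = QcReport()
    sentinel = object()
    for a, b in itertools.zip_longest(r1, r2, fillvalue=sentinel):
        if a is sentinel or b is sentinel:
            short = "r1" if a is sentinel else "r2"
            raise ValueError(f"paired FASTQ streams differ in length ({short} shorter)")
        if _pair_key(a.id) != _pair_key(b.id):
            raise ValueError(f"unpaired read ids: {a.id!r} vs {b.id!r}")
        report.input_reads += 2
        va, vb = assess_read(a, t), assess_read(b, t)
        if va == KEEP and vb == KEEP:
            pairs.append((a, b))
            report.kept_reads += 2
            continue
        for verdict in (va, vb):
            if verdict != KEEP:
                setattr(report, _REASON_FIELD[verdict],
                        getattr(report, _REASON_FIELD[verdict]) + 1)
        survivor = a if va == KEEP else (b if vb == KEEP else None)
        if survivor is not None:
            if mode == "keep-orphans":
                orphans.append(survivor)
                report.kept_reads += 1
            else:
                report.dropped_as_orphan += 1
    report.check()
    return pairs, orphans, report


def filter_reads(
    reads: Iterable[FastqRead], t: QcThresholds
) -> Iterator[tuple[FastqRead, str]]:
    """Single-end convenience: yield (read, verdict) for a stream."""
    for read in reads:
        yield read, assess_read(read, t)
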