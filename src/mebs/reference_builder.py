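"""Consensus reference construction from per-position pileup counts.

The rule is a plain majority vote over read observations: positions covered
by fewer than ``min_cov`` observations become N; otherwise the alternative
(base or deletion) supported by most reads is emitted, with exact ties broken
uniformly at random by a caller-supplied seeded generator.  Insertions are a
separate junction vote (insertion string vs. the reads that do not insert)
decided with the same majority-with-random-ties semantics.  The reference
base is never privileged: read support alone decides.

Alongside the consensus, a per-position liftover map records where every
source position lands on the new sequence (or that it was deleted), so that
annotations can be carried across indels.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import numpy as np

from .io_formats import FormatError, Genome, Region

#: sentinel returned by consensus_base when the majority deletes the position
DELETED = "-"

_BASES = ("A", "C", "G", "T")


@dataclass
class PileupColumn:
    """Per-reference-position observation counts.

    ``base_counts`` maps base -> count over {A,C,G,T} (an ``N`` key is
    tolerated: N observations count toward coverage but are never candidates).
    ``insertion_counts`` counts insertions anchored *after* this position.
    """

    scaffold: str
    pos: int
    ref_base: str = "N"
    base_counts: dict[str, int] = field(default_factory=dict)
    deletion_count: int = 0
    insertion_counts: dict[str, int] = field(default_factory=dict)

    @property
    def coverage(self) -> int:
        return sum(self.base_counts.values()) + self.deletion_count


@dataclass
class Liftover:
    """Monotone source-position -> target-position maps, -1 = deleted."""

    maps: dict[str, np.ndarray]

    def map(self, scaffold: str, pos: int) -> Optional[int]:
        t = int(self.maps[scaffold][pos])
        return None if t < 0 else t


@dataclass
class ConsensusGenome:
    genome: Genome
    liftover: Liftover
    stats: dict[str, dict[str, int]]


def consensus_base(
    col: PileupColumn, min_cov: int = 4, rng: Optional[np.random.Generator] = None
) -> str:
    """Majority base for one column: N, a base, or DELETED.

    Deletion-supporting reads count toward coverage and compete with bases in
    a single vote.  Ties require ``rng``.
    """
    if col.coverage < min_cov:
        return "N"
    candidates = [(b, c) for b, c in col.base_counts.items()
                  if b in _BASES and c > 0]
    if col.deletion_count > 0:
        candidates.append((DELETED, col.deletion_count))
    if not candidates:
        return "N"  # covered, but only N base calls
    top = max(c for _, c in candidates)
    tied = sorted(b for b, c in candidates if c == top)
    if len(tied) == 1:
        return tied[0]
    if rng is None:
        raise ValueError("tie at a pileup column but no rng supplied")
    return tied[int(rng.integers(len(tied)))]


def _junction_insertion(
    col: PileupColumn, min_cov: int, rng: Optional[np.random.Generator]
) -> str:
    """Majority vote at the junction after ``col``: '' means no insertion."""
    if not col.insertion_counts or col.coverage < min_cov:
        return ""
    total_ins = sum(col.insertion_counts.values())
    candidates = [("", col.coverage - total_ins)]
    candidates += [(s, c) for s, c in col.insertion_counts.items() if c > 0]
    top = max(c for _, c in candidates)
    tied = sorted(s for s, c in candidates if c == top)
    if len(tied) == 1:
        return tied[0]
    if rng is None:
        raise ValueError("tie at an insertion junction but no rng supplied")
    return tied[int(rng.integers(len(tied)))]


def build_consensus(
    columns: Iterable[PileupColumn],
    source: Genome,
    min_cov: int = 4,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> ConsensusGenome:
    """Build the consensus genome from a sorted stream of pileup columns.

    Columns must arrive grouped by scaffold (in source order) and sorted by
    position; source positions absent from the stream are implicitly
    zero-coverage and become N.  Tie draws are consumed in scaffold/position
    order, so results are reproducible for a given seed.
    """
    if rng is None:
        rng = np.random.default_rng(0 if seed is None else seed)

    scaffold_order = list(source.scaffolds)
    order_index = {s: i for i, s in enumerate(scaffold_order)}
    it = iter(columns)
    cur = next(it, None)

    new_scaffolds: dict[str, str] = {}
    maps: dict[str, np.ndarray] = {}
    stats: dict[str, dict[str, int]] = {}
    for si, scaffold in enumerate(scaffold_order):
        src = source[scaffold]
        out: list[str] = []
        lift = np.full(len(src), -1, dtype=np.int64)
        st = {"n_count": 0, "substitutions": 0, "insertions": 0, "deletions": 0}
        cursor = 0
        for pos in range(len(src)):
            col = None
            if cur is not None and cur.scaffold == scaffold:
                if cur.pos < pos:
                    raise FormatError(
                        f"pileup not sorted at {cur.scaffold}:{cur.pos}")
                if cur.pos >= len(src):
                    raise FormatError(
                        f"pileup position {cur.pos} beyond scaffold "
                        f"{scaffold!r} of length {len(src)}")
                if cur.pos == pos:
                    col = cur
                    cur = next(it, None)
                    if (cur is not None and cur.scaffold == scaffold
                            and cur.pos <= pos):
                        raise FormatError(
                            f"pileup not sorted at {cur.scaffold}:{cur.pos}")
            base = "N" if col is None else consensus_base(col, min_cov, rng)
            if base == DELETED:
                st["deletions"] += 1
            else:
                out.append(base)
                lift[pos] = cursor
                cursor += 1
                if base == "N":
                    st["n_count"] += 1
                elif base != src[pos]:
                    st["substitutions"] += 1
            if col is not None:
                ins = _junction_insertion(col, min_cov, rng)
                if ins:
                    out.append(ins)
                    cursor += len(ins)
                    st["insertions"] += 1
        new_scaffolds[scaffold] = "".join(out)
        maps[scaffold] = lift
        stats[scaffold] = st
    if cur is not None:
        if cur.scaffold in order_index:
            raise FormatError(
                f"pileup not sorted at {cur.scaffold}:{cur.pos} "
                "(scaffold already emitted)")
        raise FormatError(f"pileup column on unknown scaffold {cur.scaffold!r}")
    return ConsensusGenome(Genome(new_scaffolds), Liftover(maps), stats)


def lift_regions(
    regions: Iterable[Region], liftover: Liftover
) -> tuple[list[Region], list[Region]]:
    """Map regions from source to consensus coordinates across indels.

    The start maps to the first non-deleted position >= start, the end to
    one past the last non-deleted position < end.  Regions falling entirely
    inside deleted segments are dropped and returned separately.
    """
    lifted: list[Region] = []
    dropped: list[Region] = []
    for r in regions:
        if r.scaffold not in liftover.maps:
            raise FormatError(f"region {r.name!r} on unknown scaffold {r.scaffold!r}")
        arr = liftover.maps[r.scaffold]
        if r.end > len(arr):
            raise FormatError(f"region {r.name!r} extends past scaffold end")
        seg = arr[r.start : r.end]
        kept = seg[seg >= 0]
        if kept.size == 0:
            dropped.append(r)
            continue
        lifted.append(
            Region(
                scaffold=r.scaffold,
                start=int(kept[0]),
                end=int(kept[-1]) + 1,
                strand=r.strand,
                kind=r.kind,
                name=r.name,
            )
        )
    return lifted, dropped


def average_coverage(n_mapped_reads: int, read_length: int, genome_size: int) -> float:
    """x-fold coverage = mapped reads x read length / genome size."""
    if genome_size <= 0:
        raise ValueError("genome size must be positive")
    return n_mapped_reads * read_length / genome_size


@dataclass
class CoverageTrack:
    """Per-scaffold read depth, one integer per reference position."""

    depths: dict[str, np.ndarray]

    @classmethod
    def zeros(cls, genome: Genome) -> "CoverageTrack":
        return cls({s: np.zeros(n, dtype=np.int64) for s, n in genome.lengths.items()})

    @classmethod
    def from_reads(cls, reads: Iterable, genome: Genome) -> "CoverageTrack":
        """Depth track from AlignedReads (M/D reference span counts)."""
        track = cls.zeros(genome)
        for r in reads:
            d = track.depths[r.scaffold]
            d[r.start : min(r.end, len(d))] += 1
        return track

    @property
    def total_length(self) -> int:
        return sum(len(d) for d in self.depths.values())


def breadth_and_depth(track: CoverageTrack) -> tuple[float, float]:
    """(breadth as % of positions with depth >= 1, mean depth over covered).

    Mean depth over an entirely uncovered track is reported as 0.0.
    """
    total = track.total_length
    covered = sum(int((d > 0).sum()) for d in track.depths.values())
    depth_sum = sum(int(d[d > 0].sum()) for d in track.depths.values())
    breadth = 100.0 * covered / total if total else 0.0
    mean_depth = depth_sum / covered if covered else 0.0
    return breadth, mean_depth


# ---------------------------------------------------------------------------
# Pileup I/O

_HEADER = "scaffold\tpos\tref\tA\tC\tG\tT\tN\tdel\tinsertions\n"


def write_pileup_tsv(columns: Iterable[PileupColumn], path: str | Path) -> None:
    """Internal pileup TSV (0-based positions; insertions as seq:count,...)."""
    with open(path, "w") as fh:
        fh.write(_HEADER)
        for c in columns:
            ins = ",".join(f"{s}:{n}" for s, n in sorted(c.insertion_counts.items()))
            counts = "\t".join(str(c.base_counts.get(b, 0)) for b in "ACGTN")
            fh.write(
                f"{c.scaffold}\t{c.pos}\t{c.ref_base}\t{counts}\t"
                f"{c.deletion_count}\t{ins}\n"
            )


def read_pileup_tsv(path: str | Path) -> Iterator[PileupColumn]:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("scaffold\t"):
            raise FormatError(f"{path}: missing pileup TSV header")
        for lineno, line in enumerate(fh, start=2):
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 10:
                raise FormatError(f"{path}:{lineno}: expected 10 columns")
            base_counts = {b: int(cols[3 + i]) for i, b in enumerate("ACGTN")}
            base_counts = {b: c for b, c in base_counts.items() if c}
            ins: dict[str, int] = {}
            if cols[9]:
                for item in cols[9].split(","):
                    s, n = item.rsplit(":", 1)
                    ins[s] = int(n)
            yield PileupColumn(
                scaffold=cols[0],
                pos=int(cols[1]),
                ref_base=cols[2],
                base_counts=base_counts,
                deletion_count=int(cols[8]),
                insertion_counts=ins,
            )


_MPILEUP_SKIP = {"$"}


def iter_mpileup(path: str | Path) -> Iterator[PileupColumn]:
    """Parse a samtools-mpileup text file into PileupColumns.

    Handles ./, match codes, explicit bases, * deletion placeholders,
    +n/-n indel annotations and ^X/$ read boundary marks.  Positions are
    converted from mpileup's 1-based convention.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 5:
                raise FormatError(f"{path}:{lineno}: short mpileup line")
            scaffold, pos1, ref = cols[0], int(cols[1]), cols[2].upper()
            bases = cols[4]
            counts: dict[str, int] = {}
            dels = 0
            ins: dict[str, int] = {}
            i = 0
            while i < len(bases):
                ch = bases[i]
                if ch == "^":
                    i += 2
                    continue
                if ch == "$":
                    i += 1
                    continue
                if ch in "+-":
                    j = i + 1
                    while j < len(bases) and bases[j].isdigit():
                        j += 1
                    n = int(bases[i + 1 : j])
                    seq = bases[j : j + n].upper()
                    if ch == "+":
                        ins[seq] = ins.get(seq, 0) + 1
                    # '-' announces upcoming '*' columns; nothing counted here
                    i = j + n
                    continue
                if ch in ".,":
                    counts[ref] = counts.get(ref, 0) + 1
                elif ch == "*":
                    dels += 1
                elif ch.upper() in "ACGTN":
                    b = ch.upper()
                    counts[b] = counts.get(b, 0) + 1
                else:
                    raise FormatError(
                        f"{path}:{lineno}: unknown mpileup base code {ch!r}"
                    )
                i += 1
            yield PileupColumn(
                scaffold=scaffold,
                pos=pos1 - 1,
                ref_base=ref if ref in "ACGTN" else "N",
                base_counts=counts,
                deletion_count=dels,
                insertion_counts=ins,
            )


def write_liftover_tsv(liftover: Liftover, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("scaffold\tsource_pos\ttarget_pos\n")
        for scaffold, arr in liftover.maps.items():
            for pos, tgt in enumerate(arr):
                fh.write(f"{scaffold}\t{pos}\t{int(tgt)}\n")


def write_stats_json(consensus: ConsensusGenome, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(consensus.stats, fh, indent=2, sort_keys=True)
        fh.write("\n")
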