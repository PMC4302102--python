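"""Per-cytosine methylation extraction from directional bisulfite alignments.

A directional library sequences only the two bisulfite-converted original
strands, so each read informs cytosines on exactly one reference strand:
original-top reads report top-strand cytosines (read C = methylated, read
T = converted, i.e. unmethylated) and original-bottom reads report
bottom-strand cytosines, which sit at reference G positions in top-strand
orientation (read G = methylated, read A = converted).  Read bases other
than the C/T (or G/A) pair at an informative position are sequencing or
mapping errors and are ignored rather than counted as evidence.

Where the two mates of a fragment overlap, each reference position is
counted once; on disagreement the first-seen mate (mate 1) wins.  Non-unique
alignments are skipped and counted.

The sequence context of a cytosine is the two following bases on its own
strand: CG, CHG or CHH with H = A, T or C; windows running off the scaffold
or containing N give context ``unknown`` (emitted, but excluded from
summaries).
"""
from __future__ import annotations

import json
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import pandas as pd

from .io_formats import (
    ORIGINAL_BOTTOM,
    ORIGINAL_TOP,
    AlignedRead,
    FormatError,
    Genome,
    write_bedgraph,
)

CONTEXTS = ("CG", "CHG", "CHH")


@dataclass
class CytosineCall:
    scaffold: str
    pos: int
    strand: str
    context: str
    meth: int = 0
    unmeth: int = 0

    @property
    def depth(self) -> int:
        return self.meth + self.unmeth


@dataclass
class FragmentMethProfile:
    fragment_id: str
    n_cytosines: int
    n_methylated: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_methylated <= self.n_cytosines:
            raise ValueError(
                f"fragment {self.fragment_id!r}: methylated count exceeds "
                "observed cytosines"
            )


@dataclass
class ContextSummary:
    """Observation-level methylation totals per sequence context."""

    meth: dict[str, int]
    unmeth: dict[str, int]
    uncovered: set[str] = field(default_factory=set)

    def percent(self, context: str) -> float:
        m, u = self.meth.get(context, 0), self.unmeth.get(context, 0)
        return 100.0 * m / (m + u) if m + u else 0.0

    @property
    def overall_percent(self) -> float:
        """% methylated over all C observations, pooled across contexts."""
        m = sum(self.meth.values())
        u = sum(self.unmeth.values())
        return 100.0 * m / (m + u) if m + u else 0.0

    def to_dict(self) -> dict:
        return {
            "contexts": {
                c: {
                    "meth": self.meth.get(c, 0),
                    "unmeth": self.unmeth.get(c, 0),
                    "percent_methylated": self.percent(c),
                    "uncovered": c in self.uncovered,
                }
                for c in CONTEXTS
            },
            "overall_percent_methylated": self.overall_percent,
        }


def classify_context(genome: Genome, scaffold: str, pos: int, strand: str) -> str:
    """CG / CHG / CHH / unknown for the cytosine at (pos, strand)."""
    seq = genome[scaffold]
    if strand == "+":
        if seq[pos] != "C":
            raise ValueError(f"{scaffold}:{pos}(+) is {seq[pos]}, not C")
        if pos + 1 >= len(seq):
            return "unknown"
        b1 = seq[pos + 1]
        if b1 == "G":
            return "CG"
        if b1 == "N":
            return "unknown"
        if pos + 2 >= len(seq):
            return "unknown"
        b2 = seq[pos + 2]
        if b2 == "N":
            return "unknown"
        return "CHG" if b2 == "G" else "CHH"
    elif strand == "-":
        # a bottom-strand C sits at a top-strand G; its downstream bases are
        # the complements of the top-strand bases to its left
        if seq[pos] != "G":
            raise ValueError(f"{scaffold}:{pos}(-) is {seq[pos]}, not G (no C)")
        if pos - 1 < 0:
            return "unknown"
        b1 = seq[pos - 1]
        if b1 == "C":  # complement G
            return "CG"
        if b1 == "N":
            return "unknown"
        if pos - 2 < 0:
            return "unknown"
        b2 = seq[pos - 2]
        if b2 == "N":
            return "unknown"
        return "CHG" if b2 == "C" else "CHH"
    raise ValueError(f"bad strand {strand!r}")


def methylation_ratio(call: CytosineCall) -> float:
    """Percent of reads showing this cytosine methylated."""
    if call.depth < 1:
        raise ValueError("methylation ratio undefined at zero coverage")
    return 100.0 * call.meth / call.depth


def _read_observations(
    read: AlignedRead, genome: Genome
) -> Iterator[tuple[int, str, bool]]:
    """Yield (ref_pos, strand, is_methylated) for one read's informative sites."""
    if read.conversion_strand is None:
        raise FormatError(
            f"read {read.read_id!r} lacks a conversion-strand tag; "
            "bisulfite calling requires directional XG-tagged alignments"
        )
    seq = genome[read.scaffold]
    if read.conversion_strand == ORIGINAL_TOP:
        ref_c, meth_base, unmeth_base, strand = "C", "C", "T", "+"
    elif read.conversion_strand == ORIGINAL_BOTTOM:
        ref_c, meth_base, unmeth_base, strand = "G", "G", "A", "-"
    else:
        raise FormatError(f"unknown conversion strand {read.conversion_strand!r}")
    for q, r in read.aligned_pairs():
        if seq[r] != ref_c:
            continue
        b = read.seq[q]
        if b == meth_base:
            yield r, strand, True
        elif b == unmeth_base:
            yield r, strand, False
        # other bases: mismatch, ignored


def _group_fragments(
    reads: Iterable[AlignedRead], stats: dict
) -> Iterator[list[AlignedRead]]:
    """Group unique reads by fragment (read id); order of appearance kept."""
    fragments: dict[str, list[AlignedRead]] = defaultdict(list)
    order: list[str] = []
    for read in reads:
        if not read.unique:
            stats["skipped_non_unique"] += 1
            continue
        if read.read_id not in fragments:
            order.append(read.read_id)
        fragments[read.read_id].append(read)
    for rid in order:
        yield fragments[rid]


def _fragment_observations(
    mates: list[AlignedRead], genome: Genome
) -> dict[tuple[str, int, str], bool]:
    """Deduplicated observations of one fragment; earlier mates take precedence."""
    obs: dict[tuple[str, int, str], bool] = {}
    for read in mates:
        for pos, strand, is_meth in _read_observations(read, genome):
            key = (read.scaffold, pos, strand)
            if key not in obs:  # mate-1 precedence on overlap
                obs[key] = is_meth
    return obs


def call_from_alignments(
    reads: Iterable[AlignedRead],
    genome: Genome,
    stats: Optional[dict] = None,
) -> list[CytosineCall]:
    """Aggregate per-cytosine methylation calls from bisulfite alignments.

    Returns calls sorted by (scaffold, pos, strand); every emitted call has
    at least one observation.
    """
    if stats is None:
        stats = {}
    stats.setdefault("skipped_non_unique", 0)
    stats.setdefault("fragments", 0)
    stats.setdefault("observations", 0)
    counts: dict[tuple[str, int, str], list[int]] = {}
    for mates in _group_fragments(reads, stats):
        stats["fragments"] += 1
        for key, is_meth in _fragment_observations(mates, genome).items():
            stats["observations"] += 1
            c = counts.setdefault(key, [0, 0])
            c[0 if is_meth else 1] += 1
    calls = [
        CytosineCall(
            scaffold=scaf,
            pos=pos,
            strand=strand,
            context=classify_context(genome, scaf, pos, strand),
            meth=m,
            unmeth=u,
        )
        for (scaf, pos, strand), (m, u) in counts.items()
    ]
    calls.sort(key=lambda c: (c.scaffold, c.pos, c.strand))
    return calls


def context_summary(calls: Iterable[CytosineCall]) -> ContextSummary:
    """Observation-level totals per context; ``unknown`` calls are excluded."""
    meth: dict[str, int] = {c: 0 for c in CONTEXTS}
    unmeth: dict[str, int] = {c: 0 for c in CONTEXTS}
    for call in calls:
        if call.context not in CONTEXTS:
            continue
        meth[call.context] += call.meth
        unmeth[call.context] += call.unmeth
    uncovered = {c for c in CONTEXTS if meth[c] + unmeth[c] == 0}
    return ContextSummary(meth=meth, unmeth=unmeth, uncovered=uncovered)


def conversion_efficiency(calls: Iterable[CytosineCall]) -> float:
    """Bisulfite conversion efficiency from pooled CHG+CHH observations.

    Non-CG cytosines are assumed biologically unmethylated, so the fraction
    read as converted estimates the chemical efficiency.
    """
    m = u = 0
    for call in calls:
        if call.context in ("CHG", "CHH"):
            m += call.meth
            u += call.unmeth
    if m + u == 0:
        raise ValueError("no CHG/CHH observations; efficiency undefined")
    return 100.0 * u / (m + u)


def fragment_profiles(
    reads: Iterable[AlignedRead],
    genome: Genome,
    stats: Optional[dict] = None,
) -> tuple[list[FragmentMethProfile], Counter]:
    """Per-fragment observed-cytosine and methylated-cytosine counts.

    Also returns the histogram of methylated-C counts per fragment (the
    capture-efficiency diagnostic: its mode reflects how many methylated
    cytosines a captured fragment typically carries).
    """
    if stats is None:
        stats = {}
    stats.setdefault("skipped_non_unique", 0)
    profiles: list[FragmentMethProfile] = []
    histogram: Counter = Counter()
    for mates in _group_fragments(reads, stats):
        obs = _fragment_observations(mates, genome)
        n_meth = sum(1 for v in obs.values() if v)
        profiles.append(
            FragmentMethProfile(mates[0].read_id, len(obs), n_meth)
        )
        histogram[n_meth] += 1
    return profiles, histogram


def capture_specificity(profiles: Iterable[FragmentMethProfile]) -> float:
    """% of fragments with zero methylated Cs among fragments observing >= 1 C.

    Fully converted fragments were unmethylated, so this estimates the
    unspecific (non-methylated) fraction of the captured library.
    """
    informative = [p for p in profiles if p.n_cytosines >= 1]
    if not informative:
        return 0.0
    zero = sum(1 for p in informative if p.n_methylated == 0)
    return 100.0 * zero / len(informative)


# ---------------------------------------------------------------------------
# Reports


def calls_to_frame(calls: Iterable[CytosineCall]) -> pd.DataFrame:
    """Tabular view of calls for the statistics layer."""
    rows = [
        (c.scaffold, c.pos, c.strand, c.context, c.meth, c.unmeth)
        for c in calls
    ]
    return pd.DataFrame(
        rows, columns=["scaffold", "pos", "strand", "context", "meth", "unmeth"]
    )


def write_calls_tsv(calls: Iterable[CytosineCall], path: str | Path) -> None:
    """Methylation-extractor style report (positions written 1-based)."""
    with open(path, "w") as fh:
        fh.write("scaffold\tpos\tstrand\tcontext\tmeth\tunmeth\tratio\n")
        for c in calls:
            fh.write(
                f"{c.scaffold}\t{c.pos + 1}\t{c.strand}\t{c.context}\t"
                f"{c.meth}\t{c.unmeth}\t{methylation_ratio(c):.4f}\n"
            )


def read_calls_tsv(path: str | Path) -> list[CytosineCall]:
    calls = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("scaffold\t"):
            raise FormatError(f"{path}: missing calls TSV header")
        for line in fh:
            cols = line.rstrip("\n").split("\t")
            calls.append(
                CytosineCall(
                    scaffold=cols[0],
                    pos=int(cols[1]) - 1,
                    strand=cols[2],
                    context=cols[3],
                    meth=int(cols[4]),
                    unmeth=int(cols[5]),
                )
            )
    return calls


def write_context_bedgraphs(
    calls: Iterable[CytosineCall], out_dir: str | Path, prefix: str = "meth"
) -> None:
    out_dir = Path(out_dir)
    by_context: dict[str, list] = {c: [] for c in CONTEXTS}
    for c in calls:
        if c.context in by_context:
            by_context[c.context].append(
                (c.scaffold, c.pos, c.pos + 1, methylation_ratio(c))
            )
    for context, entries in by_context.items():
        write_bedgraph(entries, out_dir / f"{prefix}_{context}.bedGraph",
                       track_name=f"{prefix} {context}")


def write_summary_json(
    summary: ContextSummary, path: str | Path, extra: Optional[dict] = None
) -> None:
    payload = summary.to_dict()
    if extra:
        payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
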