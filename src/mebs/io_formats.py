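"""Readers and writers for the standard formats the pipeline touches.

One coordinate convention holds everywhere inside the package: positions are
0-based and intervals are half-open ``[start, end)``.  Conversion to and from
the 1-based conventions of SAM and GFF3 happens only at the I/O boundary in
this module.

Sequences are restricted to the five-letter alphabet {A, C, G, T, N}; other
IUPAC ambiguity codes are rejected at parse time so that every downstream
stage can rely on it.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = frozenset("ACGTN")
COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: conversion-strand labels for directional bisulfite reads
ORIGINAL_TOP = "original-top"
ORIGINAL_BOTTOM = "original-bottom"

REGION_KINDS = ("gene", "exon", "promoter", "cgi", "tss", "other")


class FormatError(ValueError):
    """Raised on malformed input files."""


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class Genome:
    """A set of named scaffolds over {A, C, G, T, N}.

    Scaffold order is preserved (insertion order of the mapping).
    """

    scaffolds: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.scaffolds.items():
            if not name:
                raise FormatError("empty scaffold id")
            if not seq:
                raise FormatError(f"scaffold {name!r} has empty sequence")
            bad = set(seq) - ALPHABET
            if bad:
                raise FormatError(
                    f"scaffold {name!r} contains letters outside ACGTN: "
                    f"{sorted(bad)}"
                )

    def __getitem__(self, name: str) -> str:
        return self.scaffolds[name]

    def __contains__(self, name: str) -> bool:
        return name in self.scaffolds

    def __iter__(self) -> Iterator[str]:
        return iter(self.scaffolds)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.scaffolds.items()}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.scaffolds.values())


@dataclass
class FastqRead:
    """A read with per-base integer Phred scores (decoded from Phred+33)."""

    id: str
    seq: str
    quals: list[int]

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.quals):
            raise FormatError(
                f"read {self.id!r}: sequence length {len(self.seq)} != "
                f"quality length {len(self.quals)}"
            )
        if any(q < 0 or q > 60 for q in self.quals):
            raise FormatError(f"read {self.id!r}: quality outside [0, 60]")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class AlignedRead:
    """A mapped (optionally bisulfite-converted) read.

    ``seq`` is stored in reference orientation, as SAM does.  ``cigar`` is a
    list of ``(op, length)`` with op in {M, I, D}.  ``conversion_strand`` is
    one of the module constants ORIGINAL_TOP / ORIGINAL_BOTTOM, or None for a
    conventional (non-bisulfite) read.
    """

    read_id: str
    scaffold: str
    start: int
    strand: str
    seq: str
    quals: list[int]
    cigar: list[tuple[str, int]]
    conversion_strand: Optional[str] = None
    mate_id: Optional[str] = None
    unique: bool = True

    def __post_init__(self) -> None:
        qlen = sum(n for op, n in self.cigar if op in "MI")
        if qlen != len(self.seq):
            raise FormatError(
                f"read {self.read_id!r}: CIGAR M+I length {qlen} != "
                f"sequence length {len(self.seq)}"
            )

    @property
    def ref_span(self) -> int:
        """Reference bases consumed (sum of M and D operations)."""
        return sum(n for op, n in self.cigar if op in "MD")

    @property
    def end(self) -> int:
        return self.start + self.ref_span

    def aligned_pairs(self) -> Iterator[tuple[int, int]]:
        """Yield (query_offset, reference_position) for every M base."""
        q, r = 0, self.start
        for op, n in self.cigar:
            if op == "M":
                for k in range(n):
                    yield q + k, r + k
                q += n
                r += n
            elif op == "I":
                q += n
            elif op == "D":
                r += n


@dataclass
class Region:
    """A typed genomic interval, 0-based half-open."""

    scaffold: str
    start: int
    end: int
    strand: str = "."
    kind: str = "other"
    name: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"region {self.name!r} on {self.scaffold}: invalid interval "
                f"[{self.start}, {self.end})"
            )
        if self.strand not in "+-.":
            raise FormatError(f"region {self.name!r}: bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Region") -> bool:
        return (
            self.scaffold == other.scaffold
            and self.start < other.end
            and other.start < self.end
        )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> Genome:
    """Read a (possibly multi-line, CRLF-tolerant) FASTA file.

    Sequences are uppercased; record order is preserved.  Letters outside
    {A,C,G,T,N} and duplicate ids are rejected with the offending line number.
    """
    scaffolds: dict[str, str] = {}
    name: Optional[str] = None
    chunks: list[str] = []

    def flush() -> None:
        if name is not None:
            scaffolds[name] = "".join(chunks)

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line:
                continue
            if line.startswith(">"):
                flush()
                name = line[1:].split()[0] if len(line) > 1 else ""
                if not name:
                    raise FormatError(f"{path}:{lineno}: empty FASTA header")
                if name in scaffolds:
                    raise FormatError(
                        f"{path}:{lineno}: duplicate scaffold id {name!r}"
                    )
                chunks = []
            else:
                if name is None:
                    raise FormatError(
                        f"{path}:{lineno}: sequence before first header"
                    )
                upper = line.upper()
                bad = set(upper) - ALPHABET
                if bad:
                    raise FormatError(
                        f"{path}:{lineno}: letters outside ACGTN: {sorted(bad)}"
                    )
                chunks.append(upper)
        flush()
    return Genome(scaffolds)


def write_fasta(genome: Genome, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.scaffolds.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# FASTQ (Phred+33)


def read_fastq(path: str | Path) -> Iterator[FastqRead]:
    """Stream 4-line FASTQ records with Phred+33 qualities."""
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            yield FastqRead(
                id=rec.id,
                seq=str(rec.seq).upper(),
                quals=list(rec.letter_annotations["phred_quality"]),
            )
    except ValueError as exc:  # Biopython names the offending record
        raise FormatError(f"{path}: {exc}") from exc


def write_fastq(reads: Iterable[FastqRead], path: str | Path) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.seq), id=r.id, description="")
        rec.letter_annotations["phred_quality"] = list(r.quals)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


# ---------------------------------------------------------------------------
# SAM

_XG_TO_STRAND = {"CT": ORIGINAL_TOP, "GA": ORIGINAL_BOTTOM}
_STRAND_TO_XG = {v: k for k, v in _XG_TO_STRAND.items()}
_CIGAR_OPS = {0: "M", 1: "I", 2: "D", 7: "M", 8: "M"}


def read_alignments(
    path: str | Path,
    genome: Optional[Genome] = None,
    stats: Optional[dict] = None,
) -> Iterator[AlignedRead]:
    """Stream mapped records from a SAM file.

    SAM 1-based POS is converted to the internal 0-based convention.
    Unmapped and secondary/supplementary records are skipped (counted in
    ``stats`` if a dict is supplied).  A read is flagged non-unique when
    MAPQ == 0 or an XS secondary-hit tag is present.  The Bismark-style
    ``XG:Z:CT`` / ``XG:Z:GA`` tag gives the conversion strand; absent tag
    means a conventional DNA read.
    """
    if stats is None:
        stats = {}
    stats.setdefault("skipped_unmapped", 0)
    stats.setdefault("skipped_secondary", 0)
    stats.setdefault("parsed", 0)
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                stats["skipped_unmapped"] += 1
                continue
            if rec.is_secondary or rec.is_supplementary:
                stats["skipped_secondary"] += 1
                continue
            if genome is not None and rec.reference_name not in genome:
                raise FormatError(
                    f"{path}: read {rec.query_name!r} mapped to unknown "
                    f"scaffold {rec.reference_name!r}"
                )
            cigar: list[tuple[str, int]] = []
            for op, n in rec.cigartuples or []:
                if op not in _CIGAR_OPS:
                    raise FormatError(
                        f"{path}: read {rec.query_name!r} has unsupported "
                        f"CIGAR operation code {op}"
                    )
                cigar.append((_CIGAR_OPS[op], n))
            conv = None
            if rec.has_tag("XG"):
                xg = rec.get_tag("XG")
                if xg not in _XG_TO_STRAND:
                    raise FormatError(
                        f"{path}: read {rec.query_name!r} has unknown "
                        f"XG tag value {xg!r}"
                    )
                conv = _XG_TO_STRAND[xg]
            unique = not (rec.mapping_quality == 0 or rec.has_tag("XS"))
            read = AlignedRead(
                read_id=rec.query_name,
                scaffold=rec.reference_name,
                start=rec.reference_start,
                strand="-" if rec.is_reverse else "+",
                seq=(rec.query_sequence or "").upper(),
                quals=list(rec.query_qualities or []),
                cigar=cigar,
                conversion_strand=conv,
                mate_id=rec.query_name if rec.is_paired else None,
                unique=unique,
            )
            if genome is not None and read.end > len(genome[read.scaffold]):
                raise FormatError(
                    f"{path}: read {rec.query_name!r} extends past the end "
                    f"of scaffold {read.scaffold!r}"
                )
            stats["parsed"] += 1
            yield read


def write_sam(
    reads: Iterable[AlignedRead], genome: Genome, path: str | Path
) -> None:
    """Write reads as plain SAM with an @SQ header built from the genome."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [
            {"SN": name, "LN": length}
            for name, length in genome.lengths.items()
        ],
    }
    tids = {name: i for i, name in enumerate(genome.lengths)}
    op_code = {"M": 0, "I": 1, "D": 2}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for r in reads:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = r.read_id
            seg.query_sequence = r.seq
            seg.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in r.quals)
            )
            seg.reference_id = tids[r.scaffold]
            seg.reference_start = r.start
            seg.mapping_quality = 40 if r.unique else 0
            seg.cigartuples = [(op_code[op], n) for op, n in r.cigar]
            flag = 0
            if r.strand == "-":
                flag |= 0x10
            if r.mate_id is not None:
                flag |= 0x1
            seg.flag = flag
            tags = []
            if r.conversion_strand is not None:
                tags.append(("XG", _STRAND_TO_XG[r.conversion_strand]))
            if not r.unique:
                tags.append(("XS", 1))
            seg.set_tags(tags)
            out.write(seg)


# ---------------------------------------------------------------------------
# Regions: BED / GFF3


def _infer_fmt(path: str | Path) -> str:
    suffix = Path(path).suffix.lower()
    if suffix in (".bed",):
        return "bed"
    if suffix in (".gff", ".gff3"):
        return "gff3"
    raise FormatError(f"cannot infer region format from {path}")


def read_regions(path: str | Path, fmt: Optional[str] = None) -> list[Region]:
    """Read regions from BED (0-based half-open) or GFF3 (1-based inclusive).

    GFF3 coordinates are shifted to the internal convention.  The GFF3
    ``type`` column / BED name prefix maps onto the Region kind vocabulary
    when it matches; everything else becomes ``other``.
    """
    fmt = fmt or _infer_fmt(path)
    regions: list[Region] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            try:
                if fmt == "bed":
                    scaffold = cols[0]
                    start, end = int(cols[1]), int(cols[2])
                    name = cols[3] if len(cols) > 3 else ""
                    strand = cols[5] if len(cols) > 5 else "."
                    kind = name if name in REGION_KINDS else "other"
                elif fmt == "gff3":
                    scaffold = cols[0]
                    kind_raw = cols[2].lower()
                    start, end = int(cols[3]) - 1, int(cols[4])
                    strand = cols[6]
                    kind = kind_raw if kind_raw in REGION_KINDS else "other"
                    m = re.search(r"(?:ID|Name)=([^;]+)", cols[8]) if len(cols) > 8 else None
                    name = m.group(1) if m else ""
                else:
                    raise FormatError(f"unknown region format {fmt!r}")
            except (IndexError, ValueError) as exc:
                raise FormatError(f"{path}:{lineno}: malformed {fmt} line") from exc
            if start >= end:
                raise FormatError(
                    f"{path}:{lineno}: start {start} >= end {end} after "
                    "coordinate conversion"
                )
            if strand == ".":
                strand = "."
            regions.append(
                Region(scaffold=scaffold, start=start, end=end, strand=strand,
                       kind=kind, name=name)
            )
    return regions


def write_bed(regions: Iterable[Region], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            name = r.name or r.kind
            fh.write(f"{r.scaffold}\t{r.start}\t{r.end}\t{name}\t0\t{r.strand}\n")


def write_gff3(regions: Iterable[Region], path: str | Path, source: str = "mebs") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in regions:
            attrs = f"ID={r.name}" if r.name else "."
            fh.write(
                f"{r.scaffold}\t{source}\t{r.kind}\t{r.start + 1}\t{r.end}\t."
                f"\t{r.strand}\t.\t{attrs}\n"
            )


def write_bedgraph(
    entries: Iterable[tuple[str, int, int, float]],
    path: str | Path,
    track_name: str = "",
) -> None:
    """Write (scaffold, start, end, value) tuples as bedGraph."""
    with open(path, "w") as fh:
        if track_name:
            fh.write(f'track type=bedGraph name="{track_name}"\n')
        for scaffold, start, end, value in entries:
            fh.write(f"{scaffold}\t{start}\t{end}\t{value:g}\n")
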