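"""Ground-truth simulator for the whole pipeline.

Generates a genome with CpG-rich islands and gene models, a bimodal truth
methylome (hypo- and hypermethylated domains), methyl-CpG-binding-domain
(MBD) capture biased toward methylated fragments, directional bisulfite
conversion, and paired 90 bp reads with base-call errors — everything the
other modules consume, with the truth recorded so closed-loop recovery can
be tested without any external data.

Model choices, in brief:

* CpG methylation is realized symmetrically on both strands of a CpG (as
  maintenance methylation makes it); CHG/CHH sites are independent
  per-strand Bernoulli draws at low global rates.
* Capture is driven by the fragment's methylated-CpG count ``m`` through a
  logistic curve sigma(m) = 1/(1+exp(-k(m - m0))); the default curve gives
  single-mC fragments substantial capture probability.  Fragments with no
  methylated CpG enter the library only through the unmethylated
  contamination branch (a configurable fraction of captured fragments drawn
  from realized fully-unmethylated molecules), so the contamination
  parameter is directly the expected unmethylated share of the library.
* Bisulfite conversion turns each unmethylated C into T with probability
  1 - conversion_failure; methylated Cs are untouched.  The directional
  protocol sequences the converted original top or bottom strand of each
  fragment (chosen 50/50), so each fragment informs cytosines on one strand.
* Sequenced fragment lengths follow a truncated normal reflecting a
  size-selected library (mean 134 bp on [100, 200]); reads are 90 bp pairs.

Everything is driven by one seeded numpy Generator: identical config + seed
gives byte-identical outputs.
"""
from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np
import pandas as pd

from .io_formats import (
    ORIGINAL_BOTTOM,
    ORIGINAL_TOP,
    AlignedRead,
    FastqRead,
    Genome,
    Region,
    revcomp,
)
from .reference_builder import PileupColumn

_BASE_CODES = np.frombuffer(b"ACGT", dtype=np.uint8)
_A, _C, _G, _T, _N = (ord(x) for x in "ACGTN")

# context codes in the packed arrays
CTX_CG, CTX_CHG, CTX_CHH, CTX_UNKNOWN = 0, 1, 2, 3
_CTX_NAMES = {CTX_CG: "CG", CTX_CHG: "CHG", CTX_CHH: "CHH", CTX_UNKNOWN: "unknown"}


@dataclass
class SimConfig:
    """All tunable knobs of the simulator.  ``seed`` is mandatory."""

    seed: int
    # genome
    genome_length: int = 200_000
    n_scaffolds: int = 2
    background_gc: float = 0.40
    # planted CpG islands
    n_cgis: int = 10
    cgi_length_mean: int = 800
    cgi_length_sd: int = 100
    cgi_cpg_rate: float = 0.20
    cgi_gc: float = 0.60
    # planted genes
    n_genes: int = 20
    gene_span: int = 4000
    # methylome
    cg_hyper: float = 0.90
    cg_hypo: float = 0.02
    chg_rate: float = 0.003
    chh_rate: float = 0.004
    hyper_fraction: float = 0.5
    cgi_hyper_fraction: float = 0.5
    domain_min: int = 2000
    domain_max: int = 8000
    # MBD capture
    capture_midpoint: float = 1.0
    capture_steepness: float = 1.2
    contamination: float = 0.0126
    # bisulfite + sequencing
    conversion_failure: float = 0.005
    n_fragments: int = 20_000
    fragment_mean: float = 134.0
    fragment_sd: float = 30.0
    fragment_min: int = 100
    fragment_max: int = 200
    read_length: int = 90
    error_rate: float = 0.001
    # relative genome (consensus-building inputs)
    snv_rate: float = 0.01
    indel_rate: float = 0.001
    relative_depth: int = 10

    def __post_init__(self) -> None:
        rates = (
            self.background_gc, self.cgi_cpg_rate, self.cgi_gc, self.cg_hyper,
            self.cg_hypo, self.chg_rate, self.chh_rate, self.hyper_fraction,
            self.cgi_hyper_fraction, self.contamination,
            self.conversion_failure, self.error_rate, self.snv_rate,
            self.indel_rate,
        )
        if any(not 0.0 <= r <= 1.0 for r in rates):
            raise ValueError("all rates must lie in [0, 1]")
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if self.fragment_min < self.read_length:
            raise ValueError("fragments shorter than the read length are not modelled")

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown simulator config keys: {sorted(unknown)}")
        return cls(**d)


def capture_probability(m: np.ndarray | float, cfg: SimConfig) -> np.ndarray | float:
    """Logistic capture probability as a function of methylated-CpG count."""
    return 1.0 / (1.0 + np.exp(-cfg.capture_steepness * (np.asarray(m, dtype=float) - cfg.capture_midpoint)))


# ---------------------------------------------------------------------------
# context classification (vectorized, matches methylation_caller.classify_context)


def context_code_arrays(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-position context codes for top (+) and bottom (-) strand Cs.

    -1 marks positions that are not a C on that strand.
    """
    L = len(arr)
    plus = np.full(L, -1, dtype=np.int8)
    minus = np.full(L, -1, dtype=np.int8)
    isc = arr == _C
    isg = arr == _G
    b1 = np.zeros(L, dtype=np.uint8)
    b2 = np.zeros(L, dtype=np.uint8)
    if L > 1:
        b1[:-1] = arr[1:]
    if L > 2:
        b2[:-2] = arr[2:]
    plus[isc] = CTX_UNKNOWN
    plus[isc & (b1 == _G)] = CTX_CG
    non_g = isc & (b1 != _G) & (b1 != _N) & (b1 != 0)
    valid2 = (b2 != 0) & (b2 != _N)
    plus[non_g & valid2 & (b2 == _G)] = CTX_CHG
    plus[non_g & valid2 & (b2 != _G)] = CTX_CHH
    p1 = np.zeros(L, dtype=np.uint8)
    p2 = np.zeros(L, dtype=np.uint8)
    if L > 1:
        p1[1:] = arr[:-1]
    if L > 2:
        p2[2:] = arr[:-2]
    minus[isg] = CTX_UNKNOWN
    minus[isg & (p1 == _C)] = CTX_CG
    non_c = isg & (p1 != _C) & (p1 != _N) & (p1 != 0)
    valid2m = (p2 != 0) & (p2 != _N)
    minus[non_c & valid2m & (p2 == _C)] = CTX_CHG
    minus[non_c & valid2m & (p2 != _C)] = CTX_CHH
    return plus, minus


# ---------------------------------------------------------------------------
# genome


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASE_CODES[rng.choice(4, size=n, p=p)]


def _cgi_sequence(rng: np.random.Generator, length: int, cfg: SimConfig) -> np.ndarray:
    """CpG-dense island sequence: emit CG dinucleotides at cgi_cpg_rate."""
    out = np.empty(length + 1, dtype=np.uint8)
    i = 0
    emit_cg = rng.random(length) < cfg.cgi_cpg_rate
    singles = _random_bases(rng, length, cfg.cgi_gc)
    for k in range(length):
        if i >= length:
            break
        if emit_cg[k] and i + 1 < length:
            out[i] = _C
            out[i + 1] = _G
            i += 2
        else:
            out[i] = singles[k]
            i += 1
    return out[:length]


def simulate_genome(
    cfg: SimConfig, rng: Optional[np.random.Generator] = None
) -> tuple[Genome, dict[str, list[Region]]]:
    """Background genome with planted CGIs and gene models.

    Returns the genome and the planted truth regions keyed by kind
    ('cgi', 'tss', 'gene', 'exon').
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    per_scaffold = cfg.genome_length // cfg.n_scaffolds
    if cfg.n_cgis and per_scaffold < cfg.cgi_length_mean * 3:
        raise ValueError("planted regions exceed the genome length")
    regions: dict[str, list[Region]] = {"cgi": [], "tss": [], "gene": [], "exon": []}
    scaffolds: dict[str, str] = {}
    cgi_counts = _split_count(cfg.n_cgis, cfg.n_scaffolds)
    gene_counts = _split_count(cfg.n_genes, cfg.n_scaffolds)
    for s in range(cfg.n_scaffolds):
        name = f"scaf{s + 1}"
        arr = _random_bases(rng, per_scaffold, cfg.background_gc)
        # plant CGIs at evenly spaced, jittered anchors
        n_cgi = cgi_counts[s]
        margin = 1000
        if n_cgi:
            anchors = np.linspace(margin, per_scaffold - margin - 2 * cfg.cgi_length_mean,
                                  n_cgi).astype(int)
            for a in anchors:
                length = int(np.clip(rng.normal(cfg.cgi_length_mean, cfg.cgi_length_sd),
                                     300, 2 * cfg.cgi_length_mean))
                start = int(a + rng.integers(0, 200))
                end = start + length
                if end > per_scaffold:
                    raise ValueError("planted CGI exceeds the scaffold length")
                arr[start:end] = _cgi_sequence(rng, length, cfg)
                regions["cgi"].append(
                    Region(name, start, end, ".", "cgi", f"{name}_cgi_{start}")
                )
        # plant gene models
        for _ in range(gene_counts[s]):
            strand = "+" if rng.random() < 0.5 else "-"
            tss = int(rng.integers(cfg.gene_span + 100,
                                   per_scaffold - cfg.gene_span - 100))
            if strand == "+":
                gstart, gend = tss, tss + cfg.gene_span
            else:
                gstart, gend = tss - cfg.gene_span + 1, tss + 1
            gene_name = f"{name}_gene_{tss}"
            regions["tss"].append(Region(name, tss, tss + 1, strand, "tss", gene_name))
            regions["gene"].append(Region(name, gstart, gend, strand, "gene", gene_name))
            n_exons = int(rng.integers(2, 5))
            starts = np.sort(rng.choice(cfg.gene_span - 400, size=n_exons, replace=False))
            last_end = gstart
            for k, off in enumerate(starts):
                es = max(gstart + int(off), last_end)
                ee = min(es + int(rng.integers(100, 400)), gend)
                if ee <= es:
                    continue
                regions["exon"].append(
                    Region(name, es, ee, strand, "exon", f"{gene_name}_ex{k}")
                )
                last_end = ee
        scaffolds[name] = arr.tobytes().decode()
    return Genome(scaffolds), regions


def _split_count(total: int, parts: int) -> list[int]:
    base = total // parts
    out = [base] * parts
    for i in range(total - base * parts):
        out[i] += 1
    return out


# ---------------------------------------------------------------------------
# methylome


@dataclass
class Methylome:
    """Per-strand-cytosine truth methylation probabilities.

    ``prob_plus[scaffold][i]`` is the Bernoulli parameter of the top-strand C
    at position i (NaN where there is no C); ``context_plus`` holds packed
    context codes (-1 = not a C).  ``hyper_mask`` marks hypermethylated
    positions; ``hyper_regions`` lists them as intervals.
    """

    prob_plus: dict[str, np.ndarray]
    prob_minus: dict[str, np.ndarray]
    context_plus: dict[str, np.ndarray]
    context_minus: dict[str, np.ndarray]
    hyper_mask: dict[str, np.ndarray]
    hyper_regions: list[Region] = field(default_factory=list)

    def truth_probability(self, scaffold: str, pos: int, strand: str) -> float:
        arr = self.prob_plus if strand == "+" else self.prob_minus
        return float(arr[scaffold][pos])


def simulate_methylome(
    genome: Genome,
    regions: dict[str, list[Region]],
    cfg: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> Methylome:
    """Assign every strand-C its context-specific truth probability.

    The genome is tiled into hypo/hyper domains (hyper with probability
    ``hyper_fraction``); planted CGIs override their domain, each being
    hyper with probability ``cgi_hyper_fraction``.  CpG probabilities are
    strand-symmetric; CHG/CHH use the global low rates everywhere.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    prob_plus: dict[str, np.ndarray] = {}
    prob_minus: dict[str, np.ndarray] = {}
    ctx_plus: dict[str, np.ndarray] = {}
    ctx_minus: dict[str, np.ndarray] = {}
    hyper_mask: dict[str, np.ndarray] = {}
    hyper_regions: list[Region] = []
    cgis_by_scaffold: dict[str, list[Region]] = {}
    for r in regions.get("cgi", []):
        cgis_by_scaffold.setdefault(r.scaffold, []).append(r)
    for name, seq in genome.scaffolds.items():
        L = len(seq)
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        cp, cm = context_code_arrays(arr)
        mask = np.zeros(L, dtype=bool)
        pos = 0
        while pos < L:
            dl = int(rng.integers(cfg.domain_min, cfg.domain_max + 1))
            if rng.random() < cfg.hyper_fraction:
                mask[pos : pos + dl] = True
            pos += dl
        for cgi in cgis_by_scaffold.get(name, []):
            mask[cgi.start : cgi.end] = rng.random() < cfg.cgi_hyper_fraction
        runs = _mask_to_regions(mask, name)
        hyper_regions.extend(runs)
        pp = np.full(L, np.nan, dtype=np.float64)
        pm = np.full(L, np.nan, dtype=np.float64)
        pp[cp >= 0] = cfg.chh_rate  # default for unknown-context Cs
        pm[cm >= 0] = cfg.chh_rate
        pp[cp == CTX_CHG] = cfg.chg_rate
        pm[cm == CTX_CHG] = cfg.chg_rate
        pp[cp == CTX_CHH] = cfg.chh_rate
        pm[cm == CTX_CHH] = cfg.chh_rate
        cg_p = cp == CTX_CG
        pp[cg_p] = np.where(mask[cg_p], cfg.cg_hyper, cfg.cg_hypo)
        cg_m = cm == CTX_CG
        # symmetric with the paired top-strand C one base to the left
        pair_mask = np.zeros(L, dtype=bool)
        pair_mask[1:] = mask[:-1]
        pair_mask[0] = mask[0]
        pm[cg_m] = np.where(pair_mask[cg_m], cfg.cg_hyper, cfg.cg_hypo)
        prob_plus[name] = pp
        prob_minus[name] = pm
        ctx_plus[name] = cp
        ctx_minus[name] = cm
        hyper_mask[name] = mask
    return Methylome(prob_plus, prob_minus, ctx_plus, ctx_minus, hyper_mask,
                     hyper_regions)


def _mask_to_regions(mask: np.ndarray, scaffold: str) -> list[Region]:
    out = []
    diff = np.diff(mask.astype(np.int8))
    starts = list(np.where(diff == 1)[0] + 1)
    ends = list(np.where(diff == -1)[0] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask))
    for s, e in zip(starts, ends):
        out.append(Region(scaffold, int(s), int(e), ".", "other", "hyper"))
    return out


# ---------------------------------------------------------------------------
# capture + bisulfite + reads


@dataclass
class SimulatedLibrary:
    """One captured, bisulfite-converted, sequenced library with its truth."""

    r1: list[FastqRead]
    r2: list[FastqRead]
    truth_reads: list[AlignedRead]
    fragments: pd.DataFrame
    truth_context_counts: dict[str, list[int]]  # context -> [meth, unmeth]
    candidates_drawn: int


def simulate_capture_and_reads(
    genome: Genome,
    methylome: Methylome,
    cfg: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> SimulatedLibrary:
    """Draw captured fragments and sequence them as directional PE reads.

    Per captured fragment the truth table records the realized methylated
    CpG count, whether it entered via the contamination branch, and the
    molecule states at read-observed cytosine sites (the pre-sequencing-
    error expectation the caller should recover).
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 2)
    if cfg.n_fragments == 0:
        warnings.warn("empty capture set requested; outputs are empty")
        empty = pd.DataFrame(
            columns=["fragment_id", "scaffold", "start", "length", "conv_strand",
                     "m_cpg", "m_total", "contaminant", "n_observed",
                     "n_observed_meth"]
        )
        return SimulatedLibrary([], [], [], empty, {c: [0, 0] for c in ("CG", "CHG", "CHH", "unknown")}, 0)

    names = list(genome.scaffolds)
    arrs = {n: np.frombuffer(genome[n].encode(), dtype=np.uint8) for n in names}
    lengths = np.array([len(arrs[n]) for n in names], dtype=float)
    weights = lengths / lengths.sum()

    r1: list[FastqRead] = []
    r2: list[FastqRead] = []
    truth_reads: list[AlignedRead] = []
    frag_rows = []
    ctx_counts = {c: [0, 0] for c in ("CG", "CHG", "CHH", "unknown")}
    candidates = 0

    for idx in range(cfg.n_fragments):
        contaminant = bool(rng.random() < cfg.contamination)
        for _attempt in range(100_000):
            candidates += 1
            si = int(rng.choice(len(names), p=weights))
            name = names[si]
            arr = arrs[name]
            L = int(np.clip(round(rng.normal(cfg.fragment_mean, cfg.fragment_sd)),
                            cfg.fragment_min, cfg.fragment_max))
            if L >= len(arr):
                continue
            s = int(rng.integers(0, len(arr) - L + 1))
            e = s + L
            cp = methylome.context_plus[name][s:e]
            cm = methylome.context_minus[name][s:e]
            pp = methylome.prob_plus[name][s:e]
            pm = methylome.prob_minus[name][s:e]
            plus_sites = np.where(cp >= 0)[0]
            minus_sites = np.where(cm >= 0)[0]
            meth_plus = rng.random(plus_sites.size) < pp[plus_sites]
            # bottom CpGs copy their paired top draw; everything else draws
            meth_plus_full = np.zeros(L, dtype=bool)
            meth_plus_full[plus_sites] = meth_plus
            minus_draws = rng.random(minus_sites.size) < pm[minus_sites]
            paired = (cm[minus_sites] == CTX_CG) & (minus_sites >= 1)
            meth_minus = np.where(paired, meth_plus_full[np.maximum(minus_sites - 1, 0)],
                                  minus_draws)
            m_cpg = int(meth_plus[cp[plus_sites] == CTX_CG].sum())
            m_cpg += int(meth_minus[(cm[minus_sites] == CTX_CG) & ~paired].sum())
            m_total = int(meth_plus.sum()) + int(meth_minus.sum())
            if contaminant:
                if m_total == 0:
                    break
            else:
                if m_cpg >= 1 and rng.random() < capture_probability(m_cpg, cfg):
                    break
        else:
            raise RuntimeError("could not draw a fragment satisfying the capture branch")

        conv = ORIGINAL_TOP if rng.random() < 0.5 else ORIGINAL_BOTTOM
        mol = arr[s:e].copy()
        if conv == ORIGINAL_TOP:
            sites, meth, ctx = plus_sites, meth_plus, cp
            converted_char, strand = _T, "+"
        else:
            sites, meth, ctx = minus_sites, meth_minus, cm
            converted_char, strand = _A, "-"
        conv_draws = rng.random(sites.size) < (1.0 - cfg.conversion_failure)
        converted = (~meth) & conv_draws
        mol[sites[converted]] = converted_char
        reads_meth_state = ~converted  # reads as C (methylated or failed conversion)

        rl = min(cfg.read_length, L)
        w1 = (0, rl)
        w2 = (L - rl, L)
        frag_id = f"frag{idx:07d}"
        covered = np.zeros(L, dtype=bool)
        covered[w1[0] : w1[1]] = True
        covered[w2[0] : w2[1]] = True
        obs = covered[sites]
        n_observed = int(obs.sum())
        n_observed_meth = int((obs & reads_meth_state).sum())
        for code, state in zip(ctx[sites[obs]], reads_meth_state[obs]):
            ctx_counts[_CTX_NAMES[int(code)]][0 if state else 1] += 1

        mate_seqs = []
        for (ws, we) in (w1, w2):
            piece = mol[ws:we].copy()
            err = rng.random(we - ws) < cfg.error_rate
            if err.any():
                where = np.where(err)[0]
                idx_now = np.searchsorted(_BASE_CODES, piece[where])
                # N or exotic bases do not occur in simulated genomes
                shift = rng.integers(1, 4, size=where.size)
                piece[where] = _BASE_CODES[(idx_now + shift) % 4]
            mate_seqs.append(piece)
        quals = [list(rng.integers(33, 41, rl)) for _ in range(2)]
        seqs_top = [m.tobytes().decode() for m in mate_seqs]
        strands = ("+", "-") if conv == ORIGINAL_TOP else ("-", "+")
        for k, (ws, we) in enumerate((w1, w2)):
            truth_reads.append(
                AlignedRead(
                    read_id=frag_id,
                    scaffold=name,
                    start=s + ws,
                    strand=strands[k],
                    seq=seqs_top[k],
                    quals=[int(q) for q in quals[k]],
                    cigar=[("M", rl)],
                    conversion_strand=conv,
                    mate_id=frag_id,
                    unique=True,
                )
            )
        # FASTQ in sequencing orientation: read 1 starts at the 5' end of the
        # sequenced (converted original) strand
        if conv == ORIGINAL_TOP:
            fq1 = seqs_top[0]
            fq2 = revcomp(seqs_top[1])
            q1, q2 = quals[0], quals[1][::-1]
        else:
            fq1 = revcomp(seqs_top[1])
            fq2 = seqs_top[0]
            q1, q2 = quals[1][::-1], quals[0]
        r1.append(FastqRead(f"{frag_id}/1", fq1, [int(q) for q in q1]))
        r2.append(FastqRead(f"{frag_id}/2", fq2, [int(q) for q in q2]))
        frag_rows.append(
            (frag_id, name, s, L, conv, m_cpg, m_total, contaminant,
             n_observed, n_observed_meth)
        )

    fragments = pd.DataFrame(
        frag_rows,
        columns=["fragment_id", "scaffold", "start", "length", "conv_strand",
                 "m_cpg", "m_total", "contaminant", "n_observed",
                 "n_observed_meth"],
    )
    return SimulatedLibrary(r1, r2, truth_reads, fragments, ctx_counts, candidates)


# ---------------------------------------------------------------------------
# relative genome + pileup


@dataclass
class RelativeGenome:
    """A mutated relative of the source genome plus consensus-builder inputs."""

    genome: Genome
    variants: pd.DataFrame  # scaffold, pos, kind, ref, alt
    deleted: dict[str, np.ndarray]  # bool per source position
    insertions: dict[str, dict[int, str]]  # anchored after source position
    snv_base: dict[str, np.ndarray]  # mutated base code per retained position
    depth: int

    def pileup_columns(self, depth: Optional[int] = None) -> Iterator[PileupColumn]:
        """Pileup of the relative's reads against the source, at uniform depth.

        Columns reflect the exact source<->mutant alignment: every source
        position is observed ``depth`` times showing the mutated base (or a
        deletion), and accepted insertions are seen by all reads crossing
        the junction.
        """
        d = self.depth if depth is None else depth
        for name, dele in self.deleted.items():
            bases = self.snv_base[name]
            ins = self.insertions[name]
            for pos in range(len(dele)):
                if dele[pos]:
                    col = PileupColumn(name, pos, ref_base=chr(bases[pos]),
                                       deletion_count=d)
                else:
                    col = PileupColumn(name, pos,
                                       base_counts={chr(bases[pos]): d})
                if pos in ins:
                    col.insertion_counts = {ins[pos]: d}
                yield col


def simulate_relative(
    genome: Genome,
    cfg: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> RelativeGenome:
    """Mutate the genome with SNVs and short indels and derive its pileup.

    SNVs are drawn per position at ``snv_rate``; indel events at
    ``indel_rate`` (insertion or deletion of 1-3 bp, non-overlapping).  With
    both rates 0 the relative is the source and the consensus rebuild is an
    identity.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 3)
    scaffolds: dict[str, str] = {}
    rows = []
    deleted: dict[str, np.ndarray] = {}
    insertions: dict[str, dict[int, str]] = {}
    snv_base: dict[str, np.ndarray] = {}
    for name, seq in genome.scaffolds.items():
        arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
        L = len(arr)
        snv_pos = np.where(rng.random(L) < cfg.snv_rate)[0]
        # never mutate N positions; shift each SNV base to a different one
        snv_pos = snv_pos[arr[snv_pos] != _N]
        old_idx = np.searchsorted(_BASE_CODES, arr[snv_pos])
        arr[snv_pos] = _BASE_CODES[(old_idx + rng.integers(1, 4, snv_pos.size)) % 4]
        for p in snv_pos:
            rows.append((name, int(p), "snv", seq[p], chr(arr[p])))

        dele = np.zeros(L, dtype=bool)
        ins: dict[int, str] = {}
        indel_pos = np.where(rng.random(L) < cfg.indel_rate)[0]
        busy_until = -1
        for p in indel_pos:
            p = int(p)
            if p <= busy_until or p >= L - 5:
                continue
            ilen = int(rng.integers(1, 4))
            if rng.random() < 0.5:
                ins_seq = _random_bases(rng, ilen, cfg.background_gc).tobytes().decode()
                ins[p] = ins_seq
                rows.append((name, p, "ins", "", ins_seq))
                busy_until = p
            else:
                dele[p : p + ilen] = True
                rows.append((name, p, "del", seq[p : p + ilen], ""))
                busy_until = p + ilen - 1

        pieces: list[bytes] = []
        keep = ~dele
        pos = 0
        boundary = sorted(ins)
        for anchor in boundary:
            seg = arr[pos : anchor + 1]
            pieces.append(seg[keep[pos : anchor + 1]].tobytes())
            pieces.append(ins[anchor].encode())
            pos = anchor + 1
        seg = arr[pos:]
        pieces.append(seg[keep[pos:]].tobytes())
        scaffolds[name] = b"".join(pieces).decode()
        deleted[name] = dele
        insertions[name] = ins
        snv_base[name] = arr
    variants = pd.DataFrame(rows, columns=["scaffold", "pos", "kind", "ref", "alt"])
    return RelativeGenome(Genome(scaffolds), variants, deleted, insertions,
                          snv_base, cfg.relative_depth)


# ---------------------------------------------------------------------------
# planted QC dataset


@dataclass
class QcSimParams:
    n_pairs: int = 1000
    read_length: int = 90
    adapter: str = "AGATCGGAAGAGC"
    n_adapter: int = 50
    n_nrich: int = 30
    n_lowqual: int = 20
    n_boundary_n: int = 5
    n_boundary_q: int = 5
    base_qual: int = 38
    low_qual: int = 10


def simulate_qc_dataset(
    params: QcSimParams, rng: np.random.Generator
) -> tuple[list[FastqRead], list[FastqRead], dict[str, int]]:
    """Paired FASTQ with planted, disjoint filter failures.

    Failures are planted in mate 1 of distinct pairs: ``n_adapter`` reads
    contain the adapter, ``n_nrich`` carry just over 10% Ns, ``n_lowqual``
    just over 10% sub-Q20 bases.  Boundary reads sit exactly at 10% and must
    be kept under the strict "more than" rule.  Returns (r1, r2, truth
    counts).
    """
    p = params
    total_planted = p.n_adapter + p.n_nrich + p.n_lowqual + p.n_boundary_n + p.n_boundary_q
    if total_planted > p.n_pairs:
        raise ValueError("more planted reads than pairs")
    rl = p.read_length
    over = max(int(np.ceil(rl * 0.10)) + 1, 1)        # strictly more than 10%
    at = int(np.floor(rl * 0.10))                     # exactly at the boundary
    r1: list[FastqRead] = []
    r2: list[FastqRead] = []
    kinds = (["adapter"] * p.n_adapter + ["nrich"] * p.n_nrich
             + ["lowqual"] * p.n_lowqual + ["boundary_n"] * p.n_boundary_n
             + ["boundary_q"] * p.n_boundary_q
             + ["clean"] * (p.n_pairs - total_planted))
    order = rng.permutation(len(kinds))
    for i, ki in enumerate(order):
        kind = kinds[ki]
        seq = _random_bases(rng, rl, 0.5)
        quals = np.full(rl, p.base_qual, dtype=int)
        if kind == "adapter":
            pos = int(rng.integers(0, rl - len(p.adapter)))
            seq[pos : pos + len(p.adapter)] = np.frombuffer(
                p.adapter.encode(), dtype=np.uint8
            )
        elif kind in ("nrich", "boundary_n"):
            k = over if kind == "nrich" else at
            where = rng.choice(rl, size=k, replace=False)
            seq[where] = _N
        elif kind in ("lowqual", "boundary_q"):
            k = over if kind == "lowqual" else at
            where = rng.choice(rl, size=k, replace=False)
            quals[where] = p.low_qual
        r1.append(FastqRead(f"pair{i:05d}/1", seq.tobytes().decode(), list(map(int, quals))))
        mate = _random_bases(rng, rl, 0.5)
        r2.append(FastqRead(f"pair{i:05d}/2", mate.tobytes().decode(),
                            [p.base_qual] * rl))
    truth = {
        "adapter": p.n_adapter,
        "nrich": p.n_nrich,
        "lowqual": p.n_lowqual,
        "boundary": p.n_boundary_n + p.n_boundary_q,
        "clean": p.n_pairs - total_planted,
    }
    return r1, r2, truth
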