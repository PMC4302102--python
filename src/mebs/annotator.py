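"""CpG-island detection and promoter annotation.

Islands follow the classic sliding-window definition: a region of at least
``min_length`` bp whose GC content is at least ``min_gc`` percent and whose
observed/expected CpG ratio

    ObsExp = (N_CpG * L) / (N_C * N_G)

is at least ``min_obs_exp`` (0 when either N_C or N_G is zero).  The search
slides a ``window``-sized seed 1 bp at a time; qualifying seeds whose
windows chain with gaps below one window form a candidate cluster (the
merge rule), and each cluster is reduced to its longest sub-span that still
meets both criteria at ``min_length`` or more.  This is the exhaustive form
of the classic seed-extend-rollback procedure: the jump-based extension
heuristic can strand a qualifying island when one extension window fails,
whereas the cluster scan cannot, and boundaries agree with other
implementations to within one window.

Windows containing N are never seeds and stop extension, so islands cannot
bridge long runs of undetermined sequence (a consensus genome can be N-rich).

Promoters are the 2 kb immediately upstream of a transcription start site on
its own strand, clipped at scaffold bounds.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .io_formats import Genome, Region


@dataclass
class CgiParams:
    min_gc: float = 55.0
    min_obs_exp: float = 0.65
    min_length: int = 500
    window: int = 200

    def __post_init__(self) -> None:
        if self.window > self.min_length:
            raise ValueError("window must not exceed min_length")
        if min(self.min_gc, self.min_obs_exp, self.min_length, self.window) <= 0:
            raise ValueError("all CGI parameters must be positive")


@dataclass
class CpgIsland:
    region: Region
    gc_percent: float
    obs_exp: float
    cpg_count: int

    @property
    def start(self) -> int:
        return self.region.start

    @property
    def end(self) -> int:
        return self.region.end


class _SeqProfile:
    """Prefix-sum view of a sequence for O(1) window criteria checks."""

    def __init__(self, seq: str):
        arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
        c = arr == ord("C")
        g = arr == ord("G")
        n = arr == ord("N")
        cpg = np.zeros(len(arr), dtype=bool)
        if len(arr) > 1:
            cpg[:-1] = c[:-1] & g[1:]
        self.len = len(arr)
        # prefix[i] = count in seq[:i]
        self.c = np.concatenate(([0], np.cumsum(c)))
        self.g = np.concatenate(([0], np.cumsum(g)))
        self.n = np.concatenate(([0], np.cumsum(n)))
        self.cpg = np.concatenate(([0], np.cumsum(cpg)))

    def counts(self, start: int, end: int) -> tuple[int, int, int, int]:
        """(N_C, N_G, N_CpG, N_N) over [start, end); CpGs counted within."""
        nc = int(self.c[end] - self.c[start])
        ng = int(self.g[end] - self.g[start])
        nn = int(self.n[end] - self.n[start])
        # exclude a CpG whose G falls outside the span
        ncpg = int(self.cpg[max(end - 1, start)] - self.cpg[start])
        return nc, ng, ncpg, nn

    def metrics(self, start: int, end: int) -> tuple[float, float, int]:
        nc, ng, ncpg, _ = self.counts(start, end)
        length = end - start
        gc = 100.0 * (nc + ng) / length
        obs_exp = (ncpg * length) / (nc * ng) if nc and ng else 0.0
        return gc, obs_exp, ncpg

    def qualifies(self, start: int, end: int, p: CgiParams) -> bool:
        nc, ng, ncpg, nn = self.counts(start, end)
        if nn > 0:
            return False
        length = end - start
        gc = 100.0 * (nc + ng) / length
        if gc < p.min_gc:
            return False
        obs_exp = (ncpg * length) / (nc * ng) if nc and ng else 0.0
        return obs_exp >= p.min_obs_exp

    def span_ok(self, start: int, end: int, p: CgiParams) -> bool:
        """Full-span criteria (N counts in length but not as C/G)."""
        gc, obs_exp, _ = self.metrics(start, end)
        return gc >= p.min_gc and obs_exp >= p.min_obs_exp


def _best_qualifying_span(
    prof: _SeqProfile, start: int, end: int, p: CgiParams
) -> Optional[tuple[int, int]]:
    """Longest sub-span of [start, end) meeting length and both criteria.

    The common case — the whole merged candidate qualifies — is O(1); only
    failing candidates pay for the exhaustive trim search.  Ties prefer the
    leftmost span.
    """
    if end - start >= p.min_length and prof.span_ok(start, end, p):
        return start, end
    if end - start < p.min_length:
        return None
    length = end - start
    c = prof.c[start : end + 1] - prof.c[start]
    g = prof.g[start : end + 1] - prof.g[start]
    cpg = prof.cpg[start : end + 1] - prof.cpg[start]
    best: Optional[tuple[int, int]] = None
    best_len = p.min_length - 1
    for a in range(0, length - p.min_length + 1):
        bs = np.arange(a + best_len + 1, length + 1)
        if bs.size == 0:
            continue
        nc = c[bs] - c[a]
        ng = g[bs] - g[a]
        ncpg = cpg[np.maximum(bs - 1, a)] - cpg[a]
        span = bs - a
        ok = (nc > 0) & (ng > 0)
        gc_ok = 100.0 * (nc + ng) >= p.min_gc * span
        with np.errstate(divide="ignore", invalid="ignore"):
            oe_ok = ok & (ncpg * span >= p.min_obs_exp * nc * ng)
        good = np.where(ok & gc_ok & oe_ok)[0]
        if good.size:
            b = int(bs[good[-1]])
            if b - a > best_len:
                best = (start + a, start + b)
                best_len = b - a
    return best


def island_metrics(seq: str, start: int, end: int) -> tuple[float, float, int]:
    """(GC %, ObsExp CpG ratio, CpG count) over seq[start:end]."""
    return _SeqProfile(seq).metrics(start, end)


def find_cgis(
    seq: str, params: Optional[CgiParams] = None, scaffold: str = ""
) -> list[CpgIsland]:
    """Detect CpG islands on one scaffold sequence.

    Returns sorted, non-overlapping islands with their GC%, ObsExp and CpG
    count.  A sequence shorter than the window yields no islands.
    """
    p = params or CgiParams()
    w = p.window
    if len(seq) < w:
        return []
    prof = _SeqProfile(seq)
    L = prof.len

    # vectorized 1 bp seed scan
    starts = np.arange(L - w + 1)
    nc = prof.c[starts + w] - prof.c[starts]
    ng = prof.g[starts + w] - prof.g[starts]
    nn = prof.n[starts + w] - prof.n[starts]
    ncpg = prof.cpg[starts + w - 1] - prof.cpg[starts]
    gc_ok = 100.0 * (nc + ng) >= p.min_gc * w
    oe_ok = (nc > 0) & (ng > 0) & (ncpg * w >= p.min_obs_exp * nc * ng)
    seeds = starts[(nn == 0) & gc_ok & oe_ok]

    # chain seeds into candidate clusters: merge while the gap between
    # consecutive seed windows is below one window
    clusters: list[list[int]] = []
    for s in seeds:
        s = int(s)
        if clusters and s - clusters[-1][1] < w:
            clusters[-1][1] = s + w
        else:
            clusters.append([s, s + w])

    islands: list[CpgIsland] = []
    for start, end in clusters:
        span = _best_qualifying_span(prof, start, end, p)
        if span is None:
            continue
        start, end = span
        gc, obs_exp, ncpg = prof.metrics(start, end)
        islands.append(
            CpgIsland(
                region=Region(scaffold=scaffold or "seq", start=start, end=end,
                              kind="cgi", name=f"cgi_{start}"),
                gc_percent=gc,
                obs_exp=obs_exp,
                cpg_count=ncpg,
            )
        )
    return islands


def find_cgis_genome(
    genome: Genome, params: Optional[CgiParams] = None
) -> list[CpgIsland]:
    out: list[CpgIsland] = []
    for name, seq in genome.scaffolds.items():
        out.extend(find_cgis(seq, params, scaffold=name))
    return out


def promoters_from_tss(
    tss: Iterable[Region],
    upstream_bp: int = 2000,
    scaffold_lengths: Optional[dict[str, int]] = None,
) -> list[Region]:
    """Promoters as the region ``upstream_bp`` upstream of each stranded TSS.

    Plus strand: [tss - upstream, tss); minus strand: the mirror image
    [tss + 1, tss + 1 + upstream).  Clipped at scaffold bounds when lengths
    are supplied.
    """
    promoters: list[Region] = []
    for t in tss:
        if t.strand not in "+-":
            raise ValueError(f"TSS {t.name!r} has no strand; promoters need one")
        pos = t.start
        if t.strand == "+":
            start, end = pos - upstream_bp, pos
        else:
            start, end = pos + 1, pos + 1 + upstream_bp
        start = max(start, 0)
        if scaffold_lengths is not None:
            end = min(end, scaffold_lengths[t.scaffold])
        if start >= end:
            continue  # TSS at the very scaffold edge leaves no promoter
        promoters.append(
            Region(scaffold=t.scaffold, start=start, end=end, strand=t.strand,
                   kind="promoter", name=t.name or f"promoter_{pos}")
        )
    return promoters


def cgi_promoter_relation(
    cgis: Iterable[CpgIsland],
    promoters: Iterable[Region],
    tail_bp: int = 10_000,
    bin_width: int = 1000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-CGI promoter overlap and distance, plus a distance histogram.

    A CGI is "inside" a promoter on any >= 1 bp overlap (distance 0);
    otherwise the distance is the gap to the nearest promoter on the same
    scaffold.  The histogram uses ``bin_width`` bins up to ``tail_bp`` plus
    one open tail bin for everything at least ``tail_bp`` away.
    """
    proms: dict[str, list[Region]] = {}
    for prom in promoters:
        proms.setdefault(prom.scaffold, []).append(prom)
    rows = []
    for cgi in cgis:
        r = cgi.region
        scaffold_proms = proms.get(r.scaffold, [])
        if not scaffold_proms:
            rows.append((r.scaffold, r.start, r.end, False, np.inf))
            continue
        starts = np.array([p.start for p in scaffold_proms])
        ends = np.array([p.end for p in scaffold_proms])
        gaps = np.maximum(0, np.maximum(starts - r.end, r.start - ends))
        inside = bool((np.minimum(ends, r.end) > np.maximum(starts, r.start)).any())
        rows.append((r.scaffold, r.start, r.end, inside, float(gaps.min())))
    table = pd.DataFrame(
        rows, columns=["scaffold", "start", "end", "inside_promoter", "distance"]
    )
    edges = list(range(0, tail_bp + bin_width, bin_width))
    finite = table["distance"].replace(np.inf, np.nan).dropna()
    counts, _ = np.histogram(finite, bins=edges + [np.inf])
    labels = [f"{edges[i]}-{edges[i + 1]}" for i in range(len(edges) - 1)]
    labels.append(f">={tail_bp}")
    hist = pd.DataFrame({"bin": labels, "count": counts})
    return table, hist


def write_cgi_tsv(cgis: Iterable[CpgIsland], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("scaffold\tstart\tend\tlength\tgc_percent\tobs_exp\tcpg_count\n")
        for c in cgis:
            r = c.region
            fh.write(
                f"{r.scaffold}\t{r.start}\t{r.end}\t{r.end - r.start}\t"
                f"{c.gc_percent:.2f}\t{c.obs_exp:.4f}\t{c.cpg_count}\n"
            )
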