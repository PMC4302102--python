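"""Region-level aggregation and library-comparison statistics.

Region methylation pools read-level observations (sum of methylated over sum
of all observations inside the region, both strands), matching the
summation-style percentage used throughout the pipeline; an unweighted mean
of per-site ratios is available as an option.  Level histograms, coverage
partitions between two libraries, replicate correlations and the
shifted-position consistency rule (|posA - posB| <= tolerance * posA) live
here as well.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_formats import Region
from .methylation_caller import CytosineCall, calls_to_frame
from .reference_builder import CoverageTrack

CallsLike = Union[pd.DataFrame, Iterable[CytosineCall]]


def _as_frame(calls: CallsLike) -> pd.DataFrame:
    if isinstance(calls, pd.DataFrame):
        return calls
    return calls_to_frame(calls)


@dataclass
class RegionMethylation:
    region: Region
    n_cytosines_covered: int
    pooled_meth: int
    pooled_unmeth: int

    @property
    def covered(self) -> bool:
        return self.n_cytosines_covered > 0

    @property
    def level(self) -> Optional[float]:
        total = self.pooled_meth + self.pooled_unmeth
        return 100.0 * self.pooled_meth / total if total else None


def region_methylation(
    calls: CallsLike,
    regions: Iterable[Region],
    mode: str = "pooled",
) -> list[RegionMethylation]:
    """Aggregate cytosine calls over regions (both strands included).

    ``pooled`` weights every read observation equally; ``mean`` averages the
    per-site ratios instead.  Regions without covered cytosines are returned
    flagged (``covered`` False, level None), not scored.
    """
    if mode not in ("pooled", "mean"):
        raise ValueError(f"unknown mode {mode!r}")
    df = _as_frame(calls)
    by_scaffold: dict[str, pd.DataFrame] = {
        str(s): g.sort_values("pos").reset_index(drop=True)
        for s, g in df.groupby("scaffold")
    }
    known = set(by_scaffold) | {str(s) for s in df["scaffold"].unique()}
    out: list[RegionMethylation] = []
    for region in regions:
        g = by_scaffold.get(region.scaffold)
        if g is None:
            if df.empty or region.scaffold in known:
                g = df.iloc[0:0]
            else:
                raise ValueError(
                    f"region {region.name!r} on scaffold {region.scaffold!r} "
                    "absent from the call set"
                )
        pos = g["pos"].to_numpy()
        lo = int(np.searchsorted(pos, region.start, side="left"))
        hi = int(np.searchsorted(pos, region.end, side="left"))
        sub = g.iloc[lo:hi]
        n_sites = len(sub)
        if mode == "pooled" or n_sites == 0:
            meth = int(sub["meth"].sum())
            unmeth = int(sub["unmeth"].sum())
        else:
            ratios = sub["meth"] / (sub["meth"] + sub["unmeth"])
            # represent the unweighted mean as a pseudo-count pair
            meth = float(ratios.mean()) * n_sites  # type: ignore[assignment]
            unmeth = n_sites - meth  # type: ignore[assignment]
        out.append(
            RegionMethylation(
                region=region,
                n_cytosines_covered=n_sites,
                pooled_meth=meth,
                pooled_unmeth=unmeth,
            )
        )
    return out


@dataclass
class BinScheme:
    """Ordered bin edges over [0, 100] with labels.

    A value equal to a shared edge is assigned to the lower bin; the first
    bin includes its left edge.
    """

    edges: Sequence[float]
    labels: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        e = list(self.edges)
        if sorted(e) != e or len(set(e)) != len(e):
            raise ValueError("bin edges must be strictly increasing")
        if e[0] != 0 or e[-1] != 100:
            raise ValueError("bin edges must cover [0, 100]")
        if self.labels is None:
            self.labels = [f"{a:g}-{b:g}" for a, b in zip(e[:-1], e[1:])]
        elif len(self.labels) != len(e) - 1:
            raise ValueError("need one label per bin")

    @classmethod
    def bimodal(cls) -> "BinScheme":
        """Very low / intermediate / very high: 0-4, 4-75, 75-100."""
        return cls([0, 4, 75, 100], ["very_low", "intermediate", "very_high"])

    @classmethod
    def low_mid_high(cls) -> "BinScheme":
        """Low / intermediate / high: 0-40, 40-60, 60-100."""
        return cls([0, 40, 60, 100], ["low", "intermediate", "high"])


def bin_levels(levels: Iterable[float], scheme: BinScheme) -> np.ndarray:
    """Histogram of methylation levels under a bin scheme.

    Boundary values go to the lower bin of the shared edge.
    """
    arr = np.asarray(list(levels), dtype=float)
    if arr.size and (arr.min() < 0 or arr.max() > 100):
        raise ValueError("methylation levels must lie in [0, 100]")
    edges = np.asarray(scheme.edges, dtype=float)
    if arr.size == 0:
        return np.zeros(len(edges) - 1, dtype=int)
    idx = np.digitize(arr, edges[1:-1], right=True)
    return np.bincount(idx, minlength=len(edges) - 1)


def coverage_overlap(
    track_a: CoverageTrack, track_b: CoverageTrack
) -> dict[str, float]:
    """Position-wise partition of the genome by coverage in two libraries.

    Returns percentages {both, only_a, only_b, neither} summing to 100.
    """
    if set(track_a.depths) != set(track_b.depths):
        raise ValueError("coverage tracks cover different scaffolds")
    both = only_a = only_b = total = 0
    for scaffold, da in track_a.depths.items():
        db = track_b.depths[scaffold]
        if len(da) != len(db):
            raise ValueError(f"coverage track length mismatch on {scaffold!r}")
        a = da > 0
        b = db > 0
        both += int((a & b).sum())
        only_a += int((a & ~b).sum())
        only_b += int((~a & b).sum())
        total += len(da)
    neither = total - both - only_a - only_b
    return {
        "both": 100.0 * both / total,
        "only_a": 100.0 * only_a / total,
        "only_b": 100.0 * only_b / total,
        "neither": 100.0 * neither / total,
    }


def replicate_correlation(
    calls_a: CallsLike,
    calls_b: CallsLike,
    min_depth: int = 1,
    mode: str = "ratio",
) -> float:
    """Pearson r between two libraries over positions covered in both.

    ``depth`` mode correlates per-position depth, ``ratio`` mode the
    methylation percentages.  Sites must reach ``min_depth`` in both
    libraries.  Raises on fewer than two shared sites; returns NaN when
    either vector has zero variance.
    """
    if mode not in ("depth", "ratio"):
        raise ValueError(f"unknown mode {mode!r}")
    a = _as_frame(calls_a).copy()
    b = _as_frame(calls_b).copy()
    for df in (a, b):
        df["depth"] = df["meth"] + df["unmeth"]
    merged = a.merge(b, on=["scaffold", "pos", "strand"], suffixes=("_a", "_b"))
    merged = merged[
        (merged["depth_a"] >= min_depth) & (merged["depth_b"] >= min_depth)
    ]
    if len(merged) < 2:
        raise ValueError("fewer than two shared positions")
    if mode == "depth":
        x = merged["depth_a"].to_numpy(dtype=float)
        y = merged["depth_b"].to_numpy(dtype=float)
    else:
        x = 100.0 * merged["meth_a"].to_numpy() / merged["depth_a"].to_numpy()
        y = 100.0 * merged["meth_b"].to_numpy() / merged["depth_b"].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    r, _ = sps.pearsonr(x, y)
    return float(r)


def shifted_position_match(
    pos_a: int, pos_b: int, tolerance: float = 0.10
) -> bool:
    """True when posB lies within +-tolerance*posA of posA.

    The window scales with the first argument, so the rule is deliberately
    asymmetric; at position 0 the window is empty and only an exact match
    passes.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    if pos_a < 0 or pos_b < 0:
        raise ValueError("positions must be non-negative")
    return abs(pos_a - pos_b) <= tolerance * pos_a


def shifted_position_fraction(
    pairs: Iterable[tuple[int, int]], tolerance: float = 0.10
) -> float:
    """% of paired read placements consistent under the +-tolerance rule."""
    matched = total = 0
    for pos_a, pos_b in pairs:
        total += 1
        matched += shifted_position_match(pos_a, pos_b, tolerance)
    return 100.0 * matched / total if total else 0.0


# ---------------------------------------------------------------------------
# Interval set operations for promoter/CGI partitions


def subtract_regions(
    regions: Iterable[Region], others: Iterable[Region]
) -> list[Region]:
    """Pieces of ``regions`` not covered by any of ``others``."""
    by_scaffold: dict[str, list[Region]] = {}
    for o in others:
        by_scaffold.setdefault(o.scaffold, []).append(o)
    out: list[Region] = []
    for r in regions:
        cuts = sorted(
            (max(o.start, r.start), min(o.end, r.end))
            for o in by_scaffold.get(r.scaffold, [])
            if o.start < r.end and r.start < o.end
        )
        pos = r.start
        piece = 0
        for cs, ce in cuts:
            if cs > pos:
                out.append(Region(r.scaffold, pos, cs, r.strand, r.kind,
                                  f"{r.name}.{piece}" if r.name else ""))
                piece += 1
            pos = max(pos, ce)
        if pos < r.end:
            out.append(Region(r.scaffold, pos, r.end, r.strand, r.kind,
                              f"{r.name}.{piece}" if piece and r.name else r.name))
    return out


def partition_by_overlap(
    regions: Iterable[Region], others: Iterable[Region]
) -> tuple[list[Region], list[Region]]:
    """Split regions into (overlapping any of others, not overlapping)."""
    others = list(others)
    inside: list[Region] = []
    outside: list[Region] = []
    for r in regions:
        (inside if any(r.overlaps(o) for o in others) else outside).append(r)
    return inside, outside
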