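"""Hi-C loop reconciliation and peak -> anchor -> TSS connectivity.

Loops are pairs of anchors.  Two loops from different replicates (or
conditions) are considered the same interaction when both anchor centers
agree within a tolerance (10 kb by default), anchor-to-anchor in order
(anchor1 vs anchor1, anchor2 vs anchor2; anchors are stored sorted so no
swap is considered).  The connectivity chain then asks, for a set of
transcription-factor peaks: which peaks sit within 5 kb of a loop
anchor, and of those, which loop to a transcription start site within
15 kb of the opposite anchor — partitioned by whether the mediating loop
is conserved between conditions or condition-specific.
"""

from __future__ import annotations

import math
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Sequence

from .intervals import GenomicInterval, Peak, ValidationError

__all__ = [
    "Loop",
    "TssRecord",
    "ConnectivityReport",
    "reconcile_replicate_loops",
    "compare_condition_loops",
    "assign_peaks_to_anchors",
    "connect_peaks_to_tss",
    "connectivity_summary",
]


@dataclass(frozen=True)
class Loop:
    """A chromatin interaction between two anchors.

    Anchors are normalized to (chrom, start)-lexicographic order at
    construction, so anchor1 <= anchor2 always holds.
    """

    anchor1: GenomicInterval
    anchor2: GenomicInterval
    condition: str = ""
    replicate: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        a, b = self.anchor1, self.anchor2
        if (a.chrom, a.start) > (b.chrom, b.start):
            object.__setattr__(self, "anchor1", b)
            object.__setattr__(self, "anchor2", a)

    def anchor(self, side: int) -> GenomicInterval:
        if side not in (1, 2):
            raise ValidationError(f"anchor side must be 1 or 2, got {side}")
        return self.anchor1 if side == 1 else self.anchor2

    @property
    def chrom_pair(self) -> tuple[str, str]:
        return (self.anchor1.chrom, self.anchor2.chrom)


@dataclass(frozen=True)
class TssRecord:
    """A transcription start site."""

    gene_id: str
    chrom: str
    tss_position: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.tss_position < 0:
            raise ValidationError(f"TSS position must be >= 0: {self.gene_id}")
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"bad strand {self.strand!r} for {self.gene_id}")


def _loop_distance(l1: Loop, l2: Loop) -> float:
    """Max over the two ordered anchor-center distances; inf across chrom pairs."""
    if l1.chrom_pair != l2.chrom_pair:
        return math.inf
    return float(
        max(
            abs(l1.anchor1.center - l2.anchor1.center),
            abs(l1.anchor2.center - l2.anchor2.center),
        )
    )


def _index_by_pair(loops: Sequence[Loop]) -> dict[tuple[str, str], list[int]]:
    d: dict[tuple[str, str], list[int]] = {}
    for i, lp in enumerate(loops):
        d.setdefault(lp.chrom_pair, []).append(i)
    return d


def _candidates_within(
    l1: Loop, loops2: Sequence[Loop], idx2: dict, tol: float
) -> list[int]:
    """Indices of loops2 on the same chromosome pair with both anchors within tol."""
    out = []
    for j in idx2.get(l1.chrom_pair, ()):  # per-pair lists are short at desk scale
        if _loop_distance(l1, loops2[j]) <= tol:
            out.append(j)
    return out


def reconcile_replicate_loops(
    rep1: Sequence[Loop],
    rep2: Sequence[Loop],
    tol: float = 10_000,
) -> list[tuple[Loop, Loop]]:
    """Loops reproducible between two replicates.

    A rep1 loop is replicated when some rep2 loop on the same chromosome
    pair has both ordered anchor centers within ``tol`` bp (inclusive).
    Returns the passing rep1 loops, each with its best (smallest
    max-anchor-distance) rep2 partner.
    """
    if tol <= 0:
        raise ValidationError(f"tol must be > 0, got {tol}")
    idx2 = _index_by_pair(rep2)
    out: list[tuple[Loop, Loop]] = []
    for l1 in rep1:
        cands = _candidates_within(l1, rep2, idx2, tol)
        if cands:
            best = min(
                cands,
                key=lambda j: (
                    _loop_distance(l1, rep2[j]),
                    rep2[j].anchor1.start,
                    rep2[j].anchor2.start,
                ),
            )
            out.append((l1, rep2[best]))
    return out


def compare_condition_loops(
    cond1: Sequence[Loop],
    cond2: Sequence[Loop],
    tol: float = 10_000,
) -> tuple[list[tuple[Loop, Loop]], list[Loop], list[Loop]]:
    """Partition two condition loop sets into shared and condition-specific.

    Shared loops are one-to-one pairs chosen greedily by increasing
    max-anchor distance (the same inclusive ``tol`` rule as replicate
    reconciliation, with a symmetric deterministic tie-break), so
    ``len(shared) + len(specific_1) == len(cond1)`` and likewise for
    cond2.
    """
    if tol <= 0:
        raise ValidationError(f"tol must be > 0, got {tol}")
    idx2 = _index_by_pair(cond2)
    cand: list[tuple] = []
    for i, l1 in enumerate(cond1):
        for j in _candidates_within(l1, cond2, idx2, tol):
            l2 = cond2[j]
            d = _loop_distance(l1, l2)
            key = (
                d,
                min(l1.anchor1.center, l2.anchor1.center),
                max(l1.anchor1.center, l2.anchor1.center),
                min(l1.anchor2.center, l2.anchor2.center),
                max(l1.anchor2.center, l2.anchor2.center),
            )
            cand.append((*key, i, j))
    cand.sort()
    used1: set[int] = set()
    used2: set[int] = set()
    shared: list[tuple[Loop, Loop]] = []
    for *_k, i, j in cand:
        if i in used1 or j in used2:
            continue
        used1.add(i)
        used2.add(j)
        shared.append((cond1[i], cond2[j]))
    specific_1 = [l for i, l in enumerate(cond1) if i not in used1]
    specific_2 = [l for j, l in enumerate(cond2) if j not in used2]
    return shared, specific_1, specific_2


@dataclass(frozen=True)
class AnchorAssignment:
    """A peak sitting within tolerance of one anchor of one loop."""

    peak_index: int
    loop_index: int
    side: int  # 1 or 2


def assign_peaks_to_anchors(
    peaks: Sequence[Peak],
    loops: Sequence[Loop],
    tol: float = 5_000,
) -> list[AnchorAssignment]:
    """All (peak, loop, side) triples with peak center within tol of the anchor center.

    One peak may hit several loops and both anchors.  Inclusive
    boundary.  Deduplicated peak counts are derived downstream.
    """
    if tol <= 0:
        raise ValidationError(f"tol must be > 0, got {tol}")
    # sort peaks per chromosome for bisection against each anchor
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for i, p in enumerate(peaks):
        by_chrom.setdefault(p.chrom, []).append((p.center, i))
    for v in by_chrom.values():
        v.sort()
    out: list[AnchorAssignment] = []
    for li, lp in enumerate(loops):
        for side in (1, 2):
            anc = lp.anchor(side)
            entries = by_chrom.get(anc.chrom)
            if not entries:
                continue
            centers = [c for c, _ in entries]
            lo = bisect_left(centers, anc.center - tol)
            hi = bisect_right(centers, anc.center + tol)
            for _c, i in entries[lo:hi]:
                out.append(AnchorAssignment(peak_index=i, loop_index=li, side=side))
    return out


@dataclass(frozen=True)
class Connection:
    """A peak looped to a gene TSS through opposite anchors of one loop."""

    peak_index: int
    loop_index: int
    side: int
    gene_id: str


def connect_peaks_to_tss(
    assignments: Sequence[AnchorAssignment],
    loops: Sequence[Loop],
    tss: Sequence[TssRecord],
    tol: float = 15_000,
) -> list[Connection]:
    """Chain anchor-assigned peaks to TSSs near the opposite anchor.

    For each (peak, loop, side) assignment, every TSS on the opposite
    anchor's chromosome whose position lies within ``tol`` bp (inclusive)
    of that anchor's center yields a connection record.  Strand-agnostic.
    """
    if tol <= 0:
        raise ValidationError(f"tol must be > 0, got {tol}")
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for k, t in enumerate(tss):
        by_chrom.setdefault(t.chrom, []).append((t.tss_position, k))
    for v in by_chrom.values():
        v.sort()
    out: list[Connection] = []
    for a in assignments:
        other = loops[a.loop_index].anchor(3 - a.side)
        entries = by_chrom.get(other.chrom)
        if not entries:
            continue
        positions = [p for p, _ in entries]
        lo = bisect_left(positions, other.center - tol)
        hi = bisect_right(positions, other.center + tol)
        for _p, k in entries[lo:hi]:
            out.append(
                Connection(
                    peak_index=a.peak_index,
                    loop_index=a.loop_index,
                    side=a.side,
                    gene_id=tss[k].gene_id,
                )
            )
    return out


def _pct(numer: int, denom: int) -> int:
    """Nearest-integer percentage; half rounds away from zero; 0 on empty denominator."""
    if denom == 0:
        return 0
    return int(math.floor(100.0 * numer / denom + 0.5))


@dataclass
class ConnectivityReport:
    """Counts and percentages along the peak -> anchor -> TSS chain."""

    n_peaks_total: int
    n_peaks_in_anchors: int
    n_peaks_tss_connected: int
    n_via_conserved_loops: int
    n_via_specific_loops: int
    connections: list[Connection] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (
            self.n_peaks_tss_connected
            <= self.n_peaks_in_anchors
            <= self.n_peaks_total
        ):
            raise ValidationError("connectivity counts must be nested")
        if (
            self.n_via_conserved_loops + self.n_via_specific_loops
            != self.n_peaks_tss_connected
        ):
            raise ValidationError("conserved + specific must equal TSS-connected")

    @property
    def pct_in_anchors(self) -> int:
        return _pct(self.n_peaks_in_anchors, self.n_peaks_total)

    @property
    def pct_tss_connected(self) -> int:
        return _pct(self.n_peaks_tss_connected, self.n_peaks_in_anchors)

    @property
    def pct_via_conserved(self) -> int:
        return _pct(self.n_via_conserved_loops, self.n_peaks_tss_connected)

    def as_dict(self) -> dict:
        return {
            "n_peaks_total": self.n_peaks_total,
            "n_peaks_in_anchors": self.n_peaks_in_anchors,
            "n_peaks_tss_connected": self.n_peaks_tss_connected,
            "n_via_conserved_loops": self.n_via_conserved_loops,
            "n_via_specific_loops": self.n_via_specific_loops,
            "pct_in_anchors": self.pct_in_anchors,
            "pct_tss_connected": self.pct_tss_connected,
            "pct_via_conserved": self.pct_via_conserved,
        }


def connectivity_summary(
    peaks: Sequence[Peak],
    loops_shared: Sequence[Loop],
    loops_specific: Sequence[Loop],
    tss: Sequence[TssRecord],
    peak_anchor_tol: float = 5_000,
    tss_anchor_tol: float = 15_000,
) -> ConnectivityReport:
    """Run the full connectivity chain and tally it.

    The chain runs over shared and condition-specific loops together.  A
    TSS-connected peak is attributed to "conserved" when at least one of
    its connecting loops is shared between conditions, otherwise to
    "specific" — so the two tallies partition the connected peaks.
    """
    loops = list(loops_shared) + list(loops_specific)
    n_shared = len(loops_shared)
    assignments = assign_peaks_to_anchors(peaks, loops, tol=peak_anchor_tol)
    connections = connect_peaks_to_tss(assignments, loops, tss, tol=tss_anchor_tol)

    peaks_in_anchors = {a.peak_index for a in assignments}
    connected: dict[int, bool] = {}  # peak index -> has a shared-loop connection
    for c in connections:
        via_shared = c.loop_index < n_shared
        connected[c.peak_index] = connected.get(c.peak_index, False) or via_shared

    n_conserved = sum(1 for v in connected.values() if v)
    return ConnectivityReport(
        n_peaks_total=len(peaks),
        n_peaks_in_anchors=len(peaks_in_anchors),
        n_peaks_tss_connected=len(connected),
        n_via_conserved_loops=n_conserved,
        n_via_specific_loops=len(connected) - n_conserved,
        connections=connections,
    )
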