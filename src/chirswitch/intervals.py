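"""Genomic intervals with center-distance semantics.

All downstream stages (binding-site switch classification, ATAC peak
merging, loop-anchor assignment) compare features by the distance between
their *centers*, not by base-pair overlap.  This module owns that
convention: 0-based half-open coordinates, an optional summit override for
the center, inclusive distance thresholds, greedy nearest-pair matching,
and left-to-right midpoint merging.
"""

from __future__ import annotations

import math
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "DIFFERENT_CHROM",
    "GenomicInterval",
    "Peak",
    "center_distance",
    "match_peak_sets",
    "merge_peaks",
    "MatchResult",
]

#: Sentinel distance returned when two intervals lie on different
#: chromosomes.  Infinite, so it fails every finite threshold comparison.
DIFFERENT_CHROM = math.inf


class ValidationError(ValueError):
    """Raised when an input record violates a domain invariant."""


@dataclass(frozen=True)
class GenomicInterval:
    """A chromosome span with a defined center (0-based, half-open).

    Parameters
    ----------
    chrom : str
        Chromosome name, passed through verbatim.
    start, end : int
        0-based half-open span; ``start < end`` and ``start >= 0``.
    center : int, optional
        Override for the representative point (e.g. a peak summit).
        Defaults to ``floor((start + end) / 2)``; must lie inside the span.
    """

    chrom: str
    start: int
    end: int
    center: int = field(default=-1)

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.center == -1:
            object.__setattr__(self, "center", (self.start + self.end) // 2)
        elif not (self.start <= self.center < self.end):
            raise ValidationError(
                f"center {self.center} outside interval "
                f"{self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Peak:
    """A called peak: an interval plus the evidence attached to it.

    ``fe_by_replicate`` holds one fold-enrichment value per replicate of
    the assay; ``q_value`` is the upstream caller's significance on the
    probability scale; ``motif_hit`` flags a predicted binding motif
    inside the peak (``None`` when not annotated).
    """

    interval: GenomicInterval
    q_value: float | None = None
    fe_by_replicate: tuple[float, ...] = ()
    condition: str = ""
    factor: str = ""
    motif_hit: bool | None = None
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "fe_by_replicate", tuple(float(f) for f in self.fe_by_replicate)
        )
        if any(f < 0 for f in self.fe_by_replicate):
            raise ValidationError("fold enrichment must be >= 0")
        if self.q_value is not None and not (0.0 <= self.q_value <= 1.0):
            raise ValidationError(f"q-value {self.q_value} outside [0, 1]")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def center(self) -> int:
        return self.interval.center


def center_distance(a: GenomicInterval, b: GenomicInterval) -> float:
    """Distance in bp between the centers of two intervals.

    Returns :data:`DIFFERENT_CHROM` (``inf``) when the intervals lie on
    different chromosomes, so the result always compares correctly
    against a finite threshold.  Symmetric in its arguments.
    """
    if a.chrom != b.chrom:
        return DIFFERENT_CHROM
    return float(abs(a.center - b.center))


def _as_interval(x: GenomicInterval | Peak) -> GenomicInterval:
    return x.interval if isinstance(x, Peak) else x


@dataclass
class MatchResult:
    """Outcome of matching two peak sets by center distance."""

    matched: list[tuple[Peak, Peak]]
    unique_a: list[Peak]
    unique_b: list[Peak]

    @property
    def n_matched(self) -> int:
        return len(self.matched)


def match_peak_sets(
    set_a: Sequence[Peak],
    set_b: Sequence[Peak],
    threshold: float = 150,
) -> MatchResult:
    """One-to-one matching of two peak sets by center distance.

    Two peaks may pair only when they sit on the same chromosome with
    centers within ``threshold`` bp (inclusive).  Pairs are chosen
    greedily by increasing distance — equivalent to iterated
    mutual-nearest matching — so the pairing is one-to-one and every
    unmatched peak is more than ``threshold`` away from every remaining
    unmatched peak of the other set.  Ties on distance break on the
    symmetric key (min center, max center, min start, max start), making
    the pair set deterministic and invariant under swapping A and B.
    """
    if threshold <= 0:
        raise ValidationError(f"threshold must be > 0, got {threshold}")

    by_chrom_b: dict[str, list[tuple[int, int]]] = {}
    for j, pb in enumerate(set_b):
        by_chrom_b.setdefault(pb.chrom, []).append((pb.center, j))
    for entries in by_chrom_b.values():
        entries.sort()

    # candidate pairs within threshold, found by bisection per A peak
    candidates: list[tuple[float, int, int, int, int, int, int]] = []
    for i, pa in enumerate(set_a):
        entries = by_chrom_b.get(pa.chrom)
        if not entries:
            continue
        centers = [c for c, _ in entries]
        lo = bisect_left(centers, pa.center - threshold)
        hi = bisect_right(centers, pa.center + threshold)
        for c, j in entries[lo:hi]:
            pb = set_b[j]
            d = abs(pa.center - c)
            key = (
                float(d),
                min(pa.center, c),
                max(pa.center, c),
                min(pa.interval.start, pb.interval.start),
                max(pa.interval.start, pb.interval.start),
            )
            candidates.append((*key, i, j))

    candidates.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    matched: list[tuple[Peak, Peak]] = []
    for *_key, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matched.append((set_a[i], set_b[j]))

    unique_a = [p for i, p in enumerate(set_a) if i not in used_a]
    unique_b = [p for j, p in enumerate(set_b) if j not in used_b]
    return MatchResult(matched=matched, unique_a=unique_a, unique_b=unique_b)


def merge_peaks(
    peaks: Iterable[Peak | GenomicInterval],
    threshold: float = 150,
) -> list[GenomicInterval]:
    """Combine nearby peaks into single representative intervals.

    Within each chromosome, peaks are taken in center order and chained
    greedily left to right: whenever the next center lies within
    ``threshold`` bp (inclusive) of the current merged center, the two
    are combined and the merged center becomes the midpoint of the two
    centers (floor on odd sums).  Output centers are therefore pairwise
    more than ``threshold`` apart, so the operation is idempotent.

    The merged interval spans the union of its contributors; its center
    carries the chained midpoint.
    """
    if threshold <= 0:
        raise ValidationError(f"threshold must be > 0, got {threshold}")

    by_chrom: dict[str, list[GenomicInterval]] = {}
    for p in peaks:
        iv = _as_interval(p)
        by_chrom.setdefault(iv.chrom, []).append(iv)

    out: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda iv: (iv.center, iv.start))
        cur_center = ivs[0].center
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.center - cur_center <= threshold:
                cur_center = (cur_center + iv.center) // 2
                cur_start = min(cur_start, iv.start)
                cur_end = max(cur_end, iv.end)
            else:
                out.append(
                    GenomicInterval(chrom, cur_start, cur_end, center=cur_center)
                )
                cur_center, cur_start, cur_end = iv.center, iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_start, cur_end, center=cur_center))
    return out
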