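"""Windowed tag counting, fold enrichment, and reproducibility filters.

Peak strength is measured as fold enrichment (FE): the tag density inside
a fixed window around the peak center, relative to the genome-average tag
density of the library.  FE = 1 is the background expectation.  Filters
implement the strict-inequality reproducibility rules used throughout the
pipeline: a ChIP peak is kept when its caller q-value is < 1e-4 and FE
exceeds 10 in every replicate (20 for the "strong" subset); an ATAC peak
when FE exceeds 3 in all three replicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .intervals import GenomicInterval, Peak, ValidationError

__all__ = [
    "TagTable",
    "WindowCount",
    "count_tags_in_windows",
    "fold_enrichment",
    "filter_chip_peaks",
    "filter_strong_peaks",
    "filter_atac_peaks",
]

logger = logging.getLogger(__name__)


@dataclass
class TagTable:
    """Sorted per-chromosome tag (read 5' end) positions for one library.

    Parameters
    ----------
    positions : mapping of chrom -> array of int bp
        Stored sorted; one entry per aligned read.
    total_tags : int, optional
        Library size.  Defaults to the number of stored positions; may be
        larger when the table holds a subset of the library.
    genome_size : int
        Effective genome length in bp.
    """

    positions: Mapping[str, np.ndarray]
    genome_size: int
    total_tags: int = 0
    _sorted: dict = field(init=False, repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        if self.genome_size <= 0:
            raise ValidationError("genome_size must be > 0")
        self._sorted = {
            chrom: np.sort(np.asarray(pos, dtype=np.int64))
            for chrom, pos in self.positions.items()
        }
        n_stored = int(sum(len(v) for v in self._sorted.values()))
        if n_stored == 0:
            raise ValidationError("TagTable holds no tag positions")
        if self.total_tags == 0:
            self.total_tags = n_stored
        elif self.total_tags < n_stored:
            raise ValidationError(
                f"total_tags={self.total_tags} < stored positions={n_stored}"
            )

    def count_window(self, chrom: str, center: int, halfwidth: int) -> int:
        """Number of tags p with |p - center| <= halfwidth."""
        pos = self._sorted.get(chrom)
        if pos is None:
            return 0
        lo = np.searchsorted(pos, center - halfwidth, side="left")
        hi = np.searchsorted(pos, center + halfwidth, side="right")
        return int(hi - lo)


@dataclass(frozen=True)
class WindowCount:
    """Tag count and fold enrichment for one window around a center."""

    chrom: str
    center: int
    halfwidth: int
    count: int
    fold_enrichment: float


def fold_enrichment(
    count: float, window_len: int, total_tags: int, genome_size: int
) -> float:
    """Observed tag density over genome-average density.

    FE = (count / window_len) / (total_tags / genome_size).  A window
    whose count equals the genome-background expectation scores exactly 1.
    """
    if window_len <= 0:
        raise ValidationError("window_len must be > 0")
    if total_tags <= 0:
        raise ValidationError("total_tags must be > 0")
    if genome_size <= 0:
        raise ValidationError("genome_size must be > 0")
    return (count / window_len) / (total_tags / genome_size)


def count_tags_in_windows(
    tags: TagTable,
    centers: Sequence[GenomicInterval],
    halfwidth: int = 250,
) -> list[WindowCount]:
    """Count tags within +/- halfwidth of each interval's center.

    Windows are independent: a tag may be counted by two overlapping
    windows.  A window length of ``2*halfwidth + 1`` (both boundary
    positions inclusive) feeds the FE denominator.  Centers on a
    chromosome absent from the tag table count 0 (warning logged once
    per chromosome).
    """
    if halfwidth <= 0:
        raise ValidationError("halfwidth must be > 0")
    window_len = 2 * halfwidth + 1
    missing: set[str] = set()
    out: list[WindowCount] = []
    for iv in centers:
        if iv.chrom not in tags._sorted and iv.chrom not in missing:
            missing.add(iv.chrom)
            logger.warning("chromosome %s absent from tag table; counts are 0", iv.chrom)
        c = tags.count_window(iv.chrom, iv.center, halfwidth)
        fe = fold_enrichment(c, window_len, tags.total_tags, tags.genome_size)
        out.append(WindowCount(iv.chrom, iv.center, halfwidth, c, fe))
    return out


def _check_fe(peaks: Sequence[Peak]) -> None:
    for p in peaks:
        if len(p.fe_by_replicate) == 0:
            raise ValidationError(f"peak {p.name or p.interval} carries no FE values")


def filter_chip_peaks(
    peaks: Sequence[Peak],
    q_max: float = 1e-4,
    fe_min: float = 10.0,
) -> list[Peak]:
    """Reproducible ChIP peaks: q-value < q_max and FE > fe_min in every replicate.

    Both comparisons are strict; a peak exactly at either threshold is
    dropped.  Input order is preserved.
    """
    _check_fe(peaks)
    for p in peaks:
        if p.q_value is None:
            raise ValidationError(f"peak {p.name or p.interval} lacks a q-value")
    kept = [
        p
        for p in peaks
        if p.q_value < q_max and all(f > fe_min for f in p.fe_by_replicate)
    ]
    logger.info("filter_chip_peaks: kept %d / %d", len(kept), len(peaks))
    return kept


def filter_strong_peaks(peaks: Sequence[Peak], fe_min: float = 20.0) -> list[Peak]:
    """Strong-peak subset: FE > fe_min (strict) in every replicate."""
    _check_fe(peaks)
    kept = [p for p in peaks if all(f > fe_min for f in p.fe_by_replicate)]
    logger.info("filter_strong_peaks: kept %d / %d", len(kept), len(peaks))
    return kept


def filter_atac_peaks(
    peaks: Sequence[Peak],
    fe_min: float = 3.0,
    n_replicates: int = 3,
) -> list[Peak]:
    """Reproducible ATAC peaks: FE > fe_min (strict) in all n_replicates.

    Each peak must carry exactly ``n_replicates`` FE values.
    """
    for p in peaks:
        if len(p.fe_by_replicate) != n_replicates:
            raise ValidationError(
                f"peak {p.name or p.interval} carries {len(p.fe_by_replicate)} "
                f"FE values, expected {n_replicates}"
            )
    kept = [p for p in peaks if all(f > fe_min for f in p.fe_by_replicate)]
    logger.info("filter_atac_peaks: kept %d / %d", len(kept), len(peaks))
    return kept
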