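"""Readers and writers for the plain-text formats the pipeline speaks.

BED-family conventions: 0-based half-open coordinates; narrowPeak column
10 is the summit offset from ``start`` and populates the peak center when
it is >= 0; chromosome names pass through verbatim.  Malformed lines
raise :class:`ParseError` with the file and line number.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .diffexp import CountMatrix
from .intervals import GenomicInterval, Peak, ValidationError
from .classify import PWM
from .loops import Loop, TssRecord
from .peaks import TagTable

__all__ = [
    "ParseError",
    "read_bed",
    "write_bed",
    "read_narrowpeak",
    "write_narrowpeak",
    "read_bedpe",
    "write_bedpe",
    "read_tss",
    "write_tss",
    "read_counts",
    "write_counts",
    "read_design",
    "read_tags",
    "read_pwm",
    "read_fasta",
]

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """A malformed line in an input file, carrying its location."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = path
        self.lineno = lineno


def _rows(path) -> Iterable[tuple[int, list[str]]]:
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t")


def _warn_if_empty(records: list, path) -> list:
    if not records:
        logger.warning("%s contained no records", path)
    return records


# ---------------------------------------------------------------------------
# BED / narrowPeak

def read_bed(path) -> list[GenomicInterval]:
    """BED3+ file -> intervals (center = midpoint)."""
    out = []
    for lineno, f in _rows(path):
        try:
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2])))
        except (IndexError, ValueError, ValidationError) as e:
            raise ParseError(path, lineno, f"bad BED line: {e}") from e
    return _warn_if_empty(out, path)


def write_bed(path, intervals: Sequence[GenomicInterval | Peak], names: Sequence[str] | None = None) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for i, item in enumerate(intervals):
            iv = item.interval if isinstance(item, Peak) else item
            name = (
                names[i] if names is not None
                else (item.name if isinstance(item, Peak) and item.name else f"iv{i}")
            )
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t.\n")


def read_narrowpeak(path, n_replicates_from_signal: bool = False) -> list[Peak]:
    """10-column narrowPeak -> peaks.

    Column 7 (signalValue) becomes a single-replicate fold enrichment,
    column 9 (qValue, -log10) becomes the probability-scale q-value, and
    column 10 (summit offset) sets the center when >= 0.
    """
    out = []
    for lineno, f in _rows(path):
        try:
            chrom, start, end = f[0], int(f[1]), int(f[2])
            name = f[3] if len(f) > 3 else ""
            signal = float(f[6]) if len(f) > 6 and f[6] != "." else 0.0
            qlog = float(f[8]) if len(f) > 8 and f[8] != "." else -1.0
            summit = int(f[9]) if len(f) > 9 else -1
            center = start + summit if summit >= 0 else -1
            q = 10.0 ** (-qlog) if qlog >= 0 else None
            out.append(
                Peak(
                    interval=GenomicInterval(chrom, start, end, center=center),
                    q_value=min(q, 1.0) if q is not None else None,
                    fe_by_replicate=(signal,),
                    name=name,
                )
            )
        except (IndexError, ValueError, ValidationError) as e:
            raise ParseError(path, lineno, f"bad narrowPeak line: {e}") from e
    return _warn_if_empty(out, path)


def write_narrowpeak(path, peaks: Sequence[Peak]) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for i, p in enumerate(peaks):
            iv = p.interval
            fe = p.fe_by_replicate[0] if p.fe_by_replicate else 0.0
            qlog = -np.log10(p.q_value) if p.q_value not in (None, 0) else -1.0
            summit = iv.center - iv.start
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.name or f'peak{i}'}\t0\t.\t"
                f"{fe:.4f}\t-1\t{qlog:.4f}\t{summit}\n"
            )


# ---------------------------------------------------------------------------
# BEDPE loops

def read_bedpe(path) -> list[Loop]:
    """BEDPE (6+ columns) -> loops; anchors re-ordered if needed (note logged)."""
    out = []
    for lineno, f in _rows(path):
        try:
            a = GenomicInterval(f[0], int(f[1]), int(f[2]))
            b = GenomicInterval(f[3], int(f[4]), int(f[5]))
            name = f[6] if len(f) > 6 else ""
        except (IndexError, ValueError, ValidationError) as e:
            raise ParseError(path, lineno, f"bad BEDPE line: {e}") from e
        if (a.chrom, a.start) > (b.chrom, b.start):
            logger.info("%s:%d: anchors out of order, swapped", path, lineno)
        out.append(Loop(anchor1=a, anchor2=b, name=name))
    return _warn_if_empty(out, path)


def write_bedpe(path, loops: Sequence[Loop]) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for i, lp in enumerate(loops):
            a, b = lp.anchor1, lp.anchor2
            fh.write(
                f"{a.chrom}\t{a.start}\t{a.end}\t{b.chrom}\t{b.start}\t{b.end}\t"
                f"{lp.name or f'loop{i}'}\n"
            )


# ---------------------------------------------------------------------------
# TSS table

def read_tss(path) -> list[TssRecord]:
    """BED6 (name = gene id) -> TSS records; TSS = start for +, end-1 for -."""
    out = []
    for lineno, f in _rows(path):
        try:
            start, end = int(f[1]), int(f[2])
            strand = f[5] if len(f) > 5 else "+"
            pos = start if strand != "-" else end - 1
            out.append(TssRecord(gene_id=f[3], chrom=f[0], tss_position=pos, strand=strand))
        except (IndexError, ValueError, ValidationError) as e:
            raise ParseError(path, lineno, f"bad TSS line: {e}") from e
    return _warn_if_empty(out, path)


def write_tss(path, tss: Sequence[TssRecord]) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for t in tss:
            fh.write(
                f"{t.chrom}\t{t.tss_position}\t{t.tss_position + 1}\t{t.gene_id}\t0\t{t.strand}\n"
            )


# ---------------------------------------------------------------------------
# count matrices and designs

def read_counts(path, design_path=None) -> CountMatrix:
    """TSV with header row (samples) and first column (feature id).

    ``design_path`` is a two-column TSV (sample, group); without it all
    samples land in one group.  An optional ``length`` column in the
    counts file supplies feature lengths.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    lengths = None
    if "length" in df.columns:
        lengths = df.pop("length")
    if (df.values < 0).any():
        raise ParseError(path, 0, "negative count entry")
    if design_path is not None:
        design = pd.read_csv(
            design_path, sep="\t", header=None, names=["sample", "group"], comment="#"
        )
        groups = pd.Series(design["group"].values, index=design["sample"].values)
    else:
        groups = pd.Series("all", index=df.columns)
    return CountMatrix(counts=df, groups=groups, feature_length=lengths)


def write_counts(path, cm: CountMatrix) -> None:
    df = cm.counts.copy()
    if cm.feature_length is not None:
        df.insert(0, "length", cm.feature_length)
    df.to_csv(path, sep="\t", index_label="feature")


def read_design(path) -> pd.Series:
    design = pd.read_csv(path, sep="\t", header=None, names=["sample", "group"], comment="#")
    return pd.Series(design["group"].values, index=design["sample"].values)


# ---------------------------------------------------------------------------
# tag tables

def read_tags(path, genome_size: int, total_tags: int = 0) -> TagTable:
    """Two-column TSV (chrom, position) or BED3 (position = start) -> TagTable."""
    pos: dict[str, list[int]] = {}
    for lineno, f in _rows(path):
        try:
            pos.setdefault(f[0], []).append(int(f[1]))
        except (IndexError, ValueError) as e:
            raise ParseError(path, lineno, f"bad tag line: {e}") from e
    return TagTable(
        positions={c: np.array(v) for c, v in pos.items()},
        genome_size=genome_size,
        total_tags=total_tags,
    )


# ---------------------------------------------------------------------------
# PWM and FASTA

def read_pwm(path, pseudocount: float = 0.0) -> PWM:
    """JASPAR text (>header then 4 rows A/C/G/T, bracketed or bare counts)."""
    name = ""
    rows: dict[str, list[float]] = {}
    order = "ACGT"
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].strip()
                continue
            parts = line.replace("[", " ").replace("]", " ").split()
            if parts and parts[0].upper() in order and parts[0].upper() not in rows:
                base, vals = parts[0].upper(), parts[1:]
            elif len(rows) < 4:
                base, vals = order[len(rows)], parts
            else:
                raise ParseError(path, lineno, "unexpected extra matrix row")
            try:
                rows[base] = [float(v) for v in vals]
            except ValueError as e:
                raise ParseError(path, lineno, f"bad matrix value: {e}") from e
    if set(rows) != set(order):
        raise ParseError(path, 0, f"need rows A,C,G,T; got {sorted(rows)}")
    matrix = np.array([rows[b] for b in order]).T
    return PWM(matrix=matrix, pseudocount=pseudocount, name=name)


def read_fasta(path) -> dict[str, str]:
    """FASTA -> {name: sequence} (uppercased)."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
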