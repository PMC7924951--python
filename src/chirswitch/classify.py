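"""Classification of condition-specific transcription-factor binding sites.

Comparing the sites bound by one TCF/LEF factor in the low-CHIR condition
with those bound by another in the high-CHIR condition partitions the
union into three sets under the 150 bp center-distance rule:

* **lost** (set 1) — bound only in the low condition;
* **switch** (set 2) — bound in both (matched pairs), where the factors
  interchange between conditions;
* **de novo** (set 3) — bound only in the high condition.

The module also scores overlap significance with a hypergeometric tail,
scans sequences against a position weight matrix (log-odds, both
strands), and stratifies the switch fraction by motif status.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .intervals import Peak, ValidationError, match_peak_sets

__all__ = [
    "SiteClassification",
    "PWM",
    "classify_sites",
    "overlap_significance",
    "pwm_scan",
    "motif_stratified_overlap",
]

_BASES = "ACGT"
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass
class SiteClassification:
    """Partition of two condition-specific peak sets.

    ``set2_switch`` holds (low-condition peak, high-condition peak)
    pairs whose centers are within ``threshold`` bp.
    """

    set1_lost: list[Peak]
    set2_switch: list[tuple[Peak, Peak]]
    set3_denovo: list[Peak]
    threshold: float

    @property
    def counts(self) -> dict[str, int]:
        return {
            "lost": len(self.set1_lost),
            "switch": len(self.set2_switch),
            "denovo": len(self.set3_denovo),
        }


def classify_sites(
    low_peaks: Sequence[Peak],
    high_peaks: Sequence[Peak],
    threshold: float = 150,
) -> SiteClassification:
    """Partition low- and high-condition peaks into lost / switch / de novo.

    Matching is one-to-one by center distance (see
    :func:`~chirswitch.intervals.match_peak_sets`); counts reconcile
    exactly: ``lost + switch = len(low_peaks)`` and
    ``denovo + switch = len(high_peaks)``.
    """
    m = match_peak_sets(low_peaks, high_peaks, threshold=threshold)
    return SiteClassification(
        set1_lost=m.unique_a,
        set2_switch=m.matched,
        set3_denovo=m.unique_b,
        threshold=threshold,
    )


def overlap_significance(
    n_a: int, n_b: int, n_shared: int, n_possible_sites: int
) -> float:
    """log10 hypergeometric upper-tail p-value for an observed overlap.

    Probability of drawing at least ``n_shared`` of the ``n_a`` marked
    sites when ``n_b`` sites are sampled without replacement from a
    universe of ``n_possible_sites``.  Returned on the log10 scale to
    survive the extreme values typical of genome-scale overlaps.  The
    universe size is the caller's modelling choice; the statistic is a
    generic enrichment test, not a reproduction of any published value.
    """
    if not (0 <= n_shared <= min(n_a, n_b) <= n_possible_sites):
        raise ValidationError(
            f"inconsistent counts: shared={n_shared}, nA={n_a}, nB={n_b}, "
            f"universe={n_possible_sites}"
        )
    if n_shared == 0:
        return 0.0  # p = 1
    # upper tail P(X >= n_shared), X ~ Hypergeom(M, n, N)
    logp = stats.hypergeom.logsf(
        n_shared - 1, M=n_possible_sites, n=n_a, N=n_b
    )
    return float(logp / math.log(10))


@dataclass
class PWM:
    """Position weight matrix over A, C, G, T.

    ``matrix`` is length x 4 (columns A, C, G, T).  Raw counts or
    frequencies are accepted: each row is smoothed with ``pseudocount``
    and renormalized to sum to 1.  ``background`` must sum to 1.
    """

    matrix: np.ndarray
    background: np.ndarray | None = None
    pseudocount: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4 or len(self.matrix) == 0:
            raise ValidationError("PWM matrix must be non-empty with 4 columns (A,C,G,T)")
        if np.any(self.matrix < 0):
            raise ValidationError("PWM entries must be >= 0")
        m = self.matrix + self.pseudocount
        row_sums = m.sum(axis=1, keepdims=True)
        if np.any(row_sums <= 0):
            raise ValidationError("PWM row sums to 0 even after pseudocount")
        self.matrix = m / row_sums
        if self.background is None:
            self.background = np.full(4, 0.25)
        else:
            self.background = np.asarray(self.background, dtype=float)
            if self.background.shape != (4,) or not math.isclose(
                float(self.background.sum()), 1.0, rel_tol=0, abs_tol=1e-6
            ):
                raise ValidationError("background must be 4 probabilities summing to 1")

    def __len__(self) -> int:
        return len(self.matrix)

    def log_odds(self) -> np.ndarray:
        """length x 4 matrix of log2(p / background); zeros map to -inf."""
        with np.errstate(divide="ignore"):
            return np.log2(self.matrix) - np.log2(self.background)

    @property
    def max_score(self) -> float:
        return float(self.log_odds().max(axis=1).sum())


def _encode(sequence: str) -> np.ndarray:
    """Map A,C,G,T -> 0..3 and anything else (incl. N) -> 4."""
    table = np.full(256, 4, dtype=np.int8)
    for i, b in enumerate(_BASES):
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return table[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


def reverse_complement(sequence: str) -> str:
    return "".join(_COMPLEMENT.get(b, "N") for b in reversed(sequence.upper()))


def pwm_scan(
    sequence: str,
    pwm: PWM,
    score_min: float,
) -> list[tuple[int, str, float]]:
    """Scan a sequence with a PWM on both strands.

    Each window of ``len(pwm)`` bases scores
    ``sum_i log2(p_i(base) / bg(base))``; the reverse strand scores the
    window's reverse complement.  Windows containing N (or any non-ACGT
    base) are skipped.  Hits with score >= ``score_min`` are returned as
    ``(offset, strand, score)`` sorted by offset (``+`` before ``-`` at
    equal offset); offsets index the forward strand.
    """
    L = len(pwm)
    if L > len(sequence):
        return []
    enc = _encode(sequence)
    lo = pwm.log_odds()
    # pad log-odds with a -inf column for invalid bases
    lo_pad = np.hstack([lo, np.full((L, 1), -np.inf)])
    n_win = len(sequence) - L + 1
    idx = np.arange(n_win)[:, None] + np.arange(L)[None, :]
    codes = enc[idx]
    valid = (codes < 4).all(axis=1)
    with np.errstate(invalid="ignore"):
        fwd = lo_pad[np.arange(L)[None, :], codes].sum(axis=1)
        rc_codes = 3 - codes[:, ::-1]  # complement of reversed window
        rev = np.where(
            valid, lo_pad[np.arange(L)[None, :], np.where(codes < 4, rc_codes, 4)].sum(axis=1), -np.inf
        )
    hits: list[tuple[int, str, float]] = []
    for off in range(n_win):
        if not valid[off]:
            continue
        if fwd[off] >= score_min:
            hits.append((off, "+", float(fwd[off])))
        if rev[off] >= score_min:
            hits.append((off, "-", float(rev[off])))
    return hits


def annotate_motif_hits(
    peaks: Sequence[Peak],
    sequences: Mapping[str, str],
    pwm: PWM,
    score_min: float,
) -> list[Peak]:
    """Return peaks with ``motif_hit`` set from a PWM scan of each peak span.

    ``sequences`` maps chromosome name to its full sequence; a peak is
    motif-positive when any window inside its interval scores at least
    ``score_min`` on either strand.
    """
    out: list[Peak] = []
    for p in peaks:
        seq = sequences.get(p.chrom)
        hit = False
        if seq is not None:
            sub = seq[p.interval.start : p.interval.end]
            hit = bool(pwm_scan(sub, pwm, score_min))
        out.append(
            Peak(
                interval=p.interval,
                q_value=p.q_value,
                fe_by_replicate=p.fe_by_replicate,
                condition=p.condition,
                factor=p.factor,
                motif_hit=hit,
                name=p.name,
            )
        )
    return out


def motif_stratified_overlap(
    classification: SiteClassification,
    motif_flags_low: Mapping[Peak, bool] | None = None,
) -> tuple[float, float]:
    """Fraction of low-condition peaks that switched, by motif status.

    Returns ``(fraction_with_motif, fraction_without_motif)`` where each
    fraction is |switch ∩ stratum| / |stratum| over the low-condition
    peaks.  Motif status comes from ``motif_flags_low`` when given, else
    from each peak's own ``motif_hit`` flag; a missing flag raises.  An
    empty stratum yields ``nan``.
    """

    def flag(p: Peak) -> bool:
        if motif_flags_low is not None:
            if p not in motif_flags_low:
                raise ValidationError(f"no motif flag for low peak {p.name or p.interval}")
            return bool(motif_flags_low[p])
        if p.motif_hit is None:
            raise ValidationError(f"peak {p.name or p.interval} lacks a motif flag")
        return p.motif_hit

    matched_low = [low for low, _ in classification.set2_switch]
    all_low = matched_low + list(classification.set1_lost)
    n_pos = sum(flag(p) for p in all_low)
    n_neg = len(all_low) - n_pos
    pos_matched = sum(flag(p) for p in matched_low)
    neg_matched = len(matched_low) - pos_matched
    frac_pos = pos_matched / n_pos if n_pos else math.nan
    frac_neg = neg_matched / n_neg if n_neg else math.nan
    return frac_pos, frac_neg
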