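"""Shared fixtures and independent brute-force oracles.

The oracles deliberately use naive all-pairs loops and no shared code
with the package internals, so they can arbitrate correctness of the
indexed implementations.
"""

from __future__ import annotations

import numpy as np
import pytest

from chirswitch import GenomicInterval, Loop, Peak, TssRecord


def make_peak(chrom="chr1", center=1000, halfwidth=250, q=1e-6, fe=(30.0, 30.0),
              name="", motif=None, condition=""):
    start = max(0, center - halfwidth)
    return Peak(
        interval=GenomicInterval(chrom, start, center + halfwidth + 1, center=center),
        q_value=q,
        fe_by_replicate=fe,
        name=name,
        motif_hit=motif,
        condition=condition,
    )


def make_loop(chrom="chr1", c1=100_000, c2=400_000, width=10_000, name="",
              condition="", replicate=""):
    hw = width // 2
    return Loop(
        anchor1=GenomicInterval(chrom, c1 - hw, c1 + hw, center=c1),
        anchor2=GenomicInterval(chrom, c2 - hw, c2 + hw, center=c2),
        name=name,
        condition=condition,
        replicate=replicate,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


# ---------------------------------------------------------------------------
# oracles

def oracle_match(set_a, set_b, threshold):
    """All-pairs greedy nearest matching with the symmetric tie-break key.

    Returns the matched pair set as frozenset of (index_a, index_b).
    """
    cand = []
    for i, a in enumerate(set_a):
        for j, b in enumerate(set_b):
            if a.chrom != b.chrom:
                continue
            d = abs(a.center - b.center)
            if d <= threshold:
                cand.append((
                    d,
                    min(a.center, b.center), max(a.center, b.center),
                    min(a.interval.start, b.interval.start),
                    max(a.interval.start, b.interval.start),
                    i, j,
                ))
    cand.sort()
    used_a, used_b, pairs = set(), set(), set()
    for *_k, i, j in cand:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.add((i, j))
    return pairs


def oracle_merge_centers(centers, threshold):
    """Left-to-right greedy chained midpoint merge on one chromosome."""
    out = []
    centers = sorted(centers)
    cur = centers[0]
    for c in centers[1:]:
        if c - cur <= threshold:
            cur = (cur + c) // 2
        else:
            out.append(cur)
            cur = c
    out.append(cur)
    return out


def oracle_loop_match(loops1, loops2, tol):
    """Indices of loops1 having any loops2 partner with both anchors within tol."""
    hits = set()
    for i, l1 in enumerate(loops1):
        for l2 in loops2:
            if l1.chrom_pair != l2.chrom_pair:
                continue
            if (
                abs(l1.anchor1.center - l2.anchor1.center) <= tol
                and abs(l1.anchor2.center - l2.anchor2.center) <= tol
            ):
                hits.add(i)
                break
    return hits


def oracle_assignments(peaks, loops, tol):
    out = set()
    for i, p in enumerate(peaks):
        for li, lp in enumerate(loops):
            for side, anc in ((1, lp.anchor1), (2, lp.anchor2)):
                if p.chrom == anc.chrom and abs(p.center - anc.center) <= tol:
                    out.add((i, li, side))
    return out


def oracle_connections(assignments, loops, tss, tol):
    out = set()
    for (i, li, side) in assignments:
        other = loops[li].anchor1 if side == 2 else loops[li].anchor2
        for t in tss:
            if t.chrom == other.chrom and abs(t.tss_position - other.center) <= tol:
                out.add((i, li, side, t.gene_id))
    return out


def random_peaks(rng, n, chroms=("chr1", "chr2"), span=2_000_000):
    peaks = []
    for k in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        center = int(rng.integers(500, span))
        peaks.append(make_peak(chrom=chrom, center=center, name=f"p{k}"))
    return peaks


def random_loops(rng, n, chroms=("chr1", "chr2"), span=50_000_000):
    loops = []
    for k in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        c1 = int(rng.integers(100_000, span - 2_000_000))
        c2 = c1 + int(rng.integers(100_000, 1_000_000))
        loops.append(make_loop(chrom=chrom, c1=c1, c2=c2, name=f"L{k}"))
    return loops


def random_tss(rng, n, chroms=("chr1", "chr2"), span=50_000_000):
    return [
        TssRecord(
            gene_id=f"g{k}",
            chrom=chroms[int(rng.integers(len(chroms)))],
            tss_position=int(rng.integers(0, span)),
            strand="+" if k % 2 == 0 else "-",
        )
        for k in range(n)
    ]
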