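"""Synthetic two-condition genomics fixtures with planted ground truth.

Every input the pipeline consumes can be generated here at desk scale:

* a two-condition peak landscape with planted lost / switch / de novo
  binding sites, per-replicate fold enrichment, q-values, motif flags
  and Gaussian center jitter;
* negative-binomial count matrices with known per-feature log2 fold
  changes and per-sample size factors;
* a loop universe with conserved and condition-specific loops, replicate
  copies with anchor jitter, and a planted peak -> anchor -> TSS
  connectivity chain whose intended summary is recorded as truth.

Sites and loops are laid out on a coarse grid whose spacing is far above
every matching tolerance, so planted structure is unambiguous: any
recovery error is attributable to the jitter actually injected, not to
accidental collisions.  All randomness flows from ``SimConfig.seed``
through one ``numpy`` generator, so outputs are fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, Peak, ValidationError
from .loops import Loop, TssRecord

__all__ = [
    "SimConfig",
    "PeakLandscape",
    "LoopUniverse",
    "simulate_peak_landscape",
    "simulate_counts",
    "simulate_loop_universe",
    "fig4_preset",
    "fig5_preset",
    "de_null_preset",
    "de_power_preset",
]

_DEFAULT_GENOME = (("chr1", 50_000_000), ("chr2", 50_000_000))
# mouse-like layout for the genome-scale loop scenario
_LARGE_GENOME = tuple((f"chr{i}", 100_000_000) for i in range(1, 20))


@dataclass
class SimConfig:
    """Parameters for all three generators.  See module docstring.

    Jitter defaults are 20% of the matching tolerance they stress
    (30 bp vs the 150 bp peak rule; 2 kb vs the 10 kb loop rule), the
    regime in which matching is exercised but near-lossless.
    """

    seed: int = 0
    genome: tuple[tuple[str, int], ...] = _DEFAULT_GENOME

    # --- peak landscape ---
    n_sites: Mapping[str, int] = field(
        default_factory=lambda: {"lost": 300, "switch": 400, "denovo": 300}
    )
    n_fail: int = 50  # planted filter-failing peaks per condition
    center_jitter_sd: float = 30.0
    fe_mean: float = 40.0
    fe_sd: float = 5.0
    fe_floor: float = 21.0  # truncation keeping planted passers above FE>20
    n_replicates: int = 2
    motif_fraction: Mapping[str, float] = field(
        default_factory=lambda: {"lost": 0.5, "switch": 0.5, "denovo": 0.5}
    )
    site_spacing: int = 5_000
    peak_halfwidth: int = 250

    # --- count matrices ---
    n_genes: int = 2_000
    n_per_group: int = 3
    nb_mean: float = 100.0
    nb_dispersion: float = 0.1
    lfc_value: float = 0.0
    lfc_fraction: float = 0.0

    # --- loop universe (defaults are the genome-scale planted chain) ---
    n_peaks_total: int = 5_530
    n_peaks_in_anchors: int = 1_573
    n_tss_connected: int = 647
    n_via_conserved: int = 371
    n_background_loops: int = 500
    n_decoy_tss: int = 1_000
    anchor_jitter_sd: float = 2_000.0  # condition-level anchor jitter
    replicate_jitter_sd: float = 1_000.0
    anchor_width: int = 10_000
    loop_slot_stride: int = 250_000
    peak_anchor_offset_max: int = 2_000  # planted peaks land this close to anchors
    tss_anchor_offset_max: int = 8_000

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.n_sites.values()):
            raise ValidationError("site counts must be >= 0")
        if self.center_jitter_sd < 0 or self.anchor_jitter_sd < 0:
            raise ValidationError("jitter SDs must be >= 0")
        if not (
            self.n_via_conserved
            <= self.n_tss_connected
            <= self.n_peaks_in_anchors
            <= self.n_peaks_total
        ):
            raise ValidationError("loop chain counts must be nested")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# ---------------------------------------------------------------------------
# presets

def fig4_preset(seed: int = 0) -> SimConfig:
    """Two-condition binding-site scenario with the study's motif structure.

    Planted so that exactly 73% of motif-positive and 29% of
    motif-negative low-condition sites are shared with the high
    condition: 100 motif-positive low sites (73 switch + 27 lost) and
    100 motif-negative (29 switch + 71 lost).
    """
    return SimConfig(
        seed=seed,
        n_sites={"lost": 98, "switch": 102, "denovo": 300},
        motif_fraction={"lost": 27 / 98, "switch": 73 / 102, "denovo": 0.8},
    )


def fig5_preset(seed: int = 0) -> SimConfig:
    """Genome-scale loop scenario planting the published connectivity chain

    (5530 peaks, 1573 in anchors, 647 TSS-connected, 371 via conserved
    loops) on a mouse-sized grid.
    """
    return SimConfig(seed=seed, genome=_LARGE_GENOME)


def de_null_preset(seed: int = 0) -> SimConfig:
    """Null count matrix: no planted fold changes, dispersion 0.1."""
    return SimConfig(seed=seed, lfc_value=0.0, lfc_fraction=0.0)


def de_power_preset(seed: int = 0) -> SimConfig:
    """Power scenario: 10% of features at 8-fold (lfc=3), dispersion 0.05."""
    return SimConfig(seed=seed, nb_dispersion=0.05, lfc_value=3.0, lfc_fraction=0.1)


# ---------------------------------------------------------------------------
# shared helpers

def _grid_positions(
    genome: tuple[tuple[str, int], ...], n: int, stride: int, margin: int
) -> list[tuple[str, int]]:
    """First n (chrom, position) grid points with the given stride."""
    slots: list[tuple[str, int]] = []
    for chrom, length in genome:
        pos = margin
        while pos + margin < length:
            slots.append((chrom, pos))
            pos += stride
    if n > len(slots):
        raise ValidationError(
            f"{n} sites exceed genome capacity of {len(slots)} at spacing {stride}"
        )
    return slots[:n]


def _jitter(rng: np.random.Generator, pos: int, sd: float, lo: int = 300) -> int:
    if sd == 0:
        return max(int(pos), lo)
    return max(int(round(pos + rng.normal(0.0, sd))), lo)


# ---------------------------------------------------------------------------
# peak landscape

@dataclass
class PeakLandscape:
    """Planted two-condition peak sets with a per-site truth table."""

    low_peaks: list[Peak]
    high_peaks: list[Peak]
    truth: pd.DataFrame  # site_id, class, chrom, position, motif

    def truth_class(self, site_id: str) -> str:
        return self.truth.set_index("site_id").loc[site_id, "class"]


def _emit_peak(
    rng: np.random.Generator,
    cfg: SimConfig,
    chrom: str,
    position: int,
    condition: str,
    name: str,
    motif: bool,
    fail_mode: str | None = None,
) -> Peak:
    center = _jitter(rng, position, cfg.center_jitter_sd, lo=cfg.peak_halfwidth + 1)
    fe = np.maximum(
        rng.normal(cfg.fe_mean, cfg.fe_sd, size=cfg.n_replicates), cfg.fe_floor
    )
    q = float(rng.uniform(0.0, 1e-5))
    if fail_mode == "q":
        q = float(rng.uniform(1e-3, 1.0))
    elif fail_mode == "fe":
        fe[int(rng.integers(cfg.n_replicates))] = float(rng.uniform(1.0, 9.0))
    return Peak(
        interval=GenomicInterval(
            chrom, center - cfg.peak_halfwidth, center + cfg.peak_halfwidth + 1,
            center=center,
        ),
        q_value=q,
        fe_by_replicate=tuple(fe),
        condition=condition,
        motif_hit=motif,
        name=name,
    )


def simulate_peak_landscape(config: SimConfig) -> PeakLandscape:
    """Generate low- and high-condition peak sets with planted classes.

    Lost sites emit a peak in the low condition only, switch sites in
    both (with independent center jitter per condition), de novo sites
    in the high condition only.  Within each class, motif flags are
    assigned to an exact ``round(motif_fraction * n)`` count of sites so
    planted fractions reproduce by construction.  ``n_fail`` additional
    peaks per condition carry a failing q-value or a failing replicate
    FE, exercising the upstream filters; they are labeled class
    ``fail_q`` / ``fail_fe`` in the truth table and belong to neither
    condition comparison after filtering.
    """
    rng = config.rng()
    classes = []
    for cls in ("lost", "switch", "denovo"):
        classes += [cls] * int(config.n_sites.get(cls, 0))
    n_real = len(classes)
    n_total = n_real + 2 * config.n_fail
    slots = _grid_positions(config.genome, n_total, config.site_spacing, margin=10_000)
    order = rng.permutation(n_total)
    site_slots = [slots[i] for i in order]

    # exact motif counts per class
    motif_flags: dict[str, list[bool]] = {}
    for cls in ("lost", "switch", "denovo"):
        n = int(config.n_sites.get(cls, 0))
        k = int(round(config.motif_fraction.get(cls, 0.0) * n))
        flags = [True] * k + [False] * (n - k)
        motif_flags[cls] = list(rng.permutation(flags))

    low: list[Peak] = []
    high: list[Peak] = []
    rows = []
    counters = {"lost": 0, "switch": 0, "denovo": 0}
    for idx, cls in enumerate(classes):
        chrom, pos = site_slots[idx]
        motif = motif_flags[cls][counters[cls]]
        counters[cls] += 1
        sid = f"s{idx:05d}"
        rows.append((sid, cls, chrom, pos, motif))
        if cls in ("lost", "switch"):
            low.append(_emit_peak(rng, config, chrom, pos, "low", f"{sid}:low", motif))
        if cls in ("switch", "denovo"):
            high.append(_emit_peak(rng, config, chrom, pos, "high", f"{sid}:high", motif))

    for k in range(2 * config.n_fail):
        idx = n_real + k
        chrom, pos = site_slots[idx]
        condition = "low" if k % 2 == 0 else "high"
        fail_mode = "q" if (k // 2) % 2 == 0 else "fe"
        sid = f"s{idx:05d}"
        rows.append((sid, f"fail_{fail_mode}", chrom, pos, False))
        p = _emit_peak(
            rng, config, chrom, pos, condition, f"{sid}:{condition}", False, fail_mode
        )
        (low if condition == "low" else high).append(p)

    truth = pd.DataFrame(
        rows, columns=["site_id", "class", "chrom", "position", "motif"]
    )
    return PeakLandscape(low_peaks=low, high_peaks=high, truth=truth)


# ---------------------------------------------------------------------------
# count matrices

def simulate_counts(config: SimConfig):
    """NB count matrix with known fold changes; returns (CountMatrix, truth).

    counts_ij ~ NB(mean * sf_j * 2^(lfc_i * [j in group high]), dispersion)
    with per-sample size factors drawn log-uniform in [0.5, 2].  The
    first ``round(lfc_fraction * n_genes)`` features carry
    ``lfc_value``; the truth table records per-feature LFC, gene
    lengths (log-uniform, 0.5-5 kb) and the drawn size factors.
    """
    from .diffexp import CountMatrix  # local import to avoid cycle at module load

    if config.nb_mean <= 0:
        raise ValidationError("nb_mean must be > 0")
    rng = config.rng()
    n = config.n_genes
    k = config.n_per_group
    lfc = np.zeros(n)
    n_de = int(round(config.lfc_fraction * n))
    lfc[:n_de] = config.lfc_value
    sf = np.exp(rng.uniform(np.log(0.5), np.log(2.0), size=2 * k))
    group = np.array([0] * k + [1] * k)
    mu = config.nb_mean * sf[None, :] * 2.0 ** (lfc[:, None] * group[None, :])
    alpha = max(config.nb_dispersion, 1e-8)
    size = 1.0 / alpha
    p = size / (size + mu)
    counts = rng.negative_binomial(size, p)

    genes = [f"g{i:05d}" for i in range(n)]
    samples = [f"low_{j+1}" for j in range(k)] + [f"high_{j+1}" for j in range(k)]
    groups = pd.Series(["low"] * k + ["high"] * k, index=samples)
    lengths = pd.Series(
        np.round(np.exp(rng.uniform(np.log(500), np.log(5000), size=n))).astype(int),
        index=genes,
    )
    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=samples),
        groups=groups,
        feature_length=lengths,
    )
    truth = pd.DataFrame({"gene": genes, "lfc": lfc, "length": lengths.values})
    truth.attrs["size_factors"] = pd.Series(sf, index=samples)
    return cm, truth


# ---------------------------------------------------------------------------
# loop universe

@dataclass
class LoopUniverse:
    """Planted loops, peaks and TSSs with the intended connectivity report."""

    loops: dict[tuple[str, str], list[Loop]]  # (condition, replicate) -> loops
    peaks: list[Peak]  # high-condition factor peaks
    tss: list[TssRecord]
    loop_truth: pd.DataFrame  # loop_id, kind, chrom, planted anchor centers
    expected: dict  # intended ConnectivityReport counts


def _emit_loop(
    rng: np.random.Generator,
    cfg: SimConfig,
    chrom: str,
    c1: int,
    c2: int,
    condition: str,
    replicate: str,
    name: str,
) -> Loop:
    hw = cfg.anchor_width // 2
    j1 = _jitter(rng, c1, cfg.replicate_jitter_sd, lo=hw + 1)
    j2 = _jitter(rng, c2, cfg.replicate_jitter_sd, lo=hw + 1)
    return Loop(
        anchor1=GenomicInterval(chrom, j1 - hw, j1 + hw, center=j1),
        anchor2=GenomicInterval(chrom, j2 - hw, j2 + hw, center=j2),
        condition=condition,
        replicate=replicate,
        name=name,
    )


def simulate_loop_universe(config: SimConfig):
    """Generate replicate/condition loop sets with a planted connectivity chain.

    Loop slots are laid out every ``loop_slot_stride`` bp with anchors at
    fixed offsets inside each slot, so distinct loops can never be
    confused at the 10 kb tolerance.  The planted chain places
    ``n_peaks_in_anchors`` peaks within ``peak_anchor_offset_max`` bp of
    anchor 1 of their own loop, and a TSS within
    ``tss_anchor_offset_max`` bp of anchor 2 for the
    ``n_tss_connected`` connected ones — offsets measured from the
    high-condition replicate-1 emission, so with jitters below the
    tolerances the chain reproduces the planted counts.  Of the
    connected loops, ``n_via_conserved`` are emitted in both conditions
    (condition-level anchor jitter applied independently), the rest only
    in the high condition.  Remaining peaks sit in loop-free slots;
    decoy TSSs sit far from every anchor; ``n_background_loops`` extra
    loops carry no peak and no TSS.

    Returns a :class:`LoopUniverse`.
    """
    if config.anchor_jitter_sd > 0 and config.loop_slot_stride < 4 * config.anchor_jitter_sd:
        import warnings

        warnings.warn("anchor spacing close to jitter scale; matching may be ambiguous")
    rng = config.rng()
    n_loops = config.n_peaks_in_anchors + config.n_background_loops
    n_free = config.n_peaks_total - config.n_peaks_in_anchors
    n_slots = n_loops + max(n_free, config.n_decoy_tss)
    slots = _grid_positions(
        config.genome, n_slots, config.loop_slot_stride, margin=1_000_000
    )
    slots = [slots[i] for i in rng.permutation(len(slots))]
    loop_slots = slots[:n_loops]
    free_slots = slots[n_loops:]

    # planted kinds per loop slot
    kinds: list[str] = []
    for i in range(config.n_peaks_in_anchors):
        if i < config.n_via_conserved:
            kinds.append("peak_tss_conserved")
        elif i < config.n_tss_connected:
            kinds.append("peak_tss_specific")
        else:  # anchor peak, no TSS; alternate conserved/specific
            kinds.append("peak_only_conserved" if i % 2 == 0 else "peak_only_specific")
    for i in range(config.n_background_loops):
        kinds.append(["bg_conserved", "bg_high", "bg_low"][i % 3])

    loops: dict[tuple[str, str], list[Loop]] = {
        (cond, rep): [] for cond in ("low", "high") for rep in ("rep1", "rep2")
    }
    peaks: list[Peak] = []
    tss: list[TssRecord] = []
    rows = []
    a1_off = 50_000
    a2_off = 200_000
    for li, ((chrom, base), kind) in enumerate(zip(loop_slots, kinds)):
        p1, p2 = base + a1_off, base + a2_off
        name = f"L{li:05d}"
        rows.append((name, kind, chrom, p1, p2))
        conserved = "conserved" in kind or kind == "bg_conserved"
        conditions = (
            ("low", "high") if conserved else
            (("low",) if kind == "bg_low" else ("high",))
        )
        emitted_high_rep1: Loop | None = None
        for cond in conditions:
            c1 = _jitter(rng, p1, config.anchor_jitter_sd, lo=config.anchor_width)
            c2 = _jitter(rng, p2, config.anchor_jitter_sd, lo=config.anchor_width)
            for rep in ("rep1", "rep2"):
                lp = _emit_loop(rng, config, chrom, c1, c2, cond, rep, name)
                loops[(cond, rep)].append(lp)
                if cond == "high" and rep == "rep1":
                    emitted_high_rep1 = lp
        if kind.startswith("peak"):
            # planted peak near anchor 1 of the observed high-condition loop
            off = int(rng.integers(-config.peak_anchor_offset_max,
                                   config.peak_anchor_offset_max + 1))
            center = emitted_high_rep1.anchor1.center + off
            peaks.append(
                Peak(
                    interval=GenomicInterval(chrom, center - 250, center + 251,
                                             center=center),
                    q_value=float(rng.uniform(0.0, 1e-5)),
                    fe_by_replicate=tuple(
                        np.maximum(rng.normal(40.0, 5.0, size=2), 21.0)
                    ),
                    condition="high",
                    name=f"P_{name}",
                )
            )
            if kind.startswith("peak_tss"):
                toff = int(rng.integers(-config.tss_anchor_offset_max,
                                        config.tss_anchor_offset_max + 1))
                tss.append(
                    TssRecord(
                        gene_id=f"G_{name}",
                        chrom=chrom,
                        tss_position=emitted_high_rep1.anchor2.center + toff,
                        strand="+" if li % 2 == 0 else "-",
                    )
                )

    # free peaks far from every anchor, and decoy TSSs likewise
    for i in range(n_free):
        chrom, base = free_slots[i]
        center = base + a1_off
        peaks.append(
            Peak(
                interval=GenomicInterval(chrom, center - 250, center + 251),
                q_value=float(rng.uniform(0.0, 1e-5)),
                fe_by_replicate=tuple(np.maximum(rng.normal(40.0, 5.0, size=2), 21.0)),
                condition="high",
                name=f"P_free{i:05d}",
            )
        )
    for i in range(config.n_decoy_tss):
        chrom, base = free_slots[i % len(free_slots)]
        tss.append(
            TssRecord(
                gene_id=f"G_decoy{i:05d}", chrom=chrom,
                tss_position=base + a2_off + (i // len(free_slots)) * 2_000,
            )
        )

    loop_truth = pd.DataFrame(
        rows, columns=["loop_id", "kind", "chrom", "anchor1", "anchor2"]
    )
    expected = {
        "n_peaks_total": config.n_peaks_total,
        "n_peaks_in_anchors": config.n_peaks_in_anchors,
        "n_peaks_tss_connected": config.n_tss_connected,
        "n_via_conserved_loops": config.n_via_conserved,
        "n_via_specific_loops": config.n_tss_connected - config.n_via_conserved,
    }
    return LoopUniverse(
        loops=loops, peaks=peaks, tss=tss, loop_truth=loop_truth, expected=expected
    )
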