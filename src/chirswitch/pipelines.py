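"""End-to-end analyses: binding-site switch classification and loop connectivity.

``run_switch_pipeline`` composes the ChIP filtering, strong-peak
selection, center-distance classification and motif stratification
stages; ``run_connectivity_pipeline`` composes replicate reconciliation,
condition comparison and the peak -> anchor -> TSS chain.  Both write
their intermediates and a machine-readable JSON summary into the
configured output directory.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Sequence

from . import io as cio
from .classify import SiteClassification, classify_sites, motif_stratified_overlap
from .config import PipelineConfig
from .intervals import Peak
from .loops import (
    ConnectivityReport,
    Loop,
    TssRecord,
    compare_condition_loops,
    connectivity_summary,
    reconcile_replicate_loops,
)
from .peaks import filter_chip_peaks, filter_strong_peaks

__all__ = ["run_switch_pipeline", "run_connectivity_pipeline"]

logger = logging.getLogger(__name__)


def _outdir(config: PipelineConfig) -> Path:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def run_switch_pipeline(
    low_peaks: Sequence[Peak],
    high_peaks: Sequence[Peak],
    config: PipelineConfig | None = None,
    write: bool = True,
) -> tuple[SiteClassification, dict]:
    """Filter two condition peak sets and classify lost / switch / de novo.

    Applies the reproducibility filter (q < q_max, FE > fe_min in every
    replicate), optionally the strong-peak filter (FE > fe_strong), then
    one-to-one center matching at ``overlap_bp``.  When motif flags are
    present on the low-condition peaks the switch fraction is stratified
    by motif status.  Returns the classification and a summary dict
    (also written as ``switch_summary.json`` plus three BED files and a
    pair table when ``write``).
    """
    config = config or PipelineConfig()
    stages = {}
    low = filter_chip_peaks(low_peaks, q_max=config.q_max, fe_min=config.fe_min)
    high = filter_chip_peaks(high_peaks, q_max=config.q_max, fe_min=config.fe_min)
    stages["reproducible"] = {"low": len(low), "high": len(high)}
    if config.strong_only:
        low = filter_strong_peaks(low, fe_min=config.fe_strong)
        high = filter_strong_peaks(high, fe_min=config.fe_strong)
        stages["strong"] = {"low": len(low), "high": len(high)}
    cls = classify_sites(low, high, threshold=config.overlap_bp)

    summary = {
        "input": {"low": len(low_peaks), "high": len(high_peaks)},
        "stages": stages,
        "counts": cls.counts,
        "threshold_bp": config.overlap_bp,
    }
    if all(p.motif_hit is not None for p in low):
        frac_pos, frac_neg = motif_stratified_overlap(cls)
        summary["motif_stratified"] = {
            "fraction_with_motif_matched": frac_pos,
            "fraction_without_motif_matched": frac_neg,
        }
    if write:
        out = _outdir(config)
        cio.write_bed(out / "set1_lost.bed", cls.set1_lost)
        cio.write_bed(out / "set3_denovo.bed", cls.set3_denovo)
        with open(out / "set2_switch_pairs.tsv", "wt") as fh:
            fh.write("low_name\tlow_chrom\tlow_center\thigh_name\thigh_center\n")
            for a, b in cls.set2_switch:
                fh.write(f"{a.name}\t{a.chrom}\t{a.center}\t{b.name}\t{b.center}\n")
        (out / "switch_summary.json").write_text(json.dumps(summary, indent=2))
    return cls, summary


def run_connectivity_pipeline(
    peaks: Sequence[Peak],
    loops_by_rep: dict[tuple[str, str], Sequence[Loop]],
    tss: Sequence[TssRecord],
    config: PipelineConfig | None = None,
    conditions: tuple[str, str] = ("low", "high"),
    chain_condition: str | None = None,
    write: bool = True,
) -> tuple[ConnectivityReport, dict]:
    """Reconcile replicates, compare conditions, and run the connectivity chain.

    ``loops_by_rep`` maps (condition, replicate) to loop lists; each
    condition's first two replicates are reconciled at ``loop_tol``,
    conditions compared with the same rule, and the chain
    (peak within ``peak_anchor_tol`` of an anchor; TSS within
    ``tss_anchor_tol`` of the opposite anchor) runs over the
    ``chain_condition`` (default: the second condition) loops, labeled
    conserved when shared between conditions.
    """
    config = config or PipelineConfig()
    cond1, cond2 = conditions
    chain_condition = chain_condition or cond2

    reconciled: dict[str, list[Loop]] = {}
    for cond in conditions:
        reps = sorted(rep for c, rep in loops_by_rep if c == cond)
        if len(reps) >= 2:
            pairs = reconcile_replicate_loops(
                loops_by_rep[(cond, reps[0])],
                loops_by_rep[(cond, reps[1])],
                tol=config.loop_tol,
            )
            reconciled[cond] = [l1 for l1, _ in pairs]
        elif len(reps) == 1:
            reconciled[cond] = list(loops_by_rep[(cond, reps[0])])
        else:
            reconciled[cond] = []

    shared, spec1, spec2 = compare_condition_loops(
        reconciled[cond1], reconciled[cond2], tol=config.loop_tol
    )
    if chain_condition == cond2:
        shared_side = [b for _a, b in shared]
        specific_side = spec2
    else:
        shared_side = [a for a, _b in shared]
        specific_side = spec1

    report = connectivity_summary(
        peaks,
        shared_side,
        specific_side,
        tss,
        peak_anchor_tol=config.peak_anchor_tol,
        tss_anchor_tol=config.tss_anchor_tol,
    )
    summary = {
        "replicated_loops": {c: len(v) for c, v in reconciled.items()},
        "loops": {
            "shared": len(shared),
            f"specific_{cond1}": len(spec1),
            f"specific_{cond2}": len(spec2),
        },
        "chain_condition": chain_condition,
        "report": report.as_dict(),
    }
    if write:
        out = _outdir(config)
        cio.write_bedpe(out / "loops_shared.bedpe", shared_side)
        cio.write_bedpe(out / "loops_specific.bedpe", specific_side)
        all_loops = list(shared_side) + list(specific_side)
        with open(out / "connections.tsv", "wt") as fh:
            fh.write("peak\tloop\tside\tgene\n")
            for c in report.connections:
                pk = peaks[c.peak_index]
                fh.write(
                    f"{pk.name or c.peak_index}\t"
                    f"{all_loops[c.loop_index].name or c.loop_index}\t"
                    f"{c.side}\t{c.gene_id}\n"
                )
        (out / "connectivity_summary.json").write_text(json.dumps(summary, indent=2))
    return report, summary
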