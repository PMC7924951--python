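"""Count normalization and negative-binomial differential testing.

This is a documented, simplified NB Wald pipeline in the DESeq2 family:
median-of-ratios size factors, a pooled within-group method-of-moments
dispersion per feature, log2 fold changes with a 0.5 pseudocount, a
normal-approximation Wald test on the fold change, and Benjamini-Hochberg
adjustment.  It deliberately omits DESeq2's shrinkage estimators, Cook's
distance outlier handling and independent filtering, and is not
bit-compatible with DESeq2; its guarantees are the calibration
properties exercised in the test suite (near-nominal type-I error under
an NB null, high power for large planted effects).

The module also computes TPM and applies the downstream gene/region
calling rules: a differentially expressed gene needs group-mean
TPM > 5, fold change > 3 and NB p < 0.05 (all strict); a differentially
accessible region (DAR) needs BH-adjusted p below the chosen cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .intervals import GenomicInterval, ValidationError

__all__ = [
    "CountMatrix",
    "DiffResult",
    "size_factors",
    "nb_wald_test",
    "compute_tpm",
    "call_differential_genes",
    "call_dars",
    "dar_windows",
]

_LN2 = np.log(2.0)


@dataclass
class CountMatrix:
    """Integer counts, features x samples, with a sample -> group design.

    ``feature_length`` (bp per feature) is required only for TPM.
    """

    counts: pd.DataFrame
    groups: pd.Series
    feature_length: pd.Series | None = None

    def __post_init__(self) -> None:
        c = self.counts
        if (c.values < 0).any():
            raise ValidationError("counts must be non-negative")
        if not np.allclose(c.values, np.round(c.values)):
            raise ValidationError("counts must be integers")
        self.counts = c.astype(np.int64)
        self.groups = pd.Series(self.groups)
        missing = set(c.columns) - set(self.groups.index)
        if missing:
            raise ValidationError(f"samples without group label: {sorted(missing)}")
        self.groups = self.groups.loc[c.columns]
        if self.feature_length is not None:
            self.feature_length = pd.Series(self.feature_length).loc[c.index]
            if (self.feature_length <= 0).any():
                raise ValidationError("feature lengths must be > 0")

    @property
    def features(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def samples_in_group(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])


@dataclass
class DiffResult:
    """Per-feature differential test output (group B relative to group A)."""

    table: pd.DataFrame  # columns: baseMean, log2FC, pvalue, padj
    group_a: str
    group_b: str
    tpm_by_group: pd.DataFrame | None = field(default=None)


def size_factors(counts: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios sample scaling factors.

    For features with nonzero counts in every sample, factor_j is the
    median over features of count_ij / geometric-mean_i.  Raises when no
    feature is nonzero everywhere (a pseudo-reference over nonzero
    entries would be needed; supply deeper counts instead).
    """
    c = counts.counts if isinstance(counts, CountMatrix) else counts
    vals = c.values.astype(float)
    all_pos = (vals > 0).all(axis=1)
    if not all_pos.any():
        raise ValidationError(
            "no feature has nonzero counts in all samples; cannot form the "
            "median-of-ratios reference (consider a pseudo-reference fallback)"
        )
    logs = np.log(vals[all_pos])
    log_geomean = logs.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logs - log_geomean, axis=0))
    return pd.Series(factors, index=c.columns, name="size_factor")


def _mom_dispersion(norm: np.ndarray, group_idx: list[np.ndarray]) -> np.ndarray:
    """Moderated method-of-moments NB dispersion per feature.

    For each group, alpha_g = (s^2 - m) / m^2 on the normalized counts;
    the per-feature estimate averages valid groups.  With few samples
    this raw estimate is noisy enough to break Wald calibration, so it
    is floored at the across-feature median dispersion (a conservative
    moderation in the common-dispersion spirit of edgeR) and at 1e-8.
    """
    n_feat = norm.shape[0]
    est = np.zeros((n_feat, len(group_idx)))
    ok = np.zeros((n_feat, len(group_idx)), dtype=bool)
    for g, idx in enumerate(group_idx):
        x = norm[:, idx]
        m = x.mean(axis=1)
        v = x.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (v - m) / m**2
        good = m > 0
        est[:, g] = np.where(good, a, 0.0)
        ok[:, g] = good
    n_ok = ok.sum(axis=1)
    alpha = np.where(n_ok > 0, est.sum(axis=1) / np.maximum(n_ok, 1), 0.0)
    common = float(np.median(alpha))
    return np.maximum(alpha, max(common, 1e-8))


def nb_wald_test(
    counts: CountMatrix,
    group_a: str,
    group_b: str,
) -> DiffResult:
    """Two-group negative-binomial Wald test on normalized counts.

    Per feature: normalized group means mu_A, mu_B; dispersion alpha by
    pooled method of moments, floored at the across-feature median;
    LFC = log2((mu_B + 0.5) / (mu_A + 0.5));
    Wald statistic LFC / SE(LFC) with the NB variance mu + alpha*mu^2
    propagated through the log transform; two-sided normal p-value; BH
    adjustment over all tested features.
    """
    cols_a = counts.samples_in_group(group_a)
    cols_b = counts.samples_in_group(group_b)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValidationError(
            "each group needs >= 2 samples for dispersion estimation "
            f"(got {len(cols_a)} in {group_a!r}, {len(cols_b)} in {group_b!r})"
        )
    sub = counts.counts[cols_a + cols_b]
    sf = size_factors(sub)
    norm = sub.values / sf.values[None, :]
    idx_a = np.arange(len(cols_a))
    idx_b = np.arange(len(cols_a), len(cols_a) + len(cols_b))

    mu_a = norm[:, idx_a].mean(axis=1)
    mu_b = norm[:, idx_b].mean(axis=1)
    alpha = _mom_dispersion(norm, [idx_a, idx_b])

    lfc = np.log2(mu_b + 0.5) - np.log2(mu_a + 0.5)
    # delta method: Var(log2(mean + 0.5)) = Var(mean) / ((mean+0.5)^2 ln2^2)
    var_a = (mu_a + alpha * mu_a**2) / len(idx_a) / ((mu_a + 0.5) ** 2 * _LN2**2)
    var_b = (mu_b + alpha * mu_b**2) / len(idx_b) / ((mu_b + 0.5) ** 2 * _LN2**2)
    se = np.sqrt(var_a + var_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, lfc / np.where(se > 0, se, 1.0), 0.0)
    pvalue = 2.0 * stats.norm.sf(np.abs(z))
    pvalue = np.where(lfc == 0.0, 1.0, pvalue)
    padj = multipletests(pvalue, method="fdr_bh")[1]

    table = pd.DataFrame(
        {
            "baseMean": (mu_a + mu_b) / 2.0,
            "log2FC": lfc,
            "pvalue": pvalue,
            "padj": padj,
        },
        index=counts.features,
    )
    return DiffResult(table=table, group_a=group_a, group_b=group_b)


def compute_tpm(counts: CountMatrix) -> pd.DataFrame:
    """Transcripts per million; every column sums to 1e6.

    rate_i = count_i / (length_i / 1000); TPM_i = rate_i / sum(rate) * 1e6.
    """
    if counts.feature_length is None:
        raise ValidationError("feature_length is required for TPM")
    rate = counts.counts.values / (counts.feature_length.values[:, None] / 1000.0)
    totals = rate.sum(axis=0)
    if (totals <= 0).any():
        bad = list(counts.samples[totals <= 0])
        raise ValidationError(f"zero total length-normalized rate in samples {bad}")
    tpm = rate / totals[None, :] * 1e6
    return pd.DataFrame(tpm, index=counts.features, columns=counts.samples)


def call_differential_genes(
    diff: DiffResult,
    tpm: pd.DataFrame,
    groups: pd.Series,
    tpm_min: float = 5.0,
    fc_min: float = 3.0,
    p_max: float = 0.05,
) -> pd.DataFrame:
    """Apply the DE gene rules: TPM > tpm_min, FC > fc_min, p < p_max (all strict).

    TPM is summarized as the mean per group; the TPM rule applies to the
    larger of the two group means.  Fold change is the ratio of group
    -mean TPMs with a 0.5 pseudocount, taken in whichever direction
    exceeds 1.  Direction ("up" = higher in group B) follows the fold
    change sign.  Returns the called genes with their statistics.
    """
    missing = diff.table.index.difference(tpm.index)
    if len(missing):
        raise ValidationError(f"tested genes missing from TPM: {list(missing)[:5]}...")
    tpm = tpm.loc[diff.table.index]
    cols_a = list(groups.index[groups == diff.group_a])
    cols_b = list(groups.index[groups == diff.group_b])
    tpm_a = tpm[cols_a].mean(axis=1)
    tpm_b = tpm[cols_b].mean(axis=1)
    ratio = (tpm_b + 0.5) / (tpm_a + 0.5)
    fc = np.maximum(ratio, 1.0 / ratio)
    keep = (
        (np.maximum(tpm_a, tpm_b) > tpm_min)
        & (fc > fc_min)
        & (diff.table["pvalue"] < p_max)
    )
    out = diff.table.loc[keep].copy()
    out["tpm_" + diff.group_a] = tpm_a[keep]
    out["tpm_" + diff.group_b] = tpm_b[keep]
    out["fold_change"] = fc[keep]
    out["direction"] = np.where(ratio[keep] > 1.0, "up", "down")
    return out


def dar_windows(
    merged_peaks: Sequence[GenomicInterval], halfwidth: int = 500
) -> list[GenomicInterval]:
    """±halfwidth windows around merged peak centers, for DAR counting."""
    return [
        GenomicInterval(
            iv.chrom,
            max(0, iv.center - halfwidth),
            iv.center + halfwidth + 1,
            center=iv.center,
        )
        for iv in merged_peaks
    ]


def call_dars(
    merged_atac_peaks: Sequence[GenomicInterval],
    window_counts: CountMatrix,
    group_a: str,
    group_b: str,
    padj_max: float = 0.05,
) -> pd.DataFrame:
    """Differentially accessible regions among merged ATAC peak windows.

    Runs :func:`nb_wald_test` on the per-window count matrix (rows must
    align with ``merged_atac_peaks``) and keeps windows with BH-adjusted
    p below ``padj_max``, labeling each with the condition of higher
    accessibility.
    """
    if len(merged_atac_peaks) != len(window_counts.features):
        raise ValidationError(
            f"{len(merged_atac_peaks)} windows but "
            f"{len(window_counts.features)} count rows"
        )
    diff = nb_wald_test(window_counts, group_a, group_b)
    tab = diff.table.copy()
    tab["chrom"] = [iv.chrom for iv in merged_atac_peaks]
    tab["center"] = [iv.center for iv in merged_atac_peaks]
    out = tab.loc[tab["padj"] < padj_max].copy()
    out["higher_in"] = np.where(out["log2FC"] > 0, group_b, group_a)
    return out
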