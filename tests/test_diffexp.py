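"""Size factors, NB Wald test behaviour, TPM and the DE/DAR calling rules."""

import numpy as np
import pandas as pd
import pytest

import chirswitch as cs
from chirswitch import (
    CountMatrix,
    ValidationError,
    call_dars,
    call_differential_genes,
    compute_tpm,
    dar_windows,
    nb_wald_test,
    size_factors,
)
from chirswitch.intervals import GenomicInterval


def cm_from(counts, groups, lengths=None):
    df = pd.DataFrame(counts)
    df.index = [f"g{i}" for i in range(len(df))]
    groups = pd.Series(groups, index=df.columns)
    lengths = (
        pd.Series(lengths, index=df.index) if lengths is not None else None
    )
    return CountMatrix(counts=df, groups=groups, feature_length=lengths)


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        cm = cm_from({"a": [5, 10, 3], "b": [5, 10, 3]}, ["g1", "g2"])
        assert np.allclose(size_factors(cm), 1.0)

    def test_doubled_sample_scales_proportionally(self):
        cm = cm_from({"a": [5, 10, 3], "b": [10, 20, 6]}, ["g1", "g2"])
        sf = size_factors(cm)
        assert sf["b"] / sf["a"] == pytest.approx(2.0)

    def test_single_feature_hand_arithmetic(self):
        cm = cm_from({"a": [4], "b": [16]}, ["g1", "g2"])
        sf = size_factors(cm)
        assert sf["a"] == pytest.approx(0.5) and sf["b"] == pytest.approx(2.0)

    def test_no_everywhere_nonzero_feature_rejected(self):
        cm = cm_from({"a": [0, 5], "b": [5, 0]}, ["g1", "g2"])
        with pytest.raises(ValidationError):
            size_factors(cm)


class TestNbWaldTest:
    def test_identical_groups_null_identity(self):
        counts = {"a1": [10, 50], "a2": [12, 60], "b1": [10, 50], "b2": [12, 60]}
        cm = cm_from(counts, ["A", "A", "B", "B"])
        res = nb_wald_test(cm, "A", "B").table
        assert np.allclose(res["log2FC"], 0.0)
        assert np.allclose(res["pvalue"], 1.0)

    def test_group_swap_flips_lfc_and_keeps_p(self, rng):
        cm, _ = cs.simulate_counts(cs.de_power_preset(5))
        fwd = nb_wald_test(cm, "low", "high").table
        rev = nb_wald_test(cm, "high", "low").table
        assert np.allclose(fwd["log2FC"], -rev["log2FC"])
        assert np.allclose(fwd["pvalue"], rev["pvalue"])

    def test_small_group_rejected(self):
        cm = cm_from({"a1": [5], "b1": [5], "b2": [6]}, ["A", "B", "B"])
        with pytest.raises(ValidationError):
            nb_wald_test(cm, "A", "B")

    def test_bh_adjustment_monotone_and_never_smaller(self):
        cm, _ = cs.simulate_counts(cs.de_null_preset(2))
        res = nb_wald_test(cm, "low", "high").table
        assert (res["padj"] >= res["pvalue"] - 1e-15).all()
        ranked = res.sort_values("pvalue")
        assert (np.diff(ranked["padj"].values) >= -1e-12).all()

    def test_null_type_one_error_near_nominal(self):
        cm, _ = cs.simulate_counts(cs.de_null_preset(1))
        res = nb_wald_test(cm, "low", "high").table
        frac = (res["pvalue"] < 0.05).mean()
        assert 0.03 <= frac <= 0.07

    def test_power_on_planted_eightfold_effects(self):
        cm, truth = cs.simulate_counts(cs.de_power_preset(1))
        res = nb_wald_test(cm, "low", "high").table
        de = truth["lfc"].values != 0
        power = (res["padj"].values[de] < 0.05).mean()
        assert power > 0.8

    def test_directionally_agrees_with_pydeseq2_on_planted_effects(self):
        """Independent cross-check: strong planted effects must be found by
        both this test and DESeq2 (pydeseq2), with consistent LFC signs."""
        pydeseq2 = pytest.importorskip("pydeseq2")
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        cfg = cs.de_power_preset(4)
        cfg.n_genes = 300
        cm, truth = cs.simulate_counts(cfg)
        mine = nb_wald_test(cm, "low", "high").table

        meta = pd.DataFrame({"condition": cm.groups.values}, index=cm.samples)
        dds = DeseqDataSet(
            counts=cm.counts.T, metadata=meta, design="~condition", quiet=True
        )
        dds.deseq2()
        ds = DeseqStats(dds, contrast=["condition", "high", "low"], quiet=True)
        ds.summary()
        ref = ds.results_df

        de = truth["lfc"].values != 0
        assert (mine["padj"].values[de] < 0.05).all()
        assert (ref["padj"].values[de] < 0.05).all()
        sign_agree = np.sign(mine["log2FC"].values[de]) == np.sign(
            ref["log2FoldChange"].values[de]
        )
        assert sign_agree.all()
        r = np.corrcoef(mine["log2FC"], ref["log2FoldChange"])[0, 1]
        assert r > 0.9


class TestTpm:
    def test_equal_rates_split_evenly(self):
        cm = cm_from({"s": [10, 20]}, ["g1"], lengths=[1000, 2000])
        tpm = compute_tpm(cm)
        assert np.allclose(tpm["s"], [5e5, 5e5])

    def test_single_feature_forced_to_million(self):
        cm = cm_from({"s": [7]}, ["g1"], lengths=[800])
        assert compute_tpm(cm)["s"].iloc[0] == pytest.approx(1e6)

    def test_depth_invariance_and_column_sums(self, rng):
        cm, _ = cs.simulate_counts(cs.de_null_preset(3))
        tpm = compute_tpm(cm)
        assert np.allclose(tpm.sum(axis=0), 1e6, rtol=1e-6)
        doubled = CountMatrix(
            counts=cm.counts * 2, groups=cm.groups, feature_length=cm.feature_length
        )
        assert np.allclose(compute_tpm(doubled), tpm)

    def test_missing_lengths_rejected(self):
        cm = cm_from({"s1": [1], "s2": [2]}, ["a", "b"])
        with pytest.raises(ValidationError):
            compute_tpm(cm)


class TestCallDifferentialGenes:
    @staticmethod
    def _fixture(tpm_a, tpm_b, p):
        table = pd.DataFrame(
            {"baseMean": [10.0], "log2FC": [np.log2((tpm_b + 0.5) / (tpm_a + 0.5))],
             "pvalue": [p], "padj": [p]},
            index=["g0"],
        )
        diff = cs.DiffResult(table=table, group_a="A", group_b="B")
        tpm = pd.DataFrame({"a1": [tpm_a], "a2": [tpm_a], "b1": [tpm_b], "b2": [tpm_b]},
                           index=["g0"])
        groups = pd.Series(["A", "A", "B", "B"], index=tpm.columns)
        return diff, tpm, groups

    def test_passing_gene_called_with_direction(self):
        diff, tpm, groups = self._fixture(50, 2, 0.001)
        out = call_differential_genes(diff, tpm, groups)
        assert list(out.index) == ["g0"] and out["direction"].iloc[0] == "down"

    def test_tpm_and_fc_rules_reject(self):
        diff, tpm, groups = self._fixture(4, 2, 1e-6)
        assert call_differential_genes(diff, tpm, groups).empty

    def test_fc_boundary_strict(self):
        # ratio exactly 3 with the 0.5 pseudocount: tpm_b = 3*tpm_a + 1
        diff, tpm, groups = self._fixture(10.0, 31.0, 0.001)
        assert call_differential_genes(diff, tpm, groups).empty
        diff, tpm, groups = self._fixture(10.0, 31.1, 0.001)
        assert not call_differential_genes(diff, tpm, groups).empty

    def test_tpm_boundary_strict(self):
        diff, tpm, groups = self._fixture(5.0, 0.5, 0.001)
        assert call_differential_genes(diff, tpm, groups).empty


class TestCallDars:
    @staticmethod
    def _window_fixture(rng, n_windows=200, planted=5, fold=10.0, depth=200.0):
        windows = [
            GenomicInterval("chr1", i * 10_000, i * 10_000 + 1001)
            for i in range(n_windows)
        ]
        mu = np.full((n_windows, 6), depth)
        mu[:planted, 3:] *= fold
        counts = rng.poisson(mu)
        df = pd.DataFrame(
            counts, index=[f"w{i}" for i in range(n_windows)],
            columns=["a1", "a2", "a3", "b1", "b2", "b3"],
        )
        cm = CountMatrix(
            counts=df, groups=pd.Series(["low"] * 3 + ["high"] * 3, index=df.columns)
        )
        return windows, cm

    def test_planted_tenfold_windows_recovered(self, rng):
        windows, cm = self._window_fixture(rng)
        dars = call_dars(windows, cm, "low", "high")
        assert set(dars.index) >= {f"w{i}" for i in range(5)}
        assert (dars.loc["w0":"w4", "higher_in"] == "high").all()

    def test_identical_window_not_a_dar(self, rng):
        windows, cm = self._window_fixture(rng, planted=0)
        flat = cm.counts.copy()
        flat.iloc[10] = 150  # identical across all samples
        cm2 = CountMatrix(counts=flat, groups=cm.groups)
        dars = call_dars(windows, cm2, "low", "high")
        assert "w10" not in dars.index

    def test_null_false_discoveries_bounded(self, rng):
        windows, cm = self._window_fixture(rng, planted=0)
        dars = call_dars(windows, cm, "low", "high")
        # BH at 0.05 over an all-null set: expected false calls ~ 0
        assert len(dars) <= max(2, 0.05 * len(windows))

    def test_row_mismatch_rejected(self, rng):
        windows, cm = self._window_fixture(rng)
        with pytest.raises(ValidationError):
            call_dars(windows[:-1], cm, "low", "high")

    def test_dar_windows_span_and_center(self):
        merged = [GenomicInterval("chr1", 5_000, 6_000)]
        (w,) = dar_windows(merged, halfwidth=500)
        assert (w.start, w.end, w.center) == (5_000, 6_001, 5_500)
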