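"""Loop reconciliation, condition comparison and the connectivity chain."""

import pytest

from chirswitch import (
    ConnectivityReport,
    GenomicInterval,
    Loop,
    TssRecord,
    ValidationError,
    assign_peaks_to_anchors,
    compare_condition_loops,
    connect_peaks_to_tss,
    connectivity_summary,
    reconcile_replicate_loops,
)

from conftest import (
    make_loop,
    make_peak,
    oracle_assignments,
    oracle_connections,
    oracle_loop_match,
    random_loops,
    random_peaks,
    random_tss,
)


class TestLoopType:
    def test_anchors_normalized_to_order(self):
        a = GenomicInterval("chr1", 400_000, 410_000)
        b = GenomicInterval("chr1", 100_000, 110_000)
        lp = Loop(anchor1=a, anchor2=b)
        assert lp.anchor1.start < lp.anchor2.start

    def test_tss_validation(self):
        with pytest.raises(ValidationError):
            TssRecord(gene_id="g", chrom="chr1", tss_position=-5)


class TestReconcileReplicateLoops:
    def test_shift_within_tolerance_replicated(self):
        l1 = make_loop(c1=15_000, c2=115_000)
        l2 = make_loop(c1=20_000, c2=120_000)
        assert len(reconcile_replicate_loops([l1], [l2])) == 1

    def test_single_anchor_failure_suffices(self):
        l1 = make_loop(c1=15_000, c2=115_000)
        l2 = make_loop(c1=15_000, c2=130_000)  # second anchor 15 kb off
        assert reconcile_replicate_loops([l1], [l2]) == []

    def test_identity_all_replicated(self, rng):
        loops = random_loops(rng, 50)
        pairs = reconcile_replicate_loops(loops, loops)
        assert len(pairs) == 50 and all(a is b for a, b in pairs)

    def test_boundary_inclusive(self):
        l1 = make_loop(c1=100_000, c2=400_000)
        at = make_loop(c1=110_000, c2=400_000)
        beyond = make_loop(c1=110_001, c2=400_000)
        assert len(reconcile_replicate_loops([l1], [at])) == 1
        assert reconcile_replicate_loops([l1], [beyond]) == []

    def test_agrees_with_brute_force_and_is_symmetric_on_pairs(self, rng):
        for _ in range(30):
            r1 = random_loops(rng, int(rng.integers(0, 80)))
            r2 = random_loops(rng, int(rng.integers(0, 80)))
            got = {r1.index(a) for a, _ in reconcile_replicate_loops(r1, r2)}
            assert got == oracle_loop_match(r1, r2, 10_000)


class TestCompareConditionLoops:
    def test_disjoint_and_identical(self, rng):
        c1 = random_loops(rng, 30, chroms=("chr1",))
        far = [make_loop(chrom="chr2", c1=l.anchor1.center, c2=l.anchor2.center)
               for l in c1]
        shared, s1, s2 = compare_condition_loops(c1, far)
        assert not shared and len(s1) == 30 and len(s2) == 30
        shared, s1, s2 = compare_condition_loops(c1, c1)
        assert len(shared) == 30 and not s1 and not s2

    def test_jitter_boundary(self):
        base = make_loop(c1=1_000_000, c2=1_500_000)
        near = make_loop(c1=1_009_000, c2=1_509_000)
        far = make_loop(c1=1_011_000, c2=1_511_000)
        assert len(compare_condition_loops([base], [near])[0]) == 1
        shared, s1, s2 = compare_condition_loops([base], [far])
        assert not shared and len(s1) == 1 and len(s2) == 1

    def test_partition_reconciles(self, rng):
        c1 = random_loops(rng, 60)
        c2 = random_loops(rng, 45)
        shared, s1, s2 = compare_condition_loops(c1, c2)
        assert len(shared) + len(s1) == 60
        assert len(shared) + len(s2) == 45


class TestChain:
    def test_peak_anchor_distance_rule(self):
        loop = make_loop(c1=15_000, c2=315_000)
        near = make_peak(center=12_000)
        far = make_peak(center=21_000)
        got = assign_peaks_to_anchors([near, far], [loop])
        assert [(a.peak_index, a.side) for a in got] == [(0, 1)]
        assert assign_peaks_to_anchors([near], []) == []

    def test_tss_opposite_anchor_rule(self):
        loop = make_loop(c1=15_000, c2=315_000)
        peak = make_peak(center=15_500)
        assignments = assign_peaks_to_anchors([peak], [loop])
        tss_near = TssRecord("gA", "chr1", 315_000 + 14_000)
        tss_far = TssRecord("gB", "chr1", 315_000 + 15_500)
        tss_same_side = TssRecord("gC", "chr1", 15_000 + 1_000)
        conns = connect_peaks_to_tss(assignments, [loop], [tss_near, tss_far, tss_same_side])
        assert [c.gene_id for c in conns] == ["gA"]

    def test_agrees_with_brute_force(self, rng):
        for _ in range(20):
            loops = random_loops(rng, int(rng.integers(1, 60)))
            peaks = random_peaks(rng, int(rng.integers(0, 120)), span=50_000_000)
            tss = random_tss(rng, int(rng.integers(0, 120)))
            got_a = assign_peaks_to_anchors(peaks, loops)
            exp_a = oracle_assignments(peaks, loops, 5_000)
            assert {(a.peak_index, a.loop_index, a.side) for a in got_a} == exp_a
            got_c = connect_peaks_to_tss(got_a, loops, tss)
            exp_c = oracle_connections(exp_a, loops, tss, 15_000)
            assert {(c.peak_index, c.loop_index, c.side, c.gene_id) for c in got_c} == exp_c

    def test_tolerance_monotonicity(self, rng):
        loops = random_loops(rng, 40)
        peaks = random_peaks(rng, 200, span=50_000_000)
        tss = random_tss(rng, 100)
        prev_anchor, prev_conn = -1, -1
        for scale in (0.5, 1.0, 3.0):
            rep = connectivity_summary(
                peaks, loops, [], tss,
                peak_anchor_tol=5_000 * scale, tss_anchor_tol=15_000 * scale,
            )
            assert rep.n_peaks_in_anchors >= prev_anchor
            assert rep.n_peaks_tss_connected >= prev_conn
            prev_anchor, prev_conn = rep.n_peaks_in_anchors, rep.n_peaks_tss_connected


class TestConnectivityReport:
    def test_printed_chain_percentages(self):
        rep = ConnectivityReport(
            n_peaks_total=5530,
            n_peaks_in_anchors=1573,
            n_peaks_tss_connected=647,
            n_via_conserved_loops=371,
            n_via_specific_loops=647 - 371,
        )
        assert rep.pct_in_anchors == 28
        assert rep.pct_tss_connected == 41
        assert rep.pct_via_conserved == 57

    def test_empty_chain_all_zero(self):
        rep = connectivity_summary([make_peak(center=10_000)], [], [], [])
        assert rep.as_dict()["n_peaks_in_anchors"] == 0
        assert rep.pct_in_anchors == 0 and rep.pct_tss_connected == 0

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValidationError):
            ConnectivityReport(10, 20, 5, 3, 2)
        with pytest.raises(ValidationError):
            ConnectivityReport(10, 8, 5, 3, 3)

    def test_conserved_wins_attribution_tie(self):
        loop_shared = make_loop(c1=15_000, c2=315_000, name="S")
        loop_spec = make_loop(c1=16_000, c2=316_000, name="D")
        peak = make_peak(center=15_500)
        tss = [TssRecord("g", "chr1", 315_500)]
        rep = connectivity_summary([peak], [loop_shared], [loop_spec], tss)
        assert rep.n_via_conserved_loops == 1 and rep.n_via_specific_loops == 0
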