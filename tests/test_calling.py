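import math
import random

import pytest
from hypothesis import given, settings, strategies as st

from capseq import (
    EmptyDataError,
    FivePrimeCountTable,
    TssRecord,
    TssSet,
    call_tss,
    cluster_tss,
    compute_rrs,
    depleted_sites,
    enrichment_score,
    match_known_tss,
)
from oracles import brute_force_cluster


def table(entries, rt=None):
    counts = {("chr", p, s): c for p, s, c in entries}
    t = FivePrimeCountTable("t", counts, total_mapped=rt or sum(counts.values()))
    compute_rrs(t)
    return t


class TestEnrichmentScore:
    @pytest.mark.parametrize("cap,ctrl,expected", [
        (3.0, 3.0, 0.0),
        (4.0, 1.0, 2.0),
        (2.0, 0.0, math.inf),
        (0.0, 2.0, -math.inf),
    ])
    def test_log2_ratio_with_zero_conventions(self, cap, ctrl, expected):
        assert enrichment_score(cap, ctrl) == expected

    def test_both_zero_signalled_distinctly(self):
        e = enrichment_score(0.0, 0.0)
        assert math.isnan(e)
        assert not e >= 0.0  # can never satisfy a TSS threshold


class TestCallTss:
    def test_hand_evaluated_thresholds(self):
        """Six positions pushed through the filter exactly as by hand:
        Rt=10 on both sides so RRS = count * 1e5."""
        cap = table([(10, "+", 1), (20, "+", 2), (30, "+", 3),
                     (40, "-", 2), (50, "-", 1), (60, "-", 1)], rt=10)
        ctrl = table([(20, "+", 4), (30, "+", 3), (40, "-", 1),
                      (70, "+", 2)], rt=10)
        tss = call_tss(cap, ctrl, rrs_min=1.5e5, enrichment_min=0.0)
        # pos10 (rrs 1e5 < min) out; pos20 enrichment log2(2/4)<0 out;
        # pos30 enrichment 0 in; pos40 log2(2/1)>0 in; pos50/60 below rrs_min
        assert {(r.position, r.strand) for r in tss} == {(30, "+"), (40, "-")}

    def test_low_rrs_excluded_regardless_of_enrichment(self):
        cap = table([(10, "+", 14), (20, "+", 100)], rt=10_000_000)
        ctrl = table([(99, "+", 1)], rt=10_000_000)
        tss = call_tss(cap, ctrl, rrs_min=1.5)
        assert [r.position for r in tss] == [20]  # pos10 has RRS 1.4

    def test_depleted_position_excluded_from_tss(self):
        cap = table([(10, "+", 5)], rt=1_000_000)
        ctrl = table([(10, "+", 10)], rt=1_000_000)
        assert len(call_tss(cap, ctrl)) == 0
        dep = depleted_sites(cap, ctrl)
        assert [r.position for r in dep] == [10]
        assert dep.records[0].enrichment == pytest.approx(-1.0)

    def test_control_identical_to_cap_keeps_rrs_filter_only(self):
        cap = table([(10, "+", 20), (20, "-", 1), (30, "+", 5)], rt=1_000_000)
        tss = call_tss(cap, cap, rrs_min=1.5)
        assert {r.position for r in tss} == {10, 30}
        assert all(r.enrichment == 0.0 for r in tss)

    def test_empty_cap_is_an_error(self):
        ctrl = table([(10, "+", 1)])
        with pytest.raises(EmptyDataError):
            call_tss(FivePrimeCountTable("cap"), ctrl)

    def test_empty_control_gives_infinite_enrichment(self):
        cap = table([(10, "+", 20)], rt=10)
        tss = call_tss(cap, FivePrimeCountTable("ctrl"), rrs_min=1.5)
        assert tss.records[0].enrichment == math.inf


class TestDepletedSites:
    def test_control_only_position_is_depleted(self):
        cap = table([(99, "+", 1)], rt=1_000_000)
        ctrl = table([(10, "+", 20)], rt=1_000_000)
        dep = depleted_sites(cap, ctrl)
        assert [r.position for r in dep] == [10]
        assert dep.records[0].enrichment == -math.inf

    def test_equal_rrs_not_depleted(self):
        cap = table([(10, "+", 20)], rt=1_000_000)
        assert len(depleted_sites(cap, cap)) == 0


def rec(pos, rrs, strand="+", ref="chr"):
    return TssRecord(ref, pos, strand, 1, rrs)


class TestClusterTss:
    def test_nearby_positions_merge_to_strongest(self):
        out = cluster_tss(TssSet([rec(100, 10.0), rec(103, 5.0)]), cutoff=5)
        peaks = out.peaks()
        assert len(peaks) == 1 and peaks[0].position == 100
        assert len({r.cluster_id for r in out}) == 1

    def test_beyond_cutoff_stays_separate(self):
        out = cluster_tss(TssSet([rec(100, 10.0), rec(106, 5.0)]), cutoff=5)
        assert len(out.peaks()) == 2

    def test_strands_never_co_cluster(self):
        out = cluster_tss(TssSet([rec(100, 10.0, "+"), rec(100, 5.0, "-")]), cutoff=5)
        assert len(out.peaks()) == 2

    def test_equal_rrs_tie_breaks_leftmost(self):
        out = cluster_tss(TssSet([rec(103, 5.0), rec(100, 5.0)]), cutoff=5)
        (peak,) = out.peaks()
        assert peak.position == 100

    def test_membership_is_distance_to_peak_not_chaining(self):
        # 100 (strong), 104, 108: 108 is within 5 of 104 but not of 100
        out = cluster_tss(TssSet([rec(100, 10.0), rec(104, 5.0), rec(108, 4.0)]),
                          cutoff=5)
        peaks = sorted(p.position for p in out.peaks())
        assert peaks == [100, 108]

    def test_negative_cutoff_rejected(self):
        with pytest.raises(ValueError):
            cluster_tss(TssSet([rec(1, 1.0)]), cutoff=-1)

    def test_idempotent_on_peaks(self):
        rng = random.Random(0)
        records = [rec(rng.randrange(1, 500), rng.random() * 10) for _ in range(40)]
        once = cluster_tss(TssSet(records), cutoff=5)
        again = cluster_tss(TssSet(once.peaks()), cutoff=5)
        assert [(r.position, r.strand) for r in again.peaks()] == \
               [(r.position, r.strand) for r in once.peaks()]

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(
        st.tuples(st.integers(1, 60), st.sampled_from("+-"),
                  st.floats(0.1, 100, allow_nan=False)),
        min_size=1, max_size=12, unique_by=lambda e: (e[0], e[1])),
        st.integers(0, 10))
    def test_matches_exhaustive_strongest_first_oracle(self, entries, cutoff):
        records = [rec(p, r, s) for p, s, r in entries]
        out = cluster_tss(TssSet(records), cutoff=cutoff)
        oracle = brute_force_cluster(
            [("chr", s, p, r) for p, s, r in entries], cutoff)
        got = {
            (peak.position, peak.strand):
                {(m.position, m.strand) for m in members}
            for peak, members in (
                (next(m for m in mem if m.is_cluster_peak), mem)
                for mem in out.clusters().values()
            )
        }
        want = {
            (peak[2], peak[1]): {(m[2], m[1]) for m in members}
            for peak, members in oracle
        }
        assert got == want

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(
        st.tuples(st.integers(1, 300), st.sampled_from("+-"),
                  st.floats(0.1, 100, allow_nan=False)),
        min_size=1, max_size=30, unique_by=lambda e: (e[0], e[1])))
    def test_peak_separation_invariant(self, entries):
        out = cluster_tss(TssSet([rec(p, r, s) for p, s, r in entries]), cutoff=5)
        for strand in "+-":
            peaks = sorted(p.position for p in out.peaks() if p.strand == strand)
            assert all(b - a > 5 for a, b in zip(peaks, peaks[1:]))


class TestMatchKnownTss:
    def test_window_boundary(self):
        tss = TssSet([rec(1000, 1.0)])
        common, specific = match_known_tss(tss, [(1025, "+")], window=25)
        assert len(common) == 1 and len(specific) == 0
        common, specific = match_known_tss(tss, [(1026, "+")], window=25)
        assert len(common) == 0 and len(specific) == 1

    def test_strand_agreement_required_when_stranded(self):
        tss = TssSet([rec(1000, 1.0, "+")])
        common, _ = match_known_tss(tss, [(1000, "-")], window=25)
        assert len(common) == 0
        # unstranded catalog entries match either strand
        common, _ = match_known_tss(tss, [(1000, None)], window=25)
        assert len(common) == 1

    def test_empty_catalog_all_specific(self):
        tss = TssSet([rec(1000, 1.0), rec(2000, 2.0)])
        common, specific = match_known_tss(tss, [])
        assert len(common) == 0 and len(specific) == 2
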