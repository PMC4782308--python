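import numpy as np
import pytest

from capseq import (
    GenomeSequence,
    TssRecord,
    TssSet,
    build_pwm,
    cluster_tss,
    dinucleotide_classes,
    extract_windows,
    genome_background,
    information_content,
    initiation_precision,
    sample_null_windows,
    scan_fraction_with_motif,
)
from capseq.promoter import dinucleotide_group


def tss(pos, strand="+", rrs=1.0, ref="g"):
    return TssRecord(ref, pos, strand, 1, rrs)


@pytest.fixture
def genome():
    rng = np.random.default_rng(7)
    return GenomeSequence("g", "".join(rng.choice(list("ACGT"), size=5000)))


class TestWindows:
    def test_plus_strand_window(self, genome):
        (w,) = extract_windows([tss(100, "+")], genome, upstream=2, downstream=1)
        assert w.sequence == genome.subseq(98, 101, "+")
        assert w.at_offset(0) == genome.base(100)

    def test_minus_strand_window_is_reverse_complemented(self, genome):
        (w,) = extract_windows([tss(100, "-")], genome, upstream=2, downstream=1)
        assert w.sequence == genome.subseq(99, 102, "-")
        assert w.at_offset(0) == genome.base(100, "-")
        assert w.at_offset(-1) == genome.base(101, "-")

    def test_truncated_windows_are_skipped(self, genome):
        assert extract_windows([tss(10, "+")], genome, upstream=45, downstream=5) == []


class TestInformationContent:
    def test_pure_column_against_uniform_background(self):
        assert information_content(["A", "A", "A"])[0] == pytest.approx(2.0)

    def test_background_matching_column_has_zero_bits(self):
        ic = information_content(["A", "C", "G", "T"])
        assert ic[0] == pytest.approx(0.0)

    def test_non_negative_everywhere(self, genome):
        wins = extract_windows([tss(p) for p in range(100, 4000, 200)], genome)
        ic = information_content(wins, genome_background(genome))
        assert (ic >= 0).all()

    def test_planted_minus10_gives_local_peak(self, default_sim):
        """Planted TATAAT at -12..-7 shows as an information peak there."""
        genome = default_sim["genome"]
        wins = extract_windows(
            [TssRecord("sim", t.position, t.strand, 1, 1.0)
             for t in default_sim["truth"].tss],
            genome)
        ic = information_content(wins, genome_background(genome))
        offsets = np.arange(len(ic)) - 45
        peak_region = ic[(offsets >= -12) & (offsets <= -7)]
        flank = ic[offsets <= -40]  # upstream of the planted -35 element
        assert peak_region.max() > 3 * np.median(flank)


class TestPwm:
    def test_consensus_log_odds_without_pseudocount(self):
        pwm = build_pwm(["ACGT", "ACGT"], pseudocount=0.0)
        assert pwm.score("ACGT") == pytest.approx(8.0)  # 2 bits per position

    def test_pseudocount_keeps_scores_finite(self):
        pwm = build_pwm(["AAAA", "AAAA"], pseudocount=0.5)
        assert np.isfinite(pwm.log_odds).all()

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            build_pwm(["ACGT", "ACG"])

    def test_consensus_beats_every_single_mismatch_variant(self):
        rng = np.random.default_rng(0)
        motif = "TATAAT"
        # sites: consensus with 20% per-base noise
        sites = []
        for _ in range(100):
            s = [b if rng.random() > 0.2 else rng.choice(list("ACGT")) for b in motif]
            sites.append("".join(s))
        pwm = build_pwm(sites)
        consensus_score = pwm.score(motif)
        for i in range(6):
            for b in "ACGT":
                if b == motif[i]:
                    continue
                variant = motif[:i] + b + motif[i + 1 :]
                assert pwm.score(variant) < consensus_score


class TestScanFraction:
    def test_null_self_calibration(self, genome):
        # noisy sites give the PWM near-continuous scores, avoiding ties
        # at the calibration quantile
        rng = np.random.default_rng(3)
        sites = ["".join(b if rng.random() > 0.2 else rng.choice(list("ACGT"))
                         for b in "TATAAT") for _ in range(100)]
        pwm = build_pwm(sites)
        null1 = sample_null_windows(genome, 400, rng=rng)
        null2 = sample_null_windows(genome, 400, rng=rng)
        frac, null_frac = scan_fraction_with_motif(null1, pwm, null2, 0.95)
        sd = np.sqrt(0.05 * 0.95 / 400)
        assert frac == pytest.approx(0.05, abs=3 * sd)

    def test_all_consensus_windows_hit(self, default_sim):
        """Simulated promoters all carry the planted TATAAT and all score
        above a random-window threshold."""
        genome = default_sim["genome"]
        wins = extract_windows(
            [TssRecord("sim", t.position, t.strand, 1, 1.0)
             for t in default_sim["truth"].tss], genome)
        pwm = build_pwm(["TATAAT"] * 50)
        rng = np.random.default_rng(4)
        null = sample_null_windows(genome, 400, rng=rng)
        frac, _ = scan_fraction_with_motif(wins, pwm, null, 0.95)
        assert frac == 1.0

    def test_mixture_fraction_arithmetic(self, default_sim):
        """50/50 mixture of promoter and random windows scores halfway
        between 1 and the null rate."""
        genome = default_sim["genome"]
        rng = np.random.default_rng(5)
        promoters = extract_windows(
            [TssRecord("sim", t.position, t.strand, 1, 1.0)
             for t in default_sim["truth"].tss], genome)
        decoys = sample_null_windows(genome, len(promoters), rng=rng)
        null = sample_null_windows(genome, 400, rng=rng)
        pwm = build_pwm(["TATAAT"] * 50)
        frac, null_frac = scan_fraction_with_motif(promoters + decoys, pwm, null, 0.95)
        n = len(promoters) + len(decoys)
        expected = 0.5 + null_frac / 2
        assert frac == pytest.approx(expected, abs=3 * np.sqrt(0.25 / n) + 0.02)

    def test_pwm_longer_than_scan_interval_rejected(self, genome):
        pwm = build_pwm(["TATAATTATAATTA"] * 3)
        wins = extract_windows([tss(1000)], genome)
        with pytest.raises(ValueError):
            scan_fraction_with_motif(wins, pwm, wins, scan_start=-10, scan_end=-4)


class TestDinucleotideClasses:
    def test_group_assignment(self):
        assert dinucleotide_group("C", "A") == "YR"
        assert dinucleotide_group("G", "C") == "RY"
        assert dinucleotide_group("T", "T") == "YY"
        assert dinucleotide_group("A", "G") == "RR"

    def test_minus_one_plus_one_lookup(self):
        genome = GenomeSequence("g", "AACAGG")
        # + strand TSS at 4: -1 base = pos3 = C, +1 = pos4 = A -> CA, YR
        table = dinucleotide_classes([tss(4, "+")], genome)
        assert table.table.loc["CA", "count"] == 1
        # - strand TSS at 3 reads the reverse complement: -1 = pos4(-) = T,
        # +1 = pos3(-) = G -> TG, YR
        table = dinucleotide_classes([tss(3, "-")], genome)
        assert table.table.loc["TG", "count"] == 1

    def test_fractions_sum_to_one(self, genome):
        table = dinucleotide_classes([tss(p) for p in range(50, 3000, 37)], genome)
        assert table.table["tss_fraction"].sum() == pytest.approx(1.0)
        assert table.group_fractions.sum() == pytest.approx(1.0)

    def test_planted_yr_bias_recovered(self, default_sim):
        """Truth TSS carry the configured YR bias (plus the random-background
        YR rate for unbiased ones)."""
        cfg = default_sim["config"]
        records = [TssRecord("sim", t.position, t.strand, 1, 1.0)
                   for t in default_sim["truth"].tss]
        table = dinucleotide_classes(records, default_sim["genome"])
        expected = cfg.yr_bias + (1 - cfg.yr_bias) * 0.25
        n = len(records)
        sd = np.sqrt(expected * (1 - expected) / n)
        assert table.group_fractions["YR"] == pytest.approx(expected, abs=4 * sd)

    def test_strand_mirror_invariance(self):
        rng = np.random.default_rng(11)
        seq = "".join(rng.choice(list("ACGT"), size=400))
        g = GenomeSequence("g", seq)
        from Bio.Seq import reverse_complement
        g_rc = GenomeSequence("g", reverse_complement(seq))
        records = [tss(int(p), s) for p, s in
                   zip(rng.integers(10, 390, 30), rng.choice(["+", "-"], 30))]
        mirrored = [tss(g.length - r.position + 1, "-" if r.strand == "+" else "+")
                    for r in records]
        t1 = dinucleotide_classes(records, g)
        t2 = dinucleotide_classes(mirrored, g_rc)
        assert (t1.table["count"] == t2.table["count"]).all()


class TestInitiationPrecision:
    def test_singleton_cluster_is_precise(self):
        clustered = cluster_tss(TssSet([tss(100, rrs=5.0)]), 5)
        df = initiation_precision(clustered)
        assert df["precise"].all()

    def test_half_split_is_imprecise(self):
        clustered = cluster_tss(
            TssSet([tss(100, rrs=10.0), tss(102, rrs=10.0)]), 5)
        df = initiation_precision(clustered, peak_fraction_min=0.75)
        assert not df["precise"].any()
        assert df["peak_fraction"].iloc[0] == pytest.approx(0.5)

    def test_precision_decreases_with_jitter(self, default_sim, tmp_path):
        """A zero-jitter simulation yields a higher precise fraction than
        the default (jittered) one."""
        from capseq import (SimConfig, call_tss, cluster_tss, compute_rrs,
                            extract_five_prime_ends, read_alignments, simulate)
        cfg = SimConfig(seed=3, precise_fraction=1.0, n_tss=80,
                        n_processed_sites=20, depth_cap=20_000,
                        depth_control=20_000, genome_length=60_000, n_genes=15)
        out = tmp_path / "sharp"
        simulate(cfg, out)
        cap = extract_five_prime_ends(read_alignments(out / "cap.sam"))
        ctrl = extract_five_prime_ends(read_alignments(out / "control.sam"))
        compute_rrs(cap), compute_rrs(ctrl)
        sharp = initiation_precision(cluster_tss(call_tss(cap, ctrl), 5))
        jittered = initiation_precision(default_sim["clustered"])
        assert sharp["precise"].mean() > jittered["precise"].mean()
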