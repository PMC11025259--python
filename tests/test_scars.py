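import numpy as np
import pandas as pd
import pytest

from wexscape.core import SegmentRecord, ValidationError
from wexscape.scars import (
    MB,
    CnaCall,
    ScarScores,
    classify_log2r,
    cna_frequency_profile,
    count_hrd_loh,
    count_lst,
    count_tai,
    gene_cna_call,
    hrd_score,
    preprocess_segments,
    score_sample,
)


def seg(start_mb, end_mb, cnt, cnm, chrom="chr1", sample="S1", log2r=None):
    return SegmentRecord(sample, chrom, int(start_mb * MB) + 1, int(end_mb * MB),
                         cnt, cnm, log2r=log2r)


class TestPreprocess:
    def test_short_segment_removed_and_flanks_merged(self, toy_genome):
        segs = [seg(0, 20, 2, 1), seg(20, 22, 3, 1), seg(22, 50, 2, 1)]
        out = preprocess_segments(segs, toy_genome)
        assert len(out) == 1
        assert (out[0].start, out[0].end) == (1, 50 * MB)
        assert (out[0].cn_total, out[0].cn_minor) == (2, 1)

    def test_identity_without_short_segments(self, toy_genome):
        segs = [seg(0, 20, 2, 1), seg(20, 40, 3, 1)]
        assert preprocess_segments(segs, toy_genome) == segs

    def test_centromere_split(self, toy_genome):
        segs = [seg(40, 60, 2, 1)]
        out = preprocess_segments(segs, toy_genome)
        assert len(out) == 2
        assert out[0].end == 50 * MB  # p-side piece ends at centromere start
        assert out[1].start == 53 * MB + 1
        assert all((s.cn_total, s.cn_minor) == (2, 1) for s in out)

    def test_chromosome_boundary_violation(self, toy_genome):
        with pytest.raises(ValidationError, match="boundary"):
            preprocess_segments([seg(90, 120, 2, 1)], toy_genome)


class TestLoh:
    def test_qualifying_segment(self, toy_genome):
        segs = preprocess_segments([seg(55, 75, 1, 0)], toy_genome)
        assert count_hrd_loh(segs, toy_genome) == 1

    def test_whole_chromosome_excluded(self, toy_genome):
        segs = preprocess_segments([seg(0, 100, 1, 0)], toy_genome)
        assert count_hrd_loh(segs, toy_genome) == 0

    def test_length_threshold_strict(self, toy_genome):
        assert count_hrd_loh([seg(55, 69, 1, 0)], toy_genome) == 0  # 14 Mb
        assert count_hrd_loh([seg(55, 70, 1, 0)], toy_genome) == 0  # exactly 15 Mb
        assert count_hrd_loh([seg(55, 70.1, 1, 0)], toy_genome) == 1

    def test_homozygous_deletion_not_counted(self, toy_genome):
        assert count_hrd_loh([seg(55, 75, 0, 0)], toy_genome) == 0


class TestTai:
    def test_p_telomeric_imbalance(self, toy_genome):
        # 30 Mb (3,1) abutting the p telomere; centromere at 50 Mb
        assert count_tai([seg(0, 30, 3, 1)], toy_genome) == 1

    def test_balanced_two_one_is_imbalanced_but_2_2_is_not(self, toy_genome):
        # (2,1): major 1 vs minor 1? no - major = 2-1 = 1 = minor -> balanced
        assert count_tai([seg(0, 30, 2, 1)], toy_genome) == 0
        # (4,2) is balanced as well
        assert count_tai([seg(0, 30, 4, 2)], toy_genome) == 0
        # (3,1): major 2 != minor 1 -> imbalanced
        assert count_tai([seg(0, 30, 3, 1)], toy_genome) == 1

    def test_interstitial_not_counted(self, toy_genome):
        assert count_tai([seg(10, 40, 3, 1)], toy_genome) == 0

    def test_cross_centromere_disqualified(self, toy_genome):
        segs = preprocess_segments([seg(0, 60, 3, 1)], toy_genome)
        assert count_tai(segs, toy_genome) == 0

    def test_minimum_size(self, toy_genome):
        assert count_tai([seg(0, 10, 3, 1)], toy_genome) == 0  # 10 Mb < 11
        assert count_tai([seg(0, 11, 3, 1)], toy_genome) == 1


class TestLst:
    def test_two_breakpoints(self, toy_genome):
        segs = [seg(0, 20, 2, 1), seg(20, 35, 3, 1), seg(35, 50, 2, 1)]
        assert count_lst(segs, toy_genome) == 2

    def test_uniform_arm(self, toy_genome):
        assert count_lst([seg(0, 50, 2, 1)], toy_genome) == 0

    def test_short_flank_not_counted(self, toy_genome):
        segs = [seg(0, 20, 2, 1), seg(20, 28, 3, 1), seg(28, 50, 2, 1)]  # 8 Mb middle
        assert count_lst(segs, toy_genome) == 0

    def test_gap_rule(self, toy_genome):
        near = [seg(0, 20, 2, 1), seg(22, 42, 3, 1)]   # 2 Mb gap < 3 Mb
        far = [seg(0, 20, 2, 1), seg(24, 44, 3, 1)]    # 4 Mb gap
        assert count_lst(near, toy_genome) == 1
        assert count_lst(far, toy_genome) == 0

    def test_counted_per_arm(self, toy_genome):
        segs = [seg(0, 25, 2, 1), seg(25, 50, 3, 1),          # p arm breakpoint
                seg(53, 75, 2, 1), seg(75, 100, 1, 0)]        # q arm breakpoint
        assert count_lst(segs, toy_genome) == 2


class TestHrdScore:
    @pytest.mark.parametrize("loh,tai,lst,score,high", [
        (10, 15, 20, 45, True),
        (0, 0, 0, 0, False),
        (14, 14, 14, 42, True),   # boundary inclusive
        (14, 14, 13, 41, False),
    ])
    def test_sum_and_threshold(self, loh, tai, lst, score, high):
        s = hrd_score(loh, tai, lst)
        assert s.hrd_score == score and s.hrd_high is high

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            ScarScores("S1", -1, 0, 0)

    def test_monotone_in_events(self):
        assert hrd_score(5, 5, 5).hrd_score < hrd_score(6, 5, 5).hrd_score


class TestScoreSampleProperties:
    def test_diploid_genome_scores_zero(self, genome):
        segs = []
        for name in genome.names():
            c = genome[name]
            segs.append(SegmentRecord("S1", name, 1, c.length, 2, 1))
        s = score_sample(segs, genome)
        assert (s.n_loh, s.n_tai, s.n_lst) == (0, 0, 0)
        assert not s.hrd_high

    def test_split_invariance(self, toy_genome):
        base = [seg(0, 30, 3, 1), seg(55, 75, 1, 0)]
        split = [seg(0, 12, 3, 1), seg(12, 30, 3, 1), seg(55, 65, 1, 0), seg(65, 75, 1, 0)]
        a = score_sample(base, toy_genome)
        b = score_sample(split, toy_genome)
        assert (a.n_loh, a.n_tai, a.n_lst) == (b.n_loh, b.n_tai, b.n_lst) == (1, 1, 0)


class TestSyntheticRecovery:
    @pytest.mark.parametrize("targets", [(3, 2, 4), (0, 0, 0), (10, 6, 8)])
    def test_exact_recovery(self, targets, genome):
        from wexscape.simulate import simulate_segments

        rng = np.random.default_rng(42)
        segs = simulate_segments(targets, genome, rng, "S1")
        s = score_sample(segs, genome)
        assert (s.n_loh, s.n_tai, s.n_lst) == targets

    def test_extra_loh_increments_only_loh(self, genome):
        from wexscape.simulate import simulate_segments

        a = score_sample(simulate_segments((3, 2, 4), genome,
                                           np.random.default_rng(1), "S1"), genome)
        b = score_sample(simulate_segments((4, 2, 4), genome,
                                           np.random.default_rng(1), "S1"), genome)
        assert (b.n_loh, b.n_tai, b.n_lst) == (a.n_loh + 1, a.n_tai, a.n_lst)

    def test_infeasible_targets_rejected(self, toy_genome):
        from wexscape.simulate import simulate_segments

        with pytest.raises(ValidationError):
            simulate_segments((50, 0, 0), toy_genome, np.random.default_rng(0), "S1")


GENE_MODEL = pd.DataFrame({
    "gene": ["G1", "G2"],
    "chrom": ["chr1", "chr1"],
    "start": [10 * MB, 60 * MB],
    "end": [11 * MB, 61 * MB],
})


class TestGeneCna:
    @pytest.mark.parametrize("log2r,call", [
        (0.25, CnaCall.GAIN),
        (0.2, CnaCall.NEUTRAL),     # strict threshold
        (0.95, CnaCall.AMPLIFICATION),
        (-0.25, CnaCall.LOSS),
        (-0.95, CnaCall.DELETION),
        (0.0, CnaCall.NEUTRAL),
    ])
    def test_thresholds(self, log2r, call):
        assert classify_log2r(log2r) is call

    def test_log2r_column_used(self):
        calls = gene_cna_call([seg(5, 20, 2, 1, log2r=0.25)], GENE_MODEL)
        byg = {c.gene: c for c in calls}
        assert byg["G1"].call is CnaCall.GAIN

    def test_log2r_derived_from_cn(self):
        calls = gene_cna_call([seg(5, 20, 2, 1), seg(55, 70, 8, 1)], GENE_MODEL)
        byg = {c.gene: c for c in calls}
        assert byg["G1"].call is CnaCall.NEUTRAL and byg["G1"].value == 0.0
        assert byg["G2"].call is CnaCall.AMPLIFICATION  # log2(8/2) = 2

    def test_no_overlap_is_missing_neutral(self):
        calls = gene_cna_call([seg(55, 70, 3, 1)], GENE_MODEL)
        byg = {c.gene: c for c in calls}
        assert byg["G1"].call is CnaCall.NEUTRAL and byg["G1"].missing

    def test_max_overlap_wins(self):
        # G1 spans 10-11 Mb; first segment overlaps 0.4 Mb, second 0.6 Mb
        segs = [seg(5, 10.4, 8, 1), seg(10.4, 30, 2, 1)]
        byg = {c.gene: c for c in gene_cna_call(segs, GENE_MODEL)}
        assert byg["G1"].call is CnaCall.NEUTRAL


class TestCnaFrequency:
    def test_group_percentages(self):
        calls = pd.DataFrame({
            "sample_id": ["A", "B", "C", "D"],
            "group": ["IBC"] * 4,
            "gene": ["G1"] * 4,
            "call": ["gain", "amplification", "neutral", "loss"],
            "log2r": [0.3, 1.0, 0.0, -0.3],
            "missing": [False] * 4,
        })
        freq = cna_frequency_profile(calls)
        assert freq.loc["G1", "pct_gain_IBC"] == pytest.approx(50.0)
        assert freq.loc["G1", "pct_loss_IBC"] == pytest.approx(25.0)

    def test_bounds(self, small_cohort):
        from wexscape.scars import cna_call_table, load_gene_model

        dataset, _ = small_cohort
        freq = cna_frequency_profile(cna_call_table(dataset, load_gene_model()))
        pct = freq.filter(like="pct_")
        assert ((pct >= 0) & (pct <= 100)).all().all()
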