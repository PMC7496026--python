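import numpy as np
import pytest

from promdiv.align import (
    PairwiseAlignment,
    alignment_score,
    anchor_and_extend,
    filter_pairs,
    global_align,
    map_query_to_target,
    select_candidate,
)
from promdiv.io import GenomeSource, PslHit, revcomp
from promdiv.validation import brute_force_align_score
from conftest import random_seq


def hit(matches, t_start, t_end, strand="+", q_size=601, blocks=None):
    span = t_end - t_start
    blocks = blocks or ((span,), (0,), (t_start,))
    return PslHit(
        matches=matches, strand=strand, q_name="q", q_size=q_size,
        q_start=0, q_end=span, t_name="t", t_size=10_000,
        t_start=t_start, t_end=t_end,
        block_sizes=blocks[0], q_starts=blocks[1], t_starts=blocks[2],
    )


class TestSelectCandidate:
    def test_longest_passing_hit_wins(self):
        hits = [hit(238, 0, 250), hit(149, 0, 150), hit(368, 0, 400)]
        assert select_candidate(hits).span == 400

    def test_none_when_identity_too_low(self):
        assert select_candidate([hit(200, 0, 250), hit(300, 0, 400)]) is None

    def test_single_passing_hit(self):
        h = hit(240, 0, 250)
        assert select_candidate([h, hit(100, 0, 150)]) is h


class TestGlobalAlign:
    def test_identity(self):
        aln = global_align("ACGT", "ACGT")
        assert aln.column_classes() == ["match"] * 4
        assert alignment_score(aln) == 100.0

    def test_single_gap_in_b(self):
        aln = global_align("ACGT", "AGT")
        assert aln.column_classes().count("gap_b") == 1
        assert aln.dp_score == pytest.approx(brute_force_align_score("ACGT", "AGT"))

    def test_all_mismatch_cheaper_than_gaps(self):
        aln = global_align("AAAA", "TTTT")
        assert aln.column_classes() == ["mismatch"] * 4
        assert aln.dp_score == pytest.approx(-4.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            global_align("", "ACGT")

    def test_matches_bruteforce_on_short_random_pairs(self, rng):
        for _ in range(40):
            a = random_seq(rng, int(rng.integers(1, 8)))
            b = random_seq(rng, int(rng.integers(1, 8)))
            assert global_align(a, b).dp_score == pytest.approx(
                brute_force_align_score(a, b)
            ), (a, b)

    def test_n_scores_as_mismatch(self):
        aln = global_align("ANAN", "ANAN")
        assert aln.n_matches == 2  # only the As count

    def test_score_symmetry(self, rng):
        for _ in range(15):
            a, b = random_seq(rng, 30), random_seq(rng, 28)
            s1 = alignment_score(global_align(a, b))
            s2 = alignment_score(global_align(b, a))
            assert s1 == pytest.approx(s2)


class TestAlignmentScore:
    def test_570_of_601(self):
        row_a = "A" * 570 + "C" * 31
        row_b = "A" * 570 + "G" * 31
        score = alignment_score(PairwiseAlignment(row_a, row_b))
        assert round(score, 1) == 94.8

    def test_zero_matches(self):
        assert alignment_score(PairwiseAlignment("AAAA", "TTTT")) == 0.0


class TestFilterPairs:
    @staticmethod
    def _aln(row_a, row_b, tss):
        aln = PairwiseAlignment(row_a, row_b)
        aln.a_tss = tss
        return aln

    def test_score_cutoff(self):
        # 89.9% identity: 899 matches over 1000 aligned bases
        row_a = "CA" + "A" * 897 + "G" * 101
        row_b = "CA" + "A" * 897 + "T" * 101
        aln = self._aln(row_a, row_b, 1)
        assert alignment_score(aln) == pytest.approx(89.9)
        assert filter_pairs([aln], min_score=90) == []

    def test_yr_mismatch_dropped(self):
        # columns 1-2 hold the Y/R of row A (tss=2): A has "CA", B has "TA"
        aln = self._aln("ACAAAAAAAAA", "ATAAAAAAAAA", 2)
        assert filter_pairs([aln], min_score=0) == []

    def test_conserved_yr_kept(self):
        aln = self._aln("ACAAAAAAAAA", "ACAAAAAAAAA", 2)
        assert filter_pairs([aln], min_score=90) == [aln]


class TestAnchorAndExtend:
    def _setup(self, strand="+"):
        rng = np.random.default_rng(42)
        promoter = list(random_seq(rng, 601))
        promoter[299], promoter[300] = "C", "A"  # initiator
        promoter = "".join(promoter)
        flank_l, flank_r = random_seq(rng, 700), random_seq(rng, 700)
        if strand == "+":
            target = flank_l + promoter + flank_r
        else:
            target = flank_l + revcomp(promoter) + flank_r
        genome = GenomeSource.from_sequences({"t": target})
        if strand == "+":
            blocks = ((601,), (0,), (700,))
        else:
            blocks = ((601,), (0,), (700,))
        h = PslHit(
            matches=601, strand=strand, q_name="q", q_size=601, q_start=0,
            q_end=601, t_name="t", t_size=len(target), t_start=700,
            t_end=700 + 601, block_sizes=blocks[0], q_starts=blocks[1],
            t_starts=blocks[2],
        )
        return promoter, genome, h

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_unmutated_duplicate_recovered_exactly(self, strand):
        promoter, genome, h = self._setup(strand)
        window, reason = anchor_and_extend(h, genome)
        assert reason is None
        assert window.sequence == promoter
        assert window.tss_index == 300

    def test_no_yr_rejection(self):
        promoter, genome, h = self._setup()
        seq = list(genome.unmasked["t"])
        seq[700 + 299] = "G"  # break the pyrimidine
        genome = GenomeSource.from_sequences({"t": "".join(seq)})
        assert anchor_and_extend(h, genome) == (None, "no-YR")

    def test_gap_rejection_near_contig_end(self):
        promoter, genome, h = self._setup()
        short = GenomeSource.from_sequences(
            {"t": genome.unmasked["t"][: 700 + 400]}  # centre 100 bp from end
        )
        assert anchor_and_extend(h, short) == (None, "gap")

    def test_unmapped_tss_column(self):
        promoter, genome, h = self._setup()
        # two blocks that skip query positions 250-349 (the TSS column)
        h2 = PslHit(
            matches=500, strand="+", q_name="q", q_size=601, q_start=0,
            q_end=601, t_name="t", t_size=genome.length("t"), t_start=700,
            t_end=700 + 601, block_sizes=(250, 251), q_starts=(0, 350),
            t_starts=(700, 1050),
        )
        assert map_query_to_target(h2, 300) is None
        assert anchor_and_extend(h2, genome) == (None, "unmapped")
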