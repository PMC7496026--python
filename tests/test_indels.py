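import pytest

from promdiv.cpg import PairGroup
from promdiv.indels import (
    IndelSite,
    cpg_delta,
    detect_indels,
    flank_filter,
    indel_length_histogram,
    left_normalize,
    polarize_indel,
    single_nt_bias,
)
from conftest import mk_aln


def pad(core_a, core_b, flank="ACGTACGTAC"):
    """Wrap alignment cores in 10 perfectly matching columns each side."""
    return mk_aln(flank + core_a + flank, flank + core_b + flank)


class TestDetect:
    def test_simple_gap_run(self):
        aln = pad("TA", "--")
        sites = detect_indels(aln)
        assert len(sites) == 1
        s = sites[0]
        assert (s.carrier, s.length, s.sequence) == ("A", 2, "TA")
        assert (s.start_col, s.end_col) == (10, 12)
        assert s.left_matches == 10 and s.right_matches == 10

    def test_identity_alignment_empty(self):
        assert detect_indels(mk_aln("ACGTACGT", "ACGTACGT")) == []

    def test_edge_run_flagged_truncated(self):
        aln = mk_aln("ACGTACGTACGT", "--GTACGTACGT")
        (site,) = detect_indels(aln)
        assert site.left_truncated and not site.right_truncated

    def test_adjacent_runs_are_distinct_sites(self):
        aln = pad("T-A", "-C-")
        sites = detect_indels(aln)
        assert len(sites) == 3
        assert sorted(s.carrier for s in sites) == ["A", "A", "B"]

    def test_gap_columns_in_flank_count_as_mismatch(self):
        # a second gap 3 columns left of the run lowers the left count
        aln = mk_aln("ACGTACG-ACTTTACGTACGTA", "ACGTACGAAC--TACGTACGTA")
        run = [s for s in detect_indels(aln) if s.carrier == "A"][0]
        assert run.sequence == "TT"
        assert run.left_matches == 9


class TestFlankFilter:
    @pytest.mark.parametrize(
        "left,right,keep", [(10, 9, True), (8, 8, True), (8, 7, False)]
    )
    def test_threshold(self, left, right, keep):
        site = IndelSite("x", 0, 1, "A", "A", left, right)
        assert flank_filter(site, min_match=8) is keep

    def test_truncated_always_dropped(self):
        site = IndelSite("x", 0, 1, "A", "A", 10, 10, left_truncated=True)
        assert flank_filter(site) is False


def test_length_histogram():
    sites = [IndelSite("x", 0, n, "A", "A" * n) for n in (1, 1, 3, 12)]
    hist = indel_length_histogram(sites)
    assert hist == {"1": 2, "2-4": 1, "5-9": 0, "10-19": 1, "20+": 0}
    assert indel_length_histogram([]) == {k: 0 for k in hist}
    assert sum(hist.values()) == len(sites)


def test_single_nt_bias():
    sites = [IndelSite("x", 0, 1, "A", b) for b in "CGGA"]
    groups = [PairGroup.hCmC] * 4
    table = single_nt_bias(sites, groups)
    assert table.loc["hCmC", ["C", "G"]].sum() == pytest.approx(0.75)
    assert table.loc["hNmN"].isna().all()


class TestCpGDelta:
    def test_cg_rich_insertion(self):
        aln = pad("CGCG", "----")
        (site,) = detect_indels(aln)
        assert site.cpg_delta == 2

    def test_neutral_insertion(self):
        aln = pad("AT", "--")
        (site,) = detect_indels(aln)
        assert site.cpg_delta == 0

    def test_junction_cpg_on_other_row(self):
        # deleting AT between C|G creates a CpG on the shorter row
        aln = mk_aln("ACGTACGTAC" + "C" + "AT" + "G" + "ACGTACGTAC",
                     "ACGTACGTAC" + "C" + "--" + "G" + "ACGTACGTAC")
        (site,) = detect_indels(aln)
        assert site.sequence == "AT"
        assert site.cpg_delta == -1

    def test_no_c_or_g_anywhere_gives_zero(self):
        aln = pad("TTAA", "----", flank="ATATATATAT")
        (site,) = detect_indels(aln)
        assert cpg_delta(site, aln) == 0


class TestLeftNormalize:
    def test_homopolymer_shift(self):
        # deleting one A from AAAA is the same event anywhere in the run
        assert left_normalize("TAAAAG", 4, 1) == (1, "A")
        assert left_normalize("TAAAAG", 1, 1) == (1, "A")

    def test_tandem_unit_shift(self):
        assert left_normalize("TACGACGG", 4, 3) == (1, "ACG")

    def test_no_shift_possible(self):
        assert left_normalize("TACG", 2, 1) == (2, "C")


class TestPolarize:
    def test_great_ape_stem_deletion(self):
        presence = {"human": False, "chimpanzee": False, "gorilla": False,
                    "macaque": True, "baboon": True, "marmoset": True}
        event, clade = polarize_indel(presence)
        assert event == "deletion"
        assert clade == frozenset({"human", "chimpanzee", "gorilla"})

    def test_macaque_branch_insertion(self):
        presence = {"human": False, "chimpanzee": False, "gorilla": False,
                    "macaque": True, "baboon": False, "marmoset": False}
        event, clade = polarize_indel(presence)
        assert event == "insertion"
        assert clade == frozenset({"macaque"})

    def test_two_events_ambiguous(self):
        presence = {"human": False, "chimpanzee": True, "gorilla": True,
                    "macaque": True, "baboon": True, "marmoset": False}
        assert polarize_indel(presence)[0] == "ambiguous"

    def test_root_tie_ambiguous(self):
        presence = {"human": True, "chimpanzee": True, "gorilla": True,
                    "macaque": True, "baboon": True, "marmoset": False}
        assert polarize_indel(presence)[0] == "ambiguous"

    def test_partial_presence_data(self):
        presence = {"human": False, "macaque": True, "marmoset": True}
        event, clade = polarize_indel(presence)
        assert event == "deletion"
        assert clade == frozenset({"human"})

    def test_uninformative_patterns(self):
        assert polarize_indel({"human": True, "macaque": True})[0] == "ambiguous"
        assert polarize_indel(
            {"human": True, "macaque": True, "marmoset": True}
        )[0] == "ambiguous"
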