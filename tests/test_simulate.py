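import pytest

from promdiv.align import alignment_score, global_align
from promdiv.cpg import classify, count_type_changes, cpg_stats, PromoterClass
from promdiv.indels import detect_indels
from promdiv.promoters import check_yr
from promdiv.simulate import (
    MutationLog,
    SimConfig,
    evolve,
    generate_cohort,
    map_to_derived,
    replay,
    simulate_ancestor,
)


def naive_apply(ancestor: str, log: MutationLog) -> str:
    """Independent re-application of a mutation log, written without
    reference to the simulator's own replay."""
    seq = list(ancestor)
    for s in log.substitutions:
        assert seq[s.position] == s.from_base
        seq[s.position] = s.to_base
    # indel positions refer to the substituted ancestor; apply right to
    # left so earlier coordinates stay valid
    for ev in sorted(log.indels, key=lambda e: -e.position):
        if ev.kind == "insertion":
            seq[ev.position : ev.position] = list(ev.sequence)
        else:
            removed = seq[ev.position : ev.position + len(ev.sequence)]
            assert "".join(removed) == ev.sequence
            del seq[ev.position : ev.position + len(ev.sequence)]
    return "".join(seq)


class TestAncestor:
    @pytest.mark.parametrize(
        "cls,expect_island,quadrant",
        [("island", True, PromoterClass.HIGH_GC_HIGH_CPG),
         ("nonisland", False, PromoterClass.LOW_GC_LOW_CPG)],
    )
    def test_class_targets(self, rng, cls, expect_island, quadrant):
        cfg = SimConfig(seed=0)
        seq = simulate_ancestor(cls, cfg, rng)
        st = cpg_stats(seq)
        assert classify(st).is_island is expect_island
        assert classify(st) is quadrant
        target_gc = cfg.island_gc if cls == "island" else cfg.nonisland_gc
        assert abs(st.gc - target_gc) <= cfg.composition_tolerance

    def test_central_yr(self, rng):
        cfg = SimConfig(seed=0)
        for cls in ("island", "nonisland"):
            seq = simulate_ancestor(cls, cfg, rng)
            center = (len(seq) - 1) // 2
            assert seq[center - 1] in "CT" and seq[center] in "AG"


class TestEvolve:
    def test_log_replay_identity(self, rng):
        cfg = SimConfig(seed=0, sub_rate=0.02, slip_rate=1.0, tandem_rate=1.0)
        for _ in range(30):
            anc = simulate_ancestor("island", cfg, rng)
            derived, log = evolve(anc, cfg, rng)
            assert replay(anc, log) == derived
            assert naive_apply(anc, log) == derived

    def test_zero_rates_identity(self, rng):
        cfg = SimConfig(seed=0, sub_rate=0.0, slip_rate=0.0, tandem_rate=0.0)
        anc = simulate_ancestor("nonisland", cfg, rng)
        derived, log = evolve(anc, cfg, rng)
        assert derived == anc
        assert not log.substitutions and not log.indels

    def test_center_protected(self, rng):
        cfg = SimConfig(seed=0, sub_rate=0.2, slip_rate=2.0, tandem_rate=2.0)
        anc = simulate_ancestor("island", cfg, rng)
        center = (len(anc) - 1) // 2
        for _ in range(10):
            derived, log = evolve(anc, cfg, rng)
            c = map_to_derived(log, center)
            assert derived[c - 1 : c + 1] == anc[center - 1 : center + 1]

    def test_cpg_context_mutates_at_multiplier_rate(self, rng):
        cfg = SimConfig(seed=0, sub_rate=0.005, cpg_multiplier=10.0,
                        slip_rate=0.0, tandem_rate=0.0)
        ctx = ctx_mut = bg = bg_mut = 0
        for _ in range(60):
            anc = simulate_ancestor("island", cfg, rng)
            in_ctx = set()
            for i in range(len(anc) - 1):
                if anc[i : i + 2] == "CG":
                    in_ctx |= {i, i + 1}
            _, log = evolve(anc, cfg, rng)
            mutated = {s.position for s in log.substitutions}
            ctx += len(in_ctx)
            ctx_mut += len(in_ctx & mutated)
            bg += len(anc) - len(in_ctx)
            bg_mut += len(mutated - in_ctx)
        ratio = (ctx_mut / ctx) / (bg_mut / bg)
        assert ratio == pytest.approx(10.0, rel=0.2)

    def test_deamination_products_only(self, rng):
        cfg = SimConfig(seed=0, sub_rate=0.01, slip_rate=0.0, tandem_rate=0.0)
        anc = simulate_ancestor("island", cfg, rng)
        _, log = evolve(anc, cfg, rng)
        for s in log.substitutions:
            if s.cpg_context:
                assert (s.from_base, s.to_base) in {("C", "T"), ("G", "A")}


class TestCohort:
    def test_determinism(self):
        cfg = SimConfig(n_pairs=10, seed=7)
        a, b = generate_cohort(cfg), generate_cohort(cfg)
        assert [p[0].sequence for p in a.pairs] == [p[0].sequence for p in b.pairs]
        assert [p[1].sequence for p in a.pairs] == [p[1].sequence for p in b.pairs]
        assert [t.refseq_offset for t in a.truths] == [t.refseq_offset for t in b.truths]

    def test_zero_rate_pipeline_is_identity(self):
        cfg = SimConfig(n_pairs=6, seed=3, sub_rate=0.0, slip_rate=0.0,
                        tandem_rate=0.0)
        cohort = generate_cohort(cfg)
        for h, m in cohort.pairs:
            assert h.sequence == m.sequence
            aln = global_align(h.sequence, m.sequence)
            assert alignment_score(aln) == 100.0
            assert detect_indels(aln) == []

    def test_windows_anchored_and_yr_valid(self):
        cohort = generate_cohort(SimConfig(n_pairs=8, seed=5))
        for h, m in cohort.pairs:
            assert check_yr(h) and check_yr(m)

    def test_truth_groups_match_recomputation(self):
        cohort = generate_cohort(SimConfig(n_pairs=10, seed=2))
        for (h, m), t in zip(cohort.pairs, cohort.truths):
            assert classify(cpg_stats(h.sequence)) is t.human_class
            assert classify(cpg_stats(m.sequence)) is t.macaque_class

    def test_island_gain_through_cpg_unit_expansion(self):
        """Heavy tandem duplication of a CpG unit on one branch of
        near-threshold non-island ancestors flips some pairs to hNmC,
        as counted from both the truth bundle and the transition
        table."""
        cfg = SimConfig(
            n_pairs=40, island_fraction=0.0, seed=17,
            nonisland_gc=0.49, nonisland_cpg_score=0.55,
            sub_rate=0.0, slip_rate=0.0, tandem_rate=0.0,
        )
        cohort = generate_cohort(
            cfg,
            branch_overrides=({}, {"tandem_rate": 7.0, "motif_prob": 1.0}),
        )
        truth_flips = sum(
            t.expected_group.value == "hNmC" for t in cohort.truths
        )
        assert truth_flips > 0
        quad, island = count_type_changes(
            [(t.human_class, t.macaque_class) for t in cohort.truths]
        )
        assert island.loc["non-island", "island"] == truth_flips

    def test_cohort_roundtrip_write(self, tmp_path):
        cohort = generate_cohort(SimConfig(n_pairs=3, seed=1))
        cohort.write(tmp_path)
        assert (tmp_path / "cohort.fasta").exists()
        import json

        bundle = json.loads((tmp_path / "truth.json").read_text())
        assert len(bundle["pairs"]) == 3
        assert bundle["config"]["seed"] == 1
        # logs replay exactly from the serialized bundle
        p = bundle["pairs"][0]
        from promdiv.simulate import IndelEvent, Substitution

        log = MutationLog(
            [Substitution(**s) for s in p["log_human"]["substitutions"]],
            [IndelEvent(**e) for e in p["log_human"]["indels"]],
        )
        derived = replay(p["ancestor"], log)
        assert derived == cohort.pairs[0][0].sequence
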