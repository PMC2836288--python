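"""Band matching, Sulston scoring and the assembly cascade."""

import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import binom, spearmanr
from sklearn.base import clone as sk_clone

from hicfmap.assembly import (
    AssemblyParams,
    AssemblyResult,
    Contig,
    SulstonAssembler,
    assemble_pipeline,
    build_contigs,
    chance_match_probability,
    deq,
    end_merge_singletons,
    flag_q_clones,
    join_singletons,
    match_bands,
    merge_contigs,
    order_contig,
    score_all_pairs,
    sulston_log10,
    sulston_score,
)
from hicfmap.fingerprints import Band, Fingerprint
from hicfmap.simulate import BACClone, SimParams, fingerprint_clone, fingerprint_library, generate_arm

from conftest import grid, m_for_score_between, make_fp


def optimal_matching_size(f1: Fingerprint, f2: Fingerprint, tol: float) -> int:
    """Independent oracle: maximum bipartite matching over the within-channel
    within-tolerance band-pair graph."""
    G = nx.Graph()
    left = [("a", i) for i in range(f1.n_bands)]
    right = [("b", j) for j in range(f2.n_bands)]
    G.add_nodes_from(left, bipartite=0)
    G.add_nodes_from(right, bipartite=1)
    for i, ba in enumerate(f1.bands):
        for j, bb in enumerate(f2.bands):
            if ba.channel == bb.channel and abs(ba.size - bb.size) <= tol:
                G.add_edge(("a", i), ("b", j))
    matching = nx.bipartite.maximum_matching(G, top_nodes=left)
    return len(matching) // 2


class TestMatchBands:
    def test_empty_fingerprint_matches_nothing(self, tolerance):
        f1 = make_fp("a", [100.0, 200.0])
        f2 = make_fp("b", [])
        assert match_bands(f1, f2, tolerance) == 0
        assert match_bands(f2, f1, tolerance) == 0

    def test_single_pair_within_tolerance(self, tolerance):
        f1 = make_fp("a", [100.0, 200.0])
        f2 = make_fp("b", [100.3, 500.0])
        assert match_bands(f1, f2, tolerance) == 1

    def test_matching_is_per_channel(self, tolerance):
        f1 = make_fp("a", [100.0], channel="BamHI")
        f2 = make_fp("b", [100.0], channel="EcoRI")
        assert match_bands(f1, f2, tolerance) == 0

    def test_chained_near_ties_equal_optimal(self, tolerance):
        # shifted chains where a naive pairing could waste a band
        f1 = make_fp("a", [100.0, 100.4, 100.8, 101.2])
        f2 = make_fp("b", [100.2, 100.6, 101.0, 101.4])
        assert match_bands(f1, f2, tolerance) == optimal_matching_size(f1, f2, tolerance)

    @settings(max_examples=150, derandomize=True)
    @given(
        st.lists(st.integers(0, 120), min_size=0, max_size=12),
        st.lists(st.integers(0, 120), min_size=0, max_size=12),
    )
    def test_greedy_equals_maximum_bipartite_matching(self, a_tenths, b_tenths):
        # dense size grid (0.1 bp steps around 100 bp) provokes chained ties
        tolerance = 0.5
        f1 = make_fp("a", [100.0 + t / 10.0 for t in a_tenths])
        f2 = make_fp("b", [100.0 + t / 10.0 for t in b_tenths])
        m = match_bands(f1, f2, tolerance)
        assert m == optimal_matching_size(f1, f2, tolerance)
        assert m == match_bands(f2, f1, tolerance)
        assert m <= min(f1.n_bands, f2.n_bands)


class TestSulstonScore:
    def test_zero_matches_scores_one(self):
        assert sulston_score(40, 50, 0) == 1.0

    def test_all_bands_matched_single_term_closed_form(self):
        # m = nL = n1 = n2: the tail reduces to x**n exactly
        x = chance_match_probability(2, 0.5, 900.0)
        assert sulston_score(2, 2, 2) == pytest.approx(x**2, rel=1e-12)

    def test_identical_60_band_fingerprints_pass_initial_cutoff(self):
        assert sulston_score(60, 60, 60) < 1e-50

    def test_symmetric_in_band_counts(self):
        assert sulston_log10(30, 80, 20) == sulston_log10(80, 30, 20)

    def test_non_increasing_in_matched_count(self):
        vals = [sulston_log10(50, 70, m) for m in range(0, 51)]
        assert all(b <= a + 1e-12 for a, b in zip(vals, vals[1:]))
        assert all(v <= 0 for v in vals)

    @pytest.mark.parametrize("n1,n2,m", [(10, 12, 3), (40, 60, 8), (100, 150, 20), (200, 220, 40)])
    def test_matches_scipy_binomial_tail(self, n1, n2, m):
        # dual route: scipy's survival function where it does not underflow
        n_lo, n_hi = min(n1, n2), max(n1, n2)
        x = chance_match_probability(n_hi, 0.5, 900.0)
        expected = binom.sf(m - 1, n_lo, x)
        assert sulston_score(n1, n2, m) == pytest.approx(expected, rel=1e-9)

    def test_deep_tail_is_finite_where_scipy_underflows(self):
        x = chance_match_probability(300, 0.5, 9000.0)
        assert binom.sf(299, 300, x) == 0.0  # double precision underflow
        val = sulston_log10(300, 300, 300, tolerance=0.5, gel_range=9000.0)
        assert np.isfinite(val) and val < -300

    def test_invalid_match_count_raises(self):
        with pytest.raises(ValueError):
            sulston_score(5, 8, 6)


class TestScoreAllPairs:
    def test_identical_fingerprints_all_pairs_retained(self):
        fps = [make_fp(f"c{i}", grid(100, 60)) for i in range(3)]
        scores = score_all_pairs(fps, AssemblyParams())
        assert len(scores) == 3
        assert scores.get_log10("c0", "c1") == scores.get_log10("c1", "c0")

    def test_disjoint_fingerprints_empty_map(self):
        f1 = make_fp("a", grid(100, 30))
        f2 = make_fp("b", grid(500, 30))
        scores = score_all_pairs([f1, f2], AssemblyParams())
        assert len(scores) == 0

    def test_prescreen_agrees_with_exhaustive_scoring(self):
        # > 64 fingerprints activates the coarse-bin prescreen; compare with
        # brute force over every pair
        rng = np.random.default_rng(17)
        fps = []
        for g in range(20):
            base = np.sort(rng.uniform(100, 1000, size=60))
            for r in range(5):
                sizes = base + rng.normal(0, 0.08, size=60)
                fps.append(make_fp(f"g{g:02d}_r{r}", sizes))
        params = AssemblyParams()
        fast = score_all_pairs(fps, params)
        loosest = math.log10(params.loosest_cutoff)
        slow = {}
        fps_sorted = sorted(fps, key=lambda f: f.clone_id)
        for i, f1 in enumerate(fps_sorted):
            for f2 in fps_sorted[i + 1 :]:
                m = match_bands(f1, f2, params.tolerance)
                s = sulston_log10(f1.n_bands, f2.n_bands, m, params.tolerance, params.gel_range)
                if s <= loosest + 1e-9:
                    slow[(f1.clone_id, f2.clone_id)] = s
        assert fast.log10_scores == slow
        assert len(slow) == 20 * 10  # within-group pairs only


class TestBuildContigs:
    def test_single_linkage_chain(self):
        pool = grid(100, 150)
        # a-b and b-c overlap; a-c do not
        fa = make_fp("a", pool[0:60])
        fb = make_fp("b", pool[55:115])
        fc = make_fp("c", pool[110:150] + grid(820, 20))
        # force a-b, b-c above threshold by construction: share 5 bands is
        # not enough, so instead use heavy sharing
        fa = make_fp("a", pool[0:80])
        fb = make_fp("b", pool[10:90])
        fc = make_fp("c", pool[20:100])
        scores = score_all_pairs([fa, fb, fc], AssemblyParams())
        result = build_contigs(scores, 1e-50)
        assert result.n_contigs == 1
        assert result.contigs["ctg_a"].members == ("a", "b", "c")
        result.check_partition()

    def test_no_edges_all_singletons(self):
        fps = [make_fp("a", grid(100, 30)), make_fp("b", grid(500, 30))]
        result = build_contigs(score_all_pairs(fps, AssemblyParams()), 1e-50)
        assert result.n_contigs == 0
        assert result.singletons == ["a", "b"]

    def test_tiling_contig_count_equals_coverage_gaps_plus_one(self):
        """A deterministic clone tiling with two physical gaps yields three
        contigs, matching the gap count computed from the true intervals."""
        arm = generate_arm(
            SimParams(arm_length=600_000, gene_density=0), rng_seed=51, arm_id="arm"
        )
        starts = [0, 15_000, 30_000, 45_000, 60_000,      # block 1
                  200_000, 215_000, 230_000, 245_000,     # block 2
                  400_000, 415_000]                       # block 3
        clones = [
            BACClone(f"c{i:02d}", "L", "arm", s, 100_000, False)
            for i, s in enumerate(starts)
        ]
        fps = [fingerprint_clone(c, {"arm": arm}, noise_sd=0.0, rng_seed=0) for c in clones]
        result = build_contigs(score_all_pairs(fps, AssemblyParams()), 1e-50)
        intervals = sorted((c.start, c.start + c.insert_length) for c in clones)
        gaps = 0
        reach = intervals[0][1]
        for s, e in intervals[1:]:
            if s > reach:
                gaps += 1
            reach = max(reach, e)
        assert result.n_contigs == gaps + 1 == 3
        assert result.n_singletons == 0


class TestFlagQClones:
    def _tiling_contig(self):
        pool = grid(100, 200)
        members = {}
        for i in range(5):
            members[f"c{i}"] = make_fp(f"c{i}", pool[i * 20 : i * 20 + 100])
        members["rnd"] = make_fp("rnd", grid(800, 60))
        contig = Contig("ctg_c0", tuple(sorted(members)), 1e-50)
        return contig, members

    def test_only_the_foreign_clone_is_flagged(self):
        contig, members = self._tiling_contig()
        flags = flag_q_clones(contig, members, AssemblyParams())
        assert flags["rnd"] is True
        assert all(not flags[f"c{i}"] for i in range(5))

    def test_identical_members_have_no_q_clones(self):
        members = {f"c{i}": make_fp(f"c{i}", grid(100, 60)) for i in range(4)}
        contig = Contig("ctg_c0", tuple(sorted(members)), 1e-50)
        flags = flag_q_clones(contig, members, AssemblyParams())
        assert not any(flags.values())

    def test_two_member_contig_carries_no_flags(self):
        members = {"a": make_fp("a", grid(100, 60)), "b": make_fp("b", grid(400, 60))}
        contig = Contig("ctg_a", ("a", "b"), 1e-50)
        assert flag_q_clones(contig, members, AssemblyParams()) == {}


class TestDeq:
    def test_clean_assembly_is_a_fixed_point(self):
        fps = [make_fp(f"c{i}", grid(100, 60)) for i in range(5)]
        params = AssemblyParams()
        scores = score_all_pairs(fps, params)
        result = build_contigs(scores, params.initial_cutoff, params)
        before = {cid: c.members for cid, c in result.contigs.items()}
        result = deq(result, {f.clone_id: f for f in fps}, scores, params)
        assert {cid: c.members for cid, c in result.contigs.items()} == before

    def test_chimeric_contig_separated_by_deqing(self):
        """Two internally consistent clone groups joined by a promiscuous
        clone sharing part of each group's band set, plus two bad-lane
        clones (a group's bands drowned in >50% junk) that trip the Q
        threshold: deQing keeps tightening until the chimera link and then
        the bad lanes drop, leaving the groups in separate clean contigs."""
        SA, SB = grid(100, 80), grid(400, 80)
        junk1, junk2 = grid(650, 85, 1.7), grid(650.9, 85, 1.7)
        fps = {}
        for i in range(4):
            fps[f"a{i}"] = make_fp(f"a{i}", SA)
            fps[f"b{i}"] = make_fp(f"b{i}", SB)
        fps["p_link"] = make_fp("p_link", SA[:75] + SB[:75])
        fps["bad_a"] = make_fp("bad_a", SA + junk1)
        fps["bad_b"] = make_fp("bad_b", SB + junk2)

        params = AssemblyParams()
        # fixture preconditions, all derived from the score formula: the
        # chimera link passes the initial cutoff but is the weakest edge,
        # the junk-heavy clones link more strongly, in-group edges strongest
        s_link = sulston_log10(80, 150, 75)
        s_bad = sulston_log10(80, 165, 80)
        s_group = sulston_log10(80, 80, 80)
        assert -60 < s_link <= -50
        assert s_bad < s_link - 1
        assert s_group < s_bad - 1

        scores = score_all_pairs(list(fps.values()), params)
        result = build_contigs(scores, params.initial_cutoff, params)
        assert result.n_contigs == 1 and len(next(iter(result.contigs.values())).members) == 11

        result = deq(result, fps, scores, params)
        member_sets = sorted((set(c.members) for c in result.contigs.values()), key=min)
        assert member_sets == [
            {"a0", "a1", "a2", "a3"},
            {"b0", "b1", "b2", "b3"},
        ]
        assert set(result.singletons) == {"p_link", "bad_a", "bad_b"}
        for c in result.contigs.values():
            assert c.q_fraction <= params.deq_max_q_fraction
        result.check_partition()


class TestJoinSingletons:
    def _base(self):
        params = AssemblyParams()
        SA = grid(100, 60)
        fps = [make_fp(f"c{i}", SA) for i in range(3)]
        m2 = m_for_score_between(60, 60, -30.0, -22.0)
        s2_sizes = SA[:m2] + grid(820, 60 - m2)
        fps.append(make_fp("s_identical", SA))
        fps.append(make_fp("s_stage2", s2_sizes))
        fps.append(make_fp("s_nomatch", grid(700, 60, 1.9)))
        scores = score_all_pairs(fps, params)
        result = build_contigs(scores, params.initial_cutoff, params)
        return result, scores, params

    def test_staged_joining_and_stage_log(self):
        result, scores, params = self._base()
        assert set(result.singletons) >= {"s_stage2", "s_nomatch"}
        result = join_singletons(result, scores, params)
        result.check_partition()
        (contig,) = result.contigs.values()
        assert "s_identical" in contig.members
        assert "s_stage2" in contig.members
        assert result.singletons == ["s_nomatch"]
        assert result.stage_joined["s_stage2"] == "singleton_join@1e-22"
        assert result.stage_joined["s_identical"].startswith(("initial", "singleton_join@1e-30"))


class TestOrderContig:
    def test_two_member_order_is_lexicographic(self):
        contig = Contig("ctg_a", ("b", "a"), 1e-50)
        fps = [make_fp("a", grid(100, 60)), make_fp("b", grid(100, 60))]
        scores = score_all_pairs(fps, AssemblyParams())
        assert order_contig(contig, scores) == ("a", "b")

    def test_chain_orders_end_to_end(self):
        own = {i: grid(100 + 90 * i, 10) for i in range(4)}
        bridge = {i: grid(600 + 80 * i, 25, 1.3) for i in range(3)}
        fps = []
        for i in range(4):
            sizes = own[i] + (bridge[i - 1] if i > 0 else []) + (bridge[i] if i < 3 else [])
            fps.append(make_fp(f"m{i}", sizes))
        scores = score_all_pairs(fps, AssemblyParams())
        # only adjacent members share enough to be linked at all
        assert scores.get_log10("m0", "m2") is None
        contig = Contig("ctg_m0", tuple(f.clone_id for f in fps), 1e-50)
        order = order_contig(contig, scores)
        assert order in (("m0", "m1", "m2", "m3"), ("m3", "m2", "m1", "m0"))

    def test_seriation_recovers_tiling_coordinates(self):
        arm = generate_arm(
            SimParams(arm_length=600_000, gene_density=0), rng_seed=61, arm_id="arm"
        )
        starts = list(range(0, 500_001, 10_000))
        clones = [
            BACClone(f"c{i:03d}", "L", "arm", s, 100_000, False)
            for i, s in enumerate(starts)
        ]
        fps = [fingerprint_clone(c, {"arm": arm}, noise_sd=0.08, rng_seed=i) for i, c in enumerate(clones)]
        params = AssemblyParams()
        scores = score_all_pairs(fps, params)
        result = build_contigs(scores, params.initial_cutoff, params)
        assert result.n_contigs == 1
        (contig,) = result.contigs.values()
        order = order_contig(contig, scores)
        rank = {cid: i for i, cid in enumerate(order)}
        true_start = {c.clone_id: c.start for c in clones}
        rho = spearmanr(
            [rank[c] for c in sorted(rank)], [true_start[c] for c in sorted(rank)]
        ).statistic
        assert abs(rho) >= 0.9


def _chain_fixture():
    """Six-member chain contig plus singletons probing end-merge rules."""
    params = AssemblyParams()
    own = {i: grid(100 + 40 * i, 10) for i in range(6)}
    bridge = {i: grid(400 + 50 * i, 25, 1.3) for i in range(5)}
    fps = {}
    for i in range(6):
        sizes = own[i] + (bridge[i - 1] if i > 0 else []) + (bridge[i] if i < 5 else [])
        fps[f"m{i}"] = make_fp(f"m{i}", sizes)
    fps["s_mid"] = make_fp("s_mid", fps["m3"].sizes_in_channel("BamHI").tolist())
    fps["s_end"] = make_fp("s_end", fps["m5"].sizes_in_channel("BamHI").tolist())
    scores = score_all_pairs(list(fps.values()), params)
    contig = Contig("ctg_m0", tuple(f"m{i}" for i in range(6)), params.initial_cutoff)
    result = AssemblyResult(
        {"ctg_m0": contig},
        ["s_end", "s_mid"],
        params,
        clone_ids=tuple(sorted(fps)),
    )
    return result, scores, params, fps


class TestEndMergeSingletons:
    def test_middle_match_not_joined_terminal_match_joined(self):
        result, scores, params, fps = _chain_fixture()
        # the mid singleton's only cascade-passing score is to m3 (interior)
        assert scores.get_log10("s_mid", "m3") <= -50
        result = end_merge_singletons(result, scores, params)
        result.check_partition()
        assert result.singletons == ["s_mid"]
        (contig,) = result.contigs.values()
        assert "s_end" in contig.members
        assert result.stage_joined["s_end"] == "end_merge@1e-15"


class TestMergeContigs:
    def _two_groups(self, m_shared):
        params = AssemblyParams()
        SA = grid(100, 60)
        SB = SA[:m_shared] + grid(820, 60 - m_shared, 1.9)
        fps = [make_fp(f"a{i}", SA) for i in range(3)] + [
            make_fp(f"b{i}", SB) for i in range(3)
        ]
        scores = score_all_pairs(fps, params)
        result = build_contigs(scores, params.initial_cutoff, params)
        assert result.n_contigs == 2
        return result, scores, params

    def test_identical_end_pair_merges_at_first_cutoff(self):
        # two pre-existing contigs whose end clones are identical: the pair
        # passes every cutoff, so they merge at the first merge stage
        params = AssemblyParams()
        SA, SB = grid(100, 60), grid(500, 60)
        fps = [make_fp(f"a{i}", SA) for i in range(3)] + [
            make_fp(f"b{i}", SB) for i in range(2)
        ] + [make_fp("b_dup", SA)]
        scores = score_all_pairs(fps, params)
        result = AssemblyResult(
            {
                "ctg_a0": Contig("ctg_a0", ("a0", "a1", "a2"), params.initial_cutoff),
                "ctg_b0": Contig("ctg_b0", ("b0", "b1", "b_dup"), params.initial_cutoff),
            },
            [],
            params,
            clone_ids=tuple(sorted(f.clone_id for f in fps)),
        )
        result = merge_contigs(result, scores, params)
        assert result.n_contigs == 1
        merge_lines = [l for l in result.stage_log if l.startswith("merge_contigs")]
        assert merge_lines and "cutoff=1e-30" in merge_lines[0]

    def test_strong_link_merges_at_first_merge_cutoff(self):
        m = m_for_score_between(60, 60, -50.0, -30.0)
        result, scores, params = self._two_groups(m)
        result = merge_contigs(result, scores, params)
        assert result.n_contigs == 1
        assert "cutoff=1e-30" in " ".join(result.stage_log)

    def test_weak_link_merges_only_at_last_cutoff(self):
        m = m_for_score_between(60, 60, -15.0, -12.0)
        result, scores, params = self._two_groups(m)
        result = merge_contigs(result, scores, params)
        assert result.n_contigs == 1
        merge_lines = [l for l in result.stage_log if l.startswith("merge_contigs")]
        assert merge_lines == [l for l in merge_lines if "cutoff=1e-12" in l]

    def test_unlinked_contigs_unchanged(self):
        params = AssemblyParams()
        fps = [make_fp(f"a{i}", grid(100, 60)) for i in range(3)] + [
            make_fp(f"b{i}", grid(500, 60)) for i in range(3)
        ]
        scores = score_all_pairs(fps, params)
        result = build_contigs(scores, params.initial_cutoff, params)
        before = {cid: c.members for cid, c in result.contigs.items()}
        result = merge_contigs(result, scores, params)
        assert {cid: c.members for cid, c in result.contigs.items()} == before


class TestAssemblePipeline:
    def test_empty_input(self):
        result = assemble_pipeline([], AssemblyParams())
        assert result.n_contigs == 0 and result.n_singletons == 0

    def test_duplicate_fingerprints_form_one_contig(self):
        fps = [make_fp(f"c{i}", grid(100, 60)) for i in range(10)]
        result = assemble_pipeline(fps, AssemblyParams())
        assert result.n_contigs == 1
        assert len(next(iter(result.contigs.values())).members) == 10

    def _sim_fps(self, seed=71, n=40):
        arm = generate_arm(
            SimParams(arm_length=300_000, gene_density=0), rng_seed=seed, arm_id="arm"
        )
        rng = np.random.default_rng(seed)
        clones = [
            BACClone(f"c{i:03d}", "L", "arm", int(s), 60_000, False)
            for i, s in enumerate(rng.integers(0, 240_000, size=n))
        ]
        return fingerprint_library(clones, {"arm": arm}, noise_sd=0.08, seed=seed)

    def test_result_invariant_to_input_order(self):
        fps = self._sim_fps()
        r1 = assemble_pipeline(fps, AssemblyParams())
        rng = np.random.default_rng(5)
        shuffled = list(fps)
        rng.shuffle(shuffled)
        r2 = assemble_pipeline(shuffled, AssemblyParams())
        assert r1.membership() == r2.membership()
        assert sorted(r1.contigs) == sorted(r2.contigs)
        assert r1.stage_joined == r2.stage_joined

    def test_partition_and_deq_postcondition_hold_through_stages(self):
        fps = self._sim_fps(seed=73)
        params = AssemblyParams()
        fp_by_id = {f.clone_id: f for f in fps}
        scores = score_all_pairs(fps, params)
        result = build_contigs(scores, params.initial_cutoff, params)
        result.check_partition()
        result = deq(result, fp_by_id, scores, params)
        result.check_partition()
        for c in result.contigs.values():
            assert c.q_fraction <= params.deq_max_q_fraction
        for stage in (join_singletons, end_merge_singletons, merge_contigs):
            result = stage(result, scores, params)
            result.check_partition()

    def test_intra_contig_connectivity_after_initial_clustering(self):
        fps = self._sim_fps(seed=79)
        params = AssemblyParams()
        scores = score_all_pairs(fps, params)
        result = build_contigs(scores, params.initial_cutoff, params)
        cutoff = math.log10(params.initial_cutoff) + 1e-9
        for contig in result.contigs.values():
            G = nx.Graph()
            G.add_nodes_from(contig.members)
            for a in contig.members:
                for b, s in scores.neighbors.get(a, {}).items():
                    if b in contig.members and s <= cutoff:
                        G.add_edge(a, b)
            assert nx.is_connected(G)


class TestSulstonAssemblerEstimator:
    def test_fit_exposes_labels_and_contigs(self):
        fps = [make_fp(f"c{i}", grid(100, 60)) for i in range(4)]
        fps.append(make_fp("lone", grid(700, 60, 1.9)))
        est = SulstonAssembler().fit(fps)
        assert list(est.labels_[:4]) == [0, 0, 0, 0]
        assert est.labels_[4] == -1
        assert est.n_contigs_ == 1
        assert est.singletons_ == ["lone"]

    def test_get_set_params_roundtrip_and_clone(self):
        est = SulstonAssembler(initial_cutoff=1e-40, end_depth=3)
        params = est.get_params()
        assert params["initial_cutoff"] == 1e-40
        est2 = sk_clone(est).set_params(end_depth=4)
        assert est2.get_params()["end_depth"] == 4
        assert est.get_params()["end_depth"] == 3

    def test_invalid_cascade_ordering_rejected(self):
        est = SulstonAssembler(singleton_join_cutoffs=(1e-22, 1e-30))
        with pytest.raises(ValueError, match="increasing"):
            est.fit([make_fp("a", grid(100, 60)), make_fp("b", grid(100, 60))])
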