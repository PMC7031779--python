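import numpy as np
import pytest

from revenant.species_tree import (
    CompleteSpeciesTree,
    Fate,
    LineageCountProfile,
    LineageNode,
    RateFunction,
    TotalExtinctionError,
    alive_at,
    alive_just_after,
    caterpillar_sampling_tree,
    load_user_tree,
    prune_extinct,
    simulate_complete_tree,
    simulate_with_profile,
)


def fig_like_tree():
    """Handcrafted complete tree with two extinct lineages (n3, n8)."""
    nodes = {
        "n1": LineageNode("n1", None, 0.0, 1.0, Fate.SPECIATED, ("n2", "n3")),
        "n2": LineageNode("n2", "n1", 1.0, 2.0, Fate.SPECIATED, ("n4", "n5")),
        "n3": LineageNode("n3", "n1", 1.0, 1.5, Fate.EXTINCT),
        "n4": LineageNode("n4", "n2", 2.0, 4.0, Fate.ALIVE_AT_END),
        "n5": LineageNode("n5", "n2", 2.0, 3.0, Fate.SPECIATED, ("n7", "n8")),
        "n7": LineageNode("n7", "n5", 3.0, 4.0, Fate.ALIVE_AT_END),
        "n8": LineageNode("n8", "n5", 3.0, 3.5, Fate.EXTINCT),
    }
    return CompleteSpeciesTree(nodes, "n1", 4.0)


class TestSimulate:
    def test_zero_extinction_rate_yields_no_extinct_lineages(self):
        tree = simulate_complete_tree(1.0, 0.0, stop_time=2.0, seed=3)
        assert tree.extinct() == []
        assert all(
            n.fate in (Fate.SPECIATED, Fate.ALIVE_AT_END) for n in tree.nodes.values()
        )

    def test_zero_speciation_rate_yields_single_lineage(self):
        tree = simulate_complete_tree(0.0, 1.0, stop_time=10.0, seed=5)
        assert len(tree) == 1
        root = tree.nodes[tree.root_id]
        assert root.fate in (Fate.EXTINCT, Fate.ALIVE_AT_END)

    def test_rates_zero_runs_to_stop(self):
        tree = simulate_complete_tree(0.0, 0.0, stop_time=4.0, seed=0)
        assert tree.nodes["n1"].fate is Fate.ALIVE_AT_END
        assert tree.nodes["n1"].t_end == 4.0

    @pytest.mark.parametrize("bad", [dict(stop_time=-1.0), dict(stop_time=0.0)])
    def test_bad_stop_time_rejected(self, bad):
        with pytest.raises(ValueError):
            simulate_complete_tree(1.0, 0.5, seed=0, **bad)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            simulate_complete_tree(-1.0, 0.5, stop_time=1.0, seed=0)

    def test_total_extinction_flagged_not_raised(self):
        tree = simulate_complete_tree(0.0, 50.0, stop_time=5.0, seed=1)
        assert tree.totally_extinct
        assert tree.alive_at_end() == []

    def test_stop_by_total_lineage_count(self):
        tree = simulate_complete_tree(1.0, 0.0, stop_time=None, seed=2,
                                      stop_total_lineages=21)
        assert len(tree) >= 21

    def test_determinism_under_seed(self):
        a = simulate_complete_tree(1.0, 0.5, stop_time=3.0, seed=9)
        b = simulate_complete_tree(1.0, 0.5, stop_time=3.0, seed=9)
        assert a.to_newick() == b.to_newick()

    def test_mean_alive_count_matches_birth_death_expectation(self):
        # E[N(t)] = exp((lam - mu) t) for a linear birth-death process
        rng = np.random.default_rng(7)
        lam, mu, t = 1.0, 0.5, 1.0
        counts = [
            len(
                simulate_complete_tree(lam, mu, stop_time=t,
                                       seed=int(rng.integers(2**31))).alive_at_end()
            )
            for _ in range(3000)
        ]
        mean, se = np.mean(counts), np.std(counts) / np.sqrt(len(counts))
        assert abs(mean - np.exp((lam - mu) * t)) < 3 * se


class TestPiecewiseRates:
    def test_interval_validation(self):
        with pytest.raises(ValueError):
            RateFunction.piecewise([(0, 1, 0.5), (2, 3, 0.5)])  # gap
        with pytest.raises(ValueError):
            RateFunction.piecewise([(0, 1, -0.5)])

    def test_rate_lookup_and_boundaries(self):
        rf = RateFunction.piecewise([(0, 1, 0.0), (1, 2, 3.0)])
        assert rf.at(0.5) == 0.0
        assert rf.at(1.5) == 3.0
        assert rf.next_boundary(0.2) == 1.0

    def test_no_events_during_zero_rate_interval(self):
        lam = RateFunction.piecewise([(0, 5, 0.0), (5, 6, 10.0)])
        tree = simulate_complete_tree(lam, 0.0, stop_time=6.0, seed=4)
        assert all(
            n.t_end > 5.0 for n in tree.nodes.values() if n.fate is Fate.SPECIATED
        )


class TestPrune:
    def test_extinct_lineages_removed_and_unary_suppressed(self):
        pruned = prune_extinct(fig_like_tree())
        assert "n3" not in pruned.nodes and "n8" not in pruned.nodes
        # n5 had one surviving child (n7): suppressed, n7 reattaches to n2
        assert "n5" not in pruned.nodes
        assert set(pruned.nodes["n2"].children) == {"n4", "n7"}
        # n1 had one surviving child (n2): pruned tree roots at n2
        assert pruned.root_id == "n2"

    def test_root_to_tip_times_preserved_exactly(self):
        tree = fig_like_tree()
        pruned = prune_extinct(tree)
        for tip in pruned.alive_at_end():
            assert pruned.nodes[tip].t_end == tree.nodes[tip].t_end

    def test_identity_when_no_extinction(self):
        tree = simulate_complete_tree(1.0, 0.0, stop_time=2.0, seed=11)
        pruned = prune_extinct(tree)
        assert set(pruned.nodes) == set(tree.nodes)
        for lid in tree.nodes:
            assert pruned.nodes[lid].children == tree.nodes[lid].children

    def test_idempotent(self):
        pruned = prune_extinct(fig_like_tree())
        again = prune_extinct(pruned)
        assert {k: (v.t_start, v.t_end, v.children) for k, v in pruned.nodes.items()} == {
            k: (v.t_start, v.t_end, v.children) for k, v in again.nodes.items()
        }

    def test_total_extinction_raises(self):
        tree = simulate_complete_tree(0.0, 50.0, stop_time=5.0, seed=1)
        with pytest.raises(TotalExtinctionError):
            prune_extinct(tree)


class TestAliveAt:
    def test_just_after_root_start(self):
        tree = fig_like_tree()
        assert alive_at(tree, 0.5) == {"n1"}

    def test_excludes_lineage_after_its_extinction(self):
        tree = fig_like_tree()
        assert "n3" not in alive_at(tree, 1.8)
        assert alive_at(tree, 1.2) == {"n2", "n3"}

    def test_at_stop_time_equals_survivors(self):
        tree = fig_like_tree()
        assert alive_at(tree, 4.0) == set(tree.alive_at_end())

    def test_out_of_range_rejected(self):
        tree = fig_like_tree()
        for t in (0.0, -1.0, 4.5):
            with pytest.raises(ValueError):
                alive_at(tree, t)


class TestUserTree:
    def test_ultrametric_tree_all_alive(self):
        tree = load_user_tree("((A:1,B:1):1,C:2);")
        assert sorted(tree.alive_at_end()) == ["A", "B", "C"]
        assert tree.stop_time == 2.0

    def test_short_tip_marked_extinct(self):
        tree = load_user_tree("((A:1,B:0.5):1,C:2);")
        assert tree.nodes["B"].fate is Fate.EXTINCT
        assert tree.nodes["B"].t_end == pytest.approx(1.5)
        assert sorted(tree.alive_at_end()) == ["A", "C"]

    def test_trifurcation_rejected(self):
        with pytest.raises(ValueError, match="non-binary"):
            load_user_tree("(A:1,B:1,C:1);")

    def test_missing_branch_length_rejected(self):
        with pytest.raises(ValueError, match="branch length"):
            load_user_tree("((A:1,B),C:2);")

    def test_garbage_rejected(self):
        with pytest.raises(ValueError):
            load_user_tree("this is not newick")

    @pytest.mark.parametrize("seed", [0, 2, 3, 4, 9])
    def test_newick_round_trip_preserves_times(self, seed):
        tree = simulate_complete_tree(1.0, 0.5, stop_time=3.0, seed=seed)
        assert not tree.totally_extinct and len(tree) >= 3
        back = load_user_tree(tree.to_newick())
        assert set(back.nodes) == set(tree.nodes)
        for lid, node in tree.nodes.items():
            assert back.nodes[lid].t_start == pytest.approx(node.t_start, abs=1e-9)
            assert back.nodes[lid].t_end == pytest.approx(node.t_end, abs=1e-9)
            assert back.nodes[lid].fate == node.fate


class TestProfile:
    def test_counts_hit_targets_exactly(self):
        profile = LineageCountProfile(((1, 2), (2, 4), (3, 8)))
        tree = simulate_with_profile(profile, 0.1, seed=2)
        for unit, want in profile.targets:
            assert len(alive_just_after(tree, float(unit))) == want

    def test_single_lineage_profile(self):
        tree = simulate_with_profile(LineageCountProfile(((1, 1),)), 0.5, seed=3)
        assert len(alive_just_after(tree, 1.0)) == 1

    def test_constant_profile_gives_k_extant_tips(self):
        k = 4
        profile = LineageCountProfile(tuple((u, k) for u in range(1, 6)))
        tree = simulate_with_profile(profile, 0.3, seed=4, speciation=0.3)
        pruned = prune_extinct(tree)
        assert len(pruned.alive_at_end()) == k

    def test_zero_target_rejected(self):
        with pytest.raises(ValueError):
            LineageCountProfile(((1, 0),))


class TestCaterpillar:
    def test_snapshot_tips_are_zero_length(self):
        tree = caterpillar_sampling_tree(10.0, [2.0, 4.0, 6.0])
        snaps = [n for n in tree.nodes.values() if n.fate is Fate.EXTINCT]
        assert len(snaps) == 3
        assert all(n.duration == 0.0 for n in snaps)
        assert len(tree.alive_at_end()) == 1
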