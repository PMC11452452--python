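"""Optimal-subset machinery: brute force, Opt-τ, greedy exactness, scans."""

import pytest

from netdiv import (
    DiversityTable,
    PhyloNetwork,
    SwapFamily,
    brute_force_opt,
    chain_step,
    dispatch_optimize,
    example2_network,
    gap_scan,
    greedy_galled,
    greedy_level2,
    greedy_tree,
    opt_tau_contract,
    opt_tau_expand,
    random_galled_tree,
    random_level_k,
    random_tree,
)
from netdiv.optimize import FamilySizeError, _contract_masks, _expand_masks


def sets_of(fam):
    return {tuple(sorted(s)) for s in fam.sets}


class TestBruteForce:
    def test_example1_unique_optima(self, example1):
        o2 = brute_force_opt(example1, 2)
        assert o2.value == 10 and o2.sets == {frozenset({"x2", "x4"})}
        o3 = brute_force_opt(example1, 3)
        assert o3.value == 13 and o3.sets == {frozenset({"x1", "x3", "x4"})}

    def test_extremes(self, example1):
        o0 = brute_force_opt(example1, 0)
        assert o0.value == 0 and o0.sets == {frozenset()}
        o4 = brute_force_opt(example1, 4)
        assert o4.value == example1.total_weight and o4.sets == {example1.leaves}

    def test_m_out_of_range(self, example1):
        with pytest.raises(ValueError):
            brute_force_opt(example1, 5)

    def test_family_cap(self):
        star = PhyloNetwork.from_arcs([("r", f"x{i}", 1) for i in range(6)])
        with pytest.raises(FamilySizeError):
            brute_force_opt(star, 3, max_family=3)


class TestOptTau:
    def test_expand_from_best_pair(self, example1):
        fam = SwapFamily.skd(1, 2, example1.leaves)
        out = opt_tau_expand(example1, {"x2", "x4"}, 1, fam)
        assert out.value == 13
        assert out.sets == {frozenset({"x1", "x3", "x4"})}

    def test_expand_from_empty_set_gives_best_singleton(self, example1):
        out = opt_tau_expand(example1, frozenset(), 1,
                             SwapFamily.s0(example1.leaves))
        assert out.value == 6 and out.sets == {frozenset({"x2"})}

    def test_expand_one_short_of_sigma(self, example1):
        out = opt_tau_expand(example1, example1.leaves - {"x1"}, 1,
                             SwapFamily.s0(example1.leaves))
        assert out.sets == {example1.leaves}

    def test_contract_resolves_non_nesting(self, example1):
        fam = SwapFamily.skd(1, 2, example1.leaves)
        out = opt_tau_contract(example1, {"x1", "x3", "x4"}, 1, fam)
        assert out.value == 10 and out.sets == {frozenset({"x2", "x4"})}

    def test_contract_singleton_to_empty(self, example1):
        out = opt_tau_contract(example1, {"x1"}, 1, SwapFamily.s0(example1.leaves))
        assert out.sets == {frozenset()}

    @pytest.mark.parametrize("seed", range(4))
    def test_expand_contract_duality(self, seed):
        """X' ∈ τ_{k,d,j}(X) iff X ∈ τ⁻¹_{k,d,j}(X'), over all subsets."""
        net = random_level_k(6, k=2, d=2, seed=seed, weights="int:1,9")
        table = DiversityTable(net)
        fam = SwapFamily.skd(2, 2, net.leaves)
        for X in range(1 << table.n):
            for j in (1, 2):
                for Xp in _expand_masks(table, X, j, fam):
                    assert X in _contract_masks(table, Xp, j, fam)

    def test_no_candidate_errors(self, example1):
        with pytest.raises(ValueError, match="no expansion candidate"):
            opt_tau_expand(example1, frozenset(), 2,
                           SwapFamily.skd(2, 2, example1.leaves))


def assert_matches_brute(net, seq, table):
    for m in range(len(net.leaves) + 1):
        bf = brute_force_opt(net, m, table=table)
        assert seq[m].value == bf.value, f"value differs at m={m}"
        assert seq[m].sets == bf.sets, f"family differs at m={m}"


class TestGreedyTree:
    def test_star_picks_heaviest_leaf(self):
        star = PhyloNetwork.from_arcs(
            [("r", "a", 3), ("r", "b", 1), ("r", "c", 2)])
        seq = greedy_tree(star)
        assert seq[1].sets == {frozenset({"a"})} and seq[1].value == 3

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_brute_force(self, seed):
        tree = random_tree(5 + seed % 5, seed=seed,
                           weights="int:1,6" if seed % 2 else "real:0.2,3")
        table = DiversityTable(tree)
        assert_matches_brute(tree, greedy_tree(tree, table=table), table)

    def test_rejects_networks(self, example1):
        with pytest.raises(ValueError):
            greedy_tree(example1)


class TestGreedyGalled:
    def test_example1_sequence(self, example1):
        seq = greedy_galled(example1)
        assert seq.values == (0, 6, 10, 13, 14)
        assert seq[1].sets == {frozenset({"x2"})}
        assert seq[2].sets == {frozenset({"x2", "x4"})}
        assert seq[3].sets == {frozenset({"x1", "x3", "x4"})}

    def test_optima_need_not_nest(self, example1):
        """Opt_3's member does not contain Opt_2's; greedy is still exact."""
        seq = greedy_galled(example1)
        (y2,) = seq[2].sets
        (y3,) = seq[3].sets
        assert not y2 <= y3
        assert_matches_brute(example1, seq, DiversityTable(example1))

    def test_tree_input_agrees_with_tree_greedy(self):
        tree = random_tree(7, seed=9, weights="int:1,9")
        a = greedy_galled(tree)
        b = greedy_tree(tree)
        assert [f.sets for f in a] == [f.sets for f in b]

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_brute_force(self, seed):
        net = random_galled_tree(5 + seed % 5, seed=seed, weights="int:1,9")
        table = DiversityTable(net)
        assert_matches_brute(net, greedy_galled(net, table=table), table)

    @pytest.mark.parametrize("seed", range(10))
    def test_representative_mode_returns_true_optima(self, seed):
        net = random_galled_tree(7, seed=seed, weights="int:1,9")
        table = DiversityTable(net)
        seq = greedy_galled(net, mode="representative", table=table)
        for m in range(len(net.leaves) + 1):
            bf = brute_force_opt(net, m, table=table)
            (rep,) = seq[m].sets
            assert rep in bf.sets and seq[m].value == bf.value

    def test_values_monotone(self):
        net = random_galled_tree(8, seed=3, weights="real:0.1,2")
        vals = greedy_galled(net).values
        assert all(a <= b for a, b in zip(vals, vals[1:]))

    def test_remark2_contraction_recovers_optima(self, example1):
        """Each Opt_m lies in the union of optimal contractions of Opt_{m+1}."""
        table = DiversityTable(example1)
        fam = SwapFamily.skd(1, 2, example1.leaves)
        for m in range(len(example1.leaves)):
            up = brute_force_opt(example1, m + 1, table=table)
            down = set()
            for Y in up.sets:
                down |= opt_tau_contract(example1, Y, 1, fam, table=table).sets
            assert brute_force_opt(example1, m, table=table).sets <= down

    def test_rejects_level2(self):
        with pytest.raises(ValueError):
            greedy_galled(random_level_k(6, k=2, d=2, seed=0))


class TestGreedyLevel2:
    def test_example1_consistency(self, example1):
        a = greedy_level2(example1)
        b = greedy_galled(example1)
        assert [f.sets for f in a] == [f.sets for f in b]

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_on_semibinary_level2(self, seed):
        net = random_level_k(5 + seed % 4, k=2, d=2, seed=seed,
                             weights="int:1,9")
        table = DiversityTable(net)
        assert_matches_brute(net, greedy_level2(net, table=table), table)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_on_semi3ary_level1(self, seed):
        net = random_level_k(5 + seed % 4, k=1, d=3, seed=seed,
                             weights="int:1,9")
        table = DiversityTable(net)
        assert_matches_brute(net, greedy_level2(net, table=table), table)

    def test_rejects_level3(self):
        with pytest.raises(ValueError):
            greedy_level2(random_level_k(7, k=3, d=2, seed=1))


class TestDispatch:
    def test_example1_routes_to_galled(self, example1):
        seq = dispatch_optimize(example1)
        assert seq.values == (0, 6, 10, 13, 14)

    def test_complex_network_warns_and_brute_forces(self):
        net = example2_network(4)
        with pytest.warns(UserWarning, match="NP-hard"):
            fam = dispatch_optimize(net, m=2)
        assert fam.sets == brute_force_opt(net, 2).sets

    def test_brute_and_auto_agree_on_trees(self):
        tree = random_tree(6, seed=5, weights="int:1,9")
        auto = dispatch_optimize(tree)
        brute = dispatch_optimize(tree, method="brute")
        assert [f.sets for f in auto] == [f.sets for f in brute]


class TestGapScan:
    def test_galled_tree_closes_at_j1(self, example1):
        report = gap_scan(example1, J=1)
        assert report.ok and all(report.satisfied.values())

    @pytest.mark.parametrize("seed", range(5))
    def test_level2_closes_at_j2(self, seed):
        net = random_level_k(6, k=2, d=2, seed=seed, weights="int:1,9")
        report = gap_scan(net, J=2)
        assert report.ok

    def test_level3_scan_completes_with_certificates_field(self):
        net = random_level_k(7, k=3, d=2, seed=2, weights="int:1,9")
        report = gap_scan(net, J=3)
        assert set(report.satisfied) == set(range(1, 8))
        assert isinstance(report.counterexamples, tuple)


class TestChainStep:
    def test_example1_resolves_3_2_at_j1(self, example1):
        seq = dispatch_optimize(example1, method="brute")
        fam = SwapFamily.skd(1, 2, example1.leaves)
        j, pair = chain_step(example1, seq, 3, 2, fam)
        assert j == 1
        assert pair.A == frozenset({"x1", "x3"}) and pair.B == frozenset({"x2"})

    def test_1_0_returns_best_singleton(self, example1):
        seq = dispatch_optimize(example1, method="brute")
        j, pair = chain_step(example1, seq, 1, 0,
                             SwapFamily.skd(1, 2, example1.leaves))
        assert j == 1 and pair.A == frozenset({"x2"}) and not pair.B

    @pytest.mark.parametrize("seed", range(6))
    def test_galled_chains_close_in_one_step(self, seed):
        net = random_galled_tree(6, seed=seed, weights="int:1,9")
        table = DiversityTable(net)
        seq = dispatch_optimize(net, method="brute", table=table)
        fam = SwapFamily.skd(1, 2, net.leaves)
        n = len(net.leaves)
        for p in range(1, n + 1):
            for q in range(p):
                j, _ = chain_step(net, seq, p, q, fam, table=table)
                assert j == 1
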