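"""Interactome assembly, hypergeometric overlap, and bridge enumeration."""

import math

import numpy as np
import pytest
from scipy.special import gammaln, logsumexp

from pleioscan.interactome import (
    build_interactome,
    candidate_connectivity,
    find_bridges,
    hypergeom_log10_sf,
    overlap_test,
    overlap_test_sizes,
    read_edge_list,
    write_edge_list,
    write_sif,
)


def log10_sf_lgamma(k, N, K, n):
    """Independent oracle: direct log-gamma summation of the tail pmf."""
    def logpmf(i):
        return (
            gammaln(K + 1) - gammaln(i + 1) - gammaln(K - i + 1)
            + gammaln(N - K + 1) - gammaln(n - i + 1) - gammaln(N - K - n + i + 1)
            + gammaln(n + 1) + gammaln(N - n + 1) - gammaln(N + 1)
        )
    return logsumexp([logpmf(i) for i in range(k, min(K, n) + 1)]) / math.log(10)


def log10_sf_exact(k, N, K, n):
    """Second oracle: exact big-integer enumeration via math.comb."""
    num = sum(math.comb(K, i) * math.comb(N - K, n - i)
              for i in range(k, min(K, n) + 1))
    den = math.comb(N, n)

    def log10_int(v):
        shift = max(0, v.bit_length() - 60)
        return (math.log2(v >> shift) + shift) * math.log10(2)

    return log10_int(num) - log10_int(den)


class TestBuild:
    def test_seed_incidence_rule(self):
        """Only edges touching a seed are retained; interactors counted."""
        net = build_interactome(
            {"A"}, [("A", "B", "known"), ("A", "C", "novel"), ("B", "C", "known")]
        )
        assert net.interactors == {"B", "C"}
        assert net.edge_counts() == {"known": 1, "novel": 1}

    def test_empty_seed_set_gives_empty_interactome(self):
        net = build_interactome(set(), [("A", "B", "known")])
        assert not net.nodes and net.graph.number_of_edges() == 0

    def test_symmetric_duplicates_collapse(self):
        net = build_interactome({"A"}, [("A", "B", "known"), ("B", "A", "novel")])
        assert net.graph.number_of_edges() == 1

    def test_bad_rows_rejected_and_counted(self):
        net = build_interactome(
            {"A"}, [("A", "", "known"), ("A", "A", "known"), ("A", "B", "weird"),
                    ("A", "B", "known")]
        )
        assert net.rejected_edges == 3
        assert net.interactors == {"B"}

    def test_alias_map_merges_symbols(self):
        net = build_interactome({"A"}, [("A", "Bold", "known")],
                                alias_map={"Bold": "B"})
        assert net.interactors == {"B"}

    def test_edge_list_round_trip_and_sif(self, tmp_path):
        edges = [("A", "B", "known"), ("A", "C", "novel")]
        write_edge_list(edges, tmp_path / "e.tsv")
        assert read_edge_list(tmp_path / "e.tsv") == edges
        net = build_interactome({"A"}, edges)
        write_sif(net, tmp_path / "n.sif")
        lines = (tmp_path / "n.sif").read_text().splitlines()
        assert "A\tpp_known\tB" in lines and "A\tpp_novel\tC" in lines


class TestOverlap:
    def test_complete_overlap_closed_form(self):
        """N=10, K=n=k=5: p = 1/C(10,5) = 1/252."""
        t = overlap_test_sizes(10, 5, 5, 5)
        assert t.p_tail == pytest.approx(1 / 252, rel=1e-9)

    def test_zero_overlap_gives_p_one(self):
        assert overlap_test_sizes(100, 10, 10, 0).p_tail == 1.0

    def test_published_scale_overlap_is_beyond_1e72(self):
        """Interactome sizes 2058 and 1045 sharing 316 genes in a 20,000-gene
        universe: the tail is far below 1e-72."""
        t = overlap_test_sizes(20_000, 2058, 1045, 316)
        assert t.log10_p <= -72

    @pytest.mark.parametrize(
        "k,N,K,n",
        [(316, 20_000, 2058, 1045), (5, 10, 5, 5), (3, 100, 20, 10),
         (40, 500, 100, 80), (1, 20_000, 30, 20)],
    )
    def test_agreement_with_both_independent_oracles(self, k, N, K, n):
        """Implementation matches log-gamma summation and exact big-integer
        enumeration to 6 significant figures in log10-space."""
        got = hypergeom_log10_sf(k, N, K, n)
        assert got == pytest.approx(log10_sf_lgamma(k, N, K, n), rel=1e-6)
        assert got == pytest.approx(log10_sf_exact(k, N, K, n), rel=1e-6)

    def test_monte_carlo_oracle_at_moderate_p(self):
        """Random equal-size draws reproduce the tail probability within
        sampling error for moderate p."""
        N, K, n, k = 60, 20, 15, 8
        p = 10 ** hypergeom_log10_sf(k, N, K, n)
        assert p >= 1e-4
        rng = np.random.default_rng(123)
        universe = np.arange(N)
        fixed = set(range(K))
        draws = 40_000
        hits = sum(
            len(fixed.intersection(rng.choice(universe, size=n, replace=False)))
            >= k
            for _ in range(draws)
        )
        mc = hits / draws
        se = math.sqrt(p * (1 - p) / draws)
        assert abs(mc - p) < 5 * se

    def test_tail_monotone_decreasing_in_k(self):
        vals = [hypergeom_log10_sf(k, 1000, 100, 50) for k in range(0, 30)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_universe_smaller_than_union_rejected(self):
        net_a = build_interactome({"A"}, [("A", "B", "known")])
        net_b = build_interactome({"C"}, [("C", "D", "known")])
        with pytest.raises(ValueError, match="universe"):
            overlap_test(net_a, net_b, universe_n=3)

    def test_full_vs_interactor_only_modes(self):
        net_a = build_interactome({"A"}, [("A", "M", "known")])
        net_b = build_interactome({"B"}, [("B", "M", "known"), ("B", "A", "known")])
        full = overlap_test(net_a, net_b, universe_n=100, mode="full")
        inter = overlap_test(net_a, net_b, universe_n=100, mode="interactors")
        assert full.overlap_k == 2  # M shared; A is a seed of one, interactor of other
        assert inter.overlap_k == 1


class TestBridges:
    def test_direct_edge_only(self):
        net_a = build_interactome({"X"}, [("X", "Y", "known")])
        net_b = build_interactome({"Y"}, [("X", "Y", "known")])
        rep = find_bridges(net_a, net_b)
        assert rep.direct_edges == [("X", "Y")]
        assert not rep.common_interactors and not rep.two_step_paths

    def test_single_intermediate_path(self):
        net_a = build_interactome({"X"}, [("X", "M", "known")])
        net_b = build_interactome({"Y"}, [("M", "Y", "novel")])
        rep = find_bridges(net_a, net_b)
        assert rep.two_step_paths == [("X", "M", "Y")]
        assert rep.common_interactors == {"M"}
        assert rep.direct_edges == []

    def test_disconnected_graphs_give_empty_report(self):
        net_a = build_interactome({"X"}, [("X", "P", "known")])
        net_b = build_interactome({"Y"}, [("Y", "Q", "known")])
        rep = find_bridges(net_a, net_b)
        assert not rep.direct_edges
        assert not rep.common_interactors
        assert not rep.two_step_paths

    def test_swap_invariance_up_to_transposition(self):
        net_a = build_interactome({"X", "W"}, [("X", "M", "known"),
                                               ("W", "M", "novel"),
                                               ("X", "Y", "known")])
        net_b = build_interactome({"Y"}, [("M", "Y", "novel")])
        fwd = find_bridges(net_a, net_b)
        rev = find_bridges(net_b, net_a)
        assert sorted((b, a) for a, b in fwd.direct_edges) == rev.direct_edges
        assert fwd.common_interactors == rev.common_interactors
        assert sorted((b, m, a) for a, m, b in fwd.two_step_paths) == rev.two_step_paths

    def test_matches_exhaustive_search_on_random_graphs(self):
        """Every reported bridge exists and every existing bridge is reported
        (exhaustive triple-loop oracle, graphs up to 50 nodes)."""
        rng = np.random.default_rng(31)
        for _ in range(20):
            n_nodes = int(rng.integers(10, 50))
            names = [f"N{i}" for i in range(n_nodes)]
            seeds_a = set(names[: rng.integers(1, 4)])
            seeds_b = set(names[4 : 4 + rng.integers(1, 4)])
            edges = []
            for i in range(n_nodes):
                for j in range(i + 1, n_nodes):
                    if rng.random() < 0.08:
                        edges.append((names[i], names[j], "known"))
            net_a = build_interactome(seeds_a, edges)
            net_b = build_interactome(seeds_b, edges)
            rep = find_bridges(net_a, net_b)

            union_edges = {frozenset(e[:2]) for e in edges
                           if e[0] in seeds_a | seeds_b or e[1] in seeds_a | seeds_b}
            expect_direct = sorted(
                (a, b) for a in seeds_a for b in seeds_b
                if frozenset((a, b)) in union_edges
            )
            assert rep.direct_edges == expect_direct
            expect_paths = sorted(
                (a, m, b)
                for m in set(names) - seeds_a - seeds_b
                for a in seeds_a for b in seeds_b
                if frozenset((a, m)) in union_edges
                and frozenset((m, b)) in union_edges
            )
            assert rep.two_step_paths == expect_paths
            for a, m, b in rep.two_step_paths:
                assert frozenset((a, m)) in union_edges
                assert frozenset((m, b)) in union_edges
            assert rep.common_interactors == {m for _, m, _ in expect_paths}


class TestCandidateConnectivity:
    def test_candidate_reaches_seed_via_one_intermediate(self):
        net_a = build_interactome({"R"}, [("R", "M", "known")])
        net_b = build_interactome({"S"}, [])
        [rep] = candidate_connectivity(["C"], [("C", "M", "novel")], net_a, net_b)
        assert rep.n_interactors == 1 and not rep.isolated
        assert rep.seeds_a_reached == {"R"} and rep.shared_with_a == {"M"}
        assert not rep.seeds_b_reached and not rep.shared_with_b

    def test_isolated_candidate_reported_with_zero_counts(self):
        net_a = build_interactome({"R"}, [("R", "M", "known")])
        net_b = build_interactome({"S"}, [("S", "M", "known")])
        [rep] = candidate_connectivity(["C"], [], net_a, net_b)
        assert rep.isolated and rep.n_interactors == 0
        assert not rep.seeds_a_reached and not rep.seeds_b_reached

    def test_shared_interactors_listed_per_side(self):
        """A lone candidate with its own small edge list: interactors it
        shares with each disease net are reported separately."""
        net_a = build_interactome({"R1", "R2"},
                                  [("R1", "APC", "known"), ("R2", "ATF6B", "known")])
        net_b = build_interactome({"S1"}, [("S1", "APC", "known")])
        [rep] = candidate_connectivity(
            ["C4X"],
            [("C4X", "APC", "novel"), ("C4X", "ATF6B", "novel"),
             ("C4X", "LONE", "novel")],
            net_a, net_b,
        )
        assert rep.shared_with_a == {"APC", "ATF6B"}
        assert rep.shared_with_b == {"APC"}
        assert rep.seeds_a_reached == {"R1", "R2"}
        assert rep.n_interactors == 3
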