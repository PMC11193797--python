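"""Tie construction, affiliation, topology summaries and benchmarks."""

import numpy as np
import pandas as pd
import pytest

from wealthnet.network_build import (
    MembershipEpisode,
    MultilevelNetwork,
    TieInfo,
    affiliate,
    build_ties,
    mean_tie_years,
    summarise,
    summarise_graph,
    topology_benchmarks,
)


def ep(ind, hh, s, e, res=True):
    return MembershipEpisode(ind, hh, s, e, res)


class TestBuildTies:
    def test_concurrent_membership_shared_years(self):
        net = build_ties([ep(1, "H1", 2000, 2016), ep(1, "H2", 2005, 2010)])
        assert net.n_ties == 1
        info = net.ties[("H1", "H2")]
        assert info.shared_years == 6  # 2005..2010 inclusive
        assert info.n_shared_members == 1

    def test_sequential_membership_still_ties(self):
        net = build_ties([ep(1, "H1", 2000, 2005), ep(1, "H2", 2010, 2016)])
        assert net.n_ties == 1
        assert net.ties[("H1", "H2")].shared_years == 0

    def test_years_clipped_to_window(self):
        net = build_ties([ep(1, "H1", 1990, 2030), ep(1, "H2", 1995, 2030)])
        assert net.ties[("H1", "H2")].shared_years == 17  # capped at window length

    def test_invalid_episode_rejected_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            net = build_ties([ep(1, "H1", 2010, 2005), ep(1, "H2", 2000, 2016)])
        assert net.n_ties == 0
        assert "rejected" in caplog.text

    def test_shared_years_mean_over_members(self):
        eps = [
            ep(1, "H1", 2000, 2016), ep(1, "H2", 2000, 2003),  # 4 years
            ep(2, "H1", 2000, 2016), ep(2, "H2", 2010, 2016),  # 7 years
        ]
        net = build_ties(eps)
        info = net.ties[("H1", "H2")]
        assert info.n_shared_members == 2
        assert info.shared_years == pytest.approx(5.5)

    def test_matches_pairwise_overlap_brute_force(self):
        """Random 200-episode fixture vs an independent O(n^2) oracle."""
        rng = np.random.default_rng(42)
        eps = []
        for _ in range(200):
            s = int(rng.integers(2000, 2017))
            e = min(2016, s + int(rng.integers(0, 10)))
            eps.append(ep(int(rng.integers(40)), f"H{rng.integers(25)}", s, e))
        net = build_ties(eps)

        # oracle: per individual, interval arithmetic over every household pair
        spells = {}
        for x in eps:
            spells.setdefault(x.individual_id, {}).setdefault(x.household_id, []).append(
                (x.start_year, x.end_year)
            )
        expected = {}
        for d in spells.values():
            hhs = sorted(d)
            for i in range(len(hhs)):
                for j in range(i + 1, len(hhs)):
                    years = set()
                    for s1, e1 in d[hhs[i]]:
                        for s2, e2 in d[hhs[j]]:
                            years |= set(range(max(s1, s2), min(e1, e2) + 1))
                    rec = expected.setdefault((hhs[i], hhs[j]), [0, 0])
                    rec[0] += len(years)
                    rec[1] += 1
        assert set(net.ties) == set(expected)
        for pair, (tot, cnt) in expected.items():
            assert net.ties[pair].shared_years == pytest.approx(tot / cnt)
            assert net.ties[pair].n_shared_members == cnt

    def test_order_independence(self):
        rng = np.random.default_rng(3)
        eps = [
            ep(int(rng.integers(20)), f"H{rng.integers(12)}", 2000, int(rng.integers(2000, 2017)))
            for _ in range(80)
        ]
        a = build_ties(eps)
        shuffled = list(eps)
        rng.shuffle(shuffled)
        b = build_ties(shuffled)
        assert a.households == b.households
        assert set(a.ties) == set(b.ties)
        for k in a.ties:
            assert a.ties[k].shared_years == b.ties[k].shared_years

    def test_removing_individual_never_adds_ties(self):
        rng = np.random.default_rng(5)
        eps = [
            ep(int(rng.integers(15)), f"H{rng.integers(10)}", 2000, 2016)
            for _ in range(60)
        ]
        full = build_ties(eps)
        for drop in range(15):
            sub = build_ties([x for x in eps if x.individual_id != drop])
            assert set(sub.ties) <= set(full.ties)

    def test_dataframe_input_equivalent(self):
        eps = [ep(1, "H1", 2000, 2016), ep(1, "H2", 2005, 2010)]
        df = pd.DataFrame(
            {
                "individual_id": [1, 1],
                "household_id": ["H1", "H2"],
                "start_year": [2000, 2005],
                "end_year": [2016, 2010],
            }
        )
        assert build_ties(df).ties.keys() == build_ties(eps).ties.keys()


class TestAffiliate:
    def _net(self):
        ties = {("A", "B"): TieInfo(1, 1), ("B", "C"): TieInfo(2, 1)}
        return MultilevelNetwork(households=["A", "B", "C"], ties=ties)

    def test_single_region_no_meta_ties(self):
        net = affiliate(self._net(), {"A": 0, "B": 0, "C": 0})
        assert net.meta_ties == {}
        assert all(i.same_region for i in net.ties.values())

    def test_one_cross_tie_one_meta_tie(self):
        net = affiliate(self._net(), {"A": 0, "B": 0, "C": 1})
        assert net.meta_ties == {(0, 1): 1}
        assert net.ties[("A", "B")].same_region
        assert not net.ties[("B", "C")].same_region

    def test_unmapped_household_is_hard_error(self):
        with pytest.raises(KeyError, match="C"):
            affiliate(self._net(), {"A": 0, "B": 0})

    def test_labels_match_recount_oracle(self):
        rng = np.random.default_rng(11)
        ties = {}
        hh = [f"H{i}" for i in range(30)]
        for i in range(30):
            for j in range(i + 1, 30):
                if rng.random() < 0.1:
                    ties[(hh[i], hh[j])] = TieInfo(0, 1)
        aff = {h: int(rng.integers(5)) for h in hh}
        net = affiliate(MultilevelNetwork(households=hh, ties=ties), aff)
        meta = {}
        for (a, b), info in net.ties.items():
            assert info.same_region == (aff[a] == aff[b])
            if aff[a] != aff[b]:
                key = tuple(sorted((aff[a], aff[b])))
                meta[key] = meta.get(key, 0) + 1
        assert net.meta_ties == meta


class TestSummarise:
    def test_triangle(self):
        ties = {(0, 1): TieInfo(0, 1), (1, 2): TieInfo(0, 1), (0, 2): TieInfo(0, 1)}
        net = MultilevelNetwork(households=[0, 1, 2], ties=ties)
        s = summarise(net)
        assert s.global_clustering == 1.0
        assert s.mean_path_length == 1.0
        assert s.mean_degree == pytest.approx(2.0)

    def test_mean_degree_identity(self, small_pop):
        s = summarise(small_pop.net, seed=0)
        assert s.mean_degree == pytest.approx(2 * s.n_edges / s.n_nodes, abs=0)

    def test_against_igraph_oracle(self):
        """Cross-implementation recount on a 50-node random graph."""
        import igraph as ig
        import networkx as nx

        g = nx.gnm_random_graph(50, 70, seed=2)
        s = summarise_graph(g, seed=0)
        h = ig.Graph(n=50, edges=list(g.edges()))
        assert s.global_clustering == pytest.approx(
            h.transitivity_undirected(mode="zero"), abs=1e-12
        )
        comp = max(h.connected_components(), key=len)
        sub = h.subgraph(comp)
        assert s.mean_path_length == pytest.approx(sub.average_path_length(), rel=1e-9)
        assert s.largest_component_size == len(comp)
        degs = np.array(h.degree())
        assert s.degree_sd == pytest.approx(degs.std())
        assert s.n_in_any_component == int((degs > 0).sum())

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            summarise(MultilevelNetwork(households=[], ties={}))


class TestBenchmarksAndCovariates:
    def test_ws_ring_lattice_closed_form(self):
        """Rewiring-0 small-world graph has the lattice clustering 3(k-2)/(4(k-1))."""
        import networkx as nx

        k = 6
        s = summarise_graph(nx.watts_strogatz_graph(200, k, 0.0), seed=0)
        assert s.global_clustering == pytest.approx(3 * (k - 2) / (4 * (k - 1)), abs=1e-9)

    def test_benchmark_table(self, small_pop):
        tbl = topology_benchmarks(small_pop.net, seed=1)
        assert set(tbl.index) == {"observed", "erdos_renyi", "watts_strogatz", "barabasi_albert"}
        obs = tbl.loc["observed"]
        er = tbl.loc["erdos_renyi"]
        assert er["n_nodes"] == obs["n_nodes"]
        # ER clustering concentrates near mean_degree / n
        assert er["global_clustering"] < 0.05
        assert abs(er["n_edges"] - obs["n_edges"]) <= 1

    def test_mean_tie_years(self):
        ties = {("A", "B"): TieInfo(4.0, 1), ("B", "C"): TieInfo(2.0, 1)}
        net = MultilevelNetwork(households=["A", "B", "C", "D"], ties=ties)
        mt = mean_tie_years(net)
        assert mt["A"] == 4.0
        assert mt["B"] == 3.0
        assert mt["D"] == 0.0  # isolate
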