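import itertools

import igraph as ig
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from eukmag import bin_screen as bs
from eukmag import conet
from eukmag.abundance import AbundanceMatrix


class TestSpearman:
    def test_monotone_transform_gives_rho_one(self):
        x = np.arange(1.0, 11.0)
        m = AbundanceMatrix(pd.DataFrame({"a": x, "b": np.exp(x)}).T, "CPM")
        res = conet.spearman_all_pairs(m)
        assert res.pairs.iloc[0]["rho"] == pytest.approx(1.0)

    def test_reversed_ranks_give_minus_one(self):
        x = np.arange(1.0, 11.0)
        m = AbundanceMatrix(pd.DataFrame({"a": x, "b": x[::-1]}).T, "CPM")
        res = conet.spearman_all_pairs(m)
        assert res.pairs.iloc[0]["rho"] == pytest.approx(-1.0)

    def test_matches_rank_formula_on_five_samples(self):
        """Brute-force oracle: Pearson correlation of midranks."""
        rng = np.random.default_rng(4)
        a, b = rng.random(5), rng.random(5)
        m = AbundanceMatrix(pd.DataFrame({"a": a, "b": b}).T, "CPM")
        res = conet.spearman_all_pairs(m)
        ra, rb = stats.rankdata(a), stats.rankdata(b)
        oracle = np.corrcoef(ra, rb)[0, 1]
        assert res.pairs.iloc[0]["rho"] == pytest.approx(oracle)

    def test_pairwise_nan_dropping_and_min_samples(self):
        a = [1.0, 2.0, 3.0, 4.0, np.nan]
        b = [2.0, 4.0, 6.0, 8.0, 1.0]
        c = [np.nan, np.nan, 1.0, 2.0, 3.0]
        m = AbundanceMatrix(pd.DataFrame({"a": a, "b": b, "c": c}).T, "CPM")
        res = conet.spearman_all_pairs(m)
        ab = res.pairs.set_index(["mag_i", "mag_j"])
        assert ab.loc[("a", "b"), "n"] == 4
        assert ab.loc[("a", "b"), "rho"] == pytest.approx(1.0)
        assert ab.loc[("a", "c"), "n"] == 2 and np.isnan(ab.loc[("a", "c"), "rho"])

    def test_single_mag_errors(self):
        m = AbundanceMatrix(pd.DataFrame({"a": [1.0, 2.0]}).T, "CPM")
        with pytest.raises(ValueError):
            conet.spearman_all_pairs(m)


class TestSidak:
    def test_identity_at_one_comparison(self):
        assert conet.sidak_cutoff(0.05, 1) == pytest.approx(0.05)

    def test_zero_alpha(self):
        assert conet.sidak_cutoff(0.0, 17) == 0.0

    def test_closed_form_grid(self):
        for alpha in (0.01, 0.05, 0.1):
            for n in (1, 2, 10, 100, 10_000):
                assert conet.sidak_cutoff(alpha, n) == pytest.approx(
                    1 - (1 - alpha) ** (1 / n), rel=0, abs=1e-15
                )

    def test_zero_comparisons_errors(self):
        with pytest.raises(ValueError):
            conet.sidak_cutoff(0.05, 0)


def planted_block_matrix(seed=9, n_mags=20, block=6, n_samples=40):
    """One block of co-varying MAGs among independent background MAGs."""
    rng = np.random.default_rng(seed)
    latent = rng.normal(size=n_samples)
    rows = {}
    for i in range(block):
        rows[f"B{i:02d}"] = np.exp(latent + rng.normal(0, 0.15, n_samples))
    for i in range(block, n_mags):
        rows[f"N{i:02d}"] = np.exp(rng.normal(size=n_samples))
    return AbundanceMatrix(pd.DataFrame(rows).T, "CPM")


class TestFilterEdges:
    def test_stage_order_p_filter_first(self):
        pairs = pd.DataFrame(
            {
                "mag_i": ["a", "a"],
                "mag_j": ["b", "c"],
                "rho": [0.99, 0.95],
                "p": [0.9, 1e-12],
                "n": [30, 30],
            }
        )
        corr = conet.CorrelationResult(pairs, 3)
        cfg = conet.EdgeFilterConfig(percentile=None)
        edges, report = conet.filter_edges(corr, cfg, {"a": "eukaryote",
                                                       "b": "eukaryote",
                                                       "c": "eukaryote"})
        assert list(edges["mag_j"]) == ["c"]
        assert report.n_after_sidak == 1

    def test_prok_prok_pairs_dropped_last(self):
        pairs = pd.DataFrame(
            {
                "mag_i": ["p1", "p1"],
                "mag_j": ["p2", "e1"],
                "rho": [0.99, 0.98],
                "p": [1e-12, 1e-12],
                "n": [30, 30],
            }
        )
        corr = conet.CorrelationResult(pairs, 3)
        cfg = conet.EdgeFilterConfig(percentile=None)
        domains = {"p1": "prokaryote", "p2": "prokaryote", "e1": "eukaryote"}
        edges, report = conet.filter_edges(corr, cfg, domains)
        assert list(edges["mag_j"]) == ["e1"]
        assert report.n_after_rho_min == 2 and report.n_after_domain == 1
        keep_all, _ = conet.filter_edges(
            corr, conet.EdgeFilterConfig(percentile=None, keep_prok_prok=True), domains
        )
        assert len(keep_all) == 2

    def test_planted_block_survives_exactly(self):
        """Full cascade on a planted-block fixture keeps precisely the
        within-block pairs (brute-force oracle over all pairs)."""
        m = planted_block_matrix()
        corr = conet.spearman_all_pairs(m)
        cfg = conet.EdgeFilterConfig()  # default percentile=90 active
        domains = {mag: "eukaryote" for mag in m.values.index}
        edges, report = conet.filter_edges(corr, cfg, domains)
        got = {tuple(sorted(p)) for p in zip(edges["mag_i"], edges["mag_j"])}
        block = [f"B{i:02d}" for i in range(6)]
        want = {tuple(sorted(p)) for p in itertools.combinations(block, 2)}
        assert got == want
        assert report.n_measured == 190

    def test_survivor_counts_non_increasing(self):
        m = planted_block_matrix(seed=2)
        corr = conet.spearman_all_pairs(m)
        edges, r = conet.filter_edges(
            corr, conet.EdgeFilterConfig(), {mag: "eukaryote" for mag in m.values.index}
        )
        assert (
            r.n_measured >= r.n_after_sidak >= r.n_after_percentile
            >= r.n_after_rho_min >= r.n_after_domain == len(edges)
        )


def ani_for(ids, pairs, default=90.0):
    n = len(ids)
    m = np.full((n, n), default)
    np.fill_diagonal(m, 100.0)
    idx = {g: i for i, g in enumerate(ids)}
    for (a, b), v in pairs.items():
        m[idx[a], idx[b]] = m[idx[b], idx[a]] = v
    return bs.ANIMatrix(list(ids), m)


class TestCollapseAni:
    def edges(self, rows):
        return pd.DataFrame(rows, columns=["mag_i", "mag_j", "rho", "p"])

    def test_high_ani_high_rho_merged(self):
        e = self.edges([("a", "b", 0.9, 1e-9), ("a", "c", 0.8, 1e-9)])
        ani = ani_for(["a", "b", "c"], {("a", "b"): 99.5})
        reduced, mapping = conet.collapse_ani_clusters(e, ani)
        assert mapping == {"a": "a", "b": "a", "c": "c"}
        assert len(reduced) == 1  # intra-cluster edge dropped
        assert set(reduced.iloc[0][["mag_i", "mag_j"]]) == {"a", "c"}

    def test_low_rho_not_merged_despite_ani(self):
        e = self.edges([("a", "b", 0.3, 1e-9)])
        ani = ani_for(["a", "b"], {("a", "b"): 99.5})
        _, mapping = conet.collapse_ani_clusters(e, ani)
        assert mapping == {"a": "a", "b": "b"}

    def test_chain_forms_single_cluster(self):
        e = self.edges(
            [("a", "b", 0.9, 1e-9), ("b", "c", 0.92, 1e-9), ("a", "d", 0.85, 1e-9)]
        )
        ani = ani_for("abcd", {("a", "b"): 99.3, ("b", "c"): 99.8})
        reduced, mapping = conet.collapse_ani_clusters(e, ani)
        assert mapping["a"] == mapping["b"] == mapping["c"] == "a"
        assert mapping["d"] == "d"

    def test_parallel_edges_keep_max_abs_rho(self):
        e = self.edges(
            [("a", "b", 0.9, 1e-9), ("a", "c", 0.75, 1e-9), ("b", "c", -0.95, 1e-9)]
        )
        ani = ani_for("abc", {("a", "b"): 99.5})
        reduced, _ = conet.collapse_ani_clusters(e, ani)
        assert len(reduced) == 1
        assert reduced.iloc[0]["rho"] == pytest.approx(-0.95)


def two_cliques_graph(k=5):
    g = ig.Graph()
    names = [f"x{i}" for i in range(k)] + [f"y{i}" for i in range(k)]
    g.add_vertices(names)
    edges = [(f"x{i}", f"x{j}") for i in range(k) for j in range(i + 1, k)]
    edges += [(f"y{i}", f"y{j}") for i in range(k) for j in range(i + 1, k)]
    edges += [("x0", "y0")]
    g.add_edges(edges)
    g.es["rho"] = [0.9] * g.ecount()
    g.es["weight"] = [0.9] * g.ecount()
    return g


def modularity_oracle_two_cliques(g):
    """Exhaustive search over all 2^10 bipartitions plus the one-community
    partition is infeasible; instead enumerate partitions induced by all
    subsets of a 10-node graph is 115975 Bell -- restrict to checking that
    the clique split beats merging and singletons."""
    clique_split = [0 if v["name"].startswith("x") else 1 for v in g.vs]
    merged = [0] * g.vcount()
    singletons = list(range(g.vcount()))
    q = {tuple(p): g.modularity(p, weights="weight")
         for p in (clique_split, merged, singletons)}
    best = max(q, key=q.get)
    return list(best)


class TestCommunities:
    def test_two_cliques_split_into_two_communities(self):
        g = two_cliques_graph()
        res = conet.detect_communities(g, seed=1)
        assert len(res.communities) == 2
        comm_of = res.membership
        assert len({comm_of[f"x{i}"] for i in range(5)}) == 1
        assert len({comm_of[f"y{i}"] for i in range(5)}) == 1
        oracle = modularity_oracle_two_cliques(g)
        assert g.modularity(
            [comm_of[v["name"]] for v in g.vs], weights="weight"
        ) >= g.modularity(oracle, weights="weight") - 1e-12

    def test_edgeless_graph_gives_singletons(self):
        g = ig.Graph()
        g.add_vertices(["a", "b", "c"])
        res = conet.detect_communities(g, seed=0)
        assert len(res.communities) == 3 and res.modularity == 0.0

    def test_complete_graph_single_community(self):
        g = ig.Graph.Full(6)
        g.vs["name"] = [f"n{i}" for i in range(6)]
        g.es["weight"] = [1.0] * g.ecount()
        res = conet.detect_communities(g, seed=0)
        assert len(res.communities) == 1

    def test_deterministic_under_seed(self):
        g = two_cliques_graph()
        a = conet.detect_communities(g, seed=42)
        b = conet.detect_communities(g, seed=42)
        assert a.membership == b.membership and a.modularity == b.modularity


def graph_from_edges(n, edge_list):
    g = ig.Graph()
    g.add_vertices([f"v{i}" for i in range(n)])
    g.add_edges([(f"v{i}", f"v{j}") for i, j in edge_list])
    g.es["weight"] = [1.0] * g.ecount()
    return g


def connectedness_oracle(n, edge_list, membership):
    """Exhaustive enumeration straight from the definitions."""
    comms = sorted(set(membership.values()))
    members = {c: [v for v, cc in membership.items() if cc == c] for c in comms}
    edges = {tuple(sorted((f"v{i}", f"v{j}"))) for i, j in edge_list}
    C = {}
    for x in comms:
        nx = len(members[x])
        within = sum(
            1 for a, b in itertools.combinations(sorted(members[x]), 2)
            if tuple(sorted((a, b))) in edges
        )
        C[(x, x)] = within / (nx * (nx - 1) / 2) if nx > 1 else 0.0
    for x, y in itertools.combinations(comms, 2):
        touched = set()
        for a in members[x]:
            for b in members[y]:
                if tuple(sorted((a, b))) in edges:
                    touched.add(a)
                    touched.add(b)
        C[(x, y)] = C[(y, x)] = len(touched) / max(len(members[x]), len(members[y]))
    return C


class TestConnectedness:
    def test_complete_triangle_community(self):
        g = graph_from_edges(3, [(0, 1), (1, 2), (0, 2)])
        C = conet.connectedness(g, {f"v{i}": 0 for i in range(3)})
        assert C.loc[0, 0] == pytest.approx(1.0)

    def test_four_node_community_two_edges(self):
        g = graph_from_edges(4, [(0, 1), (2, 3)])
        C = conet.connectedness(g, {f"v{i}": 0 for i in range(4)})
        assert C.loc[0, 0] == pytest.approx(2 / 6)

    def test_between_community_distinct_node_rule(self):
        # x = {v0,v1,v2}, y = {v3..v7}; cross edges touch v0, v1 and v3
        g = graph_from_edges(8, [(0, 3), (1, 3)])
        membership = {f"v{i}": (0 if i < 3 else 1) for i in range(8)}
        C = conet.connectedness(g, membership)
        assert C.loc[0, 1] == pytest.approx(3 / 5)

    def test_edge_count_mode(self):
        g = graph_from_edges(8, [(0, 3), (1, 3)])
        membership = {f"v{i}": (0 if i < 3 else 1) for i in range(8)}
        C = conet.connectedness(g, membership, between_mode="edge_count")
        assert C.loc[0, 1] == pytest.approx(2 / 5)

    def test_singleton_community_zero_diagonal(self):
        g = graph_from_edges(2, [])
        C = conet.connectedness(g, {"v0": 0, "v1": 1})
        assert C.loc[0, 0] == 0.0 and C.loc[1, 1] == 0.0

    @given(
        n=st.integers(min_value=2, max_value=8),
        edge_bits=st.integers(min_value=0),
        comm_seed=st.integers(min_value=0, max_value=10_000),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_enumeration_oracle_on_small_graphs(self, n, edge_bits, comm_seed):
        all_pairs = list(itertools.combinations(range(n), 2))
        edge_list = [p for k, p in enumerate(all_pairs) if (edge_bits >> k) & 1]
        rng = np.random.default_rng(comm_seed)
        membership = {f"v{i}": int(c) for i, c in
                      enumerate(rng.integers(0, min(n, 3), size=n))}
        g = graph_from_edges(n, edge_list)
        C = conet.connectedness(g, membership)
        oracle = connectedness_oracle(n, edge_list, membership)
        for (x, y), v in oracle.items():
            assert C.loc[x, y] == pytest.approx(v)
        # relabel invariance
        relabel = {c: 10 + c for c in set(membership.values())}
        C2 = conet.connectedness(g, {k: relabel[v] for k, v in membership.items()})
        for (x, y), v in oracle.items():
            assert C2.loc[relabel[x], relabel[y]] == pytest.approx(v)


class TestEnvCorrelation:
    def test_identical_series_rho_one(self):
        sums = pd.DataFrame({"s1": [1.0], "s2": [2.0], "s3": [3.0], "s4": [4.0]},
                            index=[0])
        env = pd.DataFrame({"temp": [1.0, 2.0, 3.0, 4.0]},
                           index=["s1", "s2", "s3", "s4"])
        out = conet.env_correlation(sums, env)
        assert out.iloc[0]["rho"] == pytest.approx(1.0)

    def test_bonferroni_with_one_comparison_is_raw(self):
        rng = np.random.default_rng(8)
        sums = pd.DataFrame([rng.random(10)], index=[0],
                            columns=[f"s{i}" for i in range(10)])
        env = pd.DataFrame({"x": rng.random(10)}, index=sums.columns)
        out = conet.env_correlation(sums, env)
        assert out.iloc[0]["p_adj"] == pytest.approx(out.iloc[0]["p"])

    def test_bonferroni_multiplies_and_caps(self):
        rng = np.random.default_rng(9)
        samples = [f"s{i}" for i in range(12)]
        sums = pd.DataFrame(rng.random((2, 12)), index=[0, 1], columns=samples)
        env = pd.DataFrame(rng.random((12, 5)), index=samples,
                           columns=list("abcde"))
        out = conet.env_correlation(sums, env)
        assert len(out) == 10
        for _, r in out.iterrows():
            assert r["p_adj"] == pytest.approx(min(1.0, r["p"] * 10))

    def test_too_few_paired_observations_marked_missing(self):
        sums = pd.DataFrame({"s1": [1.0], "s2": [2.0], "s3": [3.0]}, index=[0])
        env = pd.DataFrame({"x": [1.0, np.nan, np.nan]},
                           index=["s1", "s2", "s3"])
        out = conet.env_correlation(sums, env)
        assert np.isnan(out.iloc[0]["rho"])
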