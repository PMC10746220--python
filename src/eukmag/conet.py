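"""MAG co-occurrence network from CPM abundances.

Pipeline: all-pairs Spearman correlation across samples; a staged edge
filter (Šidák-corrected p-value, a high-percentile cut on |rho|, a final
|rho| > 0.70 threshold, and removal of prokaryote–prokaryote pairs so the
network focuses on eukaryote-involved associations); collapsing of
near-identical eukaryotic MAGs (ANI >= 99% and correlated > 0.70) into
single cluster nodes; Louvain-style modularity communities; and
within/between-community connectedness

    C_x,x = (edges within x) / (n_x (n_x - 1) / 2)
    C_x,y = (distinct members of x u y with >= 1 cross edge) / max(n_x, n_y)

plus Spearman correlations of per-community summed abundance against
environmental covariates with Bonferroni adjustment.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass
from typing import Iterable

import igraph as ig
import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .abundance import AbundanceMatrix
from .bin_screen import ANIMatrix

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05
DEFAULT_PERCENTILE = 90.0
DEFAULT_RHO_MIN = 0.70
DEFAULT_ANI_COLLAPSE = 99.0
MIN_SHARED_SAMPLES = 3


@dataclass
class CorrelationResult:
    """Unordered-pair Spearman correlations: DataFrame with columns
    mag_i, mag_j, rho, p, n (shared samples); pairs with too few shared
    samples carry NaN rho/p."""

    pairs: pd.DataFrame
    n_mags: int

    def matrix(self) -> pd.DataFrame:
        mags = sorted(set(self.pairs["mag_i"]) | set(self.pairs["mag_j"]))
        m = pd.DataFrame(np.eye(len(mags)), index=mags, columns=mags)
        for _, r in self.pairs.iterrows():
            m.loc[r["mag_i"], r["mag_j"]] = r["rho"]
            m.loc[r["mag_j"], r["mag_i"]] = r["rho"]
        return m


def spearman_all_pairs(cpm: AbundanceMatrix | pd.DataFrame) -> CorrelationResult:
    """Spearman rho and two-sided p for every unordered MAG pair, with
    midrank tie handling; samples where either MAG is missing (NaN) are
    dropped pairwise, and pairs sharing fewer than 3 samples are marked
    missing."""
    values = cpm.values if isinstance(cpm, AbundanceMatrix) else cpm
    if values.shape[0] < 2:
        raise ValueError("need at least 2 MAGs to correlate")
    mags = list(values.index)
    arr = values.values.astype(float)
    has_nan = np.isnan(arr).any()
    rows = []
    if not has_nan:
        rho_mat, p_mat = stats.spearmanr(arr.T)
        if np.ndim(rho_mat) == 0:  # scipy collapses the 2-variable case
            rho_mat = np.array([[1.0, rho_mat], [rho_mat, 1.0]])
            p_mat = np.array([[0.0, p_mat], [p_mat, 0.0]])
        n = arr.shape[1]
        for i in range(len(mags)):
            for j in range(i + 1, len(mags)):
                if n < MIN_SHARED_SAMPLES:
                    rows.append((mags[i], mags[j], np.nan, np.nan, n))
                else:
                    rows.append((mags[i], mags[j], rho_mat[i, j], p_mat[i, j], n))
    else:
        for i in range(len(mags)):
            for j in range(i + 1, len(mags)):
                mask = ~np.isnan(arr[i]) & ~np.isnan(arr[j])
                n = int(mask.sum())
                if n < MIN_SHARED_SAMPLES:
                    rows.append((mags[i], mags[j], np.nan, np.nan, n))
                    continue
                rho, p = stats.spearmanr(arr[i, mask], arr[j, mask])
                rows.append((mags[i], mags[j], rho, p, n))
    df = pd.DataFrame(rows, columns=["mag_i", "mag_j", "rho", "p", "n"])
    return CorrelationResult(df, len(mags))


def sidak_cutoff(alpha: float, n_comparisons: int) -> float:
    """Šidák multiple-comparison p-value threshold 1 - (1 - alpha)^(1/n)."""
    if n_comparisons < 1:
        raise ValueError("number of comparisons must be >= 1")
    if not 0 <= alpha < 1:
        raise ValueError("alpha must be in [0, 1)")
    return 1.0 - (1.0 - alpha) ** (1.0 / n_comparisons)


@dataclass
class EdgeFilterConfig:
    """Staged edge-filter settings.

    ``percentile`` keeps only pairs whose |rho| reaches that percentile of
    the full measured |rho| distribution; set it to None to disable the
    stage (meaningful mainly for large networks — on small node sets a
    fixed-rank cut discards structure regardless of signal).
    ``keep_prok_prok=True`` disables the eukaryote-involvement rule.
    """

    alpha: float = DEFAULT_ALPHA
    percentile: float | None = DEFAULT_PERCENTILE
    rho_min: float = DEFAULT_RHO_MIN
    ani_collapse: float = DEFAULT_ANI_COLLAPSE
    keep_prok_prok: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.percentile is not None and not 0 <= self.percentile <= 100:
            raise ValueError("percentile must be in [0, 100]")


@dataclass
class FilterReport:
    n_measured: int
    n_after_sidak: int
    n_after_percentile: int
    n_after_rho_min: int
    n_after_domain: int
    sidak_p: float
    percentile_cutoff: float | None


def filter_edges(
    corr: CorrelationResult,
    cfg: EdgeFilterConfig,
    domains: dict[str, str] | pd.Series,
) -> tuple[pd.DataFrame, FilterReport]:
    """Run the staged filter cascade and report survivor counts per stage.

    Stages, in order: (1) Šidák-corrected significance over the number of
    measured pairs; (2) |rho| at or above the configured percentile of all
    measured |rho|; (3) |rho| strictly greater than ``rho_min``;
    (4) drop prokaryote-prokaryote pairs.
    """
    if isinstance(domains, pd.Series):
        domains = domains.to_dict()
    measured = corr.pairs.dropna(subset=["rho", "p"]).copy()
    n_measured = len(measured)
    if n_measured == 0:
        report = FilterReport(0, 0, 0, 0, 0, np.nan, None)
        return measured, report
    p_cut = sidak_cutoff(cfg.alpha, n_measured)
    s1 = measured[measured["p"] < p_cut]
    if cfg.percentile is not None:
        q = np.percentile(np.abs(measured["rho"].values), cfg.percentile)
        s2 = s1[np.abs(s1["rho"].values) >= q]
    else:
        q = None
        s2 = s1
    s3 = s2[np.abs(s2["rho"].values) > cfg.rho_min]
    if cfg.keep_prok_prok:
        s4 = s3
    else:
        def euk_involved(row) -> bool:
            di = domains.get(row["mag_i"], "eukaryote")
            dj = domains.get(row["mag_j"], "eukaryote")
            return not (di == "prokaryote" and dj == "prokaryote")
        s4 = s3[s3.apply(euk_involved, axis=1)] if len(s3) else s3
    report = FilterReport(
        n_measured, len(s1), len(s2), len(s3), len(s4), p_cut, q,
    )
    logger.info(
        "edge filter: %d measured -> %d sidak -> %d percentile -> %d rho "
        "-> %d domain", n_measured, len(s1), len(s2), len(s3), len(s4),
    )
    return s4.reset_index(drop=True), report


def collapse_ani_clusters(
    edges: pd.DataFrame,
    ani: ANIMatrix | None,
    rho_min: float = DEFAULT_RHO_MIN,
    ani_threshold: float = DEFAULT_ANI_COLLAPSE,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Merge near-identical MAGs (ANI >= threshold AND rho > rho_min) into
    cluster nodes named by their lexicographically first member; edges
    inside a cluster are removed and parallel edges between cluster nodes
    keep the largest |rho|.  Returns (reduced edges, mag -> node map)."""
    mags = sorted(set(edges["mag_i"]) | set(edges["mag_j"]))
    mapping = {m: m for m in mags}
    if ani is not None and len(edges):
        idx = {m: i for i, m in enumerate(mags)}
        adj = np.zeros((len(mags), len(mags)), dtype=bool)
        for _, r in edges.iterrows():
            a, b = r["mag_i"], r["mag_j"]
            if a in ani._index and b in ani._index:
                if ani.value(a, b) >= ani_threshold and abs(r["rho"]) > rho_min:
                    adj[idx[a], idx[b]] = adj[idx[b], idx[a]] = True
        n_comp, labels = connected_components(csr_matrix(adj), directed=False)
        for lab in range(n_comp):
            members = [m for m, l in zip(mags, labels) if l == lab]
            if len(members) > 1:
                rep = min(members)
                for m in members:
                    mapping[m] = rep
    rows = {}
    for _, r in edges.iterrows():
        u, v = mapping[r["mag_i"]], mapping[r["mag_j"]]
        if u == v:
            continue
        key = (min(u, v), max(u, v))
        if key not in rows or abs(r["rho"]) > abs(rows[key]["rho"]):
            rows[key] = {"mag_i": key[0], "mag_j": key[1], "rho": r["rho"], "p": r["p"]}
    reduced = pd.DataFrame(
        list(rows.values()), columns=["mag_i", "mag_j", "rho", "p"]
    )
    return reduced.reset_index(drop=True), mapping


# ---------------------------------------------------------------------------
# Communities and connectedness
# ---------------------------------------------------------------------------

@dataclass
class CommunityGraph:
    graph: ig.Graph
    membership: dict[str, int]
    modularity: float

    @property
    def communities(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for node, c in self.membership.items():
            out.setdefault(c, []).append(node)
        return {c: sorted(v) for c, v in sorted(out.items())}


def build_graph(edges: pd.DataFrame, nodes: Iterable[str] | None = None) -> ig.Graph:
    """Weighted undirected graph from an edge table; weight = |rho|, with
    the signed rho kept as an attribute."""
    node_list = sorted(
        set(edges["mag_i"]) | set(edges["mag_j"]) | set(nodes or [])
    )
    g = ig.Graph()
    g.add_vertices(node_list)
    if len(edges):
        g.add_edges(list(zip(edges["mag_i"], edges["mag_j"])))
        g.es["rho"] = list(edges["rho"].astype(float))
        g.es["weight"] = list(np.abs(edges["rho"].values.astype(float)))
    return g


def detect_communities(graph: ig.Graph, seed: int = 0) -> CommunityGraph:
    """Multilevel (Louvain-style) modularity maximization on |rho| weights,
    made deterministic by seeding igraph's RNG and shuffling the vertex
    order from the same seed.  An edgeless graph yields singleton
    communities with Q = 0."""
    if graph.vcount() == 0:
        raise ValueError("empty graph")
    names = graph.vs["name"]
    if graph.ecount() == 0:
        return CommunityGraph(graph, {n: i for i, n in enumerate(sorted(names))}, 0.0)
    rng = random.Random(seed)
    order = list(range(graph.vcount()))
    rng.shuffle(order)
    shuffled = graph.permute_vertices([order.index(i) for i in range(len(order))])
    # permute_vertices maps old index i -> new index given; rebuild with names
    ig.set_random_number_generator(random.Random(seed))
    clustering = shuffled.community_multilevel(weights="weight")
    ig.set_random_number_generator(random)  # restore default RNG
    membership = {
        shuffled.vs[i]["name"]: c for i, c in enumerate(clustering.membership)
    }
    # canonical community ids: ordered by smallest member name
    comm_members: dict[int, list[str]] = {}
    for n, c in membership.items():
        comm_members.setdefault(c, []).append(n)
    order_map = {
        c: rank
        for rank, c in enumerate(
            sorted(comm_members, key=lambda c: min(comm_members[c]))
        )
    }
    membership = {n: order_map[c] for n, c in membership.items()}
    q = float(shuffled.modularity(clustering.membership, weights="weight"))
    return CommunityGraph(graph, membership, q)


def connectedness(
    graph: ig.Graph,
    membership: dict[str, int],
    between_mode: str = "distinct_nodes",
) -> pd.DataFrame:
    """Within/between-community connectedness matrix.

    Diagonal: realized fraction of the n_x(n_x-1)/2 possible
    within-community edges (0 with a warning for singletons).  Off-diagonal
    (default "distinct_nodes" mode): distinct members of either community
    with at least one edge into the other, divided by the larger community
    size; "edge_count" mode divides the raw cross-edge count instead.
    """
    if between_mode not in ("distinct_nodes", "edge_count"):
        raise ValueError(f"unknown between_mode {between_mode!r}")
    nodes = set(graph.vs["name"])
    if set(membership) != nodes:
        raise ValueError("membership must cover exactly the graph's nodes")
    comms = sorted(set(membership.values()))
    members = {c: {n for n, cc in membership.items() if cc == c} for c in comms}
    edge_set = {
        tuple(sorted((graph.vs[e.source]["name"], graph.vs[e.target]["name"])))
        for e in graph.es
    }
    C = pd.DataFrame(0.0, index=comms, columns=comms)
    for ci in comms:
        n_x = len(members[ci])
        within = sum(1 for u, v in edge_set if u in members[ci] and v in members[ci])
        possible = n_x * (n_x - 1) / 2
        if possible == 0:
            logger.warning("community %s is a singleton; C_x,x set to 0", ci)
            C.loc[ci, ci] = 0.0
        else:
            C.loc[ci, ci] = within / possible
    for i, cx in enumerate(comms):
        for cy in comms[i + 1:]:
            cross = [
                (u, v)
                for u, v in edge_set
                if (u in members[cx]) != (u in members[cy])
                and ((u in members[cx] and v in members[cy])
                     or (u in members[cy] and v in members[cx]))
            ]
            if between_mode == "distinct_nodes":
                touched = {u for u, v in cross} | {v for u, v in cross}
                num = len(touched)
            else:
                num = len(cross)
            val = num / max(len(members[cx]), len(members[cy]))
            C.loc[cx, cy] = C.loc[cy, cx] = val
    return C


def env_correlation(
    community_cpm_sums: pd.DataFrame,
    env_table: pd.DataFrame,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Spearman correlation of each community's summed abundance against
    each environmental variable, Bonferroni-adjusted over all comparisons;
    pairs with fewer than 3 jointly observed samples are left missing."""
    shared = community_cpm_sums.columns.intersection(env_table.index)
    if len(shared) == 0:
        raise ValueError("no shared samples between abundance and environment tables")
    comparisons = [
        (c, v) for c in community_cpm_sums.index for v in env_table.columns
    ]
    n_comp = len(comparisons)
    rows = []
    for c, v in comparisons:
        a = community_cpm_sums.loc[c, shared].astype(float)
        e = env_table.loc[shared, v].astype(float)
        mask = a.notna() & e.notna()
        if mask.sum() < 3:
            rows.append((c, v, np.nan, np.nan, np.nan, False))
            continue
        rho, p = stats.spearmanr(a[mask], e[mask])
        p_adj = min(1.0, p * n_comp)
        rows.append((c, v, rho, p, p_adj, bool(p_adj < alpha)))
    return pd.DataFrame(
        rows, columns=["community", "variable", "rho", "p", "p_adj", "significant"]
    )


def community_abundance_sums(
    cpm: AbundanceMatrix | pd.DataFrame,
    membership: dict[str, int],
    mapping: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-community CPM sums across samples (community x sample).  When a
    MAG -> cluster-node mapping is given, MAG abundances are first assigned
    to their node."""
    values = cpm.values if isinstance(cpm, AbundanceMatrix) else cpm
    rows = {}
    for mag in values.index:
        node = mapping.get(mag, mag) if mapping else mag
        if node not in membership:
            continue
        c = membership[node]
        rows[c] = rows.get(c, 0) + values.loc[mag].astype(float)
    out = pd.DataFrame(rows).T
    out.index.name = "community"
    return out.sort_index()
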