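"""Network topology scoring and consensus hub calling on protein-interaction graphs.

Computes the twelve node-centrality parameters used for hub-gene inference
(degree, betweenness, stress, closeness, eccentricity, radiality,
clustering coefficient, MNC, DMNC, MCC, bottleneck, EPC) and implements two
hub definitions: the consensus rule — top 5% in at least 9 of the 12
parameters — and a plain degree cutoff (> 30 neighbors). Candidate genes
are ranked by maximal clique centrality (MCC), the score that drives the
target shortlist.

Graphs are simple and undirected (networkx.Graph). Path-based scores are
computed within connected components; eccentricity is treated as
"smaller = more central" when quantile-thresholding.
"""

from __future__ import annotations

import math
import warnings
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "CENTRALITY_COLUMNS",
    "compute_centralities",
    "identify_hubs",
    "degree_hub_flag",
    "neighborhood_subgraph",
    "rank_by_mcc",
    "read_edge_list",
    "write_edge_list",
]

CENTRALITY_COLUMNS = [
    "eccentricity", "clustering_coefficient", "dmnc", "bottleneck",
    "radiality", "mnc", "degree", "epc", "closeness", "betweenness",
    "stress", "mcc",
]

# eccentricity is a distance (small = central); every other score is a
# centrality (large = central)
_INVERTED = {"eccentricity"}


def _component_matrices(g: nx.Graph, nodes: list) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs shortest-path distance and path-count matrices (inf / 0
    off-component)."""
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    dist = np.full((n, n), np.inf)
    sigma = np.zeros((n, n))
    for s in nodes:
        si = idx[s]
        dist[si, si] = 0.0
        sigma[si, si] = 1.0
        # BFS with path counting
        frontier = [s]
        d = 0
        while frontier:
            nxt = []
            for v in frontier:
                for w in g[v]:
                    wi = idx[w]
                    if not np.isfinite(dist[si, wi]):
                        dist[si, wi] = d + 1
                        nxt.append(w)
                    if dist[si, wi] == d + 1:
                        sigma[si, wi] += sigma[si, idx[v]]
            frontier = nxt
            d += 1
    return dist, sigma


def _stress(dist: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """Stress centrality: number of shortest paths passing through each node,
    over unordered pairs s < t with s, t != v."""
    n = dist.shape[0]
    out = np.zeros(n)
    for v in range(n):
        through = dist[:, v][:, None] + dist[v, :][None, :]
        on_path = np.isclose(through, dist) & np.isfinite(dist)
        contrib = np.where(on_path, sigma[:, v][:, None] * sigma[v, :][None, :], 0.0)
        contrib[v, :] = 0.0
        contrib[:, v] = 0.0
        np.fill_diagonal(contrib, 0.0)
        out[v] = contrib.sum() / 2.0
    return out


def _bottleneck(g: nx.Graph, nodes: list, dist: np.ndarray) -> np.ndarray:
    """Bottleneck: number of single-source BFS shortest-path trees in which
    the node's subtree holds more than a quarter of the tree's nodes.
    Parent ties broken toward the lowest node id (deterministic)."""
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    counts = np.zeros(n)
    for s in nodes:
        si = idx[s]
        reachable = [v for v in nodes if np.isfinite(dist[si, idx[v]])]
        tree_n = len(reachable)
        if tree_n < 2:
            continue
        parent: dict = {}
        for v in reachable:
            if v == s:
                continue
            dv = dist[si, idx[v]]
            preds = [u for u in g[v] if np.isclose(dist[si, idx[u]], dv - 1)]
            parent[v] = min(preds, key=str)
        children: dict = {v: [] for v in reachable}
        for v, p in parent.items():
            children[p].append(v)
        subtree = {v: 1 for v in reachable}
        for v in sorted(reachable, key=lambda u: -dist[si, idx[u]]):
            for c in children[v]:
                subtree[v] += subtree[c]
        for v in reachable:
            if subtree[v] > tree_n / 4.0:
                counts[idx[v]] += 1
    return counts


def _mcc(g: nx.Graph, nodes: list) -> np.ndarray:
    """Maximal clique centrality: sum over maximal cliques containing v of
    (|C|-1)!. A node whose neighborhood is edgeless only lies in size-2
    maximal cliques, so its MCC equals its degree (the degree fallback)."""
    idx = {v: i for i, v in enumerate(nodes)}
    out = np.zeros(len(nodes))
    for clique in nx.find_cliques(g):
        if len(clique) < 2:
            continue
        w = math.factorial(len(clique) - 1)
        for v in clique:
            out[idx[v]] += w
    return out


def compute_centralities(
    g: nx.Graph,
    epc_trials: int = 1000,
    epc_keep_prob: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """All 12 topology parameters per node.

    Shortest-path scores are computed within each connected component
    (radiality uses the component diameter; closeness is networkx's
    component-scaled convention). EPC is the Monte-Carlo mean size of the
    node's connected component over ``epc_trials`` edge-subsampled graphs,
    each edge kept independently with probability ``epc_keep_prob``.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    nodes = list(g.nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    dist, sigma = _component_matrices(g, nodes)

    degree = np.array([g.degree(v) for v in nodes], dtype=float)
    clustering = np.array([nx.clustering(g, v) for v in nodes], dtype=float)
    betweenness_d = nx.betweenness_centrality(g, normalized=False)
    betweenness = np.array([betweenness_d[v] for v in nodes])
    closeness_d = nx.closeness_centrality(g)
    closeness = np.array([closeness_d[v] for v in nodes])
    stress = _stress(dist, sigma)
    bottleneck = _bottleneck(g, nodes, dist)
    mcc = _mcc(g, nodes)

    eccentricity = np.zeros(n)
    radiality = np.zeros(n)
    for comp in nx.connected_components(g):
        comp = list(comp)
        ci = [idx[v] for v in comp]
        sub = dist[np.ix_(ci, ci)]
        if len(comp) == 1:
            continue
        ecc = sub.max(axis=1)
        diam = float(sub.max())
        for v_loc, v in enumerate(comp):
            eccentricity[idx[v]] = ecc[v_loc]
            others = np.delete(sub[v_loc], v_loc)
            radiality[idx[v]] = float(np.mean(diam + 1.0 - others))

    mnc = np.zeros(n)
    dmnc = np.zeros(n)
    for v in nodes:
        nbrs = list(g[v])
        if not nbrs:
            continue
        sub = g.subgraph(nbrs)
        comp = max(nx.connected_components(sub), key=len)
        comp_g = sub.subgraph(comp)
        mnc[idx[v]] = comp_g.number_of_nodes()
        dmnc[idx[v]] = comp_g.number_of_edges() / comp_g.number_of_nodes() ** 1.7

    # EPC by Monte-Carlo edge percolation with union-find via networkx
    rng = np.random.default_rng(seed)
    edges = list(g.edges)
    epc = np.zeros(n)
    for _ in range(epc_trials):
        keep = rng.random(len(edges)) < epc_keep_prob
        sub = nx.Graph()
        sub.add_nodes_from(nodes)
        sub.add_edges_from(e for e, k in zip(edges, keep) if k)
        for comp in nx.connected_components(sub):
            size = len(comp)
            for v in comp:
                epc[idx[v]] += size
    epc /= max(epc_trials, 1)

    return pd.DataFrame(
        dict(eccentricity=eccentricity, clustering_coefficient=clustering,
             dmnc=dmnc, bottleneck=bottleneck, radiality=radiality, mnc=mnc,
             degree=degree, epc=epc, closeness=closeness,
             betweenness=betweenness, stress=stress, mcc=mcc),
        index=pd.Index(nodes, name="node"),
    )


def identify_hubs(table: pd.DataFrame, top_frac: float = 0.05, min_params: int = 9) -> pd.Series:
    """Consensus hub flag: in the top ``top_frac`` for >= ``min_params`` of
    the 12 parameters. Score >= the empirical (1 - top_frac) quantile counts
    as top (ties included); eccentricity is inverted first."""
    if not 0 < top_frac < 1:
        raise ValueError("top_frac must be in (0,1)")
    if not 1 <= min_params <= len(CENTRALITY_COLUMNS):
        raise ValueError("min_params must be in [1,12]")
    if len(table) < math.ceil(1 / top_frac):
        warnings.warn("fewer nodes than 1/top_frac: quantile is degenerate", stacklevel=2)
    hits = np.zeros(len(table), dtype=int)
    for col in CENTRALITY_COLUMNS:
        scores = table[col].to_numpy(dtype=float)
        if col in _INVERTED:
            scores = -scores
        cut = np.quantile(scores, 1 - top_frac)
        hits += (scores >= cut).astype(int)
    return pd.Series(hits >= min_params, index=table.index, name="hub_consensus")


def degree_hub_flag(table: pd.DataFrame, min_degree: int = 30) -> pd.Series:
    """Degree hub flag: strictly more than ``min_degree`` neighbors."""
    return pd.Series(table["degree"] > min_degree, index=table.index, name="hub_degree30")


def neighborhood_subgraph(g: nx.Graph, seed_genes: Iterable, order: int = 1) -> nx.Graph:
    """Induced subgraph on the seed genes and their <= ``order``-hop neighbors."""
    seeds = [s for s in seed_genes]
    if not seeds:
        raise ValueError("empty seed set")
    missing = [s for s in seeds if s not in g]
    if missing:
        warnings.warn(f"{len(missing)} seed genes absent from the network; dropped", stacklevel=2)
    present = set(s for s in seeds if s in g)
    if not present:
        raise ValueError("no seed gene present in the network")
    keep = set(present)
    frontier = set(present)
    for _ in range(order):
        frontier = {w for v in frontier for w in g[v]} - keep
        keep |= frontier
    return g.subgraph(keep).copy()


def rank_by_mcc(table: pd.DataFrame, candidate_genes: Sequence) -> pd.DataFrame:
    """Candidates ranked by descending MCC; ties by degree, then id."""
    missing = [c for c in candidate_genes if c not in table.index]
    if missing:
        raise KeyError(f"candidates not in centrality table: {missing[:5]}")
    sub = table.loc[sorted(set(candidate_genes), key=str), ["mcc", "degree"]].copy()
    sub = sub.sort_values(["mcc", "degree"], ascending=False, kind="stable")
    sub["mcc_rank"] = np.arange(1, len(sub) + 1)
    return sub


def read_edge_list(path, min_confidence: float | None = None) -> nx.Graph:
    """Two-column (plus optional confidence) tab-separated edge list."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    g = nx.Graph()
    for row in df.itertuples(index=False):
        a, b = row[0], row[1]
        conf = float(row[2]) if len(row) > 2 and row[2] is not None else None
        if min_confidence is not None and conf is not None and conf < min_confidence:
            continue
        if a != b:
            g.add_edge(a, b, **({"confidence": conf} if conf is not None else {}))
    return g


def write_edge_list(g: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        for a, b, data in g.edges(data=True):
            conf = data.get("confidence")
            fh.write(f"{a}\t{b}" + (f"\t{conf}" if conf is not None else "") + "\n")
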