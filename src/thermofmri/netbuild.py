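"""Stimulus-driven graph construction and topology metrics.

Chain: global-mean regression of per-structure traces, Fisher-z adjacency
matrices, k-standardization (retain the N*k/2 strongest positive undirected
edges, or N*k directed), binary small-world indices normalized against
random same-size graphs, Louvain (Blondel) communities, and aggregation of
structures into functional groups for visualization-scale summaries.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .core import ConfigError, InputError

logger = logging.getLogger(__name__)

FISHER_CLIP = 1.0 - 1e-7  # keeps z finite for degenerate (r = +/-1) traces


# --------------------------------------------------------------------------
# Traces -> adjacency
# --------------------------------------------------------------------------
def global_regression(traces: np.ndarray) -> np.ndarray:
    """Remove the global mean trace from each structure trace by OLS.

    ``traces`` is (n_structures, n_t). The global mean over structures and an
    intercept are regressed out of every row; with a zero-variance global
    mean only mean-centering is applied (with a warning).
    """
    traces = np.asarray(traces, dtype=float)
    if traces.ndim != 2 or traces.shape[0] < 2:
        raise InputError("global regression needs >= 2 structure traces")
    g = traces.mean(axis=0)
    if np.ptp(g) == 0 or np.var(g) < 1e-24:
        warnings.warn("zero-variance global mean: mean-centering only", stacklevel=2)
        return traces - traces.mean(axis=1, keepdims=True)
    X = np.column_stack([np.ones_like(g), g])
    beta, *_ = np.linalg.lstsq(X, traces.T, rcond=None)
    return traces - (X @ beta).T


@dataclass
class AdjacencyMatrix:
    """Fisher-z (or Pearson, flagged) structure-by-structure matrix."""

    values: np.ndarray
    nodes: list[int]
    mode: str = "symmetric"  # or "directed"
    scale: str = "fisher_z"  # or "pearson_r"
    provenance: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.nodes, columns=self.nodes)


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """atanh with |r| clipped at 1 - 1e-7 so degenerate correlations stay finite."""
    return np.arctanh(np.clip(r, -FISHER_CLIP, FISHER_CLIP))


def build_adjacency(
    traces: np.ndarray,
    nodes: list[int] | None = None,
    provenance: dict | None = None,
) -> AdjacencyMatrix:
    """Pairwise Pearson correlation of structure traces as a Fisher-z matrix.

    Constant traces have no defined correlation: their rows/columns are set
    to NaN and logged; the diagonal is zeroed (excluded from edge selection).
    """
    traces = np.asarray(traces, dtype=float)
    if traces.shape[1] < 3:
        raise InputError("need >= 3 time points for a correlation")
    n = traces.shape[0]
    nodes = list(range(1, n + 1)) if nodes is None else list(nodes)
    sd = traces.std(axis=1)
    ok = sd > 0
    vals = np.full((n, n), np.nan)
    if ok.sum() >= 2:
        r = np.corrcoef(traces[ok])
        z = fisher_z(r)
        sub = np.ix_(ok, ok)
        vals[sub] = z
    if (~ok).any():
        logger.warning("excluding %d constant trace(s) from the adjacency", int((~ok).sum()))
    np.fill_diagonal(vals, 0.0)
    return AdjacencyMatrix(values=vals, nodes=nodes, provenance=provenance or {})


def mean_adjacency(matrices: list[AdjacencyMatrix], provenance: dict | None = None) -> AdjacencyMatrix:
    """Element-wise mean over animals (NaN-aware), e.g. per temperature and group."""
    if not matrices:
        raise InputError("no matrices to average")
    first = matrices[0]
    stack = np.stack([m.values for m in matrices])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(stack, axis=0)
    return AdjacencyMatrix(
        values=mean, nodes=list(first.nodes), mode=first.mode, scale=first.scale,
        provenance=provenance or {},
    )


# --------------------------------------------------------------------------
# k-standardization
# --------------------------------------------------------------------------
def k_standardize(
    matrix: AdjacencyMatrix,
    k: int = 10,
    node_attrs: dict[int, dict] | None = None,
) -> nx.Graph:
    """Retain exactly the m strongest positive connections (m = N*k/2 symmetric,
    N*k directed), with deterministic tie-breaking by ascending (i, j) index.

    Returns a networkx Graph (or DiGraph) over all nodes; if fewer positive
    entries exist than m, all are kept with a warning.
    """
    if k <= 0:
        raise ConfigError("k must be positive")
    n = matrix.n_nodes
    vals = matrix.values
    directed = matrix.mode == "directed"
    m_target = n * k if directed else (n * k) // 2

    if directed:
        ii, jj = np.where(~np.eye(n, dtype=bool))
    else:
        ii, jj = np.triu_indices(n, 1)
    w = vals[ii, jj]
    pos = np.isfinite(w) & (w > 0)
    ii, jj, w = ii[pos], jj[pos], w[pos]
    if w.size < m_target:
        warnings.warn(
            f"only {w.size} positive connections available for m = {m_target}; keeping all",
            stacklevel=2,
        )
        m_keep = w.size
    else:
        m_keep = m_target
    order = np.lexsort((jj, ii, -w))[:m_keep]

    G: nx.Graph = nx.DiGraph() if directed else nx.Graph()
    for node in matrix.nodes:
        attrs = (node_attrs or {}).get(node, {})
        G.add_node(node, **attrs)
    nodes = matrix.nodes
    for idx in order:
        G.add_edge(nodes[ii[idx]], nodes[jj[idx]], weight=float(w[idx]))
    G.graph["k"] = k
    G.graph["mode"] = matrix.mode
    G.graph.update(matrix.provenance)
    return G


# --------------------------------------------------------------------------
# Small-world metrics
# --------------------------------------------------------------------------
@dataclass
class SmallWorldMetrics:
    gamma: float  # clustering normalized against random graphs
    lam: float  # path length normalized against random graphs
    sigma: float  # gamma / lam
    c_raw: float
    l_raw: float
    n_random: int
    seed: int
    fragmented: bool = False  # True if L excluded unreachable pairs


def characteristic_path_length(G: nx.Graph) -> tuple[float, bool]:
    """Mean shortest path over connected ordered pairs (hop metric).

    Disconnected pairs are excluded; the flag reports whether any were.
    """
    n = G.number_of_nodes()
    if n < 2 or G.number_of_edges() == 0:
        raise InputError("path length undefined on an empty graph")
    total, pairs = 0.0, 0
    for comp in nx.connected_components(G.to_undirected() if G.is_directed() else G):
        sub = G.subgraph(comp)
        nc = len(comp)
        if nc < 2:
            continue
        for _, dists in nx.all_pairs_shortest_path_length(sub):
            total += sum(dists.values())
            pairs += nc - 1
    if pairs == 0:
        raise InputError("no connected pairs")
    fragmented = pairs < n * (n - 1)
    return total / pairs, fragmented


def small_world(G: nx.Graph, n_random: int = 100, seed: int = 0) -> SmallWorldMetrics:
    """Binary clustering/path-length normalized by same-N-same-m random graphs.

    C is the mean local clustering coefficient and L the characteristic path
    length of the binarized graph; gamma = C/<C_rand>, lambda = L/<L_rand>
    over ``n_random`` uniform G(n, m) graphs; sigma = gamma/lambda.
    """
    if G.number_of_edges() == 0:
        raise InputError("small-world metrics undefined on an empty graph")
    H = nx.Graph()
    H.add_nodes_from(G.nodes())
    H.add_edges_from(G.edges())
    c = nx.average_clustering(H)
    l, fragmented = characteristic_path_length(H)
    rng = np.random.default_rng(seed)
    c_rand, l_rand = [], []
    n, m = H.number_of_nodes(), H.number_of_edges()
    for _ in range(n_random):
        R = nx.gnm_random_graph(n, m, seed=int(rng.integers(2**31)))
        c_rand.append(nx.average_clustering(R))
        lr, _ = characteristic_path_length(R)
        l_rand.append(lr)
    gamma = c / np.mean(c_rand)
    lam = l / np.mean(l_rand)
    return SmallWorldMetrics(
        gamma=float(gamma),
        lam=float(lam),
        sigma=float(gamma / lam),
        c_raw=float(c),
        l_raw=float(l),
        n_random=n_random,
        seed=seed,
        fragmented=fragmented,
    )


# --------------------------------------------------------------------------
# Communities
# --------------------------------------------------------------------------
@dataclass
class CommunityPartition:
    membership: dict  # node -> community id
    modularity: float
    seed: int

    @property
    def n_communities(self) -> int:
        return len(set(self.membership.values()))


def blondel_communities(G: nx.Graph, seed: int = 0) -> CommunityPartition:
    """Louvain modularity optimization on edge weights; seed-deterministic."""
    if G.number_of_edges() < 1:
        raise InputError("community detection needs at least one edge")
    H = G.to_undirected() if G.is_directed() else G
    comms = nx.community.louvain_communities(H, weight="weight", seed=seed)
    membership = {node: ci for ci, nodes in enumerate(comms) for node in nodes}
    q = nx.community.modularity(H, comms, weight="weight")
    return CommunityPartition(membership=membership, modularity=float(q), seed=seed)


# --------------------------------------------------------------------------
# Functional-group aggregation
# --------------------------------------------------------------------------
def aggregate_functional_groups(
    G: nx.Graph,
    structure_table: pd.DataFrame,
    respect_communities: bool = False,
    partition: CommunityPartition | None = None,
    positions: dict[int, np.ndarray] | None = None,
) -> nx.Graph:
    """Condense structure nodes into functional-group nodes.

    Edge weights (sums of member-edge Pearson/Fisher weights) and connection
    counts are aggregated per group pair; within-group member edges are kept
    as ``within_weight``/``within_connections`` node attributes. With
    ``respect_communities`` nodes aggregate per (group, community) so one
    functional group may appear once per community. Node ``degree`` counts
    member edges to other condensed nodes; ``position`` is the mean member
    position when positions are given.
    """
    group_of = dict(zip(structure_table["label_id"].astype(int), structure_table["functional_group"]))
    missing = [n for n in G.nodes if int(n) not in group_of]
    if missing:
        raise InputError(f"nodes without functional group: {missing}")

    def key(node):
        g = group_of[int(node)]
        if respect_communities:
            if partition is None:
                raise InputError("respect_communities requires a partition")
            return (g, partition.membership[node])
        return g

    C = nx.Graph()
    members: dict = {}
    for node in G.nodes:
        members.setdefault(key(node), []).append(node)
    for kk, mem in members.items():
        pos = None
        if positions is not None:
            pos = np.mean([positions[int(n)] for n in mem], axis=0).tolist()
        C.add_node(kk, n_members=len(mem), position=pos, within_weight=0.0, within_connections=0, degree=0)
    for u, v, d in G.edges(data=True):
        ku, kv = key(u), key(v)
        w = float(d.get("weight", 1.0))
        if ku == kv:
            C.nodes[ku]["within_weight"] += w
            C.nodes[ku]["within_connections"] += 1
            continue
        if C.has_edge(ku, kv):
            C[ku][kv]["weight"] += w
            C[ku][kv]["n_connections"] += 1
        else:
            C.add_edge(ku, kv, weight=w, n_connections=1)
    for kk in C.nodes:
        C.nodes[kk]["degree"] = sum(C[kk][nbr]["n_connections"] for nbr in C.neighbors(kk))
    return C


# --------------------------------------------------------------------------
# Exports
# --------------------------------------------------------------------------
def edge_list(G: nx.Graph) -> pd.DataFrame:
    rows = [
        {"node_i": u, "node_j": v, "weight": d.get("weight", 1.0)} for u, v, d in G.edges(data=True)
    ]
    return pd.DataFrame(rows, columns=["node_i", "node_j", "weight"])


def kamada_kawai_coordinates(G: nx.Graph, seed: int = 0) -> pd.DataFrame:
    """2D Kamada-Kawai layout coordinates for visualization export."""
    pos = nx.kamada_kawai_layout(G, weight=None)
    return pd.DataFrame(
        [{"node": n, "x": float(p[0]), "y": float(p[1])} for n, p in pos.items()]
    )
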