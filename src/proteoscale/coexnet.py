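"""Planar-filtered co-expression network and multiscale module detection.

The network is built from all feature pairs whose correlation survives FDR
control, inserted greedily in descending correlation strength subject to the
graph remaining planar (the planar maximally filtered graph).  Planarity is
checked combinatorially; a graph embeddable on a sphere without edge
crossings is exactly a planar graph, so the combinatorial test admits the
same edge sets as a spherical embedding.

Modules are found by recursive top-down splitting: each connected component
is a candidate module; a module is split by weighted-modularity
maximization, and the split is accepted only if the gain in compactness
(mean within-part shortest-path closeness) exceeds what degree-preserving
rewires of the module subgraph produce.  Hubs are nodes whose degree is
unattainable in size-matched random graphs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import benjamini_hochberg

logger = logging.getLogger(__name__)

__all__ = [
    "PlanarNetwork",
    "ModuleHierarchy",
    "significant_pairs",
    "build_pfn",
    "multiscale_cluster",
    "detect_hubs",
]


@dataclass
class PlanarNetwork:
    """Undirected planar graph; each edge carries the signed correlation."""

    graph: nx.Graph

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def is_planar(self) -> bool:
        ok, _ = nx.check_planarity(self.graph)
        return ok

    def edge_table(self) -> pd.DataFrame:
        rows = [
            (u, v, d.get("rho", np.nan)) for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["node1", "node2", "rho"])


@dataclass
class ModuleHierarchy:
    """Rooted containment tree of feature sets with a resolution index."""

    modules: dict[str, set[str]] = field(default_factory=dict)
    parent: dict[str, str] = field(default_factory=dict)
    scale: dict[str, int] = field(default_factory=dict)

    def children(self, module_id: str) -> list[str]:
        return [c for c, p in self.parent.items() if p == module_id]

    def leaves(self) -> list[str]:
        nonleaf = set(self.parent.values())
        return [m for m in self.modules if m not in nonleaf]

    def assignment(self) -> dict[str, str]:
        """Finest module containing each node (deepest scale wins)."""
        out: dict[str, str] = {}
        for m in sorted(self.modules, key=lambda m: (self.scale[m], m)):
            for node in self.modules[m]:
                out[node] = m
        return out


def significant_pairs(
    matrix: pd.DataFrame,
    fdr: float = 0.05,
    method: str = "pearson",
    min_abs_rho: float = 0.0,
) -> pd.DataFrame:
    """All feature pairs with FDR-significant correlation.

    Returns a frame (node1, node2, rho, p, adj_p) sorted by descending |rho|
    with ties broken lexicographically by the id pair.  Constant features
    are excluded with a warning.  ``min_abs_rho`` adds an effect-size gate on
    top of FDR control: with many features, a small fraction of pure-noise
    pairs always survives the FDR step, and those spurious edges can bridge
    otherwise separate modules; a floor near the upper tail of the null
    correlation distribution (about 4 / sqrt(n_samples)) removes them.
    """
    if matrix.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    X = matrix.to_numpy(dtype=float)
    sd = X.std(axis=1)
    const = sd == 0
    if const.any():
        logger.warning("excluding %d constant features", int(const.sum()))
        matrix = matrix.loc[~const]
        X = matrix.to_numpy(dtype=float)
    ids = list(matrix.index)
    n = matrix.shape[1]
    if method == "spearman":
        X = np.apply_along_axis(stats.rankdata, 1, X)
    Xc = X - X.mean(axis=1, keepdims=True)
    norm = np.sqrt((Xc**2).sum(axis=1))
    R = (Xc @ Xc.T) / np.outer(norm, norm)
    np.clip(R, -1, 1, out=R)
    iu, ju = np.triu_indices(len(ids), k=1)
    rho = R[iu, ju]
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = rho * np.sqrt((n - 2) / np.maximum(1 - rho**2, 1e-300))
    p = 2 * stats.t.sf(np.abs(tstat), n - 2)
    p[np.abs(rho) >= 1] = 0.0
    adj = benjamini_hochberg(p)
    keep = (adj < fdr) & (np.abs(rho) >= min_abs_rho)
    df = pd.DataFrame(
        {
            "node1": [ids[i] for i in iu[keep]],
            "node2": [ids[j] for j in ju[keep]],
            "rho": rho[keep],
            "p": p[keep],
            "adj_p": adj[keep],
        }
    )
    df["_abs"] = -df["rho"].abs()
    df = df.sort_values(["_abs", "node1", "node2"], kind="stable").drop(columns="_abs")
    return df.reset_index(drop=True)


def build_pfn(candidates: pd.DataFrame) -> PlanarNetwork:
    """Greedy planar maximally filtered network.

    Traverse candidate edges in the given (descending-|rho|) order and insert
    each edge iff the graph stays planar.  Any output satisfies
    |E| <= 3|V| - 6.
    """
    g: nx.Graph = nx.Graph()
    for row in candidates.itertuples(index=False):
        u, v, rho = row.node1, row.node2, row.rho
        g.add_edge(u, v, rho=float(rho))
        ok, _ = nx.check_planarity(g)
        if not ok:
            g.remove_edge(u, v)
            for x in (u, v):
                if g.degree(x) == 0:
                    g.remove_node(x)
    return PlanarNetwork(graph=g)


def _compactness(g: nx.Graph, parts: list[set]) -> float:
    """Mean within-part pairwise closeness (1/shortest-path length)."""
    vals = []
    for part in parts:
        if len(part) < 2:
            continue
        sub = g.subgraph(part)
        total, cnt = 0.0, 0
        for src, dists in nx.all_pairs_shortest_path_length(sub):
            for dst, dd in dists.items():
                if dst != src:
                    total += 1.0 / dd
                    cnt += 1
        vals.append(total / cnt if cnt else 0.0)
    return float(np.mean(vals)) if vals else 0.0


def _best_partition(g: nx.Graph, seed: int) -> list[set]:
    comms = nx.community.louvain_communities(
        g, weight="absrho", seed=seed, resolution=1.0
    )
    return [set(c) for c in comms]


def _rewired(g: nx.Graph, rng: np.random.Generator) -> nx.Graph:
    h = g.copy()
    nswap = 2 * h.number_of_edges()
    try:
        nx.double_edge_swap(
            h, nswap=nswap, max_tries=20 * nswap + 100,
            seed=int(rng.integers(2**31 - 1)),
        )
    except nx.NetworkXError:
        pass  # too dense/degenerate to rewire: null equals observed graph
    # preserve weights approximately: reassign original weights in order
    for (u, v) in h.edges:
        h[u][v]["absrho"] = 1.0
    return h


def multiscale_cluster(
    pfn: PlanarNetwork,
    min_size: int = 10,
    n_null: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
) -> ModuleHierarchy:
    """Recursive top-down multiscale module detection.

    The root module is the full clustered node set.  Disconnected candidate
    modules split into their connected components.  A connected module is
    split by weighted-modularity maximization; the split is accepted iff the
    compactness gain exceeds the (1 - alpha) quantile of the gains obtained
    on ``n_null`` degree-preserving rewires of the module subgraph.
    Children smaller than ``min_size`` are not emitted.
    """
    if pfn.graph.number_of_nodes() == 0:
        raise ValueError("empty network")
    g = pfn.graph.copy()
    for u, v, d in g.edges(data=True):
        d["absrho"] = abs(d.get("rho", 1.0))
    hier = ModuleHierarchy()
    counter = [0]

    def new_id() -> str:
        counter[0] += 1
        return f"M{counter[0]}"

    def recurse(nodes: set, parent_id: str | None, depth: int) -> None:
        mid = new_id()
        hier.modules[mid] = set(nodes)
        hier.scale[mid] = depth
        if parent_id is not None:
            hier.parent[mid] = parent_id
        sub = g.subgraph(nodes)
        comps = [set(c) for c in nx.connected_components(sub)]
        if len(comps) > 1:
            for c in sorted(comps, key=lambda c: (-len(c), min(c))):
                if len(c) >= min_size:
                    recurse(c, mid, depth + 1)
            return
        if len(nodes) < 2 * min_size:
            return
        rng = np.random.default_rng([seed, depth, counter[0]])
        part_seed = int(rng.integers(2**31 - 1))
        parts = _best_partition(sub, part_seed)
        if len(parts) < 2:
            return
        base = _compactness(sub, [set(nodes)])
        gain = _compactness(sub, parts) - base
        null_gains = []
        for _ in range(n_null):
            h = _rewired(sub, rng)
            nparts = _best_partition(h, int(rng.integers(2**31 - 1)))
            if len(nparts) < 2:
                null_gains.append(0.0)
                continue
            null_gains.append(
                _compactness(h, nparts) - _compactness(h, [set(h.nodes)])
            )
        thresh = float(np.quantile(null_gains, 1 - alpha)) if null_gains else np.inf
        if gain <= thresh:
            return
        for c in sorted(parts, key=lambda c: (-len(c), min(c))):
            if len(c) >= min_size:
                recurse(c, mid, depth + 1)

    recurse(set(g.nodes), None, 0)
    return hier


def detect_hubs(
    pfn: PlanarNetwork,
    module: set[str],
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Significant hubs of a module by a random-graph degree null.

    For each node, the hub p-value is the (add-one corrected) fraction of
    random graphs with the module subgraph's node and edge counts in which
    any node attains the observed degree.  Nodes with p < alpha are hubs,
    sorted by descending degree.  Modules smaller than 3 yield an empty
    table.
    """
    cols = ["node", "degree", "hub_p"]
    if len(module) < 3:
        return pd.DataFrame(columns=cols)
    sub = pfn.graph.subgraph(module)
    n, m = sub.number_of_nodes(), sub.number_of_edges()
    degs = dict(sub.degree)
    rng = np.random.default_rng(seed)
    max_degs = np.empty(n_perm)
    for i in range(n_perm):
        h = nx.gnm_random_graph(n, m, seed=int(rng.integers(2**31 - 1)))
        max_degs[i] = max((d for _, d in h.degree), default=0)
    rows = []
    for node, d in degs.items():
        p = (1 + int((max_degs >= d).sum())) / (n_perm + 1)
        if p < alpha:
            rows.append((node, d, p))
    out = pd.DataFrame(rows, columns=cols)
    return out.sort_values(["degree", "node"], ascending=[False, True]).reset_index(
        drop=True
    )
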