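"""Genotype-anchored causal network inference and key driver analysis.

The causal stage anchors directionality in genetics: cis-acting variants
(eQTLs, FDR < 0.05) identify features under genetic control; the causal
inference test (CIT) orients pairs of features sharing an eQTL; the decided
orientations, plus optional TF-target relations, become structural priors
for a Metropolis-Hastings search over directed acyclic graphs scored by
Gaussian BIC.  An ensemble of independently seeded chains is summarized by
edge frequency; edges present in more than a threshold fraction (default
30%, strict) form the consensus network, which is made acyclic by
iteratively deleting the most weakly supported edge on any cycle.  Key
driver analysis then tests each node's downstream neighborhood for
enrichment of a disease signature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import benjamini_hochberg
from .modulechar import hypergeometric_enrichment, adjust_enrichments

logger = logging.getLogger(__name__)

__all__ = [
    "CitResult",
    "PriorSet",
    "ConsensusDag",
    "compute_eqtls",
    "cit_test",
    "assemble_priors",
    "mcmc_structure_search",
    "consensus_network",
    "deloop",
    "downstream_neighborhood",
    "key_driver_analysis",
]


@dataclass(frozen=True)
class CitResult:
    snp: str
    a: str
    b: str
    p_components: tuple[float, float, float, float]
    omnibus_p: float
    direction: str  # "A->B", "B->A", or "undecided"


@dataclass
class PriorSet:
    """Structural priors: hard forbidden edges and soft score bonuses."""

    forbidden: set[tuple[str, str]] = field(default_factory=set)
    bonus: dict[tuple[str, str], float] = field(default_factory=dict)


@dataclass
class ConsensusDag:
    """Directed graph with per-edge ensemble frequency."""

    graph: nx.DiGraph

    def edge_table(self) -> pd.DataFrame:
        rows = [(u, v, d["frequency"]) for u, v, d in self.graph.edges(data=True)]
        return pd.DataFrame(rows, columns=["source", "target", "frequency"])

    def is_acyclic(self) -> bool:
        return nx.is_directed_acyclic_graph(self.graph)


def compute_eqtls(
    genotypes: pd.DataFrame,
    matrix: pd.DataFrame,
    fdr: float = 0.05,
    min_minor_allele_count: int = 5,
) -> pd.DataFrame:
    """Per-(SNP, feature) linear regression of abundance on allele dosage.

    Monomorphic SNPs (or those under the minor-allele-count floor) are
    skipped with a warning.  BH adjustment runs across all tested pairs;
    rows carry beta, p, adj_p and a significance flag at FDR < ``fdr``.
    """
    samples = [s for s in matrix.columns if s in genotypes.columns]
    if len(samples) < 4:
        raise ValueError("too few shared samples")
    Y = matrix[samples].to_numpy(dtype=float)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    n = len(samples)
    rows = []
    for snp in genotypes.index:
        g = genotypes.loc[snp, samples].to_numpy(dtype=float)
        mac = int(min(g.sum(), 2 * n - g.sum()))
        if g.std() == 0 or mac < min_minor_allele_count:
            logger.warning("skipping SNP %s (monomorphic or rare)", snp)
            continue
        gc = g - g.mean()
        denom = float((gc**2).sum())
        beta = (Yc @ gc) / denom
        resid_ss = (Yc**2).sum(axis=1) - beta**2 * denom
        df = n - 2
        se = np.sqrt(np.maximum(resid_ss, 0.0) / df / denom)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, beta / se, np.inf)
        p = 2 * stats.t.sf(np.abs(t), df)
        for feat, b, pv in zip(matrix.index, beta, p):
            rows.append((snp, feat, float(b), float(pv)))
    out = pd.DataFrame(rows, columns=["snp", "feature", "beta", "p"])
    if len(out):
        out["adj_p"] = benjamini_hochberg(out["p"].to_numpy())
        out["significant"] = out["adj_p"] < fdr
    else:
        out["adj_p"] = []
        out["significant"] = []
    return out


def _f_test_added(y: np.ndarray, base: np.ndarray, added: np.ndarray) -> tuple[float, float]:
    """Partial F-test for ``added`` columns given ``base`` columns.

    Returns (F statistic, p-value).  Columns include no intercept; one is
    appended internally.
    """
    n = len(y)
    one = np.ones((n, 1))
    X0 = np.hstack([one, base]) if base.size else one
    X1 = np.hstack([X0, added])
    b0, *_ = np.linalg.lstsq(X0, y, rcond=None)
    b1, *_ = np.linalg.lstsq(X1, y, rcond=None)
    rss0 = float(((y - X0 @ b0) ** 2).sum())
    rss1 = float(((y - X1 @ b1) ** 2).sum())
    df1 = X1.shape[1] - X0.shape[1]
    df2 = n - X1.shape[1]
    if df2 <= 0 or rss1 <= 0:
        return np.inf, 0.0
    f = max((rss0 - rss1) / df1 / (rss1 / df2), 0.0)
    return f, float(stats.f.sf(f, df1, df2))


def _cit_oriented(L: np.ndarray, A: np.ndarray, B: np.ndarray) -> tuple[float, ...]:
    """Component p-values of the causal chain L -> A -> B."""
    Lc = L[:, None]
    Ac = A[:, None]
    Bc = B[:, None]
    # (1) L associated with B
    _, p1 = _f_test_added(B, np.empty((len(B), 0)), Lc)
    # (2) L associated with A given B
    _, p2 = _f_test_added(A, Bc, Lc)
    # (3) A associated with B given L
    _, p3 = _f_test_added(B, Lc, Ac)
    # (4) equivalence-style test that L is independent of B given A:
    # observed F of L in B ~ A + L compared with a noncentral F whose
    # noncentrality reflects the marginal L-B association; a small observed
    # F relative to that alternative is evidence of mediation.
    f_obs, _ = _f_test_added(B, Ac, Lc)
    n = len(B)
    r2 = np.corrcoef(L, B)[0, 1] ** 2
    ncp = n * r2 / max(1 - r2, 1e-12)
    df2 = n - 3
    p4 = float(stats.ncf.cdf(f_obs, 1, df2, max(ncp, 1e-8)))
    return p1, p2, p3, p4


def cit_test(
    dosage: pd.Series | np.ndarray,
    a: pd.Series | np.ndarray,
    b: pd.Series | np.ndarray,
    alpha: float = 0.05,
    snp: str = "L",
    a_id: str = "A",
    b_id: str = "B",
) -> CitResult:
    """Causal inference test for a (variant, feature A, feature B) triplet.

    Both orientations of the chain are tested with four component tests
    each; the omnibus p is the max of the components (intersection-union).
    The direction is the orientation with omnibus p < alpha when exactly one
    qualifies, else undecided.
    """
    L = np.asarray(dosage, dtype=float)
    A = np.asarray(a, dtype=float)
    B = np.asarray(b, dtype=float)
    if np.array_equal(A, B):
        raise ValueError("A and B are identical vectors")
    p_ab = _cit_oriented(L, A, B)
    p_ba = _cit_oriented(L, B, A)
    om_ab, om_ba = max(p_ab), max(p_ba)
    ab_ok, ba_ok = om_ab < alpha, om_ba < alpha
    if ab_ok and not ba_ok:
        direction, comp, om = "A->B", p_ab, om_ab
    elif ba_ok and not ab_ok:
        direction, comp, om = "B->A", p_ba, om_ba
    else:
        direction = "undecided"
        comp, om = (p_ab, om_ab) if om_ab <= om_ba else (p_ba, om_ba)
    return CitResult(snp=snp, a=a_id, b=b_id, p_components=tuple(comp),
                     omnibus_p=om, direction=direction)


def assemble_priors(
    cit_results: list[CitResult],
    tf_targets: list[tuple[str, str]] | None = None,
    bonus_weight: float = 1.0,
) -> PriorSet:
    """Build structural priors from CIT orientations and TF-target pairs.

    A decided orientation A->B forbids the reverse edge B->A.  Conflicting
    hard constraints (both directions decided across triplets) are dropped
    with a warning.  TF-target pairs add a score bonus for the stated
    direction.
    """
    directed: set[tuple[str, str]] = set()
    for r in cit_results:
        if r.direction == "A->B":
            directed.add((r.a, r.b))
        elif r.direction == "B->A":
            directed.add((r.b, r.a))
    conflicts = {(u, v) for (u, v) in directed if (v, u) in directed}
    if conflicts:
        logger.warning("dropping %d conflicting CIT constraints", len(conflicts) // 2)
        directed -= conflicts
    priors = PriorSet()
    priors.forbidden = {(v, u) for (u, v) in directed}
    for tf, target in tf_targets or []:
        priors.bonus[(tf, target)] = priors.bonus.get((tf, target), 0.0) + bonus_weight
    return priors


class _DagState:
    """Mutable DAG with incremental Gaussian-BIC scoring."""

    def __init__(self, X: np.ndarray, ids: list[str], priors: PriorSet,
                 max_parents: int, cache: dict, edge_penalty: float = 2.0):
        self.edge_penalty = edge_penalty
        self.X = X  # samples x features, standardized
        self.ids = ids
        self.n_nodes = X.shape[1]
        self.priors = priors
        self.max_parents = max_parents
        self.parents: list[set[int]] = [set() for _ in range(self.n_nodes)]
        self.children: list[set[int]] = [set() for _ in range(self.n_nodes)]
        self.cache = cache
        self.idx = {f: i for i, f in enumerate(ids)}
        self.forbidden = {
            (self.idx[u], self.idx[v])
            for u, v in priors.forbidden
            if u in self.idx and v in self.idx
        }
        self.bonus = {
            (self.idx[u], self.idx[v]): w
            for (u, v), w in priors.bonus.items()
            if u in self.idx and v in self.idx
        }

    def node_score(self, node: int, parents: frozenset[int]) -> float:
        key = (node, parents)
        if key in self.cache:
            return self.cache[key]
        y = self.X[:, node]
        n = len(y)
        if parents:
            P = self.X[:, sorted(parents)]
            Xd = np.hstack([np.ones((n, 1)), P])
            beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
            rss = float(((y - Xd @ beta) ** 2).sum())
            k = Xd.shape[1]
        else:
            rss = float(((y - y.mean()) ** 2).sum())
            k = 1
        rss = max(rss, 1e-10)
        # Gaussian BIC as a log-score: -(n/2) log(rss/n) - (k/2) log n
        score = -(n / 2) * np.log(rss / n) - (k / 2) * np.log(n)
        self.cache[key] = score
        return score

    def total_score(self) -> float:
        s = sum(self.node_score(i, frozenset(self.parents[i]))
                for i in range(self.n_nodes))
        s += sum(w for (u, v), w in self.bonus.items() if u in self.parents[v])
        return s

    def creates_cycle(self, u: int, v: int) -> bool:
        """Would adding u -> v close a directed cycle (path v ~> u)?"""
        if u == v:
            return True
        stack = [v]
        seen = {v}
        while stack:
            w = stack.pop()
            if w == u:
                return True
            for c in self.children[w]:
                if c not in seen:
                    seen.add(c)
                    stack.append(c)
        return False

    def delta_add(self, u: int, v: int) -> float:
        old = self.node_score(v, frozenset(self.parents[v]))
        new = self.node_score(v, frozenset(self.parents[v] | {u}))
        return new - old + self.bonus.get((u, v), 0.0) - self.edge_penalty

    def delta_delete(self, u: int, v: int) -> float:
        old = self.node_score(v, frozenset(self.parents[v]))
        new = self.node_score(v, frozenset(self.parents[v] - {u}))
        return new - old - self.bonus.get((u, v), 0.0) + self.edge_penalty

    def apply_add(self, u: int, v: int) -> None:
        self.parents[v].add(u)
        self.children[u].add(v)

    def apply_delete(self, u: int, v: int) -> None:
        self.parents[v].discard(u)
        self.children[u].discard(v)

    def edges(self) -> list[tuple[int, int]]:
        return [(u, v) for v in range(self.n_nodes) for u in self.parents[v]]


def mcmc_structure_search(
    matrix: pd.DataFrame,
    priors: PriorSet | None = None,
    max_parents: int = 3,
    n_iter: int = 2000,
    seed: int = 0,
    max_features: int = 300,
    edge_penalty: float = 2.0,
    _cache: dict | None = None,
) -> nx.DiGraph:
    """One Metropolis-Hastings DAG sample.

    Nodes are features (matrix rows), data are the sample columns.  The
    score is the Gaussian BIC per node given its parents plus prior bonuses
    and a sparsity structure prior (``edge_penalty`` log-units per edge);
    proposals add, delete, or reverse a uniformly random admissible edge
    (hard constraints and cycles never violated).  Returns the chain state
    after ``n_iter`` steps from a random seeded start.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if matrix.shape[0] > max_features:
        raise ValueError(
            f"{matrix.shape[0]} features exceed the configured cap {max_features}"
        )
    ids = list(matrix.index)
    X = matrix.to_numpy(dtype=float).T
    X = (X - X.mean(axis=0)) / np.where(X.std(axis=0) == 0, 1.0, X.std(axis=0))
    rng = np.random.default_rng(seed)
    state = _DagState(X, ids, priors or PriorSet(), max_parents,
                      _cache if _cache is not None else {}, edge_penalty)
    p = state.n_nodes

    # random seeded start: sparse random DAG respecting a random order
    order = rng.permutation(p)
    rank = np.empty(p, dtype=int)
    rank[order] = np.arange(p)
    n_start = min(p, max(1, p // 2))
    for _ in range(n_start):
        u, v = rng.integers(p), rng.integers(p)
        if rank[u] < rank[v] and (u, v) not in state.forbidden and \
                len(state.parents[v]) < max_parents and u not in state.parents[v]:
            state.apply_add(u, v)

    for _ in range(n_iter):
        move = rng.integers(3)
        u, v = int(rng.integers(p)), int(rng.integers(p))
        if u == v:
            continue
        if move == 0:  # add
            if (u, v) in state.forbidden or u in state.parents[v] or \
                    len(state.parents[v]) >= max_parents or state.creates_cycle(u, v):
                continue
            delta = state.delta_add(u, v)
            if delta >= 0 or rng.random() < np.exp(delta):
                state.apply_add(u, v)
        elif move == 1:  # delete
            if u not in state.parents[v]:
                continue
            delta = state.delta_delete(u, v)
            if delta >= 0 or rng.random() < np.exp(delta):
                state.apply_delete(u, v)
        else:  # reverse u->v to v->u
            if u not in state.parents[v] or (v, u) in state.forbidden or \
                    len(state.parents[u]) >= max_parents:
                continue
            d1 = state.delta_delete(u, v)
            state.apply_delete(u, v)
            if state.creates_cycle(v, u):
                state.apply_add(u, v)
                continue
            delta = d1 + state.delta_add(v, u)
            if delta >= 0 or rng.random() < np.exp(delta):
                state.apply_add(v, u)
            else:
                state.apply_add(u, v)

    g = nx.DiGraph()
    g.add_nodes_from(ids)
    g.add_edges_from((ids[u], ids[v]) for u, v in state.edges())
    assert nx.is_directed_acyclic_graph(g)
    return g


def sample_ensemble(
    matrix: pd.DataFrame,
    priors: PriorSet | None = None,
    n_networks: int = 100,
    n_iter: int = 2000,
    max_parents: int = 3,
    seed: int = 0,
    max_features: int = 300,
    edge_penalty: float = 2.0,
) -> list[nx.DiGraph]:
    """Independently seeded MCMC chains with random starts (shared score
    cache across chains)."""
    cache: dict = {}
    out = []
    for i in range(n_networks):
        chain_seed = int(np.random.default_rng([seed, i]).integers(2**31 - 1))
        out.append(
            mcmc_structure_search(matrix, priors, max_parents, n_iter,
                                  seed=chain_seed, max_features=max_features,
                                  edge_penalty=edge_penalty, _cache=cache)
        )
    return out


def consensus_network(
    ensemble: list[nx.DiGraph], freq_thresh: float = 0.3
) -> ConsensusDag:
    """Edges shared by strictly more than ``freq_thresh`` of the ensemble.

    Frequencies are exact counts over the ensemble size.
    """
    if not ensemble:
        raise ValueError("empty ensemble")
    counts: dict[tuple[str, str], int] = {}
    nodes: set[str] = set()
    for g in ensemble:
        nodes |= set(g.nodes)
        for u, v in g.edges:
            counts[(u, v)] = counts.get((u, v), 0) + 1
    m = len(ensemble)
    g = nx.DiGraph()
    g.add_nodes_from(sorted(nodes))
    for (u, v), c in counts.items():
        if c / m > freq_thresh:
            g.add_edge(u, v, frequency=c / m)
    return ConsensusDag(graph=g)


def deloop(consensus: ConsensusDag) -> ConsensusDag:
    """Iteratively remove the weakest-supported edge on any directed cycle.

    An edge lies on a cycle iff both endpoints are in the same nontrivial
    strongly connected component.  Ties on frequency break lexicographically
    by (source, target).  Removals are logged.
    """
    g = consensus.graph.copy()
    while True:
        sccs = [c for c in nx.strongly_connected_components(g) if len(c) > 1]
        cyclic_edges = [
            (u, v)
            for c in sccs
            for u, v in g.edges(c)
            if u in c and v in c
        ]
        cyclic_edges += [(u, v) for u, v in nx.selfloop_edges(g)]
        if not cyclic_edges:
            break
        u, v = min(cyclic_edges, key=lambda e: (g[e[0]][e[1]]["frequency"], e))
        logger.info("deloop: removing %s -> %s (freq %.3f)", u, v,
                    g[u][v]["frequency"])
        g.remove_edge(u, v)
    return ConsensusDag(graph=g)


def downstream_neighborhood(dag: nx.DiGraph, node: str, h: int) -> set[str]:
    """Nodes reachable from ``node`` in at most ``h`` directed steps."""
    if h < 0:
        raise ValueError("h must be >= 0")
    if node not in dag:
        raise KeyError(f"node {node!r} not in graph")
    reached = nx.single_source_shortest_path_length(dag, node, cutoff=h)
    return {n for n, d in reached.items() if n != node}


def key_driver_analysis(
    dag: nx.DiGraph | ConsensusDag,
    signature: set[str],
    h: int = 2,
    min_neighborhood: int = 10,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Key driver analysis on a directed network.

    Every node whose downstream neighborhood (within ``h`` steps) has at
    least ``min_neighborhood`` members is a candidate; each neighborhood is
    tested for enrichment of the signature against all network nodes, BH
    across candidates.  Key drivers have adjusted p < alpha, ranked by
    ascending adjusted p then descending fold enrichment.  The returned
    frame contains all candidates with a ``key_driver`` flag.
    """
    if not signature:
        raise ValueError("empty signature")
    g = dag.graph if isinstance(dag, ConsensusDag) else dag
    background = set(g.nodes)
    sig = signature & background
    recs, meta = [], []
    for node in sorted(g.nodes):
        nb = downstream_neighborhood(g, node, h)
        if len(nb) < min_neighborhood:
            continue
        recs.append(hypergeometric_enrichment(nb, sig, background,
                                              module_id=node))
        meta.append((node, len(nb), len(nb & sig)))
    recs = adjust_enrichments(recs)
    df = pd.DataFrame(
        {
            "node": [m[0] for m in meta],
            "h": h,
            "n_neighborhood": [m[1] for m in meta],
            "overlap": [m[2] for m in meta],
            "fold_enrichment": [r.fold_enrichment for r in recs],
            "p": [r.p for r in recs],
            "adj_p": [r.adj_p for r in recs],
        }
    )
    df = df.sort_values(["adj_p", "fold_enrichment", "node"],
                        ascending=[True, False, True], kind="stable")
    df["rank"] = np.arange(1, len(df) + 1)
    df["key_driver"] = df["adj_p"] < alpha
    return df.reset_index(drop=True)
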