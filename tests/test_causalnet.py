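"""Causal network stage: eQTLs, CIT, MCMC DAG search, consensus, KDA."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from proteoscale.causalnet import (
    CitResult,
    ConsensusDag,
    PriorSet,
    assemble_priors,
    cit_test,
    compute_eqtls,
    consensus_network,
    deloop,
    downstream_neighborhood,
    key_driver_analysis,
    mcmc_structure_search,
    sample_ensemble,
)


# ---------------------------------------------------------------- eQTLs

def _eqtl_data(rng, n=60, beta=1.2):
    g = rng.binomial(2, 0.4, n).astype(float)
    geno = pd.DataFrame([g], index=["rs1"], columns=[f"s{i}" for i in range(n)])
    X = rng.normal(size=(4, n))
    X[0] += beta * g
    expr = pd.DataFrame(X, index=[f"f{i}" for i in range(4)],
                        columns=geno.columns)
    return geno, expr


def test_eqtl_matches_linregress(rng):
    geno, expr = _eqtl_data(rng)
    out = compute_eqtls(geno, expr).set_index("feature")
    for f in expr.index:
        ref = stats.linregress(geno.loc["rs1"], expr.loc[f])
        assert abs(out.loc[f, "beta"] - ref.slope) < 1e-10
        assert abs(out.loc[f, "p"] - ref.pvalue) < 1e-10
    assert bool(out.loc["f0", "significant"])


def test_eqtl_skips_monomorphic(rng, caplog):
    geno, expr = _eqtl_data(rng)
    geno.loc["rs_mono"] = 0.0
    with caplog.at_level("WARNING"):
        out = compute_eqtls(geno, expr)
    assert "rs_mono" in caplog.text
    assert set(out["snp"]) == {"rs1"}


def test_eqtl_too_few_samples(rng):
    geno, expr = _eqtl_data(rng)
    with pytest.raises(ValueError):
        compute_eqtls(geno.iloc[:, :3], expr.iloc[:, :3])


# ---------------------------------------------------------------- CIT

def _chain(rng, n=300, beta=1.0, noise=0.5):
    L = rng.binomial(2, 0.3, n).astype(float)
    A = beta * L + noise * rng.normal(size=n)
    B = A + noise * rng.normal(size=n)
    return L, A, B


def test_cit_orients_a_causes_b(rng):
    L, A, B = _chain(rng)
    res = cit_test(L, A, B)
    assert res.direction == "A->B"
    assert res.omnibus_p == max(res.p_components)
    assert res.omnibus_p < 0.05


def test_cit_reversed_arguments_flip_direction(rng):
    L, A, B = _chain(rng)
    res = cit_test(L, B, A)
    assert res.direction == "B->A"


def test_cit_independent_features_undecided(rng):
    n = 300
    L = rng.binomial(2, 0.3, n).astype(float)
    A = L + 0.5 * rng.normal(size=n)
    B = rng.normal(size=n)  # unrelated to L and A
    res = cit_test(L, A, B)
    assert res.direction == "undecided"


def test_cit_identical_vectors_rejected(rng):
    L, A, _ = _chain(rng)
    with pytest.raises(ValueError):
        cit_test(L, A, A.copy())


# ---------------------------------------------------------------- priors

def test_assemble_priors_forbids_reverse_edges():
    results = [
        CitResult("rs1", "x", "y", (0.01,) * 4, 0.01, "A->B"),
        CitResult("rs1", "y", "z", (0.01,) * 4, 0.01, "B->A"),
        CitResult("rs2", "p", "q", (0.5,) * 4, 0.5, "undecided"),
    ]
    priors = assemble_priors(results, tf_targets=[("tf1", "x")])
    assert priors.forbidden == {("y", "x"), ("y", "z")}
    assert priors.bonus == {("tf1", "x"): 1.0}


def test_assemble_priors_drops_conflicts(caplog):
    results = [
        CitResult("rs1", "x", "y", (0.01,) * 4, 0.01, "A->B"),
        CitResult("rs2", "x", "y", (0.01,) * 4, 0.01, "B->A"),
    ]
    with caplog.at_level("WARNING"):
        priors = assemble_priors(results)
    assert "conflicting" in caplog.text
    assert priors.forbidden == set()


# ---------------------------------------------------------------- MCMC

def _chain_matrix(rng, n=200):
    x = rng.normal(size=n)
    y = x + 0.5 * rng.normal(size=n)
    z = y + 0.5 * rng.normal(size=n)
    w = rng.normal(size=n)
    return pd.DataFrame([x, y, z, w], index=["x", "y", "z", "w"],
                        columns=[f"s{i}" for i in range(n)])


def test_mcmc_output_is_acyclic_and_deterministic(rng):
    m = _chain_matrix(rng)
    g1 = mcmc_structure_search(m, n_iter=1500, seed=4)
    g2 = mcmc_structure_search(m, n_iter=1500, seed=4)
    assert nx.is_directed_acyclic_graph(g1)
    assert sorted(g1.edges) == sorted(g2.edges)


def test_mcmc_recovers_planted_adjacencies(rng):
    m = _chain_matrix(rng)
    ensemble = sample_ensemble(m, n_networks=20, n_iter=2000, seed=0)
    cons = consensus_network(ensemble, freq_thresh=0.3)
    und = {frozenset(e) for e in cons.graph.edges}
    assert frozenset(("x", "y")) in und
    assert frozenset(("y", "z")) in und
    # the isolated node picks up no consensus edge
    assert not any("w" in e for e in und)


def test_mcmc_respects_hard_constraints(rng):
    m = _chain_matrix(rng)
    priors = PriorSet(forbidden={("y", "x"), ("x", "y")})
    for i in range(5):
        g = mcmc_structure_search(m, priors, n_iter=1500, seed=i)
        assert ("y", "x") not in g.edges and ("x", "y") not in g.edges


def test_mcmc_max_parents_and_validation(rng):
    m = _chain_matrix(rng)
    g = mcmc_structure_search(m, max_parents=1, n_iter=1500, seed=0)
    assert max((g.in_degree(n) for n in g), default=0) <= 1
    with pytest.raises(ValueError):
        mcmc_structure_search(m, n_iter=0)
    with pytest.raises(ValueError):
        mcmc_structure_search(m, max_features=2)


def test_mcmc_sparsity_on_null_data(rng):
    m = pd.DataFrame(rng.normal(size=(10, 150)),
                     index=[f"f{i}" for i in range(10)],
                     columns=[f"s{i}" for i in range(150)])
    ensemble = sample_ensemble(m, n_networks=10, n_iter=1500, seed=0)
    mean_edges = np.mean([g.number_of_edges() for g in ensemble])
    # independent features: far below the 90 possible edges
    assert mean_edges < 0.05 * 90


# ---------------------------------------------------------------- consensus

def _graph(edges):
    g = nx.DiGraph()
    g.add_nodes_from("abc")
    g.add_edges_from(edges)
    return g


def test_consensus_threshold_is_strict():
    ensemble = [_graph([("a", "b")])] * 3 + [_graph([])] * 7
    cons = consensus_network(ensemble, freq_thresh=0.3)
    assert ("a", "b") not in cons.graph.edges  # 0.3 is not > 0.3
    cons2 = consensus_network(ensemble + [_graph([("a", "b")])] * 1,
                              freq_thresh=0.3)
    # 4/11 > 0.3
    assert ("a", "b") in cons2.graph.edges
    assert abs(cons2.graph["a"]["b"]["frequency"] - 4 / 11) < 1e-12
    with pytest.raises(ValueError):
        consensus_network([])


def test_deloop_removes_weakest_cycle_edge():
    g = nx.DiGraph()
    g.add_edge("a", "b", frequency=0.9)
    g.add_edge("b", "a", frequency=0.4)
    g.add_edge("b", "c", frequency=0.5)
    out = deloop(ConsensusDag(graph=g))
    assert out.is_acyclic()
    assert ("a", "b") in out.graph.edges and ("b", "a") not in out.graph.edges
    assert ("b", "c") in out.graph.edges  # off-cycle edges untouched


def test_deloop_handles_multiple_cycles_and_ties():
    g = nx.DiGraph()
    for u, v in [("a", "b"), ("b", "a"), ("c", "d"), ("d", "c")]:
        g.add_edge(u, v, frequency=0.5)
    out = deloop(ConsensusDag(graph=g))
    assert out.is_acyclic()
    # lexicographic tie-break removes (a,b) and (c,d)
    assert set(out.graph.edges) == {("b", "a"), ("d", "c")}


def test_deloop_acyclic_input_is_identity():
    g = nx.DiGraph()
    g.add_edge("a", "b", frequency=0.7)
    out = deloop(ConsensusDag(graph=g))
    assert set(out.graph.edges) == {("a", "b")}


# ---------------------------------------------------------------- KDA

def _random_dag(rng, n=25, p=0.15):
    g = nx.DiGraph()
    g.add_nodes_from(f"n{i}" for i in range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                g.add_edge(f"n{i}", f"n{j}")
    return g


def test_downstream_neighborhood_matches_bfs_oracle(rng):
    g = _random_dag(rng)
    for h in (1, 2, 3):
        for node in list(g.nodes)[:10]:
            got = downstream_neighborhood(g, node, h)
            # oracle: layer-by-layer breadth-first expansion
            frontier, seen = {node}, {node}
            for _ in range(h):
                frontier = {w for v in frontier for w in g.successors(v)} - seen
                seen |= frontier
            assert got == seen - {node}


def test_downstream_neighborhood_edges():
    g = nx.DiGraph([("a", "b"), ("b", "c")])
    assert downstream_neighborhood(g, "a", 0) == set()
    assert downstream_neighborhood(g, "a", 1) == {"b"}
    assert downstream_neighborhood(g, "a", 5) == {"b", "c"}
    with pytest.raises(ValueError):
        downstream_neighborhood(g, "a", -1)
    with pytest.raises(KeyError):
        downstream_neighborhood(g, "zz", 1)


def _driver_dag():
    g = nx.DiGraph()
    mids = [f"m{i}" for i in range(4)]
    sig = [f"t{i}" for i in range(12)]
    for m in mids:
        g.add_edge("drv", m)
    for i, t in enumerate(sig):
        g.add_edge(mids[i % 4], t)
    # decoy with a large but signature-free neighborhood
    for i in range(12):
        g.add_edge("decoy", f"d{i}")
    return g, set(sig)


def test_kda_finds_planted_driver():
    g, sig = _driver_dag()
    out = key_driver_analysis(g, sig, h=2, min_neighborhood=10)
    assert out.iloc[0]["node"] == "drv"
    assert bool(out.iloc[0]["key_driver"])
    decoy = out[out["node"] == "decoy"].iloc[0]
    assert not bool(decoy["key_driver"])


def test_kda_sinks_are_not_candidates():
    g, sig = _driver_dag()
    out = key_driver_analysis(g, sig, h=2, min_neighborhood=10)
    assert not (set(out["node"]) & sig)  # targets have empty neighborhoods


def test_kda_validation_and_consensus_wrapper():
    g, sig = _driver_dag()
    for u, v in g.edges:
        g[u][v]["frequency"] = 1.0
    out = key_driver_analysis(ConsensusDag(graph=g), sig, h=2,
                              min_neighborhood=10)
    assert out.iloc[0]["node"] == "drv"
    with pytest.raises(ValueError):
        key_driver_analysis(g, set())
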