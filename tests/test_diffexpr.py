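"""Differential expression: stratification, moderated t, BH, consensus."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from proteoscale.diffexpr import (
    benjamini_hochberg,
    call_deps,
    concordance_classify,
    consensus_signature,
    fit_moderation,
    map_isoforms_to_genes,
    moderated_ttest,
    sex_stratified_stability,
    stratify_samples,
    trait_correlation,
)


# ---------------------------------------------------------------- stratification

def _meta(**cols):
    n = len(next(iter(cols.values())))
    return pd.DataFrame(cols, index=[f"s{i}" for i in range(n)])


def test_braak_boundaries():
    g = stratify_samples(_meta(Braak=[0, 2, 3, 4, 5, 6]), "Braak")
    assert list(g.labels) == ["Low", "Low", "Medium", "Medium", "High", "High"]
    assert g.extreme_contrast == ("High", "Low")


def test_cdr_boundaries():
    g = stratify_samples(_meta(CDR=[0, 0.5, 2, 3, 5]), "CDR")
    assert list(g.labels) == ["Nondemented", "Impaired", "Impaired",
                              "Demented", "Demented"]


def test_plaque_boundaries():
    g = stratify_samples(_meta(PlaqueMean=[0.0, 0.1, 9.0, 9.1]), "PlaqueMean")
    assert list(g.labels) == ["Normal", "Mild", "Mild", "Severe"]


def test_mmse_boundaries():
    g = stratify_samples(_meta(MMSE=[30, 24, 23, 18, 17, 5]), "MMSE")
    assert list(g.labels) == ["Nondemented", "Nondemented", "Impaired",
                              "Impaired", "Demented", "Demented"]


def test_cerad_codings_differ():
    meta = _meta(CERAD=[1, 2, 3, 4])
    msbb = stratify_samples(meta, "CERAD", "msbb")
    rosmap = stratify_samples(meta, "CERAD", "rosmap")
    assert list(msbb.labels) == ["NL", "DefiniteAD", "IndefiniteAD",
                                 "IndefiniteAD"]
    assert list(rosmap.labels) == ["DefiniteAD", "IndefiniteAD",
                                   "IndefiniteAD", "NL"]


def test_stratify_errors():
    with pytest.raises(ValueError):
        stratify_samples(_meta(Braak=[-1, 2]), "Braak")
    with pytest.raises(ValueError):
        stratify_samples(_meta(Other=[1]), "Other")
    with pytest.raises(ValueError):
        stratify_samples(_meta(CERAD=[5]), "CERAD")


def test_stratify_drops_missing_values():
    g = stratify_samples(_meta(Braak=[1, np.nan, 6]), "Braak")
    assert list(g.labels.index) == ["s0", "s2"]


# ---------------------------------------------------------------- moderated t

def _two_group_matrix(rng, n_feat=40, na=8, nb=8):
    cols = [f"a{i}" for i in range(na)] + [f"b{i}" for i in range(nb)]
    m = pd.DataFrame(rng.normal(size=(n_feat, na + nb)),
                     index=[f"f{i}" for i in range(n_feat)], columns=cols)
    return m, cols[:na], cols[na:]


def test_d0_zero_recovers_pooled_t(rng):
    m, ga, gb = _two_group_matrix(rng)
    res, params = moderated_ttest(m, ga, gb, d0_override=0.0)
    t_ref, p_ref = stats.ttest_ind(m[ga], m[gb], axis=1, equal_var=True)
    assert np.allclose(res["t"], t_ref, atol=1e-10)
    assert np.allclose(res["p"], p_ref, atol=1e-10)
    assert params.d0 == 0.0


def test_moderation_shrinks_toward_prior(rng):
    m, ga, gb = _two_group_matrix(rng, n_feat=200)
    # inflate a few features' variance so the spread of log s^2 is real
    m.iloc[:10] *= 4
    res, params = moderated_ttest(m, ga, gb)
    assert 0 < params.d0 < np.inf
    # moderated |t| of the noisy features exceeds the pooled |t| because
    # their variances are shrunk toward the (smaller) prior
    pooled, _ = stats.ttest_ind(m[ga], m[gb], axis=1, equal_var=True)
    assert np.abs(res["t"].iloc[:10]).mean() > np.abs(pooled[:10]).mean()


def test_fit_moderation_infinite_d0_for_constant_variance():
    from scipy import special

    params = fit_moderation(np.full(50, 2.0), d=10)
    assert np.isinf(params.d0)
    # the prior variance corrects the chi-square bias of log s^2:
    # s0^2 = exp(mean(log s^2) - digamma(d/2) + log(d/2))
    expect = 2.0 * np.exp(np.log(5) - special.digamma(5))
    assert abs(params.s0_sq - expect) < 1e-9


def test_moderated_ttest_fc_columns(rng):
    m, ga, gb = _two_group_matrix(rng, n_feat=5)
    m.loc["f0", ga] += 1.0
    res, _ = moderated_ttest(m, ga, gb)
    assert np.allclose(res["fc"], 2.0 ** res["log2_fc"])
    assert res.loc["f0", "direction"] == "up"


def test_moderated_ttest_validation(rng):
    m, ga, gb = _two_group_matrix(rng, n_feat=3)
    with pytest.raises(ValueError):
        moderated_ttest(m, ga, ga[:4])
    with pytest.raises(ValueError):
        moderated_ttest(m, ga[:1], gb)


# ---------------------------------------------------------------- BH

def test_bh_hand_worked_example():
    # step-up on (0.01, 0.02, 0.03): 0.03*3/3=0.03; 0.02*3/2=0.03; 0.01*3=0.03
    assert np.allclose(benjamini_hochberg([0.01, 0.02, 0.03]),
                       [0.03, 0.03, 0.03])


def test_bh_matches_statsmodels(rng):
    p = rng.uniform(size=200)
    ours = benjamini_hochberg(p)
    _, ref, _, _ = multipletests(p, method="fdr_bh")
    assert np.allclose(ours, ref)


def test_bh_nan_handling():
    out = benjamini_hochberg([0.01, np.nan, 0.04])
    assert np.isnan(out[1])
    # NaN does not count toward m: equivalent to BH on the two finite values
    assert np.allclose(out[[0, 2]], benjamini_hochberg([0.01, 0.04]))


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        benjamini_hochberg([0.5, 1.2])


@settings(max_examples=50, derandomize=True, deadline=None)
@given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=60),
       st.randoms(use_true_random=False))
def test_bh_properties(pvals, rnd):
    p = np.asarray(pvals)
    adj = benjamini_hochberg(p)
    # bounds and domination of the raw p-value ordering
    assert ((adj >= p - 1e-12) & (adj <= 1 + 1e-12)).all()
    # permutation equivariance
    perm = list(range(len(p)))
    rnd.shuffle(perm)
    assert np.allclose(benjamini_hochberg(p[perm]), adj[perm])


# ---------------------------------------------------------------- calling

def _fake_result():
    return pd.DataFrame(
        {
            "fc": [1.5, 1.05, 0.5, 0.95, 1.3],
            "p": [0.001, 0.001, 0.001, 0.001, 0.2],
            "adj_p": [0.01, 0.01, 0.01, 0.01, 0.4],
        },
        index=list("abcde"),
    )


def test_call_deps_fc_gate():
    up, down = call_deps(_fake_result(), fc_thresh=1.1, fdr_thresh=0.05)
    assert up == {"a"} and down == {"c"}


def test_call_deps_no_fc_gate():
    up, down = call_deps(_fake_result(), fc_thresh=None)
    assert up == {"a", "b"} and down == {"c", "d"}


def test_call_deps_raw_p_mode():
    res = _fake_result()
    res.loc["e", "p"] = 0.01  # raw-significant, adjusted-not
    up, _ = call_deps(res, fc_thresh=1.1, p_mode="raw")
    assert "e" in up


def test_call_deps_presets_and_errors():
    up, down = call_deps(_fake_result(), preset="msbb-protein")
    assert up == {"a"} and down == {"c"}
    with pytest.raises(ValueError):
        call_deps(_fake_result(), preset="nope")
    with pytest.raises(ValueError):
        call_deps(_fake_result(), fc_thresh=0.9)
    with pytest.raises(ValueError):
        call_deps(_fake_result(), p_mode="bonferroni")


# ---------------------------------------------------------------- consensus

def test_consensus_majority_tie_and_rep_p():
    comps = [
        ({"x"}, set(), {"x": 0.01, "y": 0.2, "z": 0.03}),
        ({"x"}, {"y"}, {"x": 0.005, "y": 0.04, "z": 0.5}),
        (set(), {"y", "z"}, {"x": 0.3, "y": 0.02, "z": 0.01}),
        ({"z"}, set(), {"x": 0.9, "y": 0.9, "z": 0.02}),
    ]
    cs = consensus_signature(comps)
    assert cs.loc["x", "direction"] == "up"
    assert cs.loc["x", "rep_p"] == 0.005
    assert cs.loc["y", "direction"] == "down"
    assert cs.loc["z", "direction"] == "none"  # 1 up vs 1 down: tie
    assert np.isnan(cs.loc["z", "rep_p"])


def test_consensus_order_invariance():
    comps = [
        ({"x"}, set(), {"x": 0.01}),
        (set(), {"x"}, {"x": 0.02}),
        ({"x"}, set(), {"x": 0.03}),
    ]
    a = consensus_signature(comps)
    b = consensus_signature(comps[::-1])
    pd.testing.assert_frame_equal(a, b)


def test_consensus_errors():
    with pytest.raises(ValueError):
        consensus_signature([])
    with pytest.raises(ValueError):
        consensus_signature([({"x"}, set(), {"x": 0.1})], universe=["x", "w"])


# ---------------------------------------------------------------- stability

def test_stability_full_size_matches_single_call(rng):
    m, ga, gb = _two_group_matrix(rng, n_feat=60, na=10, nb=10)
    m.loc[["f0", "f1"], ga] += 2.0
    res, _ = moderated_ttest(m, ga, gb)
    up_ref, down_ref = call_deps(res, fc_thresh=None)
    up, down, freq = sex_stratified_stability(
        m, ga, gb, n_case=10, n_control=10, n_iter=3, fc_thresh=None,
        freq_thresh=0.8, seed=1,
    )
    # full-size "down-sampling" is the plain comparison every iteration
    assert up == up_ref and down == down_ref
    assert (freq.loc[sorted(up), "up_freq"] == 1.0).all()


def test_stability_determinism_and_validation(rng):
    m, ga, gb = _two_group_matrix(rng, n_feat=30, na=8, nb=8)
    m.loc["f0", ga] += 2.5
    r1 = sex_stratified_stability(m, ga, gb, 5, 5, n_iter=4, seed=3,
                                  fc_thresh=None)
    r2 = sex_stratified_stability(m, ga, gb, 5, 5, n_iter=4, seed=3,
                                  fc_thresh=None)
    assert r1[0] == r2[0] and r1[1] == r2[1]
    pd.testing.assert_frame_equal(r1[2], r2[2])
    with pytest.raises(ValueError):
        sex_stratified_stability(m, ga, gb, 50, 5, n_iter=1)
    with pytest.raises(ValueError):
        sex_stratified_stability(m, ga, gb, 5, 5, n_iter=0)


# ---------------------------------------------------------------- mapping

def test_map_isoforms_to_genes():
    out = map_isoforms_to_genes(["G1.1", "G1.2", "G2", "UBA52", "P.x"])
    assert out == {"G1.1": "G1", "G1.2": "G1", "G2": "G2",
                   "UBA52": "UBA52", "P.x": "P.x"}


def test_concordance_counts_and_hypergeom():
    prot = pd.DataFrame({"direction": ["up", "up", "down", "none"]},
                        index=["g1", "g2", "g3", "g4"])
    gene = pd.DataFrame({"direction": ["up", "down", "down", "none"]},
                        index=["g1", "g2", "g3", "g4"])
    counts, pvals = concordance_classify(prot, gene)
    assert counts.to_numpy().sum() == 4
    assert counts.loc["up", "up"] == 1
    assert counts.loc["down", "down"] == 1
    # cell (down, down): overlap 1 of prot-down 1, gene-down 2, universe 4
    expect = stats.hypergeom.sf(0, 4, 1, 2)
    assert abs(pvals.loc["down", "down"] - expect) < 1e-12


def test_concordance_empty_universe():
    a = pd.DataFrame({"direction": ["up"]}, index=["g1"])
    b = pd.DataFrame({"direction": ["up"]}, index=["g2"])
    with pytest.raises(ValueError):
        concordance_classify(a, b)


# ---------------------------------------------------------------- correlations

def test_trait_correlation_spearman_is_pearson_on_ranks(rng):
    m = pd.DataFrame(rng.normal(size=(6, 30)),
                     index=[f"f{i}" for i in range(6)],
                     columns=[f"s{i}" for i in range(30)])
    tv = pd.Series(rng.normal(size=30), index=m.columns)
    out = trait_correlation(m, tv, method="spearman")
    for f in m.index:
        r_ref, p_ref = stats.pearsonr(stats.rankdata(m.loc[f]),
                                      stats.rankdata(tv))
        assert abs(out.loc[f, "rho"] - r_ref) < 1e-10
        assert abs(out.loc[f, "p"] - p_ref) < 1e-8


def test_trait_correlation_degenerate_features(rng):
    m = pd.DataFrame([[1.0] * 10, list(range(10))], index=["const", "ok"],
                     columns=[f"s{i}" for i in range(10)])
    tv = pd.Series(np.arange(10.0), index=m.columns)
    out = trait_correlation(m, tv)
    assert bool(out.loc["const", "degenerate"])
    assert not bool(out.loc["ok", "degenerate"])
    with pytest.raises(ValueError):
        trait_correlation(m, tv, method="kendall")
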