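"""Trait-stratified differential expression.

Implements the differential-abundance machinery of the pipeline: three-level
trait stratification (low / medium / high disease severity per clinical
axis), an empirical-Bayes moderated t-test with variance shrinkage,
threshold-based DEP/DEG calling with per-cohort presets, Benjamini-Hochberg
FDR control, consensus signatures aggregated across traits, sex-stratified
down-sampling stability selection, protein-vs-gene concordance tables, and
per-feature trait correlations.

The moderated test shrinks each feature's pooled variance s^2 toward a prior
s0^2 with prior degrees of freedom d0 fit by matching the marginal moments
of log s^2 across features; the shrunken statistic is referred to a t
distribution with d0 + d degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "StratifiedGroups",
    "ModerationParams",
    "DEP_PRESETS",
    "stratify_samples",
    "moderated_ttest",
    "benjamini_hochberg",
    "call_deps",
    "consensus_signature",
    "sex_stratified_stability",
    "concordance_classify",
    "trait_correlation",
    "map_isoforms_to_genes",
]


@dataclass
class StratifiedGroups:
    """Sample-to-severity-level assignment for one clinical trait.

    ``levels`` is ordered from least to most severe; the extreme-vs-reference
    contrast is (levels[-1], levels[0]).
    """

    trait: str
    labels: pd.Series  # sample -> level name
    levels: tuple[str, ...]

    def samples(self, level: str) -> list[str]:
        return list(self.labels.index[self.labels == level])

    @property
    def extreme_contrast(self) -> tuple[str, str]:
        return self.levels[-1], self.levels[0]


@dataclass(frozen=True)
class ModerationParams:
    """Empirical-Bayes hyperparameters: prior df d0 and prior variance s0^2."""

    d0: float
    s0_sq: float


# (fc_thresh or None, fdr_thresh, p_mode)
DEP_PRESETS: dict[str, tuple[float | None, float, str]] = {
    "msbb-protein": (1.1, 0.05, "adjusted"),
    "msbb-gene": (1.2, 0.05, "adjusted"),
    "rosmap": (None, 0.05, "adjusted"),
    "blsa": (None, 0.05, "adjusted"),
    "ahnak-kd": (1.1, 0.05, "raw"),
    "5xfad-relaxed": (None, 0.05, "raw"),
}


def _braak(v: float) -> str:
    if v <= 2:
        return "Low"
    if v <= 4:
        return "Medium"
    return "High"


def _cdr(v: float) -> str:
    if v == 0:
        return "Nondemented"
    if v <= 2:
        return "Impaired"
    return "Demented"


def _plaque(v: float) -> str:
    if v == 0:
        return "Normal"
    if v <= 9:
        return "Mild"
    return "Severe"


def _mmse(v: float) -> str:
    if v > 23:
        return "Nondemented"
    if v > 17:
        return "Impaired"
    return "Demented"


def _cerad_msbb(v: float) -> str:
    if v == 1:
        return "NL"
    if v == 2:
        return "DefiniteAD"
    if v in (3, 4):
        return "IndefiniteAD"
    raise ValueError(f"CERAD (MSBB coding) value out of range: {v}")


def _cerad_rosmap(v: float) -> str:
    if v == 4:
        return "NL"
    if v == 1:
        return "DefiniteAD"
    if v in (2, 3):
        return "IndefiniteAD"
    raise ValueError(f"CERAD (ROSMAP coding) value out of range: {v}")


_STRATA = {
    "Braak": (_braak, ("Low", "Medium", "High")),
    "CDR": (_cdr, ("Nondemented", "Impaired", "Demented")),
    "PlaqueMean": (_plaque, ("Normal", "Mild", "Severe")),
    "MMSE": (_mmse, ("Nondemented", "Impaired", "Demented")),
}


def stratify_samples(
    metadata: pd.DataFrame, trait: str, cerad_coding: str = "msbb"
) -> StratifiedGroups:
    """Assign each sample with a non-missing trait value to a severity level.

    Braak: Low <=2 < Medium <=4 < High.  CDR: Nondemented = 0,
    Impaired (0, 2], Demented > 2.  Plaque mean: Normal = 0, Mild (0, 9],
    Severe > 9.  MMSE: Nondemented > 23, Impaired (17, 23], Demented <= 17.
    CERAD uses cohort-specific codings (MSBB: definite = 2, NL = 1;
    ROSMAP: definite = 1, NL = 4).
    """
    if trait == "CERAD":
        fn = _cerad_msbb if cerad_coding == "msbb" else _cerad_rosmap
        levels = ("NL", "IndefiniteAD", "DefiniteAD")
    elif trait in _STRATA:
        fn, levels = _STRATA[trait]
    else:
        raise ValueError(f"unknown trait: {trait}")
    vals = metadata[trait].dropna()
    out_of_range = vals[(vals < 0)]
    if len(out_of_range):
        raise ValueError(f"negative {trait} values: {list(out_of_range.index[:3])}")
    labels = vals.apply(fn)
    return StratifiedGroups(trait=trait, labels=labels, levels=levels)


def _trigamma_inverse(y: float) -> float:
    # Newton iterations on trigamma(x) = y (monotone decreasing)
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_moderation(s_sq: np.ndarray, d: float) -> ModerationParams:
    """Fit (d0, s0^2) by matching the moments of log s^2.

    Zero-variance features are excluded from the fit.  If the observed
    spread of log s^2 is no larger than the sampling spread, d0 is infinite
    and all features share the prior variance.
    """
    s = s_sq[s_sq > 0]
    if len(s) < 2:
        return ModerationParams(d0=np.inf, s0_sq=float(s.mean()) if len(s) else 1.0)
    z = np.log(s)
    e = z - special.digamma(d / 2) + np.log(d / 2)
    evar = np.var(e, ddof=1) - special.polygamma(1, d / 2)
    if evar > 0:
        d0 = 2 * _trigamma_inverse(evar)
        s0 = np.exp(e.mean() + special.digamma(d0 / 2) - np.log(d0 / 2))
    else:
        d0, s0 = np.inf, np.exp(e.mean())
    return ModerationParams(d0=float(d0), s0_sq=float(s0))


def moderated_ttest(
    matrix: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    d0_override: float | None = None,
) -> tuple[pd.DataFrame, ModerationParams]:
    """Moderated two-sample t-test of group A vs group B per feature.

    Fold change is reported as 2**(mean_A - mean_B) (expression is on the
    log2 scale).  ``d0_override = 0`` recovers the ordinary pooled t-test.
    Returns (result table, moderation parameters); the table has columns
    log2_fc, fc, t, p, adj_p, direction.
    """
    ga, gb = list(group_a), list(group_b)
    if set(ga) & set(gb):
        raise ValueError("groups overlap")
    if len(ga) < 2 or len(gb) < 2:
        raise ValueError("each group needs at least 2 samples")
    A = matrix[ga].to_numpy(dtype=float)
    B = matrix[gb].to_numpy(dtype=float)
    na, nb = A.shape[1], B.shape[1]
    ma, mb = A.mean(axis=1), B.mean(axis=1)
    ssq = (((A - ma[:, None]) ** 2).sum(axis=1) + ((B - mb[:, None]) ** 2).sum(axis=1))
    d = na + nb - 2
    s_sq = ssq / d
    if d0_override is not None:
        params = ModerationParams(
            d0=float(d0_override),
            s0_sq=float(np.mean(s_sq[s_sq > 0])) if (s_sq > 0).any() else 1.0,
        )
    else:
        params = fit_moderation(s_sq, d)
    d0, s0 = params.d0, params.s0_sq
    if np.isinf(d0):
        s_tilde = np.full_like(s_sq, s0)
        df = np.inf
    else:
        s_tilde = (d0 * s0 + d * s_sq) / (d0 + d)
        df = d0 + d
    diff = ma - mb
    se = np.sqrt(s_tilde * (1 / na + 1 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / se, 0.0)
    if np.isinf(df):
        p = 2 * stats.norm.sf(np.abs(t))
    else:
        p = 2 * stats.t.sf(np.abs(t), df)
    p = np.where((diff == 0), 1.0, p)
    t = np.where(diff == 0, 0.0, t)
    res = pd.DataFrame(
        {
            "log2_fc": diff,
            "fc": 2.0**diff,
            "t": t,
            "p": p,
            "adj_p": benjamini_hochberg(p),
            "direction": np.where(diff > 0, "up", np.where(diff < 0, "down", "none")),
        },
        index=matrix.index,
    )
    return res, params


def benjamini_hochberg(p: np.ndarray | pd.Series | list[float]) -> np.ndarray:
    """Step-up BH-adjusted p-values, monotone, capped at 1, input order kept.

    NaN entries (e.g. from constant features) stay NaN and do not count
    toward the number of tests.
    """
    arr = np.asarray(p, dtype=float)
    out = np.full(arr.shape, np.nan)
    ok = ~np.isnan(arr)
    vals = arr[ok]
    if ((vals < 0) | (vals > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(vals)
    if m == 0:
        return out
    order = np.argsort(vals, kind="stable")
    ranked = vals[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    res = np.empty(m)
    res[order] = adj
    out[ok] = res
    return out


def call_deps(
    result: pd.DataFrame,
    fc_thresh: float | None = 1.1,
    fdr_thresh: float = 0.05,
    p_mode: str = "adjusted",
    preset: str | None = None,
) -> tuple[set[str], set[str]]:
    """Call (up, down) differential features from a moderated-t table.

    ``fc_thresh`` gates on fold change (> fc_thresh up, < 1/fc_thresh down);
    ``None`` disables the gate.  ``p_mode`` selects adjusted or raw p.
    Named presets cover the cohort-specific rules (e.g. ``msbb-protein``:
    FC 1.1 with FDR < 0.05; ``ahnak-kd``: FC 1.1 with raw p < 0.05).
    """
    if preset is not None:
        if preset not in DEP_PRESETS:
            raise ValueError(f"unknown preset: {preset}")
        fc_thresh, fdr_thresh, p_mode = DEP_PRESETS[preset]
    if fc_thresh is not None and fc_thresh <= 1:
        raise ValueError("fc_thresh must exceed 1")
    if p_mode not in ("adjusted", "raw"):
        raise ValueError("p_mode must be 'adjusted' or 'raw'")
    pcol = result["adj_p"] if p_mode == "adjusted" else result["p"]
    sig = pcol < fdr_thresh
    fc = result["fc"]
    if fc_thresh is None:
        up = sig & (fc > 1)
        down = sig & (fc < 1)
    else:
        up = sig & (fc > fc_thresh)
        down = sig & (fc < 1 / fc_thresh)
    return set(result.index[up.fillna(False)]), set(result.index[down.fillna(False)])


def consensus_signature(
    comparisons: list[tuple[set[str], set[str], dict[str, float]]],
    universe: list[str] | None = None,
) -> pd.DataFrame:
    """Aggregate per-trait DEP calls into a consensus up/down/none signature.

    A feature more frequently up- than down-regulated across the
    extreme-vs-reference comparisons is consensus-up (and vice versa); exact
    ties with at least one call are 'none'.  The representative p-value is
    the smallest p among comparisons agreeing with the consensus direction.
    """
    if not comparisons:
        raise ValueError("need at least one comparison")
    feats: set[str] = set(universe) if universe is not None else set()
    if universe is None:
        for up, down, pmap in comparisons:
            feats |= set(pmap)
    rows = []
    for f in sorted(feats):
        in_any = any(f in pmap for _, _, pmap in comparisons)
        if not in_any:
            raise ValueError(f"feature {f} absent from all comparisons")
        n_up = sum(f in up for up, _, _ in comparisons)
        n_down = sum(f in down for _, down, _ in comparisons)
        if n_up > n_down:
            direction = "up"
            ps = [pmap[f] for up, _, pmap in comparisons if f in up and f in pmap]
        elif n_down > n_up:
            direction = "down"
            ps = [pmap[f] for _, down, pmap in comparisons if f in down and f in pmap]
        else:
            direction = "none"
            ps = []
        rows.append((f, direction, min(ps) if ps else np.nan, n_up, n_down))
    return pd.DataFrame(
        rows, columns=["feature", "direction", "rep_p", "n_up", "n_down"]
    ).set_index("feature")


def sex_stratified_stability(
    matrix: pd.DataFrame,
    case_samples: list[str],
    control_samples: list[str],
    n_case: int,
    n_control: int,
    n_iter: int = 1000,
    freq_thresh: float = 0.8,
    fc_thresh: float | None = 1.1,
    fdr_thresh: float = 0.05,
    p_mode: str = "adjusted",
    seed: int = 0,
) -> tuple[set[str], set[str], pd.DataFrame]:
    """Stability selection under repeated down-sampling.

    At each iteration the case and control groups are down-sampled without
    replacement to ``n_case`` and ``n_control`` (matching the sizes of the
    smaller counterpart groups, e.g. the male strata when testing females),
    DEPs are called, and a feature is kept if it is called with the same
    direction in strictly more than ``freq_thresh`` of iterations.
    Per-iteration seeds derive from the master seed by counter.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if n_case > len(case_samples) or n_control > len(control_samples):
        raise ValueError("target sizes exceed group sizes")
    up_counts: dict[str, int] = {}
    down_counts: dict[str, int] = {}
    for it in range(n_iter):
        rng = np.random.default_rng([seed, it])
        case = list(rng.choice(case_samples, size=n_case, replace=False))
        ctrl = list(rng.choice(control_samples, size=n_control, replace=False))
        res, _ = moderated_ttest(matrix, case, ctrl)
        up, down = call_deps(res, fc_thresh, fdr_thresh, p_mode)
        for f in up:
            up_counts[f] = up_counts.get(f, 0) + 1
        for f in down:
            down_counts[f] = down_counts.get(f, 0) + 1
    feats = sorted(set(up_counts) | set(down_counts))
    freq = pd.DataFrame(
        {
            "up_freq": [up_counts.get(f, 0) / n_iter for f in feats],
            "down_freq": [down_counts.get(f, 0) / n_iter for f in feats],
        },
        index=feats,
    )
    stable_up = {f for f in feats if up_counts.get(f, 0) / n_iter > freq_thresh}
    stable_down = {f for f in feats if down_counts.get(f, 0) / n_iter > freq_thresh}
    return stable_up, stable_down, freq


def map_isoforms_to_genes(features: list[str] | set[str]) -> dict[str, str]:
    """GENE.k -> GENE; ids without an isoform suffix map to themselves."""
    out = {}
    for f in features:
        gene, _, suffix = f.rpartition(".")
        out[f] = gene if gene and suffix.isdigit() else f
    return out


def _gene_direction(consensus: pd.DataFrame) -> dict[str, str]:
    """Collapse isoform-level consensus calls to gene level by majority."""
    iso2gene = map_isoforms_to_genes(list(consensus.index))
    votes: dict[str, list[str]] = {}
    for f, row in consensus.iterrows():
        votes.setdefault(iso2gene[f], []).append(row["direction"])
    out = {}
    for g, dirs in votes.items():
        nu, nd = dirs.count("up"), dirs.count("down")
        out[g] = "up" if nu > nd else ("down" if nd > nu else "none")
    return out


def concordance_classify(
    protein_consensus: pd.DataFrame, gene_consensus: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """3x3 protein-vs-gene direction concordance with per-cell enrichment p.

    Isoform-level protein calls are collapsed to genes (majority across
    isoforms) and crossed with gene-level calls over the shared universe.
    Each cell's p-value is a right-tail hypergeometric test of the overlap
    between the protein-class and gene-class sets against the universe.
    Returns (count table, p-value table); count proportions sum to 1.
    """
    prot = _gene_direction(protein_consensus)
    gene = _gene_direction(gene_consensus)
    shared = sorted(set(prot) & set(gene))
    if not shared:
        raise ValueError("empty shared universe")
    cats = ("up", "down", "none")
    counts = pd.DataFrame(0, index=cats, columns=cats)
    for g in shared:
        counts.loc[prot[g], gene[g]] += 1
    n = len(shared)
    pvals = pd.DataFrame(1.0, index=cats, columns=cats)
    for i in cats:
        big_k = sum(1 for g in shared if prot[g] == i)
        for j in cats:
            m = sum(1 for g in shared if gene[g] == j)
            k = int(counts.loc[i, j])
            pvals.loc[i, j] = float(stats.hypergeom.sf(k - 1, n, big_k, m))
    return counts, pvals


def trait_correlation(
    matrix: pd.DataFrame, trait_values: pd.Series, method: str = "spearman"
) -> pd.DataFrame:
    """Per-feature correlation with a clinical trait.

    Spearman for ordinal traits, Pearson for plaque density or mRNA-protein
    pairs.  Constant features (or a constant trait) get NaN and a flag.
    BH adjustment runs across features.
    """
    tv = trait_values.loc[matrix.columns].to_numpy(dtype=float)
    rows = []
    const_trait = np.nanstd(tv) == 0
    for f in matrix.index:
        x = matrix.loc[f].to_numpy(dtype=float)
        ok = ~(np.isnan(x) | np.isnan(tv))
        if const_trait or ok.sum() < 3 or np.std(x[ok]) == 0:
            rows.append((f, np.nan, np.nan, True))
            continue
        if method == "spearman":
            rho, p = stats.spearmanr(x[ok], tv[ok])
        elif method == "pearson":
            rho, p = stats.pearsonr(x[ok], tv[ok])
        else:
            raise ValueError("method must be 'spearman' or 'pearson'")
        rows.append((f, float(rho), float(p), False))
    out = pd.DataFrame(rows, columns=["feature", "rho", "p", "degenerate"]).set_index(
        "feature"
    )
    out["adj_p"] = benjamini_hochberg(out["p"].to_numpy())
    return out
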