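"""Module characterization: enrichment, ranking, preservation, specificity,
and gene-set enrichment analysis.

Modules are scored against differential-expression signatures by right-tail
hypergeometric tests with fold enrichment FE = (k/m)/(K/N); disease
relevance is ranked by the summed significance level sum(-log10 FDR) across
the signature panel.  Cross-dataset reproducibility uses a permutation
Zsummary (mean of a density Z and a connectivity Z; > 6 = preserved), and a
module is called conserved in a reference network when it is preserved there
and overlaps at least 20% of its members with some reference module at a
corrected p < 0.05; a module conserved nowhere is region/omics-specific.
GSEA uses the weighted Kolmogorov-Smirnov running sum with a
set-membership-permutation null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import benjamini_hochberg, map_isoforms_to_genes

__all__ = [
    "EnrichmentRecord",
    "PreservationResult",
    "GseaResult",
    "hypergeometric_enrichment",
    "rank_modules",
    "assign_cell_type",
    "zsummary_preservation",
    "conservation_call",
    "gsea",
    "genes_of",
]

P_FLOOR = 1e-300


@dataclass(frozen=True)
class EnrichmentRecord:
    module_id: str
    signature_id: str
    overlap: int
    fold_enrichment: float
    p: float
    adj_p: float = np.nan


@dataclass(frozen=True)
class PreservationResult:
    module_id: str
    z_density: float
    z_connectivity: float

    @property
    def z_summary(self) -> float:
        return 0.5 * (self.z_density + self.z_connectivity)

    @property
    def preserved(self) -> bool:
        return self.z_summary > 6


@dataclass(frozen=True)
class GseaResult:
    set_id: str
    es: float
    nes: float
    p: float
    adj_p: float = np.nan


def genes_of(features: set[str] | list[str]) -> set[str]:
    """Collapse isoform ids (GENE.k) to gene symbols."""
    return set(map_isoforms_to_genes(list(features)).values())


def hypergeometric_enrichment(
    module: set[str], signature: set[str], background: set[str],
    module_id: str = "module", signature_id: str = "signature",
) -> EnrichmentRecord:
    """Right-tail hypergeometric enrichment of a module for a signature.

    FE = (k/m) / (K/N) with overlap k, module size m, signature size K and
    background size N; p = P(overlap >= k) under random draws.
    """
    if not background:
        raise ValueError("empty background")
    if not module <= background or not signature <= background:
        raise ValueError("module and signature must be subsets of background")
    n_bg, m, big_k = len(background), len(module), len(signature)
    k = len(module & signature)
    fe = (k / m) / (big_k / n_bg) if m and big_k else 0.0
    p = float(stats.hypergeom.sf(k - 1, n_bg, big_k, m)) if m and big_k else 1.0
    return EnrichmentRecord(module_id, signature_id, k, fe, p)


def adjust_enrichments(records: list[EnrichmentRecord]) -> list[EnrichmentRecord]:
    """BH-adjust a family of enrichment records (one family per call)."""
    adj = benjamini_hochberg([r.p for r in records])
    return [
        EnrichmentRecord(r.module_id, r.signature_id, r.overlap,
                         r.fold_enrichment, r.p, float(a))
        for r, a in zip(records, adj)
    ]


def rank_modules(records: list[EnrichmentRecord]) -> pd.DataFrame:
    """Rank modules by total enrichment score sum(-log10 adjusted p).

    Adjusted p-values are floored at 1e-300; descending score, ties broken
    by module id.  Returns a frame (module_id, score, rank).
    """
    scores: dict[str, float] = {}
    for r in records:
        ap = r.adj_p if not np.isnan(r.adj_p) else r.p
        scores[r.module_id] = scores.get(r.module_id, 0.0) + (
            -np.log10(max(ap, P_FLOOR))
        )
    df = pd.DataFrame(
        sorted(scores.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["module_id", "score"],
    )
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def assign_cell_type(
    module: set[str],
    marker_panel: dict[str, set[str]],
    background: set[str],
    alpha: float = 0.05,
) -> str | None:
    """Most-enriched cell-type marker signature, or None.

    The winning cell type must reach adjusted p < alpha; ties on p are
    broken by larger fold enrichment.
    """
    if not marker_panel:
        raise ValueError("empty marker panel")
    recs = [
        hypergeometric_enrichment(module, markers & background, background,
                                  signature_id=ct)
        for ct, markers in marker_panel.items()
    ]
    recs = adjust_enrichments(recs)
    best = min(recs, key=lambda r: (r.adj_p, -r.fold_enrichment, r.signature_id))
    return best.signature_id if best.adj_p < alpha else None


def _intra_connectivity(corr: np.ndarray) -> np.ndarray:
    a = np.abs(corr).copy()
    np.fill_diagonal(a, 0.0)
    return a.sum(axis=1)


def _corr(x: np.ndarray) -> np.ndarray:
    c = np.corrcoef(x)
    return np.nan_to_num(c, nan=0.0)


def zsummary_preservation(
    module: set[str],
    source_matrix: pd.DataFrame,
    reference_matrix: pd.DataFrame,
    n_perm: int = 200,
    seed: int = 0,
    min_present: float = 0.5,
) -> PreservationResult | None:
    """Permutation Zsummary of a module against a reference dataset.

    Density = mean |correlation| among module features in the reference;
    connectivity preservation = correlation of each feature's intramodule
    connectivity in source vs reference.  Each statistic is standardized
    against ``n_perm`` random same-size feature sets drawn from the
    reference; Zsummary is their mean and > 6 flags the module preserved.
    Returns None (not evaluable) when under ``min_present`` of the module
    maps into the reference.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    present = sorted(module & set(reference_matrix.index) & set(source_matrix.index))
    if len(present) < min_present * len(module) or len(present) < 3:
        return None
    rng = np.random.default_rng(seed)
    ref = reference_matrix
    src_c = _corr(source_matrix.loc[present].to_numpy(dtype=float))
    ref_c = _corr(ref.loc[present].to_numpy(dtype=float))

    iu = np.triu_indices(len(present), k=1)
    obs_density = float(np.abs(ref_c[iu]).mean())
    obs_conn = float(np.corrcoef(_intra_connectivity(src_c),
                                 _intra_connectivity(ref_c))[0, 1])

    all_ref = list(ref.index)
    null_d = np.empty(n_perm)
    null_c = np.empty(n_perm)
    for i in range(n_perm):
        pick = rng.choice(len(all_ref), size=len(present), replace=False)
        names = [all_ref[j] for j in pick]
        rc = _corr(ref.loc[names].to_numpy(dtype=float))
        null_d[i] = np.abs(rc[iu]).mean()
        # same-size random set: connectivity agreement between source and
        # reference for features that exist in both, else its ref-internal
        common = [nm for nm in names if nm in source_matrix.index]
        if len(common) >= 3:
            sc = _corr(source_matrix.loc[common].to_numpy(dtype=float))
            rc2 = _corr(ref.loc[common].to_numpy(dtype=float))
            cc = np.corrcoef(_intra_connectivity(sc), _intra_connectivity(rc2))[0, 1]
            null_c[i] = 0.0 if np.isnan(cc) else cc
        else:
            null_c[i] = 0.0
    zd = (obs_density - null_d.mean()) / max(null_d.std(ddof=1), 1e-12)
    zc = (obs_conn - null_c.mean()) / max(null_c.std(ddof=1), 1e-12)
    mid = sorted(module)[0] if module else "module"
    return PreservationResult(module_id=str(mid), z_density=float(zd),
                              z_connectivity=float(zc))


def conservation_call(
    module: set[str],
    source_matrix: pd.DataFrame,
    references: dict[str, tuple[dict[str, set[str]], pd.DataFrame]],
    overlap_frac: float = 0.2,
    alpha: float = 0.05,
    n_perm: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Conservation of a query module in reference networks.

    ``references`` maps name -> (module dict, expression matrix).  The query
    is conserved in a reference iff (1) preserved there (Zsummary > 6),
    (2) it shares at least ``overlap_frac`` of its members (gene-level) with
    at least one reference module, and (3) at least one such overlap has
    BH-corrected hypergeometric p < alpha (corrected across that
    reference's modules).  The module is *specific* iff conserved nowhere.
    The returned frame has one row per reference plus a ``specific``
    attribute in ``DataFrame.attrs``.
    """
    if not references:
        raise ValueError("no references supplied")
    q_genes = genes_of(module)
    rows = []
    for name, (ref_modules, ref_matrix) in references.items():
        pres = zsummary_preservation(module, source_matrix, ref_matrix,
                                     n_perm=n_perm, seed=seed)
        preserved = bool(pres is not None and pres.preserved)
        zsum = pres.z_summary if pres is not None else np.nan
        # gene-level overlaps against every module of this reference
        bg = genes_of(set(ref_matrix.index)) | q_genes
        recs, fracs = [], []
        for rid, rmod in sorted(ref_modules.items()):
            r_genes = genes_of(rmod)
            k = len(q_genes & r_genes)
            fracs.append(k / max(len(q_genes), 1))
            recs.append(
                hypergeometric_enrichment(q_genes, r_genes & bg, bg,
                                          signature_id=rid)
            )
        recs = adjust_enrichments(recs)
        best_i = int(np.argmax(fracs)) if fracs else -1
        qualifying = [
            (f, r) for f, r in zip(fracs, recs)
            if f >= overlap_frac and r.adj_p < alpha
        ]
        conserved = preserved and bool(qualifying)
        rows.append(
            (
                name,
                preserved,
                zsum,
                fracs[best_i] if best_i >= 0 else 0.0,
                recs[best_i].adj_p if best_i >= 0 else np.nan,
                conserved,
            )
        )
    out = pd.DataFrame(
        rows,
        columns=["reference", "preserved", "z_summary", "best_overlap_frac",
                 "best_overlap_adj_p", "conserved"],
    ).set_index("reference")
    out.attrs["specific"] = bool(not out["conserved"].any())
    return out


def gsea(
    ranked: pd.Series,
    feature_set: set[str],
    n_perm: int = 1000,
    weight: float = 1.0,
    seed: int = 0,
    set_id: str = "set",
) -> GseaResult:
    """Weighted Kolmogorov-Smirnov gene-set enrichment on a pre-ranked list.

    ``ranked`` maps feature -> score, ordered (or orderable) by descending
    score.  Hits increment the running sum proportionally to
    |score|**weight, misses decrement uniformly; ES is the extreme of the
    running sum.  The null permutes set membership over the ranked features;
    NES = ES / mean |same-sign permutation ES| and p uses an add-one
    correction.
    """
    ranked = ranked.sort_values(ascending=False)
    feats = list(ranked.index)
    hits = np.fromiter((f in feature_set for f in feats), dtype=bool, count=len(feats))
    if not hits.any():
        raise ValueError("feature set does not intersect the ranked list")

    scores = np.abs(ranked.to_numpy(dtype=float)) ** weight

    def es_for(hit_mask: np.ndarray) -> float:
        hit_w = np.where(hit_mask, scores, 0.0)
        total_hit = hit_w.sum()
        if total_hit == 0:
            hit_w = hit_mask.astype(float)
            total_hit = hit_w.sum()
        n_miss = (~hit_mask).sum()
        step = np.where(hit_mask, hit_w / total_hit,
                        -1.0 / max(n_miss, 1))
        run = np.cumsum(step)
        i = int(np.argmax(np.abs(run)))
        return float(run[i])

    es = es_for(hits)
    rng = np.random.default_rng(seed)
    n_hit = int(hits.sum())
    perm_es = np.empty(n_perm)
    for i in range(n_perm):
        mask = np.zeros(len(feats), dtype=bool)
        mask[rng.choice(len(feats), size=n_hit, replace=False)] = True
        perm_es[i] = es_for(mask)
    same_sign = perm_es[np.sign(perm_es) == np.sign(es)]
    denom = np.abs(same_sign).mean() if len(same_sign) else np.abs(perm_es).mean()
    nes = es / denom if denom > 0 else 0.0
    if es >= 0:
        p = (1 + int((perm_es >= es).sum())) / (n_perm + 1)
    else:
        p = (1 + int((perm_es <= es).sum())) / (n_perm + 1)
    return GseaResult(set_id=set_id, es=es, nes=float(nes), p=float(p))
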