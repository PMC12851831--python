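"""Donor-level pseudobulk construction and cross-cell-type correlations.

Single-nucleus counts are summed per (donor, cell type), TMM-scaled,
converted to log2 counts-per-million, and genes are duplicated per cell
type as composite (gene, cell type) features.  Cross-cell-type pairs are
called significant when |Pearson rho| > 0.2 with BH-adjusted p < 0.05 over
donor columns; same-cell-type pairs are never tested.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import benjamini_hochberg
from .preprocess import tmm_factors

logger = logging.getLogger(__name__)

__all__ = [
    "pseudobulk_aggregate",
    "normalize_pseudobulk",
    "cross_celltype_correlations",
]


def pseudobulk_aggregate(cells: pd.DataFrame) -> pd.DataFrame:
    """Sum counts over cells per (donor, cell type).

    ``cells`` has 'donor' and 'celltype' columns and one column per gene.
    Returns genes x (donor, celltype) with MultiIndex columns; per-gene
    totals are conserved.  Absent (donor, celltype) combinations simply do
    not appear (logged).
    """
    if "donor" not in cells.columns or "celltype" not in cells.columns:
        raise ValueError("cells must carry 'donor' and 'celltype' columns")
    grouped = cells.groupby(["donor", "celltype"], sort=True).sum(numeric_only=True)
    donors = cells["donor"].unique()
    ctypes = cells["celltype"].unique()
    n_absent = len(donors) * len(ctypes) - len(grouped)
    if n_absent:
        logger.info("%d (donor, celltype) combinations have no cells", n_absent)
    return grouped.T  # genes x (donor, celltype)


def normalize_pseudobulk(raw: pd.DataFrame) -> pd.DataFrame:
    """TMM-scaled log2 counts-per-million.

    Rows become (gene, cell type) composite features indexed
    ``gene@celltype``; columns are donors.  Output is nonnegative.
    """
    lib = raw.sum(axis=0)
    if (lib == 0).any():
        raise ValueError("all-zero library")
    factors = tmm_factors(raw)
    cpm = raw / (lib * factors) * 1e6
    logged = np.log2(cpm + 1.0)
    # pivot: rows (gene, celltype) -> composite id, columns donors
    out = {}
    for (donor, ct) in logged.columns:
        col = logged[(donor, ct)]
        for gene, val in col.items():
            out.setdefault(f"{gene}@{ct}", {})[donor] = val
    mat = pd.DataFrame(out).T
    mat = mat.sort_index()
    return mat[sorted(mat.columns)]


def cross_celltype_correlations(
    pseudobulk: pd.DataFrame,
    query_features: list[str] | None = None,
    target_celltypes: list[str] | None = None,
    rho_thresh: float = 0.2,
    fdr_thresh: float = 0.05,
    min_donors: int = 10,
) -> pd.DataFrame:
    """Pearson correlations between composite features of distinct cell
    types.

    Tests all cross-cell-type pairs among ``query_features`` (default: all
    features), optionally restricted to ``target_celltypes``.  BH adjustment
    runs across all pairs tested in the invocation; significance requires
    |rho| > ``rho_thresh`` and adjusted p < ``fdr_thresh``.  Constant
    features are skipped with a warning.  The (a, b) and (b, a) orderings
    are the same test; each unordered pair is reported once.
    """
    feats = list(query_features) if query_features is not None else list(pseudobulk.index)
    if target_celltypes is not None:
        allowed = set(target_celltypes)
        feats = [f for f in feats if f.rsplit("@", 1)[1] in allowed]
    rows = []
    X = pseudobulk.loc[feats]
    for i in range(len(feats)):
        for j in range(i + 1, len(feats)):
            fa, fb = feats[i], feats[j]
            ct_a, ct_b = fa.rsplit("@", 1)[1], fb.rsplit("@", 1)[1]
            if ct_a == ct_b:
                continue
            xa = X.loc[fa].to_numpy(dtype=float)
            xb = X.loc[fb].to_numpy(dtype=float)
            ok = ~(np.isnan(xa) | np.isnan(xb))
            if ok.sum() < min_donors:
                continue
            if np.std(xa[ok]) == 0 or np.std(xb[ok]) == 0:
                logger.warning("skipping constant feature pair %s, %s", fa, fb)
                continue
            rho, p = stats.pearsonr(xa[ok], xb[ok])
            rows.append((fa, fb, float(rho), float(p)))
    out = pd.DataFrame(rows, columns=["feature_a", "feature_b", "rho", "p"])
    if len(out):
        out["adj_p"] = benjamini_hochberg(out["p"].to_numpy())
        out["significant"] = (out["rho"].abs() > rho_thresh) & (
            out["adj_p"] < fdr_thresh
        )
    else:
        out["adj_p"] = []
        out["significant"] = []
    return out
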