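"""Expression preprocessing: missingness filtering, k-NN imputation,
median centering, covariate residualization, and TMM scale factors.

The preprocessing contract for proteomic matrices is: drop features missing
in more than half the samples (strictly more), impute the remainder from the
k nearest features, normalize, regress out clinical/technical covariates per
feature, and carry the residuals forward.  Count data destined for
correlation analysis are scaled by trimmed-mean-of-M-values (TMM) factors.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "filter_missing",
    "impute_missing",
    "median_center",
    "adjust_covariates",
    "tmm_factors",
]


def filter_missing(matrix: pd.DataFrame, max_missing_frac: float = 0.5) -> pd.DataFrame:
    """Drop features whose missing fraction exceeds ``max_missing_frac``.

    The boundary is strict: a feature missing in exactly half the samples is
    retained at the default threshold.  Feature order is preserved.
    """
    if matrix.empty:
        raise ValueError("empty matrix")
    if not 0 <= max_missing_frac <= 1:
        raise ValueError("max_missing_frac must be in [0, 1]")
    frac = matrix.isna().mean(axis=1)
    return matrix.loc[frac <= max_missing_frac]


def impute_missing(matrix: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """k-nearest-feature imputation.

    Each missing entry is replaced by the inverse-distance-weighted mean of
    the k nearest features (Euclidean distance on the samples where both
    features are observed), using only neighbors observed at that sample.
    Observed entries are untouched.
    """
    X = matrix.to_numpy(dtype=float)
    if np.isnan(X).all(axis=1).any():
        raise ValueError("feature with zero observed values")
    if not np.isnan(X).any():
        return matrix.copy()
    out = X.copy()
    obs = ~np.isnan(X)
    n_feat = X.shape[0]
    miss_rows = np.where(~obs.all(axis=1))[0]
    for i in miss_rows:
        # mean distance over shared observed samples vs every other feature
        shared = obs[i] & obs
        diff = X[i] - X
        with np.errstate(invalid="ignore"):
            sq = np.where(shared, diff**2, 0.0)
        cnt = shared.sum(axis=1)
        d = np.sqrt(np.where(cnt > 0, sq.sum(axis=1) / np.maximum(cnt, 1), np.inf))
        d[i] = np.inf
        d[cnt == 0] = np.inf
        order = np.argsort(d, kind="stable")
        for j in np.where(~obs[i])[0]:
            picked, wsum, vsum = 0, 0.0, 0.0
            for nb in order:
                if picked >= k or not np.isfinite(d[nb]):
                    break
                if obs[nb, j]:
                    w = 1.0 / max(d[nb], 1e-12)
                    wsum += w
                    vsum += w * X[nb, j]
                    picked += 1
            if wsum > 0:
                out[i, j] = vsum / wsum
            else:  # no observed neighbor at this sample: feature's own mean
                out[i, j] = np.nanmean(X[i])
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def median_center(matrix: pd.DataFrame) -> pd.DataFrame:
    """Subtract each sample column's median."""
    if matrix.isna().any().any():
        raise ValueError("median_center requires a complete matrix")
    return matrix - matrix.median(axis=0)


def adjust_covariates(
    matrix: pd.DataFrame, metadata: pd.DataFrame, covariates: list[str]
) -> pd.DataFrame:
    """Per-feature OLS residuals after regressing on the covariates.

    Categorical covariates are expanded to indicator columns (first level
    dropped).  Aliased (rank-deficient) design columns are removed with a
    warning.  Residuals are orthogonal to every retained covariate column.
    """
    missing = [c for c in covariates if c not in metadata.columns]
    if missing:
        raise KeyError(f"covariates not in metadata: {missing}")
    meta = metadata.loc[matrix.columns, covariates]
    design_parts = [pd.Series(1.0, index=meta.index, name="intercept")]
    for c in covariates:
        col = meta[c]
        if col.dtype == object or str(col.dtype) == "category":
            dummies = pd.get_dummies(col, prefix=c, drop_first=True, dtype=float)
            design_parts.append(dummies)
        else:
            design_parts.append(col.astype(float))
    D = pd.concat(design_parts, axis=1)
    Dv = D.to_numpy(dtype=float)
    # drop aliased columns via QR rank reveal
    q, r = np.linalg.qr(Dv)
    diag = np.abs(np.diag(r))
    keep = diag > 1e-10 * max(diag.max(), 1.0)
    if not keep.all():
        dropped = [str(D.columns[i]) for i in np.where(~keep)[0]]
        logger.warning("dropping aliased design columns: %s", dropped)
        Dv = Dv[:, keep]
    Y = matrix.to_numpy(dtype=float).T  # samples x features
    beta, *_ = np.linalg.lstsq(Dv, Y, rcond=None)
    resid = Y - Dv @ beta
    return pd.DataFrame(resid.T, index=matrix.index, columns=matrix.columns)


def tmm_factors(
    counts: pd.DataFrame, trim_m: float = 0.30, trim_a: float = 0.05
) -> pd.Series:
    """Trimmed-mean-of-M-values scale factors per sample column.

    Reference = the sample whose upper quartile (of nonzero-count fraction
    scale) is closest to the mean upper quartile.  For each sample, genes
    expressed in both sample and reference contribute a log-ratio M and
    log-abundance A; the top/bottom ``trim_m`` of M and ``trim_a`` of A are
    trimmed and the factor is 2**(precision-weighted mean M).  Factors are
    scaled to geometric mean 1.
    """
    X = counts.to_numpy(dtype=float)
    lib = X.sum(axis=0)
    if (lib == 0).any():
        raise ValueError("all-zero sample")
    # upper-quartile of scaled counts to pick the reference
    uq = np.array([np.quantile(X[:, j][X[:, j] > 0] / lib[j], 0.75) for j in range(X.shape[1])])
    ref_j = int(np.argmin(np.abs(uq - uq.mean())))
    ref = X[:, ref_j] / lib[ref_j]

    factors = np.ones(X.shape[1])
    for j in range(X.shape[1]):
        obs = X[:, j] / lib[j]
        ok = (obs > 0) & (ref > 0)
        if ok.sum() == 0:
            continue
        o, rf = obs[ok], ref[ok]
        M = np.log2(o / rf)
        A = 0.5 * np.log2(o * rf)
        # asymptotic (delta-method) variance of M
        nj, nr = lib[j], lib[ref_j]
        v = (nj - X[ok, j]) / (nj * X[ok, j]) + (nr - X[ok, ref_j]) / (nr * X[ok, ref_j])
        lo_m, hi_m = np.quantile(M, [trim_m, 1 - trim_m])
        lo_a, hi_a = np.quantile(A, [trim_a, 1 - trim_a])
        keep = (M >= lo_m) & (M <= hi_m) & (A >= lo_a) & (A <= hi_a)
        if keep.sum() == 0:
            keep = np.ones_like(M, dtype=bool)
        w = 1.0 / np.maximum(v[keep], 1e-12)
        factors[j] = 2 ** (np.sum(w * M[keep]) / np.sum(w))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")
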