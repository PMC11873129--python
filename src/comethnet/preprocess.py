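"""Probe filtering, covariate residualisation and sample-outlier flagging.

Mirrors the standard pre-network processing of a multi-region methylation
study: keep probes that are variable (MAD above the median probe MAD) in
every brain region, regress technical and biological covariates out of each
probe, and flag outlying samples on the leading principal components.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import median_abs_deviation

__all__ = [
    "mad_variable_probes",
    "residualize_covariates",
    "pc_outlier_flags",
]


def mad_variable_probes(betas_by_region: Iterable[pd.DataFrame]) -> set[str]:
    """Probes with MAD > median probe MAD in *every* region.

    The median-MAD threshold is computed within each region separately and
    the per-region surviving sets are intersected, so a probe must be
    variable in every brain region to enter the network.
    """
    betas = list(betas_by_region)
    if not betas:
        raise ValueError("need at least one region")
    shared = set(betas[0].index)
    for beta in betas[1:]:
        shared &= set(beta.index)
    if not shared:
        raise ValueError("regions have disjoint probe sets")
    kept: set[str] | None = None
    for beta in betas:
        mad = pd.Series(
            median_abs_deviation(beta.to_numpy(float), axis=1), index=beta.index
        )
        region_kept = set(beta.index[mad > mad.median()])
        kept = region_kept if kept is None else kept & region_kept
    return kept if kept is not None else set()


def _design_matrix(meta: pd.DataFrame, covariates: Sequence[str]) -> pd.DataFrame:
    """Intercept + covariates; categoricals one-hot with first level dropped."""
    cols = {"intercept": np.ones(len(meta))}
    for c in covariates:
        v = meta[c]
        if v.dtype == object or isinstance(v.dtype, pd.CategoricalDtype):
            levels = sorted(v.astype(str).unique())
            for lev in levels[1:]:
                cols[f"{c}[{lev}]"] = (v.astype(str) == lev).astype(float)
        else:
            cols[c] = v.to_numpy(float)
    X = pd.DataFrame(cols, index=meta.index)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify the offending columns by greedy rank check
        bad = []
        keep: list[str] = []
        for name in X.columns:
            trial = X[keep + [name]].to_numpy()
            if np.linalg.matrix_rank(trial) == len(keep) + 1:
                keep.append(name)
            else:
                bad.append(name)
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    return X


def residualize_covariates(
    beta: pd.DataFrame, meta: pd.DataFrame, covariates: Sequence[str]
) -> pd.DataFrame:
    """OLS out the covariates from every probe; return intercept + residuals.

    The output keeps the scale of the input (per-probe mean equals the
    fitted intercept) but values may leave [0,1]; that is expected and
    accepted downstream. ``meta`` must have one row per sample of ``beta``,
    keyed by its ``sample`` column.
    """
    meta = meta.set_index("sample").loc[list(beta.columns)]
    if meta[list(covariates)].isna().any().any():
        raise ValueError("covariates contain missing values")
    X = _design_matrix(meta, covariates).to_numpy()
    n, k = X.shape
    if n <= k:
        raise ValueError("need n_samples > n_covariates + 1")
    Y = beta.to_numpy(float).T  # samples x probes
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    out = coef[0][None, :] + resid  # intercept + residuals
    return pd.DataFrame(out.T, index=beta.index, columns=beta.columns)


def pc_outlier_flags(
    beta: pd.DataFrame, n_pcs: int = 4, sd_cut: float = 3.0
) -> pd.DataFrame:
    """Flag samples scoring beyond ``sd_cut`` SD on any of the first PCs.

    A reproducible surrogate for the usual visual PC inspection. Returns a
    frame indexed by sample with the PC scores, per-PC flags and an overall
    ``outlier`` column; flags are advisory (the caller decides removal).
    """
    n_samples = beta.shape[1]
    if n_pcs >= n_samples:
        raise ValueError("n_pcs must be < n_samples")
    X = beta.to_numpy(float).T  # samples x probes
    X = X - X.mean(axis=0)
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    scores = U[:, :n_pcs] * s[:n_pcs]
    sds = scores.std(axis=0, ddof=1)
    sds[sds == 0] = 1.0
    zs = scores / sds
    out = pd.DataFrame(
        scores, index=beta.columns, columns=[f"PC{i + 1}" for i in range(n_pcs)]
    )
    for i in range(n_pcs):
        out[f"PC{i + 1}_flag"] = np.abs(zs[:, i]) > sd_cut
    out["outlier"] = (np.abs(zs) > sd_cut).any(axis=1)
    return out
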