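"""Pairwise Pearson screening between feature blocks.

Permutation nulls (joint within-block shuffles that break the cross-block
pairing), Benjamini-Hochberg FDR over a configurable scope, MAD-based flags for
subgroup blocks whose density of significant cells is an outlier, and subgroup
averaging of the correlation matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CorrelationScreen",
    "correlation_matrix",
    "permutation_pvalues",
    "bh_fdr",
    "bh_adjusted",
    "mad_cluster_mask",
    "subgroup_average",
    "run_screen",
    "screen_long_table",
]


@dataclass
class CorrelationScreen:
    r: pd.DataFrame
    p: pd.DataFrame
    rejected: pd.DataFrame
    n_perm: int
    cluster: pd.DataFrame | None = None


def _standardize_cols(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column z-scores and a flag for zero-variance columns (left as NaN)."""
    mean = np.nanmean(M, axis=0)
    sd = np.nanstd(M, axis=0, ddof=1)
    bad = ~(sd > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = (M - mean) / sd
    Z[:, bad] = np.nan
    return Z, bad


def correlation_matrix(X: pd.DataFrame, Y: pd.DataFrame) -> pd.DataFrame:
    """Pearson r for every (X column, Y column) pair, pairwise-complete.

    Zero-variance columns give NaN entries rather than raising.
    """
    X, Y = X.align(Y, join="inner", axis=0)
    n = len(X)
    if n < 3:
        raise ValueError("need at least 3 shared subjects")
    if X.isna().any().any() or Y.isna().any().any():
        r = np.empty((X.shape[1], Y.shape[1]))
        for i, cx in enumerate(X.columns):
            for j, cy in enumerate(Y.columns):
                pair = pd.concat([X[cx], Y[cy]], axis=1).dropna()
                if len(pair) < 3 or pair.iloc[:, 0].std() == 0 or pair.iloc[:, 1].std() == 0:
                    r[i, j] = np.nan
                else:
                    r[i, j] = np.corrcoef(pair.iloc[:, 0], pair.iloc[:, 1])[0, 1]
    else:
        Zx, _ = _standardize_cols(X.to_numpy(float))
        Zy, _ = _standardize_cols(Y.to_numpy(float))
        r = Zx.T @ Zy / (n - 1)
    return pd.DataFrame(r, index=X.columns, columns=Y.columns)


def permutation_pvalues(
    X: pd.DataFrame,
    Y: pd.DataFrame,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    two_sided: bool = True,
    add_one: bool = False,
) -> pd.DataFrame:
    """Permutation p-values for every cross-block correlation.

    Subject rows of Y are shuffled jointly each iteration, breaking the X-Y
    pairing while preserving within-block structure. The default p is the
    literal proportion #{|r_perm| >= |r_obs|}/N (can be 0); ``add_one`` gives
    the (b+1)/(N+1) correction, ``two_sided=False`` uses signed exceedance.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    X, Y = X.align(Y, join="inner", axis=0)
    n = len(X)
    if n < 4:
        warnings.warn(f"n={n} is too small for a meaningful permutation null", stacklevel=2)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Mx, My = X.to_numpy(float), Y.to_numpy(float)
    if np.isnan(Mx).any() or np.isnan(My).any():
        warnings.warn("missing values mean-imputed for the permutation null", stacklevel=2)
        for M in (Mx, My):
            mean = np.nanmean(M, axis=0)
            ii = np.where(np.isnan(M))
            M[ii] = mean[ii[1]]
    Zx, bad_x = _standardize_cols(Mx)
    Zy, bad_y = _standardize_cols(My)
    Zx[:, bad_x] = 0.0
    Zy[:, bad_y] = 0.0
    r_obs = Zx.T @ Zy / (n - 1)
    stat_obs = np.abs(r_obs) if two_sided else r_obs
    count = np.zeros_like(r_obs)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_perm = Zx.T @ Zy[perm] / (n - 1)
        stat = np.abs(r_perm) if two_sided else r_perm
        count += stat >= stat_obs
    p = (count + 1) / (n_perm + 1) if add_one else count / n_perm
    p[bad_x, :] = np.nan
    p[:, bad_y] = np.nan
    return pd.DataFrame(p, index=X.columns, columns=Y.columns)


def bh_fdr(p, alpha: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up: reject all p <= p(k*) with k* the largest k
    such that p(k) <= (k/m) * alpha. NaNs are never rejected; m counts non-NaN
    tests. Returns a boolean mask with the input's shape."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return np.zeros(arr.shape, dtype=bool)
    flat = arr.ravel()
    valid = ~np.isnan(flat)
    m = int(valid.sum())
    reject = np.zeros(flat.shape, dtype=bool)
    if m:
        pv = flat[valid]
        order = np.argsort(pv, kind="stable")
        thresh = (np.arange(1, m + 1) / m) * alpha
        passing = pv[order] <= thresh
        if passing.any():
            k_star = np.max(np.nonzero(passing)[0])
            reject[valid] = pv <= pv[order][k_star]
    return reject.reshape(arr.shape)


def bh_adjusted(p) -> np.ndarray:
    """BH-adjusted p-values (monotone step-up q-values); NaN passthrough."""
    arr = np.asarray(p, dtype=float)
    flat = arr.ravel()
    out = np.full(flat.shape, np.nan)
    valid = ~np.isnan(flat)
    m = int(valid.sum())
    if m:
        pv = flat[valid]
        order = np.argsort(pv, kind="stable")
        ranked = pv[order] * m / np.arange(1, m + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        q = np.empty(m)
        q[order] = np.minimum(ranked, 1.0)
        out[valid] = q
    return out.reshape(arr.shape)


def _blocks(groups: pd.Series | list) -> list[np.ndarray]:
    g = pd.Series(groups)
    return [np.asarray(g.index[g == lvl]) if g.index.dtype != np.int64 else np.flatnonzero(g.to_numpy() == lvl)
            for lvl in pd.unique(g)]


def mad_cluster_mask(
    mask: pd.DataFrame,
    row_groups,
    col_groups,
    n_mad: float = 3.0,
) -> pd.DataFrame:
    """Flag subgroup blocks whose significant-cell density is a 3-MAD outlier.

    The matrix is partitioned into the cross-product of contiguous row/column
    subgroups; each block's density of True cells is compared against the
    median density over blocks using the raw median absolute deviation. This
    is a reconstruction of an under-described published rule and is labelled
    as such in the documentation.
    """
    M = mask.to_numpy(dtype=float)
    rg = pd.Series(list(row_groups), index=mask.index)
    cg = pd.Series(list(col_groups), index=mask.columns)
    row_lvls, col_lvls = list(pd.unique(rg)), list(pd.unique(cg))
    n_blocks = len(row_lvls) * len(col_lvls)
    if n_blocks < 3:
        raise ValueError("need at least 3 subgroup blocks for a MAD-based flag")
    dens = np.zeros((len(row_lvls), len(col_lvls)))
    for i, rl in enumerate(row_lvls):
        ri = np.flatnonzero((rg == rl).to_numpy())
        for j, cl in enumerate(col_lvls):
            ci = np.flatnonzero((cg == cl).to_numpy())
            block = M[np.ix_(ri, ci)]
            dens[i, j] = np.nanmean(block)
    med = np.median(dens)
    mad = np.median(np.abs(dens - med))
    flagged = np.abs(dens - med) > n_mad * mad
    out = pd.DataFrame(False, index=mask.index, columns=mask.columns)
    for i, rl in enumerate(row_lvls):
        for j, cl in enumerate(col_lvls):
            if flagged[i, j]:
                out.loc[(rg == rl).to_numpy(), (cg == cl).to_numpy()] = True
    return out


def subgroup_average(r: pd.DataFrame, row_groups, col_groups) -> pd.DataFrame:
    """Mean correlation over each subgroup cross-product, ignoring NaN entries."""
    rg = pd.Series(list(row_groups), index=r.index)
    cg = pd.Series(list(col_groups), index=r.columns)
    out = pd.DataFrame(
        index=pd.unique(rg), columns=pd.unique(cg), dtype=float
    )
    for rl in out.index:
        for cl in out.columns:
            block = r.loc[(rg == rl).to_numpy(), (cg == cl).to_numpy()]
            if block.size == 0:
                raise ValueError(f"empty subgroup block ({rl!r}, {cl!r})")
            out.loc[rl, cl] = np.nanmean(block.to_numpy())
    return out


def run_screen(
    morph: pd.DataFrame,
    physio: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    fdr_scope: str = "global",
    row_groups=None,
    col_groups=None,
) -> CorrelationScreen:
    """Full screen: r matrix, permutation p, BH rejections, optional cluster flags.

    ``fdr_scope="per_row_group"`` applies BH separately within each row-subgroup
    panel; the default corrects over the whole matrix.
    """
    r = correlation_matrix(morph, physio)
    p = permutation_pvalues(morph, physio, n_perm=n_perm, seed=seed)
    if fdr_scope == "per_row_group" and row_groups is not None:
        rej = pd.DataFrame(False, index=p.index, columns=p.columns)
        rg = pd.Series(list(row_groups), index=p.index)
        for lvl in pd.unique(rg):
            rows = (rg == lvl).to_numpy()
            rej.loc[rows, :] = bh_fdr(p.loc[rows, :].to_numpy(), alpha)
    else:
        rej = pd.DataFrame(bh_fdr(p.to_numpy(), alpha), index=p.index, columns=p.columns)
    cluster = None
    if row_groups is not None and col_groups is not None:
        cluster = mad_cluster_mask(rej, row_groups, col_groups)
    return CorrelationScreen(r=r, p=p, rejected=rej, n_perm=n_perm, cluster=cluster)


def screen_long_table(screen: CorrelationScreen) -> pd.DataFrame:
    """Tidy long-format view (morph_feature, physio_feature, r, p, rejected, cluster)."""
    recs = []
    for i, mf in enumerate(screen.r.index):
        for j, pf in enumerate(screen.r.columns):
            recs.append(
                {
                    "morph_feature": mf,
                    "physio_feature": pf,
                    "r": screen.r.iat[i, j],
                    "p": screen.p.iat[i, j],
                    "rejected": bool(screen.rejected.iat[i, j]),
                    "cluster": bool(screen.cluster.iat[i, j]) if screen.cluster is not None else False,
                }
            )
    return pd.DataFrame.from_records(recs)
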