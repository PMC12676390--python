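"""Confound control and biomarker selection downstream of the latent model.

* :func:`partial_correlation_matrix` — pairwise partial correlations among the
  latent scores and clinical covariates, each pair controlling for all other
  listed variables, with t-based p-values BH-corrected over the unique pairs.
* :func:`stepwise_aic_regression` — bidirectional stepwise OLS against the
  motor score (UPDRS-III) over weight-scaled selected features, optimized by
  the Akaike Information Criterion.
* :func:`transfer_to_cohort` — projection of a trained component onto an
  external cohort (the essential-tremor specificity control) with training
  standardization and a fixed-weight permutation test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .pairwise import bh_adjusted
from .spls import SPLSComponent, StandardizationParams

__all__ = [
    "StepwiseModel",
    "partial_correlation_matrix",
    "stepwise_aic_regression",
    "transfer_to_cohort",
]


def _residualize(y: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Residual of y on [1, Z] via least squares."""
    A = np.column_stack([np.ones(len(y)), Z])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return y - A @ coef


def partial_correlation_matrix(
    table: pd.DataFrame, alpha: float = 0.05
) -> dict[str, pd.DataFrame]:
    """Each pairwise partial correlation controls for all remaining variables.

    Both members of a pair are residualized on the other k variables (with an
    intercept) and their residuals correlated; p-values use the t distribution
    with n - 2 - k degrees of freedom and are BH-corrected over the unique
    pairs. Collinear controls raise with the offending variable set named.
    """
    cols = list(table.columns)
    m = len(cols)
    if m < 3:
        raise ValueError("need at least 3 variables for partial correlations")
    M = table.to_numpy(float)
    n = M.shape[0]
    k = m - 2
    if n <= m + 2:
        raise ValueError(f"need n > {m + 2} subjects for {m} variables, got {n}")
    r = pd.DataFrame(np.eye(m), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((m, m)), index=cols, columns=cols)
    pairs = []
    for i in range(m):
        for j in range(i + 1, m):
            ctrl = [c for c in range(m) if c not in (i, j)]
            Z = M[:, ctrl]
            if np.linalg.matrix_rank(np.column_stack([np.ones(n), Z])) < Z.shape[1] + 1:
                raise ValueError(f"collinear controls among {[cols[c] for c in ctrl]}")
            ri = _residualize(M[:, i], Z)
            rj = _residualize(M[:, j], Z)
            if ri.std() == 0 or rj.std() == 0:
                rho = np.nan
            else:
                rho = float(np.corrcoef(ri, rj)[0, 1])
            df_t = n - 2 - k
            if np.isnan(rho) or abs(rho) >= 1:
                pv = np.nan if np.isnan(rho) else 0.0
            else:
                tstat = rho * np.sqrt(df_t / (1 - rho**2))
                pv = 2 * stats.t.sf(abs(tstat), df_t)
            r.iloc[i, j] = r.iloc[j, i] = rho
            p.iloc[i, j] = p.iloc[j, i] = pv
            pairs.append((i, j, pv))
    adj = bh_adjusted(np.array([pv for _, _, pv in pairs]))
    p_adj = pd.DataFrame(np.zeros((m, m)), index=cols, columns=cols)
    for (i, j, _), q in zip(pairs, adj):
        p_adj.iloc[i, j] = p_adj.iloc[j, i] = q
    rejected = (p_adj <= alpha) & ~np.eye(m, dtype=bool)
    return {"r": r, "p": p, "p_adjusted": p_adj, "rejected": rejected}


@dataclass
class StepwiseModel:
    """Accepted stepwise trace and the final fit against the response."""

    selected: list[str]
    coefficients: pd.Series
    r_squared: float
    f_pvalue: float
    aic_trace: list[float] = field(default_factory=list)
    aic: float = np.nan


def _ols_aic(y: np.ndarray, X: pd.DataFrame, cols: list[str]):
    import statsmodels.api as sm

    design = sm.add_constant(X[cols]) if cols else pd.DataFrame(
        {"const": np.ones(len(y))}, index=X.index
    )
    model = sm.OLS(y, design).fit()
    return model.aic, model


def stepwise_aic_regression(
    response: pd.Series,
    candidates: pd.DataFrame,
    weights: pd.Series | None = None,
    max_predictors: int | None = None,
) -> StepwiseModel:
    """Bidirectional stepwise OLS from the intercept-only model, by AIC.

    ``weights`` (e.g. the optimal split's SPLS weights) scale each candidate
    column; zero-weight candidates are dropped. At each step the single add or
    drop with the lowest AIC is accepted if it improves; the search stops at a
    local minimum. The predictor count is capped at n/5 to guard overfitting.
    """
    y = response.to_numpy(float)
    X = candidates.copy()
    if weights is not None:
        keep = [c for c in X.columns if c in weights.index and weights[c] != 0]
        X = X[keep].mul(weights[keep], axis=1)
    X = X.loc[:, X.std() > 0]
    n = len(y)
    cap = max_predictors if max_predictors is not None else max(n // 5, 1)
    selected: list[str] = []
    current_aic, current_model = _ols_aic(y, X, selected)
    trace = [current_aic]
    while True:
        moves = []
        if len(selected) < cap:
            for c in X.columns:
                if c not in selected:
                    aic, _ = _ols_aic(y, X, selected + [c])
                    moves.append((aic, "add", c))
        for c in selected:
            aic, _ = _ols_aic(y, X, [s for s in selected if s != c])
            moves.append((aic, "drop", c))
        if not moves:
            break
        best_aic, action, col = min(moves, key=lambda t: t[0])
        if best_aic >= current_aic - 1e-10:
            break
        if action == "add":
            selected.append(col)
        else:
            selected.remove(col)
        current_aic, current_model = _ols_aic(y, X, selected)
        trace.append(current_aic)
    params = current_model.params
    return StepwiseModel(
        selected=list(selected),
        coefficients=params,
        r_squared=float(current_model.rsquared) if selected else 0.0,
        f_pvalue=float(current_model.f_pvalue) if selected else np.nan,
        aic_trace=trace,
        aic=current_aic,
    )


def transfer_to_cohort(
    comp: SPLSComponent,
    std_x: StandardizationParams,
    std_y: StandardizationParams,
    X_ext: pd.DataFrame,
    Y_ext: pd.DataFrame,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    max_missing_frac: float = 0.5,
) -> dict:
    """Apply trained weights to an external cohort and test the latent link.

    Features absent from the external tables (e.g. cortico-subcortical metrics
    in a cohort without basal-ganglia recordings) have their weights dropped
    with a disclosure; if more than ``max_missing_frac`` of the trained nonzero
    weight mass is unavailable the transfer refuses. External features are
    standardized with the training parameters; nothing from the external cohort
    feeds back into the weights.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out: dict = {"dropped_x": [], "dropped_y": []}

    def project(block: pd.DataFrame, std: StandardizationParams, w: np.ndarray, tag: str):
        present = [c for c in std.columns if c in block.columns]
        missing = [c for c in std.columns if c not in block.columns]
        w_series = pd.Series(w, index=std.columns)
        nz = w_series[w_series != 0]
        lost = nz.index.intersection(missing)
        if len(nz) > 0 and len(lost) / len(nz) > max_missing_frac:
            raise ValueError(
                f"{tag}: {len(lost)}/{len(nz)} trained nonzero weights unavailable "
                f"in the external cohort (> {max_missing_frac:.0%})"
            )
        if len(lost):
            warnings.warn(
                f"{tag}: dropping {len(lost)} trained weights absent externally: "
                f"{sorted(lost)}", stacklevel=3,
            )
        out[f"dropped_{tag}"] = sorted(lost)
        idx = [std.columns.index(c) for c in present]
        sub = StandardizationParams(
            mean=std.mean[idx], sd=std.sd[idx], columns=present
        )
        Z = sub.apply(block[present])
        return Z @ w_series[present].to_numpy()

    t = project(X_ext, std_x, comp.u, "x")
    s = project(Y_ext, std_y, comp.v, "y")
    if t.std() == 0 or s.std() == 0:
        return {**out, "t": t, "s": s, "corr": np.nan, "p": 1.0}
    corr = float(np.corrcoef(t, s)[0, 1])
    n = len(t)
    tc = (t - t.mean()) / t.std()
    sc = (s - s.mean()) / s.std()
    count = 0
    for _ in range(n_perm):
        count += abs(float(tc @ sc[rng.permutation(n)]) / n) >= abs(corr)
    p = (count + 1) / (n_perm + 1)
    return {**out, "t": t, "s": s, "corr": corr, "p": p}
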