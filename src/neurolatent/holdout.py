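"""Multiple-holdout validation for the sparse-PLS latent model.

Each of K outer splits reserves ~20% of subjects as a holdout; inside the
remaining optimization set, M train/validation resplits tune the L1 budgets by
a combined criterion of generalizability (mean validation latent correlation)
and stability (chance-corrected support overlap of the weight vectors across
resplits). The tuned model is refitted on the full optimization set, scored on
the holdout with a fixed-weight permutation test, p-values are BH-adjusted
across splits, and a Bonferroni-style omnibus decision (min p < alpha/K) is
taken. A second latent dimension is obtained per split by projection deflation.
Every quantity learned from data (standardization, budgets, weights) derives
exclusively from the split's optimization subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pairwise import bh_adjusted
from .spls import (
    SPLSComponent,
    SPLSHyperparams,
    StandardizationParams,
    _spls_weights,
    deflate,
)

__all__ = [
    "SplitPlan",
    "SplitResult",
    "FrameworkResult",
    "make_split_plan",
    "corrected_overlap",
    "default_grid",
    "tune_hyperparameters",
    "evaluate_split",
    "run_framework",
    "framework_table",
]


@dataclass
class SplitPlan:
    """Materialized outer/inner index sets, reproducible from the master seed."""

    n: int
    n_splits: int
    holdout_frac: float
    n_inner: int
    val_frac: float
    seed: int
    outer: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    inner: list[list[tuple[np.ndarray, np.ndarray]]] = field(default_factory=list)


def make_split_plan(
    n: int,
    n_splits: int = 10,
    holdout_frac: float = 0.2,
    n_inner: int = 50,
    val_frac: float = 0.2,
    seed: int = 0,
) -> SplitPlan:
    """K outer (optimization, holdout) partitions with M inner resplits each.

    Sizes round to the nearest subject (holdout = round(holdout_frac * n)); all
    draws are without replacement and deterministic given the seed.
    """
    if n < 10:
        raise ValueError("need at least 10 subjects")
    if not (0 < holdout_frac < 1 and 0 < val_frac < 1):
        raise ValueError("fractions must lie in (0, 1)")
    if n_splits < 1 or n_inner < 1:
        raise ValueError("split counts must be at least 1")
    n_hold = int(round(holdout_frac * n))
    if n_hold < 2:
        raise ValueError("holdout smaller than 2 subjects")
    rng = np.random.default_rng(seed)
    plan = SplitPlan(n, n_splits, holdout_frac, n_inner, val_frac, seed)
    for _ in range(n_splits):
        perm = rng.permutation(n)
        hold, opt = np.sort(perm[:n_hold]), np.sort(perm[n_hold:])
        n_val = max(int(round(val_frac * len(opt))), 1)
        inner = []
        for _ in range(n_inner):
            p2 = rng.permutation(len(opt))
            inner.append((np.sort(opt[p2[n_val:]]), np.sort(opt[p2[:n_val]])))
        plan.outer.append((opt, hold))
        plan.inner.append(inner)
    return plan


def corrected_overlap(vectors: list[np.ndarray] | np.ndarray) -> float:
    """Chance-corrected mean pairwise support overlap of weight vectors.

    For supports S_i, S_j in dimension p, each unordered pair contributes
    (|S_i & S_j| - E) / (min(|S_i|, |S_j|) - E) with E = |S_i||S_j|/p; pairs
    with an undefined denominator (or an empty support) contribute 0.
    """
    S = np.asarray([np.asarray(v) != 0 for v in vectors])
    if S.ndim != 2:
        raise ValueError("weight vectors must share a dimension")
    if S.shape[0] < 2:
        raise ValueError("need at least 2 weight vectors")
    p = S.shape[1]
    sizes = S.sum(axis=1)
    if np.any(sizes == 0):
        warnings.warn("empty support encountered; affected pairs contribute 0", stacklevel=2)
    inter = (S.astype(float) @ S.T)
    e = np.outer(sizes, sizes) / p
    denom = np.minimum.outer(sizes, sizes) - e
    with np.errstate(invalid="ignore", divide="ignore"):
        contrib = (inter - e) / denom
    valid = (denom != 0) & (np.outer(sizes, sizes) > 0)
    contrib = np.where(valid, contrib, 0.0)
    iu = np.triu_indices(S.shape[0], k=1)
    return float(contrib[iu].mean())


def default_grid(p: int, q: int, n_points: int = 8) -> list[tuple[float, float]]:
    """Logarithmic n x n grid over [1, sqrt(p)] x [1, sqrt(q)]."""
    cu = np.geomspace(1.0, np.sqrt(p), n_points)
    cv = np.geomspace(1.0, np.sqrt(q), n_points)
    return [(float(a), float(b)) for a in cu for b in cv]


def _standardize_block(M: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = np.nanmean(M, axis=0)
    filled = np.where(np.isnan(M), mean, M)
    sd = filled.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    return (filled - mean) / sd, mean, sd


def _apply_standardization(M: np.ndarray, mean: np.ndarray, sd: np.ndarray) -> np.ndarray:
    filled = np.where(np.isnan(M), mean, M)
    return (filled - mean) / sd


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def tune_hyperparameters(
    X: np.ndarray,
    Y: np.ndarray,
    grid: list[tuple[float, float]],
    inner_splits: list[tuple[np.ndarray, np.ndarray]],
    tol: float = 1e-6,
    max_iter: int = 500,
) -> tuple[SPLSHyperparams, dict]:
    """Choose L1 budgets by the unweighted rank-sum of two criteria.

    Per grid point, the model is fitted on each inner training fold (with
    fold-local standardization); generalizability is the mean validation latent
    correlation and stability the mean corrected support overlap of the fold
    weight vectors per block. The winner minimizes the sum of (descending)
    ranks, ties broken toward the sparser budget pair. Grid points whose fits
    all fail to converge are excluded.
    """
    if not grid:
        raise ValueError("hyperparameter grid is empty")
    from .spls import _leading_right_singular

    folds = []
    for tr, val in inner_splits:
        Xtr, mx, sx = _standardize_block(X[tr])
        Ytr, my, sy = _standardize_block(Y[tr])
        C = Xtr.T @ Ytr
        folds.append(
            (
                C,
                _apply_standardization(X[val], mx, sx),
                _apply_standardization(Y[val], my, sy),
                _leading_right_singular(C),
            )
        )
    gen = np.full(len(grid), np.nan)
    stab = np.full(len(grid), np.nan)
    usable = np.zeros(len(grid), dtype=bool)
    for gi, (cu, cv) in enumerate(grid):
        corrs, us, vs = [], [], []
        any_converged = False
        for C, Xv, Yv, v0 in folds:
            u, v, _, conv = _spls_weights(C, cu, cv, tol, max_iter, v0=v0)
            any_converged |= conv
            corrs.append(_safe_corr(Xv @ u, Yv @ v))
            us.append(u)
            vs.append(v)
        if not any_converged:
            continue
        usable[gi] = True
        gen[gi] = np.nanmean([0.0 if np.isnan(c) else c for c in corrs])
        if len(us) >= 2:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                stab[gi] = 0.5 * (corrected_overlap(us) + corrected_overlap(vs))
        else:
            stab[gi] = 0.0
    if not usable.any():
        raise RuntimeError("no grid point produced a convergent fit")
    from scipy.stats import rankdata

    big = np.where(usable, gen, -np.inf)
    rank_gen = rankdata(-big, method="average")
    big = np.where(usable, stab, -np.inf)
    rank_stab = rankdata(-big, method="average")
    ranksum = np.where(usable, rank_gen + rank_stab, np.inf)
    budget_sum = np.array([cu + cv for cu, cv in grid])
    order = np.lexsort((np.arange(len(grid)), budget_sum, ranksum))
    best = order[0]
    hp = SPLSHyperparams(c_u=grid[best][0], c_v=grid[best][1], max_iter=max_iter, tol=tol)
    diag = {
        "generalizability": gen,
        "stability": stab,
        "rank_sum": ranksum,
        "chosen_index": int(best),
        "chosen_stability": float(stab[best]),
        "chosen_generalizability": float(gen[best]),
    }
    return hp, diag


@dataclass
class SplitResult:
    """One Table-2 row: tuning choice, correlations, permutation p, counts."""

    split: int
    dim: int
    hyperparams: SPLSHyperparams
    train_corr: float
    holdout_corr: float
    p_value: float
    n_selected_physio: int
    n_selected_morph: int
    stability: float
    p_adjusted: float = np.nan
    degenerate: bool = False


def evaluate_split(
    X: np.ndarray,
    Y: np.ndarray,
    opt_idx: np.ndarray,
    hold_idx: np.ndarray,
    hp: SPLSHyperparams,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    scheme: str = "fixed",
) -> tuple[SplitResult, SPLSComponent, StandardizationParams, StandardizationParams]:
    """Refit on the full optimization set and score the holdout.

    With ``scheme="fixed"`` (default) the permutation p shuffles the holdout
    subject pairing with fixed trained weights:
    p = (1 + #{|r_perm| >= |r_obs|}) / (B + 1). ``scheme="refit"`` instead
    shuffles the optimization-set pairing and refits the model under each
    permutation (a slower sensitivity variant). Degenerate holdout scores
    (zero variance) give p = 1 with a flag.
    """
    if n_perm < 1:
        raise ValueError("need at least 1 permutation")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    std_x = StandardizationParams.fit(X[opt_idx])
    std_y = StandardizationParams.fit(Y[opt_idx])
    Xo = std_x.apply(X[opt_idx])
    Yo = std_y.apply(Y[opt_idx])
    u, v, it, conv = _spls_weights(Xo.T @ Yo, hp.c_u, hp.c_v, hp.tol, hp.max_iter)
    t, s = Xo @ u, Yo @ v
    comp = SPLSComponent(
        u=u, v=v, t=t, s=s, latent_corr=_safe_corr(t, s), hyperparams=hp,
        n_iter=it, converged=conv,
    )
    Xh = std_x.apply(X[hold_idx])
    Yh = std_y.apply(Y[hold_idx])
    th, sh = Xh @ u, Yh @ v
    r_hold = _safe_corr(th, sh)
    degenerate = np.isnan(r_hold)
    if degenerate:
        p = 1.0
    elif scheme == "fixed":
        nh = len(th)
        tc = (th - th.mean()) / th.std()
        sc = (sh - sh.mean()) / sh.std()
        count = 0
        for _ in range(n_perm):
            count += abs(float(tc @ sc[rng.permutation(nh)]) / nh) >= abs(r_hold)
        p = (count + 1) / (n_perm + 1)
    elif scheme == "refit":
        no = len(opt_idx)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(no)
            up, vp, _, _ = _spls_weights(Xo.T @ Yo[perm], hp.c_u, hp.c_v, hp.tol, hp.max_iter)
            rp = _safe_corr(Xh @ up, Yh @ vp)
            count += (not np.isnan(rp)) and abs(rp) >= abs(r_hold)
        p = (count + 1) / (n_perm + 1)
    else:
        raise ValueError(f"unknown permutation scheme {scheme!r}")
    result = SplitResult(
        split=-1, dim=-1, hyperparams=hp,
        train_corr=comp.latent_corr, holdout_corr=r_hold, p_value=p,
        n_selected_physio=int(np.count_nonzero(v)),
        n_selected_morph=int(np.count_nonzero(u)),
        stability=np.nan, degenerate=degenerate,
    )
    return result, comp, std_x, std_y


@dataclass
class FrameworkResult:
    plan: SplitPlan
    results: list[list[SplitResult]]  # [split][dim]
    components: list[list[SPLSComponent]]
    standardizations: list[tuple[StandardizationParams, StandardizationParams]]
    omnibus_pass: bool
    optimal_split: int | None
    alpha: float
    omnibus_p: float = np.nan

    def table(self, dim: int = 1) -> pd.DataFrame:
        return framework_table(self, dim)


def _joint_omnibus_p(
    scores: list[tuple[np.ndarray, np.ndarray]],
    hold_sets: list[np.ndarray],
    n: int,
    n_perm: int,
    rng: np.random.Generator,
) -> float:
    """Joint max-|r| permutation test across the K holdouts.

    One global subject relabelling per draw induces a coherent permutation of
    every split's holdout pairing, so the null preserves the dependence from
    overlapping holdout subjects; the omnibus statistic is the largest
    holdout |correlation| across splits. Exactly calibrated where the
    Bonferroni min-p rule is conservative under dependence.
    """
    stats = []
    obs = -np.inf
    zs = []
    for (t, s) in scores:
        if t.std() == 0 or s.std() == 0:
            zs.append(None)
            continue
        tc = (t - t.mean()) / t.std()
        sc = (s - s.mean()) / s.std()
        zs.append((tc, sc))
        obs = max(obs, abs(float(tc @ sc) / len(tc)))
    if not np.isfinite(obs):
        return 1.0
    count = 0
    for _ in range(n_perm):
        pi = rng.permutation(n)
        t_max = 0.0
        for z, h in zip(zs, hold_sets):
            if z is None:
                continue
            tc, sc = z
            perm = np.argsort(pi[h], kind="stable")
            t_max = max(t_max, abs(float(tc @ sc[perm]) / len(tc)))
        count += t_max >= obs
    return (count + 1) / (n_perm + 1)


def run_framework(
    X: pd.DataFrame | np.ndarray,
    Y: pd.DataFrame | np.ndarray,
    plan: SplitPlan,
    grid: list[tuple[float, float]] | None = None,
    dims: int = 2,
    n_perm: int = 1000,
    alpha: float = 0.05,
    tol: float = 1e-6,
    max_iter: int = 500,
    omnibus: str = "joint",
) -> FrameworkResult:
    """Tune, refit and holdout-test each split, for ``dims`` latent dimensions.

    X is the morphometric block, Y the physiological block. The global
    (omnibus) null — no split shows a true association — is tested on the
    first dimension either by a joint max-|r| permutation test across the K
    holdouts (``omnibus="joint"``, default; exactly calibrated under the
    dependence induced by overlapping splits) or by the Bonferroni min-p rule
    (``omnibus="bonferroni"``: reject iff min p < alpha/K, which is
    conservative under that dependence). p-values are additionally BH-adjusted
    across splits per dimension. The optimal split is the BH-significant split
    with the best rank-sum of holdout correlation and tuning stability.
    """
    Xa = X.to_numpy(float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    Ya = Y.to_numpy(float) if isinstance(Y, pd.DataFrame) else np.asarray(Y, float)
    if Xa.shape[0] != Ya.shape[0] or Xa.shape[0] != plan.n:
        raise ValueError("blocks and split plan must agree on the number of subjects")
    if grid is None:
        grid = default_grid(Xa.shape[1], Ya.shape[1])
    ss = np.random.SeedSequence(plan.seed)
    child_seeds = ss.spawn(plan.n_splits * dims + 1)
    holdout_scores: list[tuple[np.ndarray, np.ndarray]] = []
    results: list[list[SplitResult]] = []
    components: list[list[SPLSComponent]] = []
    standardizations = []
    for k, (opt_idx, hold_idx) in enumerate(plan.outer):
        split_results, split_comps = [], []
        Xk, Yk = Xa, Ya
        for d in range(dims):
            rng = np.random.default_rng(child_seeds[k * dims + d])
            hp, diag = tune_hyperparameters(
                Xk, Yk, grid, plan.inner[k], tol=tol, max_iter=max_iter
            )
            res, comp, std_x, std_y = evaluate_split(
                Xk, Yk, opt_idx, hold_idx, hp, n_perm=n_perm, seed=rng
            )
            res.split, res.dim = k, d + 1
            res.stability = diag["chosen_stability"]
            split_results.append(res)
            split_comps.append(comp)
            if d == 0:
                standardizations.append((std_x, std_y))
                holdout_scores.append(
                    (std_x.apply(Xk[hold_idx]) @ comp.u, std_y.apply(Yk[hold_idx]) @ comp.v)
                )
            if d + 1 < dims:
                # carry deflated standardized blocks into the next dimension
                Xs = std_x.apply(Xk)
                Ys = std_y.apply(Yk)
                Xk, Yk = deflate(Xs, Ys, comp)
        results.append(split_results)
        components.append(split_comps)
    for d in range(dims):
        ps = np.array([results[k][d].p_value for k in range(plan.n_splits)])
        adj = bh_adjusted(ps)
        for k in range(plan.n_splits):
            results[k][d].p_adjusted = float(adj[k])
    p1 = np.array([results[k][0].p_value for k in range(plan.n_splits)])
    if omnibus == "joint":
        omnibus_p = _joint_omnibus_p(
            holdout_scores,
            [hold for _, hold in plan.outer],
            plan.n,
            n_perm,
            np.random.default_rng(child_seeds[-1]),
        )
        omnibus_pass = bool(omnibus_p < alpha)
    elif omnibus == "bonferroni":
        omnibus_p = float(min(p1.min() * plan.n_splits, 1.0))
        omnibus_pass = bool(p1.min() < alpha / plan.n_splits)
    else:
        raise ValueError(f"unknown omnibus rule {omnibus!r}")
    sig = [k for k in range(plan.n_splits) if results[k][0].p_adjusted <= alpha]
    optimal = None
    if sig:
        from scipy.stats import rankdata

        corr = np.array([results[k][0].holdout_corr for k in sig])
        stab = np.array([results[k][0].stability for k in sig])
        ranks = rankdata(-corr, method="average") + rankdata(-stab, method="average")
        optimal = sig[int(np.argmin(ranks))]
    return FrameworkResult(
        plan=plan, results=results, components=components,
        standardizations=standardizations, omnibus_pass=omnibus_pass,
        optimal_split=optimal, alpha=alpha, omnibus_p=omnibus_p,
    )


def framework_table(fr: FrameworkResult, dim: int = 1) -> pd.DataFrame:
    """The per-split report (Table-2 layout) for one latent dimension."""
    rows = []
    for k in range(fr.plan.n_splits):
        r = fr.results[k][dim - 1]
        rows.append(
            {
                "split": k + 1,
                "train_corr": r.train_corr,
                "holdout_corr": r.holdout_corr,
                "p_value": r.p_value,
                "n_physio_selected": r.n_selected_physio,
                "n_morph_selected": r.n_selected_morph,
                "bh_adjusted_p": r.p_adjusted,
            }
        )
    return pd.DataFrame(rows)
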