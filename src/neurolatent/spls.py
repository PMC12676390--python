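"""Sparse partial least squares: paired L1-constrained unit weight vectors.

One component maximizes the cross-block covariance cov(Xu, Yv) subject to
||u||2 = ||v||2 = 1 and L1 budgets ||u||1 <= c_u, ||v||1 <= c_v (the penalized
matrix decomposition form): alternating soft-threshold updates from a leading
singular-vector start. Scores, projection deflation, standardization learned on
training data, and a plain-text component artifact round out the module.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SPLSHyperparams",
    "SPLSComponent",
    "StandardizationParams",
    "l1_unit_projection",
    "fit_spls_component",
    "deflate",
    "transform_scores",
    "component_to_text",
    "component_from_text",
]


@dataclass(frozen=True)
class SPLSHyperparams:
    """L1 budgets in [1, sqrt(dim)] per block plus iteration controls."""

    c_u: float
    c_v: float
    max_iter: int = 500
    tol: float = 1e-6

    def __post_init__(self):
        if self.c_u < 1 or self.c_v < 1:
            raise ValueError("L1 budgets must be at least 1")
        if self.tol <= 0:
            raise ValueError("tolerance must be positive")


@dataclass
class StandardizationParams:
    """Per-feature mean/SD learned on a training set; NaNs are mean-imputed."""

    mean: np.ndarray
    sd: np.ndarray
    columns: list[str]
    zero_variance: list[str] = field(default_factory=list)

    @classmethod
    def fit(cls, X: pd.DataFrame | np.ndarray, columns=None) -> "StandardizationParams":
        if isinstance(X, pd.DataFrame):
            columns = list(X.columns)
            M = X.to_numpy(float)
        else:
            M = np.asarray(X, float)
            columns = list(columns) if columns is not None else [f"x{i}" for i in range(M.shape[1])]
        mean = np.nanmean(M, axis=0)
        filled = np.where(np.isnan(M), mean, M)
        sd = filled.std(axis=0, ddof=1)
        zero = [c for c, s in zip(columns, sd) if not s > 0]
        sd = np.where(sd > 0, sd, 1.0)
        return cls(mean=mean, sd=sd, columns=columns, zero_variance=zero)

    def apply(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = [c for c in self.columns if c not in X.columns]
            if missing:
                raise ValueError(f"features missing relative to training: {missing}")
            M = X[self.columns].to_numpy(float)
        else:
            M = np.asarray(X, float)
        M = np.where(np.isnan(M), self.mean, M)
        return (M - self.mean) / self.sd


@dataclass
class SPLSComponent:
    """Fitted component: unit-norm sparse weights, training scores, diagnostics."""

    u: np.ndarray
    v: np.ndarray
    t: np.ndarray
    s: np.ndarray
    latent_corr: float
    hyperparams: SPLSHyperparams
    n_iter: int
    converged: bool
    x_names: list[str] | None = None
    y_names: list[str] | None = None
    sign_flipped: bool = False


def _ratio(a_shr: np.ndarray) -> float:
    nrm2 = np.sqrt((a_shr**2).sum())
    return a_shr.sum() / nrm2 if nrm2 > 0 else np.inf


def _project_exact(w: np.ndarray, c: float) -> np.ndarray:
    """Exact soft-threshold level for ||.||1/||.||2 = c via sorted-support roots."""
    a = np.sort(np.abs(w))[::-1]
    p = a.size
    A = np.cumsum(a)
    B = np.cumsum(a * a)
    # ratio at the lower end of each support-k interval (lambda = a[k], support k)
    bounds = np.empty(p)
    bounds[: p - 1] = a[1:]
    bounds[p - 1] = 0.0
    ks = np.arange(1, p + 1)
    l1 = A - ks * bounds
    l2sq = np.maximum(B - 2 * bounds * A + ks * bounds * bounds, 0.0)
    safe = l2sq > 0
    g = np.ones(p)
    g[safe] = l1[safe] / np.sqrt(l2sq[safe])
    hit = g >= c
    k_idx = int(np.argmax(hit)) if hit.any() else p - 1
    k = k_idx + 1
    Ak, Bk = A[k_idx], B[k_idx]
    alpha = k * (k - c**2)
    beta = 2 * Ak * (c**2 - k)
    gamma = Ak**2 - c**2 * Bk
    lo = bounds[k_idx]
    hi = a[k_idx]
    if abs(alpha) < 1e-12 * max(1.0, k**2):
        lam = -gamma / beta if abs(beta) > 0 else 0.5 * (lo + hi)
    else:
        disc = max(beta**2 - 4 * alpha * gamma, 0.0)
        roots = ((-beta + np.sqrt(disc)) / (2 * alpha), (-beta - np.sqrt(disc)) / (2 * alpha))
        inside = [r for r in roots if lo - 1e-12 <= r <= hi + 1e-12]
        lam = inside[0] if inside else min(max(roots[0], lo), hi)
    lam = min(max(lam, 0.0), hi * (1 - 1e-15))
    return np.sign(w) * np.maximum(np.abs(w) - lam, 0.0)


def _project_bisect(w: np.ndarray, c: float, iters: int = 100) -> np.ndarray:
    """Reference bisection on the soft-threshold level."""
    a = np.abs(w)
    lo, hi = 0.0, a.max()
    for _ in range(iters):
        lam = 0.5 * (lo + hi)
        shr = np.maximum(a - lam, 0.0)
        if shr.sum() == 0 or _ratio(shr) < c:
            hi = lam
        else:
            lo = lam
    shr = np.maximum(a - lo, 0.0)
    return np.sign(w) * shr


def l1_unit_projection(w: np.ndarray, c: float, method: str = "exact") -> np.ndarray:
    """Soft-threshold ``w`` so the L2-normalized result has L1 norm <= c.

    The shrinkage level solves ||S(w, l)||1 / ||S(w, l)||2 = c exactly when the
    constraint is active (c below the input's own ratio) and is 0 otherwise.
    ``c`` must lie in [1, sqrt(dim)]; c = 1 returns a one-hot vector at the
    largest-|w| coordinate and c >= sqrt(dim) returns w / ||w||2.
    """
    w = np.asarray(w, dtype=float)
    l1 = np.abs(w).sum()
    if l1 == 0:
        raise ValueError("cannot project an all-zero vector")
    if not (1.0 <= c <= np.sqrt(w.size) + 1e-9):
        raise ValueError(f"L1 budget {c} outside [1, sqrt({w.size})]")
    nrm = np.sqrt(w @ w)
    if l1 / nrm <= c:
        return w / nrm
    shr = _project_exact(w, c) if method == "exact" else _project_bisect(w, c)
    if not np.any(shr):  # tie at the maximum: fall back to a one-hot
        shr = np.zeros_like(w)
        i = int(np.argmax(np.abs(w)))
        shr[i] = w[i]
    return shr / np.linalg.norm(shr)


def _leading_right_singular(C: np.ndarray) -> np.ndarray:
    _, _, vt = np.linalg.svd(C, full_matrices=False)
    return vt[0]


def _spls_weights(
    C: np.ndarray,
    c_u: float,
    c_v: float,
    tol: float = 1e-6,
    max_iter: int = 500,
    v0: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, int, bool]:
    """Alternating updates on the cross-product matrix C = X'Y."""
    v = _leading_right_singular(C) if v0 is None else v0
    u = None
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        u_new = l1_unit_projection(C @ v, c_u)
        v_new = l1_unit_projection(C.T @ u_new, c_v)
        delta = (
            np.inf
            if u is None
            else max(np.abs(u_new - u).max(), np.abs(v_new - v).max())
        )
        u, v = u_new, v_new
        if delta < tol:
            converged = True
            break
    # deterministic sign: largest-|v| entry positive, u flipped jointly
    i = int(np.argmax(np.abs(v)))
    if v[i] < 0:
        u, v = -u, -v
    return u, v, it, converged


def fit_spls_component(
    X: np.ndarray | pd.DataFrame,
    Y: np.ndarray | pd.DataFrame,
    hp: SPLSHyperparams,
    variant: str = "pls",
    init_seed: int | None = None,
) -> SPLSComponent:
    """Fit one sparse component on standardized blocks (same subjects, no NaN).

    Initialization is the leading right singular vector of X'Y (deterministic);
    ``init_seed`` switches to a seeded random start for sensitivity analysis.
    Non-convergence at ``max_iter`` is flagged on the result, not raised. Only
    the covariance-maximizing ``variant="pls"`` is implemented; the
    correlation-maximizing CCA variant is a reserved flag.
    """
    if variant == "cca":
        raise NotImplementedError(
            "the correlation-maximizing (CCA) variant is a reserved flag; "
            "only covariance-maximizing sparse PLS is implemented"
        )
    if variant != "pls":
        raise ValueError(f"unknown variant {variant!r}")
    x_names = list(X.columns) if isinstance(X, pd.DataFrame) else None
    y_names = list(Y.columns) if isinstance(Y, pd.DataFrame) else None
    Xa = np.asarray(X, float)
    Ya = np.asarray(Y, float)
    if Xa.shape[0] != Ya.shape[0]:
        raise ValueError("X and Y must have the same subjects")
    if np.isnan(Xa).any() or np.isnan(Ya).any():
        raise ValueError("NaNs must be imputed/removed before fitting")
    if not (hp.c_u <= np.sqrt(Xa.shape[1]) + 1e-9 and hp.c_v <= np.sqrt(Ya.shape[1]) + 1e-9):
        raise ValueError("L1 budgets exceed sqrt(block dimension)")
    C = Xa.T @ Ya
    v0 = None
    if init_seed is not None:
        v0 = np.random.default_rng(init_seed).standard_normal(Ya.shape[1])
        v0 /= np.linalg.norm(v0)
    u, v, it, conv = _spls_weights(C, hp.c_u, hp.c_v, hp.tol, hp.max_iter, v0=v0)
    t = Xa @ u
    s = Ya @ v
    if t.std() > 0 and s.std() > 0:
        corr = float(np.corrcoef(t, s)[0, 1])
    else:
        corr = np.nan
    flipped = bool(v[int(np.argmax(np.abs(v)))] < 0)
    return SPLSComponent(
        u=u, v=v, t=t, s=s, latent_corr=corr, hyperparams=hp,
        n_iter=it, converged=conv, x_names=x_names, y_names=y_names,
        sign_flipped=flipped,
    )


def deflate(
    X: np.ndarray, Y: np.ndarray, comp: SPLSComponent
) -> tuple[np.ndarray, np.ndarray]:
    """Projection deflation: remove each block's component direction.

    X' = X - (Xu)u', Y' = Y - (Yv)v'; the deflated covariance along (u, v) is 0
    and repeating the deflation is idempotent.
    """
    Xa = np.asarray(X, float)
    Ya = np.asarray(Y, float)
    if Xa.shape[1] != comp.u.size or Ya.shape[1] != comp.v.size:
        raise ValueError("component dimensions do not match the blocks")
    Xd = Xa - np.outer(Xa @ comp.u, comp.u)
    Yd = Ya - np.outer(Ya @ comp.v, comp.v)
    return Xd, Yd


def transform_scores(
    X_new: pd.DataFrame | np.ndarray,
    Y_new: pd.DataFrame | np.ndarray,
    comp: SPLSComponent,
    std_x: StandardizationParams | None = None,
    std_y: StandardizationParams | None = None,
    n_perm: int = 0,
    seed: int | np.random.Generator = 0,
) -> dict:
    """Project new subjects with training standardization; optional permutation p.

    Returns ``{"t", "s", "corr"}`` plus ``"p"`` when ``n_perm > 0`` (add-one
    corrected, two-sided on |corr|, fixed weights).
    """
    Xs = std_x.apply(X_new) if std_x is not None else np.asarray(X_new, float)
    Ys = std_y.apply(Y_new) if std_y is not None else np.asarray(Y_new, float)
    t = Xs @ comp.u
    s = Ys @ comp.v
    if t.std() > 0 and s.std() > 0:
        corr = float(np.corrcoef(t, s)[0, 1])
    else:
        corr = np.nan
    out = {"t": t, "s": s, "corr": corr}
    if n_perm > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        if np.isnan(corr):
            out["p"] = 1.0
        else:
            count = 0
            tc = (t - t.mean()) / t.std()
            sc = (s - s.mean()) / s.std()
            n = len(t)
            for _ in range(n_perm):
                r = float(tc @ sc[rng.permutation(n)]) / n
                count += abs(r) >= abs(corr)
            out["p"] = (count + 1) / (n_perm + 1)
    return out


# ---------------------------------------------------------------------------
# plain-text component artifact
# ---------------------------------------------------------------------------

def component_to_text(
    comp: SPLSComponent,
    std_x: StandardizationParams,
    std_y: StandardizationParams,
    path: str | Path | None = None,
    meta: dict | None = None,
) -> str:
    """Serialize weights + standardization constants as a commented TSV."""
    def fmt(x) -> str:
        return f"{float(x):.17g}"

    lines = ["# neurolatent spls component v1"]
    lines.append(f"# c_u={fmt(comp.hyperparams.c_u)}\tc_v={fmt(comp.hyperparams.c_v)}")
    lines.append(f"# latent_corr={fmt(comp.latent_corr)}\tn_iter={comp.n_iter}\tconverged={comp.converged}")
    for k, val in (meta or {}).items():
        lines.append(f"# {k}={val}")
    lines.append("feature\tblock\tweight\tmean\tsd")
    x_names = comp.x_names or std_x.columns
    y_names = comp.y_names or std_y.columns
    for name, wt, mu, sd in zip(x_names, comp.u, std_x.mean, std_x.sd):
        lines.append(f"{name}\tX\t{fmt(wt)}\t{fmt(mu)}\t{fmt(sd)}")
    for name, wt, mu, sd in zip(y_names, comp.v, std_y.mean, std_y.sd):
        lines.append(f"{name}\tY\t{fmt(wt)}\t{fmt(mu)}\t{fmt(sd)}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def component_from_text(
    source: str | Path,
) -> tuple[SPLSComponent, StandardizationParams, StandardizationParams]:
    """Load a serialized component; scores are not stored and come back empty."""
    text = Path(source).read_text() if isinstance(source, Path) or "\n" not in str(source) else str(source)
    header: dict[str, str] = {}
    rows = []
    for line in text.splitlines():
        if line.startswith("#"):
            for part in line.lstrip("# ").split("\t"):
                if "=" in part:
                    k, _, val = part.partition("=")
                    header[k.strip()] = val
            continue
        if line.strip():
            rows.append(line.split("\t"))
    cols = rows[0]
    df = pd.DataFrame(rows[1:], columns=cols)
    for c in ("weight", "mean", "sd"):
        df[c] = df[c].astype(float)
    xb = df[df["block"] == "X"]
    yb = df[df["block"] == "Y"]
    hp = SPLSHyperparams(c_u=float(header["c_u"]), c_v=float(header["c_v"]))
    std_x = StandardizationParams(xb["mean"].to_numpy(), xb["sd"].to_numpy(), xb["feature"].tolist())
    std_y = StandardizationParams(yb["mean"].to_numpy(), yb["sd"].to_numpy(), yb["feature"].tolist())
    comp = SPLSComponent(
        u=xb["weight"].to_numpy(), v=yb["weight"].to_numpy(),
        t=np.empty(0), s=np.empty(0),
        latent_corr=float(header.get("latent_corr", "nan")),
        hyperparams=hp,
        n_iter=int(header.get("n_iter", 0)),
        converged=header.get("converged", "True") == "True",
        x_names=xb["feature"].tolist(), y_names=yb["feature"].tolist(),
    )
    return comp, std_x, std_y
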