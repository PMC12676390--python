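"""End-to-end orchestration: synthetic cohort -> screen -> latent model -> reports.

A run directory is fully determined by its :class:`RunConfig` (one master seed
fans out to fixed per-stage seeds), contains only delimited-text artifacts, and
carries a manifest with the config hash for reproducibility checks.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .downstream import partial_correlation_matrix, stepwise_aic_regression, transfer_to_cohort
from .holdout import framework_table, make_split_plan, run_framework
from .morph import screening_columns, write_feature_table
from .pairwise import run_screen, screen_long_table
from .spls import component_to_text
from .synth import LatentCohortConfig, simulate_feature_cohort

__all__ = ["RunConfig", "run_end_to_end", "write_report"]

# fixed per-stage seed offsets fanned out from the master seed
_STAGE_OFFSET = {"cohort": 11, "screen": 23, "framework": 37, "transfer": 53, "external": 71}


@dataclass
class RunConfig:
    """Validated configuration for one synthetic end-to-end run."""

    seed: int = 0
    out_dir: str = "run"
    # cohort
    n_subjects: int = 60
    p_physio: int = 84
    q_morph: int = 36
    support_u: int = 5
    support_v: int = 4
    rho_true: float = 0.7
    noise_sd: float = 0.5
    confound_age: float = 0.0
    confound_updrs: float = 0.0
    confound_years: float = 0.0
    # screen
    screen_n_perm: int = 200
    alpha: float = 0.05
    # framework
    n_splits: int = 5
    n_inner: int = 10
    holdout_frac: float = 0.2
    val_frac: float = 0.2
    framework_n_perm: int = 200
    grid_points: int = 4
    dims: int = 2
    # external (specificity control) cohort
    external_n: int = 24
    external_rho: float = 0.0

    def validate(self) -> None:
        if self.n_subjects < 10:
            raise ValueError("n_subjects must be at least 10")
        if not (0 < self.holdout_frac < 1 and 0 < self.val_frac < 1):
            raise ValueError("split fractions must lie in (0, 1)")
        LatentCohortConfig(
            n_subjects=self.n_subjects, p_physio=self.p_physio, q_morph=self.q_morph,
            support_u=self.support_u, support_v=self.support_v,
            rho_true=self.rho_true, noise_sd=self.noise_sd,
        ).validate()
        if self.dims < 1 or self.grid_points < 1:
            raise ValueError("dims and grid_points must be positive")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _cohort_cfg(cfg: RunConfig, seed: int, n: int | None = None, rho: float | None = None) -> LatentCohortConfig:
    return LatentCohortConfig(
        n_subjects=n if n is not None else cfg.n_subjects,
        p_physio=cfg.p_physio, q_morph=cfg.q_morph,
        support_u=cfg.support_u, support_v=cfg.support_v,
        rho_true=rho if rho is not None else cfg.rho_true,
        noise_sd=cfg.noise_sd,
        confound_age=cfg.confound_age, confound_updrs=cfg.confound_updrs,
        confound_years=cfg.confound_years, seed=seed,
    )


def run_end_to_end(cfg: RunConfig) -> Path:
    """Execute the full synthetic pipeline; idempotent per seed.

    Writes the cohort tables, the pairwise screen, the per-split latent-model
    report with weight artifacts, the downstream confound/biomarker tables, the
    specificity transfer and a manifest. Stage failures abort with the stage
    named in the exception.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name):
        def wrap(fn, *a, **kw):
            try:
                return fn(*a, **kw)
            except Exception as exc:  # pragma: no cover - defensive
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        return wrap

    physio, morph, covars, truth = stage("cohort")(
        simulate_feature_cohort, _cohort_cfg(cfg, cfg.seed + _STAGE_OFFSET["cohort"])
    )
    write_feature_table(physio, out / "physio.tsv")
    write_feature_table(morph, out / "morph.tsv")
    covars.to_csv(out / "covars.tsv", sep="\t", float_format="%.10g")

    scr_cols = screening_columns(morph.columns)
    morph_screen = morph[scr_cols] if scr_cols else morph
    screen = stage("screen")(
        run_screen, morph_screen, physio,
        n_perm=cfg.screen_n_perm, seed=cfg.seed + _STAGE_OFFSET["screen"], alpha=cfg.alpha,
    )
    screen.r.to_csv(out / "screen_r.tsv", sep="\t", float_format="%.10g")
    screen.p.to_csv(out / "screen_p.tsv", sep="\t", float_format="%.10g")
    screen_long_table(screen).to_csv(out / "screen_long.tsv", sep="\t", index=False, float_format="%.10g")

    plan = make_split_plan(
        cfg.n_subjects, n_splits=cfg.n_splits, holdout_frac=cfg.holdout_frac,
        n_inner=cfg.n_inner, val_frac=cfg.val_frac,
        seed=cfg.seed + _STAGE_OFFSET["framework"],
    )
    from .holdout import default_grid

    grid = default_grid(morph.shape[1], physio.shape[1], cfg.grid_points)
    fr = stage("framework")(
        run_framework, morph, physio, plan, grid=grid, dims=cfg.dims,
        n_perm=cfg.framework_n_perm, alpha=cfg.alpha,
    )
    for d in range(1, cfg.dims + 1):
        framework_table(fr, d).to_csv(
            out / f"table2_dim{d}.tsv", sep="\t", index=False, float_format="%.10g"
        )
    (out / "table2.tsv").write_text((out / "table2_dim1.tsv").read_text())
    for k in range(plan.n_splits):
        comp = fr.components[k][0]
        comp.x_names = list(morph.columns)
        comp.y_names = list(physio.columns)
        std_x, std_y = fr.standardizations[k]
        std_x.columns = list(morph.columns)
        std_y.columns = list(physio.columns)
        component_to_text(
            comp, std_x, std_y, out / f"weights_split{k + 1}.txt",
            meta={"split": k + 1, "seed": cfg.seed},
        )

    downstream: dict = {
        "omnibus_pass": fr.omnibus_pass,
        "omnibus_p": fr.omnibus_p,
        "optimal_split": fr.optimal_split,
    }
    report_split = fr.optimal_split
    if report_split is None:
        # no BH-significant split: report the min-p split, flagged exploratory
        report_split = int(np.argmin([fr.results[k][0].p_value for k in range(plan.n_splits)]))
        downstream["exploratory"] = True
    comp = fr.components[report_split][0]
    std_x, std_y = fr.standardizations[report_split]
    t_all = std_x.apply(morph.to_numpy(float)) @ comp.u
    s_all = std_y.apply(physio.to_numpy(float)) @ comp.v
    scores = pd.DataFrame(
        {"morph_score": t_all, "physio_score": s_all}, index=morph.index
    )
    scores.to_csv(out / "latent_scores.tsv", sep="\t", float_format="%.10g")

    ptab = pd.concat(
        [scores, covars[["updrs_iii", "years_since_diagnosis", "age"]]], axis=1
    )
    partial = stage("partial")(partial_correlation_matrix, ptab, cfg.alpha)
    partial["r"].to_csv(out / "partial_corr_r.tsv", sep="\t", float_format="%.10g")
    partial["p_adjusted"].to_csv(out / "partial_corr_p.tsv", sep="\t", float_format="%.10g")

    for block, table, weights in (
        ("physio", physio, pd.Series(comp.v, index=physio.columns)),
        ("morph", morph, pd.Series(comp.u, index=morph.columns)),
    ):
        model = stage("stepwise")(
            stepwise_aic_regression, covars["updrs_iii"], table, weights
        )
        pd.DataFrame(
            {"coefficient": model.coefficients}
        ).to_csv(out / f"stepwise_{block}.tsv", sep="\t", float_format="%.10g")
        downstream[f"stepwise_{block}"] = {
            "selected": model.selected,
            "r_squared": model.r_squared,
            "f_pvalue": model.f_pvalue,
        }

    ext_physio, ext_morph, _, _ = simulate_feature_cohort(
        _cohort_cfg(cfg, cfg.seed + _STAGE_OFFSET["external"], n=cfg.external_n, rho=cfg.external_rho)
    )
    transfer = stage("transfer")(
        transfer_to_cohort, comp, std_x, std_y, ext_morph, ext_physio,
        n_perm=cfg.framework_n_perm, seed=cfg.seed + _STAGE_OFFSET["transfer"],
    )
    downstream["transfer"] = {"corr": transfer["corr"], "p": transfer["p"], "n": cfg.external_n}
    (out / "downstream.json").write_text(json.dumps(downstream, indent=2, default=str) + "\n")

    manifest = {
        "package": "neurolatent",
        "version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": cfg.seed,
        "config": asdict(cfg),
        "config_hash": cfg.config_hash(),
        "stage_seeds": {k: cfg.seed + v for k, v in _STAGE_OFFSET.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return out


_EXPECTED = [
    "physio.tsv", "morph.tsv", "covars.tsv", "screen_r.tsv", "screen_p.tsv",
    "table2.tsv", "latent_scores.tsv", "partial_corr_r.tsv", "downstream.json",
    "manifest.json",
]


def write_report(run_dir: str | Path) -> str:
    """Human-readable summary of a completed run; errors list missing artifacts."""
    run_dir = Path(run_dir)
    missing = [f for f in _EXPECTED if not (run_dir / f).exists()]
    if missing:
        raise FileNotFoundError(f"incomplete run at {run_dir}: missing {missing}")
    manifest = json.loads((run_dir / "manifest.json").read_text())
    downstream = json.loads((run_dir / "downstream.json").read_text())
    table2 = pd.read_csv(run_dir / "table2.tsv", sep="\t")
    lines = [
        "neurolatent run report",
        "======================",
        f"config hash: {manifest['config_hash']}  seed: {manifest['seed']}",
        "",
        "Per-split latent model (dimension 1):",
        table2.to_string(index=False, float_format=lambda x: f"{x:.4f}"),
        "",
        f"omnibus pass: {downstream['omnibus_pass']}",
        f"optimal split: {downstream['optimal_split']}",
    ]
    if downstream.get("exploratory"):
        lines.append("NOTE: no BH-significant split; downstream tables use the min-p split.")
    for block in ("physio", "morph"):
        sw = downstream.get(f"stepwise_{block}")
        if sw:
            lines.append(
                f"stepwise {block}: r2={float(sw['r_squared']):.3f} "
                f"p={float(sw['f_pvalue']):.4g} selected={sw['selected']}"
            )
    tr = downstream.get("transfer")
    if tr:
        lines.append(
            f"external transfer (n={tr['n']}): corr={float(tr['corr']):.3f} p={float(tr['p']):.4g}"
        )
    else:
        lines.append("external transfer: absent")
    text = "\n".join(lines) + "\n"
    (run_dir / "report.txt").write_text(text)
    return text
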