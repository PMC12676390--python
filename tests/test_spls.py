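"""Sparse-PLS core: L1 projection, alternating fit, deflation, transforms."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from neurolatent.spls import (
    SPLSHyperparams,
    StandardizationParams,
    component_from_text,
    component_to_text,
    deflate,
    fit_spls_component,
    l1_unit_projection,
    transform_scores,
)
from neurolatent.synth import LatentCohortConfig, simulate_feature_cohort

from conftest import jaccard


def brute_force_projection(w, c, n_grid=4_000_001):
    """Dense lambda-grid oracle for the soft-threshold projection."""
    a = np.abs(w)
    best, best_gap = None, np.inf
    for lam in np.linspace(0, a.max() * (1 - 1e-12), 2001):
        shr = np.sign(w) * np.maximum(a - lam, 0)
        nrm = np.linalg.norm(shr)
        if nrm == 0:
            continue
        unit = shr / nrm
        l1 = np.abs(unit).sum()
        gap = abs(l1 - c) if l1 > c else (c - l1) * 1e-3  # prefer active equality
        if l1 <= c + 1e-9 and gap < best_gap:
            best, best_gap = unit, gap
    return best


class TestL1Projection:
    def test_inactive_budget_returns_normalized(self, rng):
        w = rng.standard_normal(12)
        out = l1_unit_projection(w, np.sqrt(12))
        assert np.allclose(out, w / np.linalg.norm(w))

    def test_budget_one_is_one_hot(self, rng):
        w = rng.standard_normal(9)
        out = l1_unit_projection(w, 1.0)
        assert np.count_nonzero(out) == 1
        assert out[np.argmax(np.abs(w))] == pytest.approx(np.sign(w[np.argmax(np.abs(w))]))

    def test_matches_bisection_oracle(self):
        w = np.array([3.0, 2.0, 1.0])
        exact = l1_unit_projection(w, 1.5, method="exact")
        bisect = l1_unit_projection(w, 1.5, method="bisect")
        assert np.allclose(exact, bisect, atol=1e-6)
        assert np.abs(exact).sum() == pytest.approx(1.5, abs=1e-9)
        ref = brute_force_projection(w, 1.5)
        assert np.allclose(exact, ref, atol=1e-3)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            l1_unit_projection(np.zeros(5), 1.5)

    @settings(max_examples=150, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000), st.integers(2, 40), st.floats(0.0, 1.0))
    def test_norm_invariants(self, seed, dim, cfrac):
        rng = np.random.default_rng(seed)
        w = rng.standard_normal(dim)
        c = 1.0 + cfrac * (np.sqrt(dim) - 1.0)
        out = l1_unit_projection(w, c)
        assert np.linalg.norm(out) == pytest.approx(1.0)
        assert np.abs(out).sum() <= c + 1e-8
        # equality when the constraint is active
        if np.abs(w).sum() / np.linalg.norm(w) > c:
            assert np.abs(out).sum() == pytest.approx(c, abs=1e-6)
        assert np.allclose(out, l1_unit_projection(w, c, method="bisect"), atol=1e-6)


def random_blocks(rng, n=30, p=6, q=5):
    return rng.standard_normal((n, p)), rng.standard_normal((n, q))


class TestFit:
    def test_svd_equivalence_when_unconstrained(self, rng):
        for _ in range(10):
            X, Y = random_blocks(rng)
            hp = SPLSHyperparams(c_u=np.sqrt(X.shape[1]), c_v=np.sqrt(Y.shape[1]))
            comp = fit_spls_component(X, Y, hp)
            U, S, Vt = np.linalg.svd(X.T @ Y)
            du = min(np.abs(comp.u - U[:, 0]).max(), np.abs(comp.u + U[:, 0]).max())
            dv = min(np.abs(comp.v - Vt[0]).max(), np.abs(comp.v + Vt[0]).max())
            assert du < 1e-6 and dv < 1e-6
            cov = (X @ comp.u) @ (Y @ comp.v)
            assert cov == pytest.approx(S[0], rel=1e-6)

    def test_single_shared_column(self, rng):
        x = rng.standard_normal(40)
        X = ((x - x.mean()) / x.std())[:, None]
        comp = fit_spls_component(X, X.copy(), SPLSHyperparams(1.0, 1.0))
        assert abs(comp.u[0]) == pytest.approx(1.0)
        assert comp.latent_corr == pytest.approx(1.0)

    def test_objective_monotone_over_iterations(self, rng):
        X, Y = random_blocks(rng, n=50, p=10, q=8)
        C = X.T @ Y
        _, _, vt = np.linalg.svd(C)
        v = vt[0]
        covs = []
        for _ in range(30):
            u = l1_unit_projection(C @ v, 1.8)
            v = l1_unit_projection(C.T @ u, 1.8)
            covs.append(u @ C @ v)
        assert all(b >= a - 1e-9 for a, b in zip(covs, covs[1:]))

    def test_sparsity_monotone_in_budget(self, rng):
        X, Y = random_blocks(rng, n=60, p=15, q=15)
        counts = []
        for c in (np.sqrt(15), 2.8, 2.0, 1.4, 1.0):
            comp = fit_spls_component(X, Y, SPLSHyperparams(c, c))
            counts.append(np.count_nonzero(comp.u))
        assert all(b <= a for a, b in zip(counts, counts[1:]))

    def test_sign_convention_deterministic(self, rng):
        X, Y = random_blocks(rng)
        hp = SPLSHyperparams(1.8, 1.8)
        c1 = fit_spls_component(X, Y, hp)
        c2 = fit_spls_component(X.copy(), Y.copy(), hp)
        assert np.array_equal(c1.u, c2.u) and np.array_equal(c1.v, c2.v)
        assert c1.v[np.argmax(np.abs(c1.v))] > 0

    def test_random_restart_reaches_same_optimum(self, rng):
        X, Y = random_blocks(rng, n=60)
        hp = SPLSHyperparams(1.8, 1.8)
        det = fit_spls_component(X, Y, hp)
        rand = fit_spls_component(X, Y, hp, init_seed=5)
        cov_det = (X @ det.u) @ (Y @ det.v)
        cov_rand = (X @ rand.u) @ (Y @ rand.v)
        assert cov_rand == pytest.approx(cov_det, rel=0.05)

    def test_cca_variant_is_reserved(self, rng):
        X, Y = random_blocks(rng)
        with pytest.raises(NotImplementedError):
            fit_spls_component(X, Y, SPLSHyperparams(1.5, 1.5), variant="cca")

    def test_nonconvergence_flagged_not_raised(self, rng):
        X, Y = random_blocks(rng)
        comp = fit_spls_component(X, Y, SPLSHyperparams(1.5, 1.5, max_iter=1))
        assert not comp.converged

    def test_planted_sparse_recovery_at_oracle_budget(self):
        # "oracle" budget: the truth-informed best L1 budget per seed
        jacs = []
        for seed in range(5):
            cfg = LatentCohortConfig(
                n_subjects=100, p_physio=30, q_morph=30, support_u=5, support_v=5,
                rho_true=0.7, noise_sd=0.5, seed=seed,
            )
            physio, morph, _, truth = simulate_feature_cohort(cfg)
            X = (physio - physio.mean()) / physio.std()
            Y = (morph - morph.mean()) / morph.std()
            best = 0.0
            for c in (1.5, 1.8, 2.0, np.sqrt(5)):
                comp = fit_spls_component(X, Y, SPLSHyperparams(c, c))
                best = max(best, jaccard(comp.u, truth.u_true))
            jacs.append(best)
        assert np.median(jacs) >= 0.8


class TestDeflate:
    def test_deflated_projection_is_zero(self, rng):
        X, Y = random_blocks(rng)
        comp = fit_spls_component(X, Y, SPLSHyperparams(1.8, 1.8))
        Xd, Yd = deflate(X, Y, comp)
        assert np.allclose(Xd @ comp.u, 0, atol=1e-12)
        assert np.allclose(Yd @ comp.v, 0, atol=1e-12)

    def test_idempotent(self, rng):
        X, Y = random_blocks(rng)
        comp = fit_spls_component(X, Y, SPLSHyperparams(2.0, 2.0))
        X1, Y1 = deflate(X, Y, comp)
        X2, Y2 = deflate(X1, Y1, comp)
        assert np.allclose(X1, X2) and np.allclose(Y1, Y2)

    def test_second_singular_pair_after_deflation(self, rng):
        X, Y = random_blocks(rng, n=60, p=7, q=6)
        hp = SPLSHyperparams(np.sqrt(7), np.sqrt(6))
        comp1 = fit_spls_component(X, Y, hp)
        Xd, Yd = deflate(X, Y, comp1)
        comp2 = fit_spls_component(Xd, Yd, hp)
        # the second component's covariance matches the second singular value
        s = np.linalg.svd(X.T @ Y, compute_uv=False)
        cov2 = (Xd @ comp2.u) @ (Yd @ comp2.v)
        assert cov2 == pytest.approx(s[1], rel=0.05)

    def test_dimension_mismatch(self, rng):
        X, Y = random_blocks(rng)
        comp = fit_spls_component(X, Y, SPLSHyperparams(1.5, 1.5))
        with pytest.raises(ValueError):
            deflate(X[:, :3], Y, comp)


class TestTransform:
    def test_training_scores_reproduced(self, rng):
        X, Y = random_blocks(rng)
        comp = fit_spls_component(X, Y, SPLSHyperparams(1.8, 1.8))
        out = transform_scores(X, Y, comp)
        assert np.allclose(out["t"], comp.t) and np.allclose(out["s"], comp.s)
        assert out["corr"] == pytest.approx(comp.latent_corr)

    def test_zero_weight_feature_irrelevant(self, rng):
        X, Y = random_blocks(rng, p=8)
        comp = fit_spls_component(X, Y, SPLSHyperparams(1.2, 1.5))
        zero_idx = np.flatnonzero(comp.u == 0)
        assert zero_idx.size > 0
        X2 = X.copy()
        X2[:, zero_idx[0]] = 999.0
        out = transform_scores(X2, Y, comp)
        assert np.allclose(out["t"], comp.t)

    def test_permutation_p_for_coupled_scores(self, rng):
        cfg = LatentCohortConfig(n_subjects=80, p_physio=20, q_morph=20,
                                 rho_true=0.9, noise_sd=0.3, seed=2)
        physio, morph, _, _ = simulate_feature_cohort(cfg)
        std_x = StandardizationParams.fit(physio)
        std_y = StandardizationParams.fit(morph)
        comp = fit_spls_component(std_x.apply(physio), std_y.apply(morph),
                                  SPLSHyperparams(2.0, 2.0))
        out = transform_scores(physio, morph, comp, std_x, std_y, n_perm=200, seed=1)
        assert out["p"] == pytest.approx(1 / 201)


class TestStandardization:
    def test_nan_mean_imputation(self):
        df = pd.DataFrame({"a": [1.0, np.nan, 3.0], "b": [2.0, 4.0, 6.0]})
        std = StandardizationParams.fit(df)
        Z = std.apply(df)
        assert not np.isnan(Z).any()
        assert std.mean[0] == pytest.approx(2.0)

    def test_zero_variance_recorded(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]})
        std = StandardizationParams.fit(df)
        assert std.zero_variance == ["a"]
        assert np.isfinite(std.apply(df)).all()

    def test_missing_feature_error_names_columns(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 4.0]})
        std = StandardizationParams.fit(df)
        with pytest.raises(ValueError, match="'b'"):
            std.apply(df[["a"]])


class TestSerialization:
    def test_round_trip(self, rng, tmp_path):
        X = pd.DataFrame(rng.standard_normal((30, 5)), columns=list("abcde"))
        Y = pd.DataFrame(rng.standard_normal((30, 4)), columns=list("wxyz"))
        std_x, std_y = StandardizationParams.fit(X), StandardizationParams.fit(Y)
        comp = fit_spls_component(std_x.apply(X), std_y.apply(Y), SPLSHyperparams(1.6, 1.4))
        comp.x_names, comp.y_names = list(X.columns), list(Y.columns)
        path = tmp_path / "component.txt"
        component_to_text(comp, std_x, std_y, path)
        back, bx, by = component_from_text(path)
        assert np.allclose(back.u, comp.u, atol=1e-15)
        assert np.allclose(back.v, comp.v, atol=1e-15)
        assert np.allclose(bx.mean, std_x.mean) and np.allclose(by.sd, std_y.sd)
        assert back.x_names == list(X.columns)
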