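import numpy as np
import pytest
import scipy.linalg as la

from pncca import (
    PnccaConfig,
    PnccaModel,
    apply_model,
    deflate_y,
    fit_canonical_pair,
    penalty_for_support,
    ust,
    wls_backfit,
)
from pncca.core import EmptyModelError, InfeasibleSupportError, _standardize_codes


def classical_first_rho(X, Y, ridge=0.0):
    """First canonical correlation from the generalized eigenproblem."""
    X = X - X.mean(0)
    Y = Y - Y.mean(0)
    n = len(X)
    Sxx = X.T @ X / n + ridge * np.eye(X.shape[1])
    Syy = Y.T @ Y / n + ridge * np.eye(Y.shape[1])
    Sxy = X.T @ Y / n
    M = la.solve(Sxx, Sxy) @ la.solve(Syy, Sxy.T)
    return float(np.sqrt(np.max(la.eigvals(M).real)))


class TestUst:
    def test_soft_threshold_arithmetic(self):
        v = ust(np.array([0.9, -0.5, 0.1]), 0.4)
        np.testing.assert_allclose(v, [0.5, -0.1, 0.0])

    def test_zero_penalty_keeps_scores(self):
        s = np.array([0.3, -0.2, 0.7])
        np.testing.assert_allclose(ust(s, 0.0), s)

    def test_full_shrinkage_signals_empty_model(self):
        with pytest.raises(EmptyModelError):
            ust(np.array([0.3, -0.2]), 0.35)

    def test_support_monotone_in_lambda(self, rng):
        s = rng.standard_normal(50)
        sizes = [np.count_nonzero(ust(s, lam)) for lam in np.linspace(0, np.abs(s).max() * 0.99, 20)]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))


class TestPenaltyForSupport:
    def test_order_statistic_midpoint(self):
        lam = penalty_for_support(np.array([0.9, 0.7, 0.3]), 2)
        assert lam == pytest.approx(0.5)
        assert np.count_nonzero(ust(np.array([0.9, 0.7, 0.3]), lam)) == 2

    def test_k_equals_q_selects_all(self):
        s = np.array([0.9, -0.7, 0.3])
        lam = penalty_for_support(s, 3)
        assert np.count_nonzero(ust(s, lam)) == 3

    def test_exact_support_for_distinct_scores(self, rng):
        for _ in range(100):
            s = rng.standard_normal(40)
            k = int(rng.integers(1, 41))
            lam = penalty_for_support(s, k)
            assert np.count_nonzero(ust(s, lam)) == k

    def test_infeasible_support_rejected(self):
        with pytest.raises(InfeasibleSupportError):
            penalty_for_support(np.array([0.5, 0.0, 0.0]), 2)


class TestBackfit:
    def test_orthonormal_design_single_sweep(self, rng):
        Q, _ = np.linalg.qr(rng.standard_normal((100, 5)))
        xi = rng.standard_normal(100)
        u, conv, it = wls_backfit(Q, xi, np.ones((100, 5)))
        np.testing.assert_allclose(u, Q.T @ xi, atol=1e-10)
        assert conv

    def test_equal_weights_match_ols(self, rng):
        Y = rng.standard_normal((200, 8))
        xi = rng.standard_normal(200)
        u, conv, _ = wls_backfit(Y, xi, np.ones((200, 8)))
        ref = np.linalg.lstsq(Y, xi, rcond=None)[0]
        np.testing.assert_allclose(u, ref, atol=1e-8)

    def test_zero_weight_subject_is_excluded(self, rng):
        Y = rng.standard_normal((80, 4))
        xi = rng.standard_normal(80)
        W = np.ones((80, 4))
        W[0] = 0.0
        u, *_ = wls_backfit(Y, xi, W)
        ref = np.linalg.lstsq(Y[1:], xi[1:], rcond=None)[0]
        np.testing.assert_allclose(u, ref, atol=1e-8)

    def test_large_standard_errors_downweight(self, rng):
        # a column measured badly for half the subjects pulls u_j toward
        # the well-measured half's fit
        n = 400
        Y = rng.standard_normal((n, 2))
        xi = Y[:, 0] + 0.1 * rng.standard_normal(n)
        xi[: n // 2] = -xi[: n // 2]  # first half contradicts
        W = np.ones((n, 2))
        W[: n // 2, 0] = 1e-6
        u, *_ = wls_backfit(Y, xi, W)
        ref = np.linalg.lstsq(Y[n // 2 :], xi[n // 2 :], rcond=None)[0]
        assert abs(u[0] - ref[0]) < 0.05


class TestFitCanonicalPair:
    def test_matches_classical_cca_small(self, rng):
        n, p, q = 500, 3, 5
        Z = rng.standard_normal((n, 2))
        Y = Z @ rng.standard_normal((2, p)) + rng.standard_normal((n, p))
        codes = rng.integers(0, 3, (n, q)).astype(np.int8)
        codes[:, 0] = np.clip(codes[:, 0] + (Z[:, 0] > 0), 0, 2)
        Ys = (Y - Y.mean(0)) / Y.std(0)
        cfg = PnccaConfig(n_snps=None, scaling="additive", tol=1e-9, max_iter=500)
        pair = fit_canonical_pair(codes, Ys, np.ones_like(Ys), cfg)
        ref = classical_first_rho(_standardize_codes(codes), Ys)
        assert pair.rho == pytest.approx(ref, abs=1e-6)

    def test_self_correlation_is_one(self, rng):
        # X block built so its additive coding spans the Y block
        codes = rng.integers(0, 3, (200, 4)).astype(np.int8)
        Ys = _standardize_codes(codes)
        cfg = PnccaConfig(n_snps=None, scaling="additive", tol=1e-9)
        pair = fit_canonical_pair(codes, Ys, np.ones_like(Ys), cfg)
        assert pair.rho == pytest.approx(1.0, abs=1e-8)

    def test_support_size_honoured_and_loadings_are_correlations(self, tiny_cohort, tiny_summaries):
        S = tiny_summaries
        Ys = ((S.values - S.values.mean()) / S.values.std(ddof=0)).to_numpy()
        pair = fit_canonical_pair(
            tiny_cohort["G"].codes, Ys, S.weights.to_numpy(), PnccaConfig(n_snps=3)
        )
        assert len(pair.support) == 3
        assert -1 <= pair.rho <= 1
        j = pair.support[0]
        xcol = pair.std_quants[j][tiny_cohort["G"].codes[:, j]]
        assert pair.x_loadings[int(j)] == pytest.approx(
            np.corrcoef(xcol, pair.xi)[0, 1], abs=1e-10
        )
        for m in range(Ys.shape[1]):
            assert pair.y_loadings[m] == pytest.approx(
                np.corrcoef(Ys[:, m], pair.omega)[0, 1], abs=1e-10
            )

    def test_sign_convention(self, tiny_cohort, tiny_summaries):
        S = tiny_summaries
        Ys = ((S.values - S.values.mean()) / S.values.std(ddof=0)).to_numpy()
        pair = fit_canonical_pair(
            tiny_cohort["G"].codes, Ys, S.weights.to_numpy(), PnccaConfig(n_snps=3)
        )
        assert pair.v[np.argmax(np.abs(pair.v))] > 0


class TestDeflation:
    def test_exact_multiple_removed(self, rng):
        omega = rng.standard_normal(100)
        omega = (omega - omega.mean()) / omega.std()
        Y = np.column_stack([2 * omega, rng.standard_normal(100)])
        Yr = deflate_y(Y, omega)
        np.testing.assert_allclose(Yr[:, 0], 0, atol=1e-12)

    def test_orthogonal_column_unchanged(self, rng):
        omega = rng.standard_normal(200)
        om = omega - omega.mean()
        y = rng.standard_normal(200)
        y -= om * (y @ om) / (om @ om)  # orthogonal to the centered variate
        Yr = deflate_y(np.column_stack([y]), omega)
        np.testing.assert_allclose(Yr[:, 0], y, atol=1e-8)

    def test_residual_correlations_vanish(self, rng):
        Y = rng.standard_normal((300, 6))
        omega = rng.standard_normal(300)
        Yr = deflate_y(Y, omega)
        om = omega - omega.mean()
        for j in range(6):
            c = np.corrcoef(Yr[:, j], om)[0, 1]
            assert abs(c) < 1e-10


class TestModel:
    def _fit(self, tiny_cohort, tiny_summaries, **kw):
        S = tiny_summaries
        cfg = PnccaConfig(n_snps=2, **kw)
        model = PnccaModel(
            config=cfg,
            y_columns=list(S.values.columns),
            snp_ids=list(tiny_cohort["G"].snp_ids),
        )
        model.fit(
            tiny_cohort["G"].codes, S.values.to_numpy(), S.weights.to_numpy(), n_pairs=2
        )
        return model

    def test_apply_on_training_data_reproduces_rho(self, tiny_cohort, tiny_summaries):
        model = self._fit(tiny_cohort, tiny_summaries)
        rhos = model.apply(tiny_cohort["G"].codes, tiny_summaries.values.to_numpy())
        assert rhos[0] == pytest.approx(model.pairs[0].rho, abs=1e-10)

    def test_second_pair_omega_orthogonal_to_first(self, tiny_cohort, tiny_summaries):
        model = self._fit(tiny_cohort, tiny_summaries)
        c = np.corrcoef(model.pairs[0].omega, model.pairs[1].omega)[0, 1]
        assert abs(c) < 1e-6

    def test_frozen_transformations_reused(self, tiny_cohort, tiny_summaries):
        model = self._fit(tiny_cohort, tiny_summaries, fix_transformations=True)
        for j in model.pairs[0].support:
            np.testing.assert_allclose(
                model.pairs[1].std_quants[int(j)],
                model.pairs[0].std_quants[int(j)],
                atol=0,
            )

    def test_serialization_roundtrip(self, tiny_cohort, tiny_summaries, tmp_path):
        model = self._fit(tiny_cohort, tiny_summaries)
        path = tmp_path / "model.json"
        model.to_json(path)
        loaded = PnccaModel.from_json(path)
        a = model.apply(tiny_cohort["G"].codes, tiny_summaries.values.to_numpy())
        b = loaded.apply(tiny_cohort["G"].codes, tiny_summaries.values.to_numpy())
        np.testing.assert_allclose(a, b, atol=0)
        assert loaded.to_json() == model.to_json()

    def test_same_seed_same_fit(self, tiny_cohort, tiny_summaries):
        a = self._fit(tiny_cohort, tiny_summaries, seed=5)
        b = self._fit(tiny_cohort, tiny_summaries, seed=5)
        assert a.to_json() == b.to_json()

    def test_apply_handles_unseen_category(self, tiny_cohort, tiny_summaries):
        model = self._fit(tiny_cohort, tiny_summaries)
        codes = tiny_cohort["G"].codes.copy()
        codes[0, model.pairs[0].support[0]] = 2  # possibly unseen in training
        rhos = model.apply(codes, tiny_summaries.values.to_numpy())
        assert np.isfinite(rhos).all()
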