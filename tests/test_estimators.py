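"""Penalized spline solver, smoothing selection, LOESS and hinge baseline.

The penalized solution is cross-checked against an augmented least-squares
oracle ([Phi; sqrt(lambda) C] with C'C = S solved by a generic dense solver),
GCV selection against exhaustive evaluation with an independently coded
score, K-fold selection against brute-force leave-one-out enumeration, and
LOESS against statsmodels' lowess.
"""

import io

import numpy as np
import pytest
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess

from fpboundary.basis import build_penalty, build_spline_spec, evaluate_basis, greville_abscissae
from fpboundary.estimators import (
    CrossingPairSet,
    IllPosedError,
    SingularSystemError,
    default_lambda_grid,
    gcv_select,
    hinge_threshold_fit,
    kfold_select,
    loess_fit,
    loess_span_select,
    penalized_fit,
)


def augmented_oracle(Phi, y, S, lam):
    """Solve the penalized problem as plain least squares on stacked rows."""
    w, V = np.linalg.eigh(S)
    w[w < 100 * np.finfo(float).eps * w.max()] = 0.0  # eigh noise on the null space
    C = np.sqrt(w)[:, None] * V.T  # C'C = S
    A = np.vstack([Phi, np.sqrt(lam) * C])
    b = np.concatenate([y, np.zeros(S.shape[0])])
    return np.linalg.lstsq(A, b, rcond=None)[0]


class TestPenalizedFit:
    def test_interpolates_representable_curve_at_lambda_zero(self, cubic_spec,
                                                             integral_penalty, rng):
        beta_true = rng.standard_normal(8)
        times = np.sort(rng.uniform(0, 1, 40))
        levels = evaluate_basis(cubic_spec, times) @ beta_true
        fit = penalized_fit(CrossingPairSet(times, levels), cubic_spec,
                            integral_penalty, 0.0)
        assert fit.rss == pytest.approx(0.0, abs=1e-16)
        grid = np.linspace(0, 1, 50)
        np.testing.assert_allclose(fit.predict(grid),
                                   evaluate_basis(cubic_spec, grid) @ beta_true,
                                   atol=1e-8)

    def test_huge_lambda_gives_ols_line_and_edf_two(self, cubic_spec,
                                                    integral_penalty, rng):
        times = np.sort(rng.uniform(0, 1, 60))
        levels = 0.4 + 1.3 * times + 0.05 * rng.standard_normal(60)
        fit = penalized_fit(CrossingPairSet(times, levels), cubic_spec,
                            integral_penalty, 1e12)
        coef = np.polyfit(times, levels, 1)
        np.testing.assert_allclose(fit.predict(times), np.polyval(coef, times),
                                   atol=1e-4)
        assert fit.edf == pytest.approx(2.0, abs=1e-4)

    def test_matches_augmented_system_oracle(self, rng):
        for _ in range(100):
            n = rng.integers(10, 201)
            K = int(rng.integers(4, 17))
            lam = 10.0 ** rng.uniform(-6, 6)
            spec = build_spline_spec(0, 1, K, 4)
            S = build_penalty(spec).matrix_S
            times = np.sort(rng.uniform(0, 1, n))
            levels = np.sin(3 * times) + 0.1 * rng.standard_normal(n)
            fit = penalized_fit(CrossingPairSet(times, levels), spec,
                                build_penalty(spec), lam)
            Phi = evaluate_basis(spec, times)
            beta_oracle = augmented_oracle(Phi, levels, S, lam)
            np.testing.assert_allclose(fit.coefficients, beta_oracle, atol=1e-8)

    def test_edf_monotone_in_lambda(self, cubic_spec, integral_penalty, rng):
        times = np.sort(rng.uniform(0, 1, 80))
        levels = np.cos(4 * times) + 0.1 * rng.standard_normal(80)
        pairs = CrossingPairSet(times, levels)
        edfs = [penalized_fit(pairs, cubic_spec, integral_penalty, lam).edf
                for lam in default_lambda_grid()]
        assert all(a >= b - 1e-9 for a, b in zip(edfs, edfs[1:]))
        fit0 = penalized_fit(pairs, cubic_spec, integral_penalty, 0.0)
        assert fit0.edf == pytest.approx(8.0, abs=1e-6)

    def test_edf_trace_matches_explicit_hat_matrix(self, cubic_spec,
                                                   integral_penalty, rng):
        times = np.sort(rng.uniform(0, 1, 50))
        levels = rng.standard_normal(50)
        fit = penalized_fit(CrossingPairSet(times, levels), cubic_spec,
                            integral_penalty, 3.7)
        Phi = evaluate_basis(cubic_spec, times)
        H = Phi @ np.linalg.solve(Phi.T @ Phi + 3.7 * integral_penalty.matrix_S, Phi.T)
        assert fit.edf == pytest.approx(np.trace(H), abs=1e-8)

    def test_rank_deficient_lambda_zero_raises(self, cubic_spec, integral_penalty):
        pairs = CrossingPairSet(np.array([0.4, 0.5, 0.6]), np.array([1.0, 1.1, 0.9]))
        with pytest.raises(SingularSystemError):
            penalized_fit(pairs, cubic_spec, integral_penalty, 0.0)

    def test_self_consistent_rss(self, cubic_spec, integral_penalty, rng):
        times = np.sort(rng.uniform(0, 1, 30))
        levels = rng.standard_normal(30)
        fit = penalized_fit(CrossingPairSet(times, levels), cubic_spec,
                            integral_penalty, 1.0)
        resid = levels - fit.predict(times)
        assert fit.rss == pytest.approx(float(resid @ resid), rel=1e-10)


class TestGCVSelect:
    def test_matches_exhaustive_independent_gcv(self, cubic_spec,
                                                integral_penalty, rng):
        times = np.sort(rng.uniform(0, 1, 100))
        truth = -0.8 * times + 0.9
        levels = truth + 0.05 * rng.standard_normal(100)
        pairs = CrossingPairSet(times, levels)
        grid = default_lambda_grid()
        lam_star, _ = gcv_select(pairs, cubic_spec, integral_penalty, grid)
        # independent recomputation: explicit hat matrix per lambda
        Phi = evaluate_basis(cubic_spec, times)
        scores = []
        for lam in grid:
            H = Phi @ np.linalg.solve(Phi.T @ Phi + lam * integral_penalty.matrix_S,
                                      Phi.T)
            r = levels - H @ levels
            scores.append(len(levels) * float(r @ r) / (len(levels) - np.trace(H)) ** 2)
        assert lam_star == pytest.approx(grid[int(np.argmin(scores))])

    def test_linear_data_ties_break_to_largest_lambda(self, cubic_spec,
                                                      integral_penalty):
        times = np.linspace(0, 1, 40)
        pairs = CrossingPairSet(times, 0.3 + 0.7 * times)
        grid = default_lambda_grid()
        lam_star, fit = gcv_select(pairs, cubic_spec, integral_penalty, grid)
        assert lam_star == pytest.approx(grid[-1])
        assert fit.rss < 1e-12

    def test_single_candidate_returned(self, cubic_spec, integral_penalty, rng):
        times = np.sort(rng.uniform(0, 1, 30))
        pairs = CrossingPairSet(times, rng.standard_normal(30))
        lam_star, _ = gcv_select(pairs, cubic_spec, integral_penalty, [2.5])
        assert lam_star == 2.5

    def test_too_few_points_ill_posed(self, cubic_spec, integral_penalty):
        pairs = CrossingPairSet(np.array([0.4, 0.6]), np.array([1.0, 1.1]))
        with pytest.raises(IllPosedError):
            gcv_select(pairs, cubic_spec, integral_penalty, [1e-6])


class TestKFoldSelect:
    def test_leave_one_out_matches_brute_force(self, rng):
        spec = build_spline_spec(0, 1, 4, 4)
        pen = build_penalty(spec)
        times = np.sort(rng.uniform(0, 1, 10))
        levels = np.sin(2 * times) + 0.1 * rng.standard_normal(10)
        pairs = CrossingPairSet(times, levels)
        grid = [0.01, 10.0]
        lam_star, _ = kfold_select(pairs, spec, pen, grid, k=10, seed=3)
        # brute force: for each lambda refit n times leaving one out
        cv = []
        for lam in grid:
            err = 0.0
            for i in range(10):
                mask = np.ones(10, bool)
                mask[i] = False
                f = penalized_fit(CrossingPairSet(times[mask], levels[mask]),
                                  spec, pen, lam)
                err += float((levels[i] - f.predict([times[i]])[0]) ** 2)
            cv.append(err)
        assert lam_star == pytest.approx(grid[int(np.argmin(cv))])

    def test_deterministic_given_seed(self, cubic_spec, integral_penalty, rng):
        times = np.sort(rng.uniform(0, 1, 40))
        pairs = CrossingPairSet(times, rng.standard_normal(40))
        out1 = kfold_select(pairs, cubic_spec, integral_penalty, k=5, seed=11)[0]
        out2 = kfold_select(pairs, cubic_spec, integral_penalty, k=5, seed=11)[0]
        assert out1 == out2

    def test_linear_data_picks_largest_lambda(self, cubic_spec, integral_penalty):
        times = np.linspace(0, 1, 30)
        pairs = CrossingPairSet(times, 2.0 - times)
        grid = default_lambda_grid()
        assert kfold_select(pairs, cubic_spec, integral_penalty, grid, k=5,
                            seed=0)[0] == pytest.approx(grid[-1])

    def test_k_larger_than_n_rejected(self, cubic_spec, integral_penalty):
        pairs = CrossingPairSet(np.linspace(0, 1, 5), np.zeros(5))
        with pytest.raises(ValueError):
            kfold_select(pairs, cubic_spec, integral_penalty, k=6)


class TestLoess:
    def test_reproduces_constants(self, rng):
        times = np.sort(rng.uniform(0, 1, 30))
        fit = loess_fit(CrossingPairSet(times, np.full(30, 2.5)), 0.5,
                        np.linspace(times.min(), times.max(), 20))
        np.testing.assert_allclose(fit.fitted, 2.5, atol=1e-12)
        np.testing.assert_allclose(fit.weights.sum(axis=1), 1.0, atol=1e-12)

    def test_exact_on_lines_including_endpoints(self, rng):
        times = np.sort(rng.uniform(0, 1, 40))
        levels = 1.2 - 0.6 * times
        grid = np.array([times.min(), 0.3, 0.7, times.max()])
        fit = loess_fit(CrossingPairSet(times, levels), 0.4, grid)
        np.testing.assert_allclose(fit.fitted, 1.2 - 0.6 * grid, atol=1e-8)

    def test_close_to_statsmodels_lowess(self, rng):
        """Independent LOESS implementation agrees with statsmodels at the
        data points (same tricube local-linear construction)."""
        times = np.sort(rng.uniform(0, 1, 80))
        levels = np.sin(3 * times) + 0.1 * rng.standard_normal(80)
        span = 0.5
        ours = loess_fit(CrossingPairSet(times, levels), span, times).fitted
        theirs = sm_lowess(levels, times, frac=span, it=0, return_sorted=False)
        inner = (times > 0.1) & (times < 0.9)
        assert np.max(np.abs(ours[inner] - theirs[inner])) < 0.02

    def test_recovers_declining_threshold_midpoint(self, rng):
        """At t=0.5 the smoothed crossing levels sit near the generating
        boundary q(0.5) = -0.8*0.5 + 0.9 = 0.5."""
        vals = []
        for _ in range(30):
            times = np.sort(rng.uniform(0.1, 0.9, 200))
            levels = -0.8 * times + 0.9 + 0.05 * rng.standard_normal(200)
            fit = loess_fit(CrossingPairSet(times, levels), 0.5, np.array([0.5]))
            vals.append(fit.fitted[0])
        vals = np.array(vals)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - 0.5) < 3 * max(se, 1e-3)

    def test_span_selection_matches_brute_force(self, rng):
        times = np.sort(rng.uniform(0, 1, 50))
        levels = np.sin(4 * times) + 0.2 * rng.standard_normal(50)
        pairs = CrossingPairSet(times, levels)
        grid = [0.2, 0.5, 0.9]
        got = loess_span_select(pairs, grid, k=5, seed=7)
        # brute force with the same fold partition
        from fpboundary.estimators import _fold_indices, _loess_core
        folds = _fold_indices(50, 5, 7)
        cv = []
        for span in grid:
            err = 0.0
            for fold in folds:
                mask = np.ones(50, bool)
                mask[fold] = False
                xt, yt = times[mask], levels[mask]
                t_out = np.clip(times[fold], xt.min(), xt.max())
                _, pred, _ = _loess_core(xt, yt, span, t_out)
                err += float(((levels[fold] - pred) ** 2).sum())
            cv.append(err)
        assert got == pytest.approx(grid[int(np.argmin(cv))])

    def test_linear_data_selects_largest_span(self, rng):
        times = np.sort(rng.uniform(0, 1, 40))
        pairs = CrossingPairSet(times, 0.1 + times)
        assert loess_span_select(pairs, [0.3, 0.6, 1.0], k=4, seed=0) == 1.0

    def test_evaluation_outside_range_rejected(self, rng):
        times = np.sort(rng.uniform(0.2, 0.8, 20))
        pairs = CrossingPairSet(times, np.ones(20))
        with pytest.raises(ValueError):
            loess_fit(pairs, 0.5, [0.9])


class TestHinge:
    def test_recovers_toy_kink_exactly(self):
        z = np.array([0.0, 1, 2, 3, 4])
        y = np.array([0.0, 1, 2, 4, 6])
        fit = hinge_threshold_fit(z, y, [1.0, 2.0, 3.0])
        assert fit.tau_hat == 2.0
        assert fit.rss_by_tau[2.0] == pytest.approx(0.0, abs=1e-20)
        assert (fit.beta0, fit.beta1, fit.beta2) == pytest.approx((0.0, 1.0, 1.0),
                                                                 abs=1e-10)

    def test_pure_line_ties_break_to_smallest_tau(self, rng):
        z = np.linspace(0, 4, 20)
        y = 1.0 + 0.5 * z
        fit = hinge_threshold_fit(z, y, [1.0, 2.0, 3.0])
        assert fit.tau_hat == 1.0
        assert abs(fit.beta2) < 1e-6

    def test_fit_continuous_at_threshold(self, rng):
        z = rng.uniform(0, 4, 50)
        y = 0.2 + 0.8 * z + 1.5 * np.maximum(z - 2.1, 0) + 0.1 * rng.standard_normal(50)
        fit = hinge_threshold_fit(z, y, np.linspace(0.5, 3.5, 13))
        eps = 1e-8
        left = fit.predict(fit.tau_hat - eps)
        right = fit.predict(fit.tau_hat + eps)
        assert abs(left - right) < 1e-7

    def test_per_candidate_rss_matches_normal_equations(self, rng):
        z = rng.uniform(0, 4, 30)
        y = z + np.maximum(z - 2, 0) + 0.2 * rng.standard_normal(30)
        tau_grid = [1.0, 2.0, 3.0]
        fit = hinge_threshold_fit(z, y, tau_grid)
        for tau in tau_grid:
            X = np.column_stack([np.ones_like(z), z, np.maximum(z - tau, 0)])
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            r = y - X @ beta
            assert fit.rss_by_tau[tau] == pytest.approx(float(r @ r), rel=1e-8)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            hinge_threshold_fit([0, 1, 2], [0, 1, 2], [1.0])


class TestPairSetIO:
    def test_round_trip(self, rng):
        pairs = CrossingPairSet(np.sort(rng.uniform(0, 1, 5)),
                                rng.standard_normal(5),
                                np.array(list("abcde"), dtype=object))
        buf = io.StringIO()
        pairs.write(buf)
        buf.seek(0)
        back = CrossingPairSet.read(buf)
        np.testing.assert_allclose(back.times, pairs.times)
        np.testing.assert_allclose(back.levels, pairs.levels)
        assert list(back.unit_ids) == list(pairs.unit_ids)
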