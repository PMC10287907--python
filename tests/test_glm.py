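import numpy as np
import pytest
import scipy.optimize
import scipy.sparse as sp

from suredec import (
    PenaltyConfig,
    build_bins,
    build_design,
    compute_offsets,
    fit_poisson_elasticnet,
    lambda_max,
    make_lambda_path,
)
from suredec.glm import ThetaBar, _positions_values, _interval_sums
from suredec.solver import fit_penalized_poisson, poisson_objective

from conftest import make_element, random_elements


def oracle_minimize(X, y, lam, alpha, pf, offsets=0.0):
    """Independent oracle: L-BFGS-B on the smooth split-variable form.

    Writes b_j = p_j - q_j with p, q >= 0 so |b_j| = p_j + q_j and the
    elastic-net Poisson objective becomes smooth and bound-constrained;
    minimized by scipy, with no shared code with the coordinate-descent
    solver.
    """
    X = np.asarray(X.todense() if sp.issparse(X) else X, dtype=float)
    n, m = X.shape
    offsets = np.broadcast_to(np.asarray(offsets, float), (n,))

    def f(pq):
        p, q = pq[:m], pq[m:]
        b = p - q
        mu = X @ b + offsets
        nll = -(y @ mu - np.exp(mu).sum()) / n
        pen = lam * np.sum(pf * (alpha * (p + q) + 0.5 * (1 - alpha) * b**2))
        return nll + pen

    def grad(pq):
        p, q = pq[:m], pq[m:]
        b = p - q
        mu = X @ b + offsets
        g_b = -(X.T @ (y - np.exp(mu))) / n + lam * (1 - alpha) * pf * b
        g_p = g_b + lam * alpha * pf
        g_q = -g_b + lam * alpha * pf
        return np.concatenate([g_p, g_q])

    res = scipy.optimize.minimize(
        f, np.zeros(2 * m), jac=grad, method="L-BFGS-B",
        bounds=[(0, None)] * (2 * m),
        options={"maxiter": 5000, "ftol": 1e-14, "gtol": 1e-10},
    )
    return res.x[:m] - res.x[m:], res.fun


def random_instance(rng, n=50, n_pen=8, n_unpen=2):
    X = rng.normal(size=(n, n_pen + n_unpen))
    X[:, n_pen:] = np.abs(X[:, n_pen:])  # keep unpenalized cols well-scaled
    X[:, -1] = 1.0  # intercept
    b_true = np.concatenate([rng.normal(scale=0.3, size=n_pen), [0.1, 0.5]])
    y = rng.poisson(np.exp(np.clip(X @ b_true, -5, 3))).astype(float)
    pf = np.concatenate([np.ones(n_pen), np.zeros(n_unpen)])
    return sp.csc_matrix(X), y, pf


class TestSolverAgainstOracle:
    def test_intercept_only_closed_form(self):
        X = sp.csc_matrix(np.ones((3, 1)))
        y = np.array([1.0, 2.0, 3.0])
        res = fit_penalized_poisson(X, y, lam=0.7, alpha=0.5, pf=np.zeros(1))
        assert res.coef[0] == pytest.approx(np.log(2.0), abs=1e-8)

    @pytest.mark.parametrize("alpha", [0.1, 0.5, 1.0])
    @pytest.mark.parametrize("lam", [0.01, 0.1])
    def test_matches_generic_convex_minimizer(self, alpha, lam):
        rng = np.random.default_rng(2024)
        for _ in range(4):
            X, y, pf = random_instance(rng)
            res = fit_penalized_poisson(X, y, lam=lam, alpha=alpha, pf=pf)
            b_oracle, f_oracle = oracle_minimize(X, y, lam, alpha, pf)
            scale = max(1.0, np.abs(b_oracle).max())
            np.testing.assert_allclose(res.coef, b_oracle, atol=1e-4 * scale)
            assert res.objective <= f_oracle + 1e-6

    def test_offsets_respected_by_oracle_comparison(self):
        rng = np.random.default_rng(7)
        X, y, pf = random_instance(rng, n=40, n_pen=5)
        offsets = rng.normal(scale=0.3, size=40)
        res = fit_penalized_poisson(X, y, lam=0.05, alpha=0.5, pf=pf, offsets=offsets)
        b_oracle, _ = oracle_minimize(X, y, 0.05, 0.5, pf, offsets=offsets)
        np.testing.assert_allclose(res.coef, b_oracle, atol=1e-4)

    def test_objective_not_above_zero_spatial_solution(self):
        rng = np.random.default_rng(3)
        X, y, pf = random_instance(rng)
        res = fit_penalized_poisson(X, y, lam=0.1, alpha=0.5, pf=pf)
        # fit with spatial coefficients pinned at zero (unpenalized only)
        unpen = np.flatnonzero(pf == 0)
        null = fit_penalized_poisson(X[:, unpen], y, lam=0.0, alpha=1.0, pf=np.zeros(unpen.size))
        b0 = np.zeros(X.shape[1])
        b0[unpen] = null.coef
        f0 = poisson_objective(sp.csc_matrix(X), y, b0, np.zeros(y.size), 0.1, 0.5, pf)
        assert res.objective <= f0 + 1e-10

    def test_all_zero_y_unbounded_guard(self):
        X = sp.csc_matrix(np.ones((5, 1)))
        with pytest.raises(ValueError, match="unbounded"):
            fit_penalized_poisson(X, np.zeros(5), lam=0.0, alpha=1.0, pf=np.ones(1))


def signal_design(seed=5, n=120):
    """Small fragment design with genuine spatial signal."""
    rng = np.random.default_rng(seed)
    elements = []
    for _ in range(n):
        start = int(rng.integers(0, 800))
        end = start + int(rng.integers(80, 200))
        mu = 0.5 + (0.8 if start < 400 < end else 0.0)
        elements.append(
            make_element(start, end, ipcr=int(rng.integers(1, 4)),
                         cdna=int(rng.poisson(np.exp(mu))))
        )
    bins = build_bins(elements, "+")
    return build_design(elements, bins)


class TestLambdaMaxAndPath:
    def test_fit_at_lambda_max_all_spatial_zero(self):
        design = signal_design()
        for alpha in (0.05, 1.0):
            lm = lambda_max(design, alpha)
            coefs, _ = fit_poisson_elasticnet(design, PenaltyConfig(alpha=alpha, lam=lm))
            assert np.all(coefs.beta == 0.0)
            coefs2, _ = fit_poisson_elasticnet(
                design, PenaltyConfig(alpha=alpha, lam=0.9 * lm)
            )
            assert np.any(coefs2.beta != 0.0)

    def test_doubling_alpha_halves_lambda_max(self):
        design = signal_design()
        assert lambda_max(design, 0.2) == pytest.approx(lambda_max(design, 0.1) / 2)

    def test_alpha_zero_undefined(self):
        with pytest.raises(ValueError):
            lambda_max(signal_design(), 0.0)

    def test_log_spaced_path(self):
        np.testing.assert_allclose(make_lambda_path(100, 3, 0.01), [100, 10, 1])
        np.testing.assert_allclose(make_lambda_path(5, 1), [5])
        path = make_lambda_path(7.3, 25, 1e-3)
        assert np.all(np.diff(path) < 0)
        with pytest.raises(ValueError):
            make_lambda_path(10, 5, 1.5)

    def test_training_loglik_nondecreasing_along_path(self):
        """With warm starts, unpenalized train log-likelihood improves
        monotonically as lam decreases."""
        design = signal_design()
        lm = lambda_max(design, 0.5)
        path = make_lambda_path(lm, 12, 1e-3)
        lls, beta = [], None
        for lam in path:
            coefs, res = fit_poisson_elasticnet(
                design, PenaltyConfig(alpha=0.5, lam=float(lam)), beta0=beta
            )
            beta = res.coef
            mu = np.asarray(design.X @ beta).ravel()
            lls.append(float(design.y @ mu - np.exp(mu).sum()))
        diffs = np.diff(lls)
        assert np.all(diffs >= -1e-7 * np.abs(np.array(lls)[1:]))


class TestDesignMatrix:
    def test_sqrt_length_entries(self):
        elements = [make_element(0, 10, cdna=1), make_element(5, 15, cdna=2)]
        design = build_design(elements, build_bins(elements, "+"))
        X = design.X.toarray()
        s5 = np.sqrt(5.0)
        np.testing.assert_allclose(X[:, :3], [[s5, s5, 0], [0, s5, s5]])

    def test_length_column_and_row_sums(self):
        elements = [make_element(0, 10, cdna=1), make_element(5, 15, cdna=2)]
        design = build_design(elements, build_bins(elements, "+"))
        X = design.X.toarray()
        np.testing.assert_allclose(X[:, 3], [10, 10])  # length column
        # sum over an element's bins of l_j equals L_i
        np.testing.assert_allclose((X[:, :3] ** 2).sum(axis=1), [10, 10])

    def test_single_library_n1_log_columns_zero(self):
        elements = [make_element(0, 10, ipcr=1, cdna=1), make_element(5, 15, ipcr=1, cdna=2)]
        design = build_design(elements, build_bins(elements, "+"))
        X = design.X.toarray()
        np.testing.assert_allclose(X[:, 4], 1.0)  # library indicator
        np.testing.assert_allclose(X[:, 5:], 0.0)  # log-input columns at n=1

    def test_penalty_factors_spatial_only(self):
        elements = [make_element(0, 10, cdna=1), make_element(5, 15, cdna=2)]
        bins = build_bins(elements, "+")
        full = build_design(elements, bins)
        np.testing.assert_array_equal(full.penalty_factors[:3], 1.0)
        np.testing.assert_array_equal(full.penalty_factors[3:], 0.0)
        spatial = build_design(elements, bins, spatial_only=True)
        assert spatial.X.shape[1] == 3

    def test_library_indicators_partition(self, rng):
        elements = random_elements(rng, 30, 1000, strand="+")
        design = build_design(elements, build_bins(elements, "+"))
        K = len(design.libraries)
        X = design.X.toarray()
        ind = X[:, design.n_spatial + 1 : design.n_spatial + 1 + K]
        np.testing.assert_allclose(ind.sum(axis=1), 1.0)

    def test_binning_contract_violation_is_internal_error(self):
        elements = [make_element(0, 10, cdna=1), make_element(5, 15, cdna=2)]
        bins = build_bins(elements, "+")
        with pytest.raises(RuntimeError, match="internal error"):
            build_design([make_element(2, 8, cdna=0)], bins)


class TestOffsets:
    def make_theta(self):
        return ThetaBar(
            theta_L=-0.002,
            theta0={1: 1.0, 2: 0.5},
            theta1={1: 0.2, 2: 0.1},
            theta2={1: -0.05, 2: 0.01},
        )

    def test_log_one_drops_input_terms(self):
        th = self.make_theta()
        (off,) = compute_offsets([make_element(0, 200, ipcr=1, cdna=0)], th)
        assert off == pytest.approx(200 * -0.002 + 1.0)

    def test_input_count_terms_follow_log_formula(self):
        th = self.make_theta()
        (off,) = compute_offsets([make_element(0, 100, ipcr=3, cdna=0)], th)
        ln = np.log(3)
        assert off == pytest.approx(100 * -0.002 + 1.0 + 0.2 * ln - 0.05 * ln**2)

    def test_library_routing_and_unknown_library(self):
        th = self.make_theta()
        (off,) = compute_offsets([make_element(0, 100, lib=2, ipcr=1, cdna=0)], th)
        assert off == pytest.approx(100 * -0.002 + 0.5)
        with pytest.raises(ValueError, match="unknown library"):
            compute_offsets([make_element(0, 100, lib=9, ipcr=1, cdna=0)], th)

    def test_offset_fit_equals_frozen_theta_fit(self):
        """Fitting spatial-only with offsets equals the full-design fit with
        non-spatial coefficients frozen at theta-bar."""
        rng = np.random.default_rng(21)
        elements = random_elements(rng, 80, 600, strand="+")
        bins = build_bins(elements, "+")
        full = build_design(elements, bins)
        spatial = build_design(elements, bins, spatial_only=True)
        th = ThetaBar(theta_L=-0.001,
                      theta0={1: 0.8, 2: 0.6}, theta1={1: 0.1, 2: 0.0},
                      theta2={1: 0.0, 2: 0.0})
        offsets = compute_offsets(elements, th)
        cfg = PenaltyConfig(alpha=0.5, lam=0.05)
        coefs_off, _ = fit_poisson_elasticnet(spatial, cfg, offsets=offsets)
        # frozen-theta fit: spatial columns of the full design + explicit offset
        b_oracle, _ = oracle_minimize(
            spatial.X, spatial.y, 0.05, 0.5, spatial.penalty_factors, offsets=offsets
        )
        np.testing.assert_allclose(coefs_off.beta, b_oracle, atol=1e-4)


class TestHeldOutScoring:
    def test_interval_sums_with_gaps(self):
        positions = np.array([0, 1, 2, 10, 11])
        values = np.array([1.0, 1.0, 1.0, 5.0, 5.0])
        sums = _interval_sums(positions, values, np.array([0, 2, 5]), np.array([3, 12, 8]))
        np.testing.assert_allclose(sums, [3.0, 11.0, 0.0])

    def test_positions_values_expand_bins(self):
        elements = [make_element(0, 4, cdna=1), make_element(2, 6, cdna=1)]
        bins = build_bins(elements, "+")
        beta = np.array([2.0, 3.0, 4.0])
        pos, val = _positions_values(bins, beta)
        np.testing.assert_array_equal(pos, np.arange(6))
        np.testing.assert_allclose(val, np.repeat(beta / np.sqrt(2.0), 2))
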