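"""Response function, screening, marginal likelihood, EM fitting, SEs, EAP."""

import math

import numpy as np
import pytest
import scipy.optimize
import sympy

from epirt.irt import (
    CodeIRT,
    QuadratureGrid,
    irf,
    marginal_loglik,
    observed_information_cov,
    screen_items,
)

from conftest import simulate_matrix


class TestIrf:
    def test_half_probability_at_location(self):
        for a in (0.3, 1.0, 2.8):
            assert irf(1.7, a, 1.7) == pytest.approx(0.5)

    def test_lower_asymptote(self):
        assert irf(-50.0, 1.0, 0.0, gamma=0.2) == pytest.approx(0.2, abs=1e-12)

    def test_matches_arbitrary_precision_logistic(self):
        # discrimination/location equal to the mean calibration values of a
        # large primary-care stroke-code analysis: at theta=0 the
        # endorsement probability is vanishingly small
        a, b, t = 1.020, 9.617, 0.0
        z = sympy.Float(a, 50) * (sympy.Float(t, 50) - sympy.Float(b, 50))
        oracle = float(sympy.exp(z) / (1 + sympy.exp(z)))
        assert irf(t, a, b) == pytest.approx(oracle, rel=1e-12)
        assert oracle < 1e-4

    def test_numerically_stable_for_extreme_logits(self):
        assert irf(700.0, 1.0, 0.0) == pytest.approx(1.0, abs=1e-300)
        assert irf(-700.0, 1.0, 0.0) == pytest.approx(0.0, abs=1e-300)
        assert np.isfinite(irf(np.array([-700.0, 700.0]), 35.0, 0.0)).all()


class TestScreening:
    def test_universally_endorsed_code_is_degenerate(self):
        X = np.array([[1, 1, 0], [1, 0, 1], [1, 1, 1], [1, 0, 0]], dtype=np.uint8)
        kept, excl = screen_items(X, code_ids=np.array(["a", "b", "c"]))
        assert [e["code"] for e in excl] == ["a"]
        assert excl[0]["reason"] == "degenerate"

    def test_mutually_exclusive_balanced_pair_excluded(self):
        X = np.array([[1, 0], [0, 1]] * 20, dtype=np.uint8)
        kept, excl = screen_items(X)
        assert len(kept) == 0
        assert all(e["correlation"] == pytest.approx(-1.0) for e in excl)

    def test_correlations_match_direct_covariance_oracle(self):
        rng = np.random.default_rng(2)
        X = (rng.random((400, 8)) < rng.uniform(0.1, 0.6, 8)).astype(np.uint8)
        kept, excl = screen_items(X, threshold=0.05)  # force some exclusions
        total = X.sum(axis=1)
        for e in excl:
            if e["reason"] == "degenerate":
                continue
            i = int(str(e["code"]).replace("item", ""))
            x = X[:, i].astype(float)
            rest = (total - X[:, i]).astype(float)
            num = np.mean(x * rest) - x.mean() * rest.mean()
            oracle = num / (x.std() * rest.std())
            assert e["correlation"] == pytest.approx(oracle, abs=1e-12)

    def test_invariant_to_patient_and_code_order(self):
        rng = np.random.default_rng(3)
        X = (rng.random((300, 6)) < 0.35).astype(np.uint8)
        ids = np.array(list("abcdef"))
        kept, excl = screen_items(X, threshold=0.02, code_ids=ids)
        rperm = rng.permutation(300)
        cperm = rng.permutation(6)
        kept2, excl2 = screen_items(X[rperm][:, cperm], threshold=0.02, code_ids=ids[cperm])
        assert set(ids[kept]) == set(ids[cperm][kept2])
        assert {e["code"] for e in excl} == {e["code"] for e in excl2}


class TestMarginalLoglik:
    def test_single_patient_single_item_reduces_to_weighted_sum(self):
        grid = QuadratureGrid.normal(15, 4.0)
        X = np.array([[1]])
        got = marginal_loglik(X, np.array([1.0]), np.array([0.0]), grid)
        direct = math.log(sum(w * irf(t, 1.0, 0.0) for t, w in zip(grid.nodes, grid.weights)))
        assert got == pytest.approx(direct, abs=1e-12)

    def test_all_zero_row_with_rare_items_is_finite(self):
        grid = QuadratureGrid.normal(21, 6.0)
        X = np.zeros((1, 4), dtype=np.uint8)
        val = marginal_loglik(X, np.full(4, 2.0), np.full(4, 11.0), grid)
        assert np.isfinite(val)

    def test_matches_naive_product_oracle(self):
        rng = np.random.default_rng(7)
        X = (rng.random((10, 5)) < 0.5).astype(np.uint8)
        alpha = rng.uniform(0.5, 2.5, 5)
        beta = rng.uniform(-2, 2, 5)
        grid = QuadratureGrid.normal(160, 6.0)
        got = marginal_loglik(X, alpha, beta, grid)
        oracle = 0.0
        for s in range(10):
            acc = 0.0
            for t, w in zip(grid.nodes, grid.weights):
                prod = w
                for i in range(5):
                    p = irf(t, alpha[i], beta[i])
                    prod *= p if X[s, i] else (1 - p)
                acc += prod
            oracle += math.log(acc)
        assert got == pytest.approx(oracle, abs=1e-10)

    def test_metric_identification_under_joint_shift(self):
        rng = np.random.default_rng(1)
        X = (rng.random((50, 4)) < 0.4).astype(np.uint8)
        alpha = rng.uniform(0.8, 1.5, 4)
        beta = rng.uniform(-1, 1, 4)
        grid = QuadratureGrid.normal(21, 6.0)
        delta = 0.7
        assert marginal_loglik(X, alpha, beta, grid) == pytest.approx(
            marginal_loglik(X, alpha, beta + delta, grid.shifted(delta)), abs=1e-10
        )


class TestFit:
    def test_em_estimates_match_direct_optimizer(self):
        m, n = 5, 200
        rng = np.random.default_rng(7)
        alpha = rng.uniform(0.8, 2.0, m)
        beta = rng.uniform(-1.5, 1.5, m)
        X, _ = simulate_matrix(alpha, beta, n, seed=17)
        grid = QuadratureGrid.normal(21, 6.0)
        res = CodeIRT(X, screen=False, grid=grid).fit(criterion=1e-7, max_em=2000, max_newton=200)

        def nll(p):
            a = p[:m]
            return -marginal_loglik(X, a, -p[m:] / a, grid)

        opt = scipy.optimize.minimize(
            nll, np.concatenate([np.ones(m), np.zeros(m)]), method="L-BFGS-B",
            bounds=[(1e-3, 60)] * m + [(-60, 60)] * m,
            options=dict(maxiter=3000, ftol=1e-14, gtol=1e-10),
        )
        a_o = opt.x[:m]
        b_o = -opt.x[m:] / a_o
        assert np.abs(res.items["alpha"].to_numpy() - a_o).max() < 1e-3
        assert np.abs(res.items["beta"].to_numpy() - b_o).max() < 1e-3

    def test_common_slope_fit_matches_direct_tied_slope_optimizer(self):
        m, n = 6, 400
        rng = np.random.default_rng(31)
        beta = rng.uniform(-1.5, 1.5, m)
        X, _ = simulate_matrix(np.full(m, 1.2), beta, n, seed=23)
        grid = QuadratureGrid.normal(21, 6.0)
        res = CodeIRT(X, model="1pl", screen=False, grid=grid).fit(
            criterion=1e-7, max_em=2000, max_newton=200
        )

        def nll(p):
            a = np.full(m, p[0])
            return -marginal_loglik(X, a, -p[1:] / a, grid)

        opt = scipy.optimize.minimize(
            nll, np.concatenate([[1.0], np.zeros(m)]), method="L-BFGS-B",
            bounds=[(1e-3, 60)] + [(-60, 60)] * m,
            options=dict(maxiter=3000, ftol=1e-14, gtol=1e-10),
        )
        assert res.items["alpha"].to_numpy()[0] == pytest.approx(opt.x[0], abs=1e-3)
        assert np.abs(
            res.items["beta"].to_numpy() - (-opt.x[1:] / opt.x[0])
        ).max() < 1e-3

    def test_deviance_trace_never_increases(self):
        X, _ = simulate_matrix([1.0, 1.4, 0.8], [-0.5, 0.3, 1.0], 500, seed=3)
        for model in ("1pl", "2pl"):
            res = CodeIRT(X, model=model, screen=False).fit(max_em=40, max_newton=5)
            tr = np.asarray(res.trace)
            assert np.all(np.diff(tr) <= 1e-6 * (1 + np.abs(tr[1:])))

    def test_nonconvergence_reported_not_raised(self):
        X, _ = simulate_matrix(np.full(8, 1.2), np.linspace(-2, 2, 8), 600, seed=5)
        res = CodeIRT(X, screen=False).fit(criterion=1e-12, max_em=1, max_newton=0)
        assert not res.converged
        assert res.max_last_change >= 1e-12

    def test_low_information_items_flagged_never_dropped(self):
        rng = np.random.default_rng(9)
        X = (rng.random((500, 3)) < np.array([0.5, 0.4, 0.006])).astype(np.uint8)
        X[X.sum(axis=1) == 0, 0] = 1
        res = CodeIRT(X, screen=False).fit(compute_se=False)
        assert res.items.loc[2, "flag"] == "low-information"
        assert len(res.items) + len(res.excluded_items) == 3

    def test_items_and_exclusions_cover_all_codes(self, preset_pipeline):
        _, _, _, matrix = preset_pipeline
        sub = matrix.X[:2000]
        sub = sub[:, sub.sum(axis=0) > 0]
        sub = sub[sub.sum(axis=1) > 0]
        res = CodeIRT(sub, screen=True).fit(compute_se=False, max_em=5, max_newton=0)
        assert len(res.items) + len(res.excluded_items) == sub.shape[1]


@pytest.fixture(scope="module")
def toy_fit():
    alpha = np.array([1.3, 0.9, 1.7])
    beta = np.array([-0.5, 0.8, 0.1])
    X, _ = simulate_matrix(alpha, beta, 2000, seed=11)
    grid = QuadratureGrid.normal(21, 6.0)
    res = CodeIRT(X, screen=False, grid=grid).fit(
        criterion=1e-8, max_em=3000, max_newton=100
    )
    return X, grid, res


class TestStandardErrors:
    def test_matches_finite_difference_hessian(self, toy_fit):
        X, grid, res = toy_fit
        m = 3
        a = res.items["alpha"].to_numpy()
        b = res.items["beta"].to_numpy()
        p_hat = np.concatenate([a, -a * b])

        def nll(p):
            return -marginal_loglik(X, p[:m], -p[m:] / p[:m], grid)

        eps = 1e-4
        H = np.zeros((2 * m, 2 * m))
        for i in range(2 * m):
            for j in range(2 * m):
                def f(si, sj):
                    p = p_hat.copy()
                    p[i] += si * eps
                    p[j] += sj * eps
                    return nll(p)
                H[i, j] = (f(1, 1) - f(1, -1) - f(-1, 1) + f(-1, -1)) / (4 * eps * eps)
        perm = [0, 3, 1, 4, 2, 5]  # (a_i, d_i) interleaved order used internally
        cov_fd = np.linalg.inv(H)[np.ix_(perm, perm)]
        _, post, _ = marginal_loglik(X, a, b, grid, return_posterior=True)
        cov = observed_information_cov(X, post, None, a, -a * b, np.zeros(m), grid.nodes)
        se_fd = np.sqrt(np.diag(cov_fd))
        se = np.sqrt(np.diag(cov))
        assert np.all(np.abs(se - se_fd) / se_fd < 0.05)

    def test_stacking_the_sample_halves_variance(self, toy_fit):
        X, grid, res = toy_fit
        a = res.items["alpha"].to_numpy()
        b = res.items["beta"].to_numpy()
        X2 = np.vstack([X, X])
        _, post, _ = marginal_loglik(X, a, b, grid, return_posterior=True)
        _, post2, _ = marginal_loglik(X2, a, b, grid, return_posterior=True)
        cov = observed_information_cov(X, post, None, a, -a * b, np.zeros(3), grid.nodes)
        cov2 = observed_information_cov(X2, post2, None, a, -a * b, np.zeros(3), grid.nodes)
        assert np.allclose(np.sqrt(np.diag(cov2)), np.sqrt(np.diag(cov)) / np.sqrt(2), rtol=1e-8)

    def test_rare_item_has_larger_standard_errors(self):
        rng = np.random.default_rng(13)
        theta = rng.standard_normal(2000)
        common = (rng.random(2000) < irf(theta, 1.0, 0.0)).astype(np.uint8)
        rare = (rng.random(2000) < irf(theta, 1.0, 2.8)).astype(np.uint8)
        anchor1 = (rng.random(2000) < irf(theta, 1.2, -0.5)).astype(np.uint8)
        anchor2 = (rng.random(2000) < irf(theta, 1.2, 0.7)).astype(np.uint8)
        X = np.column_stack([common, rare, anchor1, anchor2])
        res = CodeIRT(X, screen=False).fit(criterion=1e-5, max_em=500, max_newton=50)
        items = res.items.set_index("code")
        assert items.loc["item1", "n_endorsed"] < items.loc["item0", "n_endorsed"]
        assert items.loc["item1", "se_alpha"] > items.loc["item0", "se_alpha"]
        assert items.loc["item1", "se_beta"] > items.loc["item0", "se_beta"]


class TestEapScores:
    def test_more_endorsements_give_higher_scores(self):
        X, _ = simulate_matrix(np.ones(6), np.linspace(-1, 2, 6), 800, seed=19)
        res = CodeIRT(X, screen=False).fit(compute_se=False, criterion=1e-4, max_em=200)
        sums = res.X.sum(axis=1)
        assert res.eap_theta[sums == sums.max()].min() > res.eap_theta[sums == 0].max() \
            if (sums == 0).any() else True
        # monotone in the number of endorsed codes on average
        means = [res.eap_theta[sums == k].mean() for k in np.unique(sums)]
        assert np.all(np.diff(means) > 0)

    def test_symmetric_items_give_symmetric_scores(self):
        grid = QuadratureGrid.normal(41, 6.0)
        X = np.array([[1, 0], [0, 1]])
        model = CodeIRT(X, screen=False, grid=grid)
        res = model.fit(start=(np.array([1.0, 1.0]), np.array([-0.8, 0.8])),
                        criterion=np.inf, max_em=0, max_newton=0, compute_se=False)
        # complementary patterns on mirror-image items
        assert res.eap_theta[0] == pytest.approx(-res.eap_theta[1], abs=1e-10)

    def test_matches_direct_posterior_mean_integral(self):
        grid = QuadratureGrid.normal(501, 6.0)
        X = np.array([[1, 1, 0], [0, 0, 1], [1, 0, 1]], dtype=np.uint8)
        alpha = np.array([1.0, 1.5, 0.7])
        beta = np.array([-0.3, 0.4, 1.1])
        res = CodeIRT(X, screen=False, grid=grid).fit(
            start=(alpha, beta), criterion=np.inf, max_em=0, max_newton=0, compute_se=False
        )
        num = den = 0.0
        for t, w in zip(grid.nodes, grid.weights):
            like = w
            for i in range(3):
                p = irf(t, alpha[i], beta[i])
                like *= p if X[0, i] else 1 - p
            num += t * like
            den += like
        assert res.eap_theta[0] == pytest.approx(num / den, abs=1e-8)
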