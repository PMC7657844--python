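import numpy as np
import pytest

from elastica.affinity import AffinityModel, build_affinities, build_temporal
from elastica.exceptions import (
    InvalidDirectionError,
    InvalidInputError,
    InvalidParameterError,
)
from elastica.optimizer import (
    EEParams,
    build_preconditioner,
    energy,
    energy_rows,
    fit,
    gradient,
    laplacian,
    line_search,
    relative_error,
    solve_direction,
)


def two_point_model():
    w = np.array([[0.0, 0.5], [0.5, 0.0]])
    return AffinityModel(w_p=w, w_n=w.copy(), sigma=np.ones(2), perplexity=1.5)


def energy_oracle(X, model, lam, beta=0.0):
    """Brute-force double loop over all ordered pairs."""
    n = X.shape[0]
    T = model.temporal if model.temporal is not None else np.zeros((n, n))
    E = 0.0
    for m in range(n):
        for k in range(n):
            d2 = float(np.sum((X[k] - X[m]) ** 2))
            E += model.w_p[k, m] * d2
            E += lam * (model.w_n[k, m] + beta * T[k, m]) * np.exp(-d2)
    return E


class TestEnergy:
    def test_coincident_equals_lambda(self, small_model):
        n = small_model.n_samples
        X = np.ones((n, 2)) * 0.3
        params = EEParams(lambda_=10.0, perplexity=8.0)
        assert energy(X, small_model, params) == pytest.approx(10.0, rel=1e-12)

    def test_attractive_term_nonnegative(self, small_model):
        # the lam = 0 limit of the energy: quadratic attractive term only
        n = small_model.n_samples
        X = np.random.default_rng(0).standard_normal((n, 2))
        E = energy_rows(X, X, small_model.w_p, small_model.w_n, 0.0, 0)
        assert E >= 0.0
        X0 = np.zeros((n, 2))
        assert energy_rows(X0, X0, small_model.w_p, small_model.w_n, 0.0, 0) == 0.0

    def test_matches_double_loop_oracle(self, rng):
        Y = rng.standard_normal((5, 3))
        model = build_affinities(Y, perplexity=3.0)
        X = rng.standard_normal((5, 2))
        params = EEParams(lambda_=10.0, perplexity=3.0)
        E = energy(X, model, params)
        assert E == pytest.approx(energy_oracle(X, model, 10.0), rel=1e-12)

    def test_tsee_matches_oracle(self, rng):
        Y = rng.standard_normal((5, 3))
        times = np.array([0.0, 0.5, 1.0, 1.5, 2.0])
        model = build_affinities(Y, perplexity=3.0, times=times)
        X = rng.standard_normal((5, 2))
        params = EEParams(lambda_=10.0, perplexity=3.0, beta=2.0)
        E = energy(X, model, params)
        assert E == pytest.approx(energy_oracle(X, model, 10.0, beta=2.0), rel=1e-12)

    def test_shape_mismatch(self, small_model):
        with pytest.raises(InvalidInputError):
            energy(np.zeros((3, 2)), small_model, EEParams(perplexity=8.0))


class TestLaplacian:
    def test_two_by_two(self):
        W = np.array([[0.0, 0.5], [0.5, 0.0]])
        assert np.array_equal(laplacian(W), [[0.5, -0.5], [-0.5, 0.5]])

    def test_rows_sum_to_zero(self, small_model):
        L = laplacian(small_model.w_p)
        assert np.max(np.abs(L @ np.ones(L.shape[0]))) <= 1e-15

    def test_quadratic_form_oracle(self, rng):
        raw = rng.uniform(size=(6, 6))
        W = raw + raw.T
        np.fill_diagonal(W, 0.0)
        L = laplacian(W)
        x = rng.standard_normal(6)
        quad = x @ L @ x
        oracle = 0.5 * sum(
            W[m, n] * (x[m] - x[n]) ** 2 for m in range(6) for n in range(6)
        )
        assert quad == pytest.approx(oracle, rel=1e-12)

    def test_asymmetric_rejected(self):
        with pytest.raises(InvalidInputError):
            laplacian(np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestGradient:
    def test_coincident_rows_zero(self, small_model):
        n = small_model.n_samples
        X = np.full((n, 2), 1.5)
        G, work = gradient(X, small_model, EEParams(perplexity=8.0))
        # stationary by symmetry; summation-order round-off only
        assert np.max(np.abs(G)) <= 1e-13
        assert np.all(np.diagonal(work.kernel) == 1.0)
        assert np.max(np.abs(work.l_k.sum(axis=1))) <= 1e-15

    @pytest.mark.parametrize("use_times", [False, True])
    def test_finite_difference_oracle(self, use_times, rng):
        n, d = 6, 2
        Y = rng.standard_normal((n, 3))
        times = np.arange(n) * 0.5 if use_times else None
        model = build_affinities(Y, perplexity=3.0, times=times)
        params = EEParams(lambda_=10.0, perplexity=3.0, beta=1.5)
        X = rng.standard_normal((n, d)) * 0.7
        G, _ = gradient(X, model, params)
        h = 1e-6
        Gfd = np.zeros_like(X)
        for i in range(n):
            for j in range(d):
                Xp, Xm = X.copy(), X.copy()
                Xp[i, j] += h
                Xm[i, j] -= h
                Gfd[i, j] = (
                    energy(Xp, model, params) - energy(Xm, model, params)
                ) / (2 * h)
        assert np.linalg.norm(G - Gfd) <= 1e-5 * np.linalg.norm(Gfd)

    def test_translation_invariance(self, small_model, rng):
        n = small_model.n_samples
        params = EEParams(lambda_=10.0, perplexity=8.0)
        X = rng.standard_normal((n, 2))
        shift = np.array([3.0, -7.0])
        assert energy(X + shift, small_model, params) == pytest.approx(
            energy(X, small_model, params), rel=1e-12
        )
        G, _ = gradient(X, small_model, params)
        assert np.max(np.abs(G.sum(axis=0))) <= 1e-10


class TestPreconditioner:
    def test_two_point_closed_form(self):
        model = two_point_model()
        params = EEParams(perplexity=1.5, mu=0.01)
        pre = build_preconditioner(model, params)
        assert np.allclose(pre.matrix, [[2.01, -2.0], [-2.0, 2.01]])

    def test_smallest_eigenvalue_at_least_mu(self, small_model):
        mu = 1e-3
        pre = build_preconditioner(small_model, EEParams(perplexity=8.0, mu=mu))
        eigs = np.linalg.eigvalsh(pre.matrix)
        assert eigs.min() >= mu - 1e-12

    def test_mu_zero_rejected(self, small_model):
        with pytest.raises(InvalidParameterError):
            EEParams(perplexity=8.0, mu=0.0)

    def test_auto_mu_positive(self, small_model):
        pre = build_preconditioner(small_model, EEParams(perplexity=8.0, mu="auto"))
        assert pre.mu > 0


class TestSolveDirection:
    def test_zero_gradient(self, small_model):
        pre = build_preconditioner(small_model, EEParams(perplexity=8.0))
        n = small_model.n_samples
        assert np.all(solve_direction(pre, np.zeros((n, 2))) == 0.0)

    def test_identity_dominant(self, small_model, rng):
        # huge mu makes B ~ mu I, so P ~ -G / mu
        mu = 1e12
        pre = build_preconditioner(small_model, EEParams(perplexity=8.0, mu=mu))
        G = rng.standard_normal((small_model.n_samples, 2))
        P = solve_direction(pre, G)
        assert np.allclose(mu * P, -G, rtol=1e-6)

    def test_residual_and_descent(self, small_model, rng):
        # moderate mu keeps the system well-conditioned so the residual
        # bound is meaningful
        pre = build_preconditioner(small_model, EEParams(perplexity=8.0, mu=1e-3))
        G = rng.standard_normal((small_model.n_samples, 2))
        P = solve_direction(pre, G)
        residual = np.linalg.norm(pre.matrix @ P + G)
        assert residual <= 1e-8 * np.linalg.norm(G)
        oracle = np.linalg.solve(pre.matrix, -G)
        assert np.allclose(P, oracle, rtol=1e-8)
        assert float(np.sum(G * P)) < 0.0

    def test_auto_mu_solve_matches_dense_oracle(self, small_model, rng):
        # with the tiny auto regularizer the system is ill-conditioned; the
        # solve is backward-stable and agrees with a direct dense solve
        pre = build_preconditioner(small_model, EEParams(perplexity=8.0))
        G = rng.standard_normal((small_model.n_samples, 2))
        P = solve_direction(pre, G)
        oracle = np.linalg.solve(pre.matrix, -G)
        assert np.linalg.norm(P - oracle) <= 1e-6 * np.linalg.norm(oracle)
        assert float(np.sum(G * P)) < 0.0


class TestLineSearch:
    def test_steepest_descent_accepts(self, small_model, rng):
        params = EEParams(lambda_=10.0, perplexity=8.0)
        n = small_model.n_samples
        X = rng.standard_normal((n, 2)) * 0.3
        G, _ = gradient(X, small_model, params)
        E0 = energy(X, small_model, params)
        alpha, E_new = line_search(
            X, -G, E0, G, small_model, params, alpha_init=1e-4
        )
        assert alpha == 1e-4
        assert E_new < E0

    def test_quadratic_full_newton_step(self, rng):
        # lam -> 0 limit: the energy is the quadratic whose Hessian is the
        # preconditioner (up to mu), so the unit step satisfies Armijo.
        Y = rng.standard_normal((10, 3))
        model = build_affinities(Y, perplexity=4.0)
        params = EEParams(lambda_=1e-14, perplexity=4.0, mu=1e-12)
        pre = build_preconditioner(model, params)
        X = rng.standard_normal((10, 2))
        G, _ = gradient(X, model, params)
        P = solve_direction(pre, G)
        E0 = energy(X, model, params)
        alpha, E_new = line_search(X, P, E0, G, model, params, alpha_init=1.0)
        assert alpha == 1.0
        assert E_new < E0

    def test_non_descent_rejected(self, small_model, rng):
        params = EEParams(lambda_=10.0, perplexity=8.0)
        n = small_model.n_samples
        X = rng.standard_normal((n, 2)) * 0.3
        G, _ = gradient(X, small_model, params)
        E0 = energy(X, small_model, params)
        with pytest.raises(InvalidDirectionError):
            line_search(X, +G, E0, G, small_model, params)


class TestFit:
    @pytest.mark.parametrize("lam", [np.e, 10.0])
    def test_two_point_closed_form(self, lam):
        model = two_point_model()
        params = EEParams(
            lambda_=lam, perplexity=1.5, dim=1, max_iter=500, tol=1e-14, seed=2
        )
        emb = fit(model, params)
        d2 = float((emb.coords[0, 0] - emb.coords[1, 0]) ** 2)
        assert d2 == pytest.approx(np.log(lam), abs=1e-4)

    def test_tsee_beta_zero_bitwise_equals_ee(self, rng):
        Y = rng.standard_normal((25, 4))
        times = np.repeat(np.arange(5) * 0.5, 5)
        p_ee = EEParams(perplexity=6.0, max_iter=30, seed=5)
        p_ts = EEParams(perplexity=6.0, max_iter=30, seed=5, beta=0.0)
        emb_ee = fit(Y, p_ee)
        emb_ts = fit(Y, p_ts, times=times)
        assert np.array_equal(emb_ee.coords, emb_ts.coords)
        assert np.array_equal(emb_ee.energy_trace, emb_ts.energy_trace)
        assert np.array_equal(emb_ee.step_trace, emb_ts.step_trace)

    def test_three_clusters_recovered(self):
        from sklearn.neighbors import KNeighborsClassifier

        from elastica.synthetic_data import make_clusters

        ds = make_clusters(150, 3, 10, separation=12.0, seed=4)
        emb = fit(ds.data.values, EEParams(perplexity=15.0, seed=0, max_iter=120))
        knn = KNeighborsClassifier(n_neighbors=1)
        # leave-one-out 1-NN agreement in the embedding
        agree = 0
        X, y = emb.coords, ds.labels
        for i in range(150):
            mask = np.ones(150, bool)
            mask[i] = False
            knn.fit(X[mask], y[mask])
            agree += int(knn.predict(X[i : i + 1])[0] == y[i])
        assert agree / 150 >= 0.95

    def test_monotone_trace_and_determinism(self, small_gaussian):
        params = EEParams(perplexity=8.0, max_iter=50, seed=11)
        e1 = fit(small_gaussian, params)
        e2 = fit(small_gaussian, params)
        assert np.array_equal(e1.coords, e2.coords)
        assert np.all(np.diff(e1.energy_trace) <= 1e-12)

    def test_bad_x0_shape(self, small_gaussian):
        with pytest.raises(InvalidInputError):
            fit(small_gaussian, EEParams(perplexity=8.0), X0=np.zeros((3, 2)))


class TestRelativeError:
    def test_identity(self, rng):
        A = rng.standard_normal((4, 2))
        assert relative_error(A, A) == 0.0

    def test_zero_comparand(self, rng):
        A = rng.standard_normal((4, 2))
        assert relative_error(A, np.zeros_like(A)) == 1.0

    def test_direct_arithmetic(self):
        A = np.array([[3.0, 0.0], [0.0, 4.0]])
        B = A + np.array([[0.0, 0.0], [0.0, 1.0]])
        assert relative_error(A, B) == pytest.approx(0.2, rel=1e-15)

    def test_zero_reference_undefined(self):
        with pytest.raises(InvalidInputError):
            relative_error(np.zeros((2, 2)), np.ones((2, 2)))

    def test_shape_mismatch(self):
        with pytest.raises(InvalidInputError):
            relative_error(np.zeros((2, 2)), np.zeros((3, 2)))


class TestParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"lambda_": 0.0},
            {"lambda_": -1.0},
            {"dim": 0},
            {"beta": -0.5},
            {"tol": 0.0},
            {"max_iter": 0},
            {"mu": -1.0},
            {"mu": "bogus"},
            {"init_scale": 0.0},
        ],
    )
    def test_invalid_params(self, kwargs):
        with pytest.raises(InvalidParameterError):
            EEParams(**kwargs)

    def test_defaults(self):
        p = EEParams()
        assert p.lambda_ == 10.0
        assert p.perplexity == 20.0
        assert p.dim == 2
        assert p.max_iter == 200
        assert p.mu == "auto"
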