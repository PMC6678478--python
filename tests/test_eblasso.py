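import numpy as np
import pytest
from scipy import integrate, stats
from scipy.optimize import minimize

from bloomlasso.design import FeatureDesign, Term
from bloomlasso.eblasso import (
    EBLassoFit,
    FitError,
    NEGHyperparams,
    adjusted_r2,
    coefficient_tests,
    fit_eblasso,
    goodness,
    marginal_log_posterior,
    marginal_prior_density,
    penalized_objective,
    predict,
)

from conftest import toy_design


# ------------------------------------------------------------------
# prior density
# ------------------------------------------------------------------

def test_prior_density_mode_value():
    # rate r = sqrt(2*0.5) = 1, mode value r/2
    assert marginal_prior_density(0.0, 0.5) == pytest.approx(0.5)
    assert marginal_prior_density(1.0, 0.5) == pytest.approx(0.5 * np.exp(-1.0))


def test_prior_density_matches_scale_mixture():
    """The Laplace form equals the normal-exponential mixture integral."""
    lam = 0.7
    for beta in (0.0, 0.3, -1.2, 2.5):
        mix, _ = integrate.quad(
            lambda s2: stats.norm.pdf(beta, scale=np.sqrt(s2)) * lam * np.exp(-lam * s2),
            0, np.inf,
        )
        assert marginal_prior_density(beta, lam) == pytest.approx(mix, abs=1e-6)


def test_prior_density_normalised():
    val, _ = integrate.quad(lambda b: marginal_prior_density(b, 0.31), -np.inf, np.inf)
    assert val == pytest.approx(1.0, abs=1e-6)


def test_prior_density_rejects_nonpositive_lambda():
    with pytest.raises(ValueError):
        marginal_prior_density(0.0, 0.0)


def test_hyperparams_validated():
    with pytest.raises(ValueError):
        NEGHyperparams(-1.5, 0.1)
    with pytest.raises(ValueError):
        NEGHyperparams(0.1, 0.0)


# ------------------------------------------------------------------
# penalised objective (the L1 oracle)
# ------------------------------------------------------------------

def test_zero_beta_is_intercept_only_loglik():
    d = toy_design(n=50, p=2, beta=[0.4, 0.0], seed=1)
    obj = penalized_objective(d, float(np.mean(d.y)), np.zeros(2), 1.0, lam=3.0)
    resid = d.y - np.mean(d.y)
    expected = -0.5 * len(d.y) * np.log(2 * np.pi) - 0.5 * resid @ resid
    assert obj == pytest.approx(expected)


def test_lambda_zero_maximised_by_ols():
    d = toy_design(n=80, p=3, beta=[1.0, -0.5, 0.2], seed=2)
    ols = np.linalg.lstsq(d.X, d.y - d.y.mean(), rcond=None)[0]
    at_ols = penalized_objective(d, float(d.y.mean()), ols, 1.0, lam=0.0)
    rng = np.random.default_rng(0)
    for _ in range(25):
        other = ols + rng.normal(0, 0.05, 3)
        assert penalized_objective(d, float(d.y.mean()), other, 1.0, 0.0) <= at_ols


def test_grid_search_matches_soft_threshold():
    """On an orthogonal 2-column design the L1 maximiser is the
    soft-thresholded OLS solution; a brute-force grid agrees."""
    rng = np.random.default_rng(4)
    n = 64
    A = rng.standard_normal((n, 2))
    Q, _ = np.linalg.qr(A - A.mean(0))
    X = Q * np.sqrt(n)  # orthogonal columns, norm^2 = n
    y = 0.9 * X[:, 0] + 0.1 * X[:, 1] + rng.normal(0, 0.4, n)
    y -= y.mean()
    d = FeatureDesign("y", y, X, [Term.of("TN"), Term.of("TP")])
    lam, s2 = 12.0, 0.16
    ols = X.T @ y / n
    soft = np.sign(ols) * np.maximum(np.abs(ols) - lam * s2 / n, 0.0)

    grid = np.linspace(-1.5, 1.5, 601)
    best, best_val = None, -np.inf
    for b1 in grid:
        vals = np.array([
            penalized_objective(d, 0.0, np.array([b1, b2]), s2, lam) for b2 in grid
        ])
        i = int(np.argmax(vals))
        if vals[i] > best_val:
            best_val, best = vals[i], np.array([b1, grid[i]])
    np.testing.assert_allclose(best, soft, atol=1e-2)
    assert penalized_objective(d, 0.0, soft, s2, lam) >= best_val - 1e-6


def test_objective_rejects_bad_noise():
    d = toy_design(n=10, p=2)
    with pytest.raises(ValueError):
        penalized_objective(d, 0.0, np.zeros(2), 0.0, 1.0)


# ------------------------------------------------------------------
# the EB fit
# ------------------------------------------------------------------

def test_pure_noise_gives_empty_support():
    d = toy_design(n=150, p=10, beta=None, noise=1.0, seed=7)
    fit = fit_eblasso(d, NEGHyperparams(1.0, 0.01))
    assert fit.support_size == 0
    assert np.all(fit.beta_mean == 0.0)


def test_ols_limit_under_noninformative_prior():
    d = toy_design(n=200, p=3, beta=[2.0, -1.5, 1.0], noise=0.1, seed=8)
    fit = fit_eblasso(d, NEGHyperparams(-1.0, 1e6))
    ols = np.linalg.lstsq(
        np.column_stack([np.ones(d.n), d.X]), d.y, rcond=None
    )[0]
    np.testing.assert_allclose(fit.beta_mean, ols[1:], atol=1e-3)


def test_ols_limit_relative_error_large_n():
    d = toy_design(n=5000, p=3, beta=[1.0, -0.5, 0.25], noise=0.5, seed=9)
    fit = fit_eblasso(d, NEGHyperparams(-1.0, 1e6))
    ols = np.linalg.lstsq(d.X, d.y - d.y.mean(), rcond=None)[0]
    assert np.max(np.abs(fit.beta_mean - ols) / np.abs(ols)) < 1e-2


def test_objective_monotone_over_sweeps():
    d = toy_design(n=120, p=6, beta=[0.8, 0, 0, -0.4, 0, 0], seed=10)
    fit = fit_eblasso(d, NEGHyperparams(0.1, 0.1), track_objective=True)
    diffs = np.diff(fit.objective_path)
    assert np.all(diffs > -1e-8)


@pytest.mark.parametrize("p", [1, 2, 3])
def test_fit_matches_direct_marginal_maximisation(p):
    """Coordinate ascent lands on the same optimum as direct numerical
    maximisation of the marginal log-posterior (independent route)."""
    d = toy_design(n=60, p=p, beta=[0.8, 0.0, -0.5][:p], noise=0.6, seed=11)
    hp = NEGHyperparams(0.1, 0.1)
    fit = fit_eblasso(d, hp)

    def neg(log_s):
        return -marginal_log_posterior(d, np.exp(log_s), fit.sigma_e2, hp)

    # coarse grid then local refinement, all on the direct objective
    grids = [np.log(np.logspace(-6, 1, 10))] * p
    best = min(
        (tuple(v) for v in np.stack(np.meshgrid(*grids), -1).reshape(-1, p)),
        key=lambda v: neg(np.array(v)),
    )
    res = minimize(neg, np.array(best), method="Nelder-Mead",
                   options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 20000})
    s_star = np.exp(res.x)
    K = d.X.T @ d.X + fit.sigma_e2 * np.diag(1.0 / np.maximum(s_star, 1e-280))
    beta_star = np.linalg.solve(K, d.X.T @ (d.y - d.y.mean()))
    np.testing.assert_allclose(fit.beta_mean, beta_star, atol=1e-3)


def test_shrinkage_monotone_in_prior_strength():
    """Decreasing b (stronger NEG prior) never grows the L1 norm."""
    d = toy_design(n=100, p=8, beta=[0.5, 0.3, 0, 0, 0, 0, 0, 0], seed=12)
    norms = [
        np.abs(fit_eblasso(d, NEGHyperparams(0.1, b)).beta_mean).sum()
        for b in (10.0, 1.0, 0.1, 0.01, 0.001)
    ]
    assert all(a >= b - 1e-9 for a, b in zip(norms, norms[1:]))


def test_support_bounded_by_n_minus_2():
    d = toy_design(n=12, p=40, beta=None, noise=1.0, seed=13)
    fit = fit_eblasso(d, NEGHyperparams(-0.9, 10.0))
    assert fit.support_size <= 10


def test_fit_deterministic(small_survey=None):
    d = toy_design(n=90, p=5, beta=[0.7, 0, 0.2, 0, 0], seed=14)
    f1 = fit_eblasso(d, NEGHyperparams(0.1, 0.1))
    f2 = fit_eblasso(d, NEGHyperparams(0.1, 0.1))
    assert np.array_equal(f1.beta_mean, f2.beta_mean)
    assert f1.sigma_e2 == f2.sigma_e2


# ------------------------------------------------------------------
# inference on coefficients / goodness of fit
# ------------------------------------------------------------------

def _fake_fit(mean, var, n):
    p = len(mean)
    support = np.array([i for i, m in enumerate(mean) if m != 0.0])
    return EBLassoFit(
        mu=0.0, beta_mean=np.asarray(mean, float), beta_var=np.asarray(var, float),
        support=support, sigma_e2=1.0, t_stats=np.zeros(len(support)),
        p_values=np.ones(len(support)), n=n,
    )


def test_t_statistic_oracle():
    fit = _fake_fit([1.0, 0.5, -0.3], [1.0, 0.01, 0.01], n=58)
    t, p = coefficient_tests(fit, 58)
    assert t[0] == pytest.approx(1.0)
    # Student-t oracle: df = 58 - 3 - 1
    assert p[0] == pytest.approx(2 * stats.t.sf(1.0, 54), abs=1e-12)
    assert p[0] == pytest.approx(0.3216, abs=2e-4)


def test_vanishing_variance_drives_p_to_zero():
    fit = _fake_fit([1.0], [1e-12], n=58)
    _, p = coefficient_tests(fit, 58)
    assert p[0] < 1e-10


def test_df_guard():
    fit = _fake_fit([1.0, 1.0, 1.0], [1.0, 1.0, 1.0], n=4)
    with pytest.raises(FitError):
        coefficient_tests(fit, 4)


def test_perfect_fit_r2_one():
    d = toy_design(n=40, p=2, beta=[1.0, -2.0], noise=1.0, seed=15)
    d.y = d.X @ np.array([1.0, -2.0])  # exactly linear
    fit = fit_eblasso(d, NEGHyperparams(-1.0, 1e6))
    g = goodness(fit, d)
    assert g["r2"] == pytest.approx(1.0, abs=1e-8)
    assert g["adj_r2"] == pytest.approx(1.0, abs=1e-8)


@pytest.mark.parametrize(
    "r2, n, k, expected",
    [(0.841, 58, 3, 0.832), (0.796, 58, 5, 0.776), (0.628, 58, 4, 0.600)],
)
def test_adjusted_r2_convention(r2, n, k, expected):
    assert adjusted_r2(r2, n, k) == pytest.approx(expected, abs=5e-4)


def test_predict_checks_columns():
    d = toy_design(n=30, p=3, beta=[1, 0, 0], seed=16)
    fit = fit_eblasso(d, NEGHyperparams(0.1, 0.1))
    with pytest.raises(FitError):
        predict(fit, np.zeros((5, 2)))
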