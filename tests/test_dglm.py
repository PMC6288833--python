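"""DGLM engine: closed forms, grid-search oracle, likelihood properties."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mvqtlmap import DesignPair, fit_dglm, loglik_normal
from mvqtlmap.dglm import fit_dglm_batch


def two_group_data():
    """6 points in two groups with SDs 1 and 3 (means 0 and 2)."""
    y = np.array([-0.8, 0.1, 0.9, -1.0, 2.0, 5.2])
    group = np.array([0, 0, 0, 1, 1, 1], dtype=float)
    X = np.column_stack([np.ones(6), group])
    return DesignPair(X, X, y, ("int", "grp"), ("int", "grp"))


def grid_search_two_group_ml(y, group):
    """Independent oracle: the two-group DGLM decouples into per-group
    (mean, log-variance) problems; maximize each on a dense refined grid."""
    out = []
    for g in (0, 1):
        yk = y[group == g]
        mu_grid = np.linspace(yk.min() - 2, yk.max() + 2, 400)
        th_grid = np.linspace(-8, 6, 400)
        for _ in range(3):  # successive refinement
            M, T = np.meshgrid(mu_grid, th_grid, indexing="ij")
            ll = -0.5 * (
                len(yk) * T + np.sum((yk[None, None, :] - M[..., None]) ** 2, axis=-1)
                * np.exp(-T)
            )
            i, j = np.unravel_index(np.argmax(ll), ll.shape)
            mu_best, th_best = M[i, j], T[i, j]
            dm = mu_grid[1] - mu_grid[0]
            dt = th_grid[1] - th_grid[0]
            mu_grid = np.linspace(mu_best - 2 * dm, mu_best + 2 * dm, 400)
            th_grid = np.linspace(th_best - 2 * dt, th_best + 2 * dt, 400)
        out.append((mu_best, th_best))
    return out


def test_intercept_only_closed_form():
    rng = np.random.default_rng(0)
    y = rng.normal(3.0, 2.0, 40)
    X = np.ones((40, 1))
    fit = fit_dglm(DesignPair(X, X, y))
    assert fit.converged
    assert fit.beta[0] == pytest.approx(y.mean(), abs=1e-8)
    # ML variance divides by n, not n-1
    assert np.exp(fit.theta[0]) == pytest.approx(y.var(ddof=0), rel=1e-7)


def test_homoscedastic_limit_equals_ols():
    rng = np.random.default_rng(1)
    n = 60
    X = np.column_stack([np.ones(n), rng.normal(size=n), rng.normal(size=n)])
    y = X @ [1.0, 0.5, -0.3] + rng.normal(size=n)
    fit = fit_dglm(DesignPair(X, np.ones((n, 1)), y))
    ols = np.linalg.lstsq(X, y, rcond=None)[0]
    assert np.allclose(fit.beta, ols, atol=1e-7)
    rss = np.sum((y - X @ ols) ** 2)
    ll_ml = -0.5 * n * (np.log(2 * np.pi * rss / n) + 1)
    assert fit.loglik == pytest.approx(ll_ml, abs=1e-7)


def test_two_group_fit_matches_grid_oracle():
    design = two_group_data()
    fit = fit_dglm(design)
    y, group = design.y, design.X_mean[:, 1]
    oracle = grid_search_two_group_ml(y, group)
    means = (fit.beta[0], fit.beta[0] + fit.beta[1])
    thetas = (fit.theta[0], fit.theta[0] + fit.theta[1])
    for (mu_o, th_o), mu_f, th_f in zip(oracle, means, thetas):
        assert mu_f == pytest.approx(mu_o, abs=5e-4)
        assert th_f == pytest.approx(th_o, abs=5e-4)


def test_loglik_trace_is_monotone():
    rng = np.random.default_rng(2)
    n = 80
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    y = X @ [0.0, 1.0] + rng.normal(size=n) * np.exp(0.4 * X[:, 1])
    fit = fit_dglm(DesignPair(X, X, y))
    assert np.all(np.diff(fit.loglik_trace) >= -1e-9)
    assert fit.converged


def test_loglik_stationary_at_optimum():
    rng = np.random.default_rng(3)
    n = 200
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    y = X @ [1.0, 0.8] + rng.normal(size=n) * np.exp(0.3 * X[:, 1])
    fit = fit_dglm(DesignPair(X, X, y))
    w = fit.fitted_sds**-2
    resid = y - fit.fitted_means
    grad_beta = X.T @ (w * resid)
    grad_theta = 0.5 * X.T @ (resid**2 * w - 1)
    assert np.linalg.norm(grad_beta) < 1e-5
    assert np.linalg.norm(grad_theta) < 1e-5


def test_nested_models_never_lose_likelihood():
    rng = np.random.default_rng(4)
    n = 100
    x = rng.normal(size=n)
    y = 0.5 * x + rng.normal(size=n) * np.exp(0.3 * x)
    ones = np.ones((n, 1))
    X = np.column_stack([np.ones(n), x])
    full = fit_dglm(DesignPair(X, X, y))
    for Xm, Xv in [(ones, X), (X, ones), (ones, ones)]:
        null = fit_dglm(DesignPair(Xm, Xv, y))
        assert full.loglik >= null.loglik - 1e-8


def test_rank_deficient_design_names_columns():
    n = 30
    x = np.linspace(0, 1, n)
    X = np.column_stack([np.ones(n), x, 2 * x])
    with pytest.raises(ValueError, match="collinear"):
        fit_dglm(DesignPair(X, np.ones((n, 1)), np.zeros(n),
                            ("int", "a", "a_doubled"), ("int",)))


def test_loglik_normal_values_and_errors():
    assert loglik_normal([0.0], [0.0], [1.0]) == pytest.approx(
        -0.5 * np.log(2 * np.pi), abs=1e-9
    )
    with pytest.raises(ValueError):
        loglik_normal([0.0], [0.0], [0.0])


@settings(max_examples=50, deadline=None)
@given(
    st.lists(st.floats(-5, 5), min_size=2, max_size=8),
    st.floats(0.2, 5.0),
)
def test_loglik_normal_scaling_identity(vals, c):
    """Scaling y, mu, sigma jointly by c shifts the loglik by -n log c."""
    y = np.array(vals)
    mu = np.zeros_like(y)
    sd = np.ones_like(y)
    base = loglik_normal(y, mu, sd)
    scaled = loglik_normal(c * y, c * mu, c * sd)
    assert scaled == pytest.approx(base - len(y) * np.log(c), abs=1e-7)
    # and it matches naive per-point summation
    naive = sum(
        -0.5 * np.log(2 * np.pi * s**2) - (yi - m) ** 2 / (2 * s**2)
        for yi, m, s in zip(y, mu, sd)
    )
    assert base == pytest.approx(naive, abs=1e-9)


def test_batched_fitter_agrees_with_single_path():
    rng = np.random.default_rng(5)
    n, B = 120, 7
    Xm = rng.normal(size=(B, n, 3))
    Xm[:, :, 0] = 1.0
    Xv = Xm[:, :, :2].copy()
    y = rng.normal(size=n)
    batch = fit_dglm_batch(Xm, Xv, y)
    for b in range(B):
        single = fit_dglm(DesignPair(Xm[b], Xv[b], y))
        assert single.loglik == pytest.approx(batch["loglik"][b], abs=1e-6)
        assert np.allclose(single.beta, batch["beta"][b], atol=1e-5)
        assert np.allclose(single.theta, batch["theta"][b], atol=1e-5)


def test_parameter_recovery_and_se_calibration():
    """Estimates land within 3 SEs of truth ~95% of the time (DGLM truth)."""
    rng = np.random.default_rng(6)
    n, reps = 5000, 60
    beta_true = np.array([1.0, 0.5])
    theta_true = np.array([-0.2, 0.4])
    hits = 0
    total = 0
    for _ in range(reps):
        x = rng.normal(size=n)
        X = np.column_stack([np.ones(n), x])
        y = X @ beta_true + rng.normal(size=n) * np.exp(0.5 * (X @ theta_true))
        fit = fit_dglm(DesignPair(X, X, y))
        for est, se, truth in zip(
            np.r_[fit.beta, fit.theta],
            np.r_[fit.se_beta, fit.se_theta],
            np.r_[beta_true, theta_true],
        ):
            hits += abs(est - truth) < 3 * se
            total += 1
    assert hits / total >= 0.95


def test_se_shrinks_like_inverse_sqrt_n():
    rng = np.random.default_rng(7)
    n_full = 6400
    x = rng.normal(size=n_full)
    y = 0.7 * x + rng.normal(size=n_full) * np.exp(0.2 * x)
    sizes = [400, 800, 1600, 3200, 6400]
    ses = []
    for n in sizes:
        X = np.column_stack([np.ones(n), x[:n]])
        fit = fit_dglm(DesignPair(X, X, y[:n]))
        ses.append(fit.se_beta[1])
    slope = np.polyfit(np.log(sizes), np.log(ses), 1)[0]
    assert -0.6 < slope < -0.4
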