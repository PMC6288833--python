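"""Double generalized linear model: joint mean and log-variance regression.

The model for a response vector y is

    y_i ~ Normal(mu_i, sigma_i^2)
    mu_i          = x_mean_i' beta
    log sigma_i^2 = x_var_i'  theta

fitted by full maximum likelihood with block-coordinate ascent: a weighted
least squares update for ``beta`` with weights 1/sigma_i^2, alternating
with a concave Newton (Fisher-scoring with step halving) update of
``theta`` driven by the squared residuals — equivalent to a gamma GLM with
log link and prior weights 1/2 on d_i = (y_i - mu_i)^2.  Both block
updates maximize their block exactly, so the log-likelihood is monotone
non-decreasing across iterations.

Estimates are ML, not REML: the genome-scan likelihood-ratio tests compare
likelihoods across different mean designs, and REML likelihoods are not
comparable in that setting.  Standard errors come from the per-block
information matrices at convergence: Cov(beta) = (X_m' W X_m)^{-1} with
W = diag(1/sigma_i^2), and Cov(theta) = 2 (X_v' X_v)^{-1}.

A batched fitter (`fit_dglm_batch`) vectorizes the same algorithm across
many small design pairs (loci x permutations); the single-fit public entry
point is a thin validated wrapper around it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DesignPair", "DglmFit", "fit_dglm", "fit_dglm_batch", "loglik_normal"]

_LOG_2PI = float(np.log(2.0 * np.pi))
_ETA_CLIP = 30.0  # log-variance bound; sigma^2 confined to [e^-30, e^30]
_D_FLOOR = 1e-12  # floor for squared residuals before the log-link update


def loglik_normal(y, means, sds) -> float:
    """Normal log-likelihood sum_i [-log(2 pi sd_i^2)/2 - (y_i-mu_i)^2/(2 sd_i^2)]."""
    y = np.asarray(y, float)
    means = np.asarray(means, float)
    sds = np.asarray(sds, float)
    if np.any(sds <= 0):
        raise ValueError("standard deviations must be positive")
    z = (y - means) / sds
    return float(np.sum(-0.5 * _LOG_2PI - np.log(sds) - 0.5 * z * z))


@dataclass
class DesignPair:
    """Aligned mean/variance design matrices and response for one fit.

    Both designs must contain an intercept column; rows with missing
    values are expected to have been dropped upstream (the scan module
    enforces a common row set between an alternative and its null).
    """

    X_mean: np.ndarray
    X_var: np.ndarray
    y: np.ndarray
    mean_names: tuple[str, ...] | None = None
    var_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.X_mean = np.atleast_2d(np.asarray(self.X_mean, float))
        self.X_var = np.atleast_2d(np.asarray(self.X_var, float))
        self.y = np.asarray(self.y, float).ravel()
        n = self.y.shape[0]
        if self.X_mean.shape[0] != n or self.X_var.shape[0] != n:
            raise ValueError("design matrices and response must share row count")
        if np.isnan(self.y).any() or np.isnan(self.X_mean).any() or np.isnan(self.X_var).any():
            raise ValueError("missing values must be dropped before fitting")
        if self.mean_names is None:
            self.mean_names = tuple(f"m{j}" for j in range(self.X_mean.shape[1]))
        if self.var_names is None:
            self.var_names = tuple(f"v{j}" for j in range(self.X_var.shape[1]))


@dataclass
class DglmFit:
    """Fitted DGLM: coefficient blocks, SEs, covariances and diagnostics."""

    beta: np.ndarray
    se_beta: np.ndarray
    theta: np.ndarray
    se_theta: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    fitted_means: np.ndarray
    fitted_sds: np.ndarray
    cov_beta: np.ndarray
    cov_theta: np.ndarray
    mean_names: tuple[str, ...] = ()
    var_names: tuple[str, ...] = ()
    loglik_trace: np.ndarray = field(default_factory=lambda: np.empty(0))


def _check_full_rank(X: np.ndarray, names, label: str) -> None:
    _, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    bad = [names[j] for j in np.nonzero(diag <= tol)[0]]
    if bad:
        raise ValueError(f"{label} design is rank deficient; collinear columns: {bad}")


def _solve_batch(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Batched linear solve with a pseudoinverse fallback for singular
    members (degenerate loci)."""
    try:
        return np.linalg.solve(A, b[..., None])[..., 0]
    except np.linalg.LinAlgError:
        out = np.empty_like(b)
        for i in range(A.shape[0]):
            try:
                out[i] = np.linalg.solve(A[i], b[i])
            except np.linalg.LinAlgError:
                out[i] = np.linalg.pinv(A[i]) @ b[i]
        return out


def fit_dglm_batch(
    X_mean: np.ndarray,
    X_var: np.ndarray,
    y: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 50,
    record_trace: bool = False,
) -> dict:
    """Fit B independent DGLMs that share a common sample size.

    Parameters
    ----------
    X_mean, X_var
        Arrays of shape (B, n, p) and (B, n, q).
    y
        Response, shape (n,) or (B, n).

    Returns a dict of batched results: ``beta`` (B, p), ``theta`` (B, q),
    ``loglik`` (B,), ``n_iter`` (B,), ``converged`` (B,) plus the
    per-block covariance matrices.
    """
    Xm = np.asarray(X_mean, float)
    Xv = np.asarray(X_var, float)
    B, n, p = Xm.shape
    q = Xv.shape[2]
    y = np.broadcast_to(np.asarray(y, float), (B, n))

    XmT = Xm.transpose(0, 2, 1)
    XvT = Xv.transpose(0, 2, 1)
    XvTXv = XvT @ Xv  # Fisher information (x2) for theta; constant across iters

    # init: OLS beta; theta from a log-scale regression on squared residuals
    beta = _solve_batch(XmT @ Xm, np.einsum("bpn,bn->bp", XmT, y))
    mu = np.einsum("bnp,bp->bn", Xm, beta)
    d = np.maximum((y - mu) ** 2, _D_FLOOR)
    # E[log chi2_1] = -1.27036...; correct the log-residual regression
    theta = _solve_batch(XvTXv, np.einsum("bqn,bn->bq", XvT, np.log(d) + 1.270362845))
    eta = np.clip(np.einsum("bnq,bq->bn", Xv, theta), -_ETA_CLIP, _ETA_CLIP)

    w = np.exp(-eta)  # 1/sigma_i^2, kept in sync with eta throughout
    ll = -0.5 * np.sum(_LOG_2PI + eta + d * w, axis=1)
    trace = [ll.copy()] if record_trace else None
    converged = np.zeros(B, dtype=bool)
    n_iter = np.zeros(B, dtype=int)

    for it in range(1, max_iter + 1):
        # restrict all work to the unconverged members of the batch
        full = converged.sum() == 0
        a = slice(None) if full else np.nonzero(~converged)[0]
        Xm_a, Xv_a, y_a = Xm[a], Xv[a], y[a]
        XmT_a, XvT_a = Xm_a.transpose(0, 2, 1), Xv_a.transpose(0, 2, 1)
        XvTXv_a = XvTXv[a]
        theta_a, eta_a, w_a, ll_a = theta[a], eta[a], w[a], ll[a]
        Ba = Xm_a.shape[0]

        # beta block: exact WLS maximizer given current sigma
        A = XmT_a @ (w_a[:, :, None] * Xm_a)
        rhs = np.einsum("bpn,bn->bp", XmT_a, w_a * y_a)
        beta_a = _solve_batch(A, rhs)
        mu_a = np.einsum("bnp,bp->bn", Xm_a, beta_a)
        d_a = np.maximum((y_a - mu_a) ** 2, _D_FLOOR)

        # theta block: Fisher scoring with vectorized step halving; the
        # block objective is concave so halving guarantees ascent.  A few
        # steps per outer pass suffice; the outer loop finishes the job.
        llv = -0.5 * np.sum(eta_a + d_a * w_a, axis=1)
        for _ in range(3):
            g = np.einsum("bqn,bn->bq", XvT_a, d_a * w_a - 1.0)
            delta = _solve_batch(XvTXv_a, g)
            step = np.ones(Ba)
            for _h in range(30):
                theta_new = theta_a + step[:, None] * delta
                eta_new = np.clip(
                    np.einsum("bnq,bq->bn", Xv_a, theta_new), -_ETA_CLIP, _ETA_CLIP
                )
                w_new = np.exp(-eta_new)
                llv_new = -0.5 * np.sum(eta_new + d_a * w_new, axis=1)
                bad = llv_new < llv - 1e-12
                if not bad.any():
                    break
                step[bad] *= 0.5
            theta_a, eta_a, w_a = theta_new, eta_new, w_new
            llv = llv_new

        ll_new = llv - 0.5 * n * _LOG_2PI
        beta[a], theta[a], eta[a], w[a], mu[a], d[a] = (
            beta_a, theta_a, eta_a, w_a, mu_a, d_a,
        )
        just = np.abs(ll_new - ll_a) < tol
        ll[a] = ll_new
        if full:
            n_iter[just] = it
            converged = just.copy()
        else:
            n_iter[a[just]] = it
            converged[a[just]] = True
        if record_trace:
            trace.append(ll.copy())
        if converged.all():
            break
    n_iter[~converged] = max_iter

    info_beta = XmT @ (w[:, :, None] * Xm)
    try:
        cov_beta = np.linalg.inv(info_beta)
        cov_theta = 2.0 * np.linalg.inv(XvTXv)
    except np.linalg.LinAlgError:
        cov_beta = np.stack([np.linalg.pinv(info_beta[i]) for i in range(B)])
        cov_theta = 2.0 * np.stack([np.linalg.pinv(XvTXv[i]) for i in range(B)])

    out = {
        "beta": beta,
        "theta": theta,
        "loglik": ll,
        "n_iter": n_iter,
        "converged": converged,
        "fitted_means": mu,
        "fitted_sds": np.exp(0.5 * eta),
        "cov_beta": cov_beta,
        "cov_theta": cov_theta,
    }
    if record_trace:
        out["loglik_trace"] = np.stack(trace, axis=1)
    return out


def fit_dglm(design: DesignPair, tol: float = 1e-8, max_iter: int = 50) -> DglmFit:
    """Fit one DGLM by joint maximum likelihood.

    Raises on rank-deficient designs (naming the collinear columns);
    returns ``converged=False`` rather than raising when the iteration
    limit is hit, leaving the decision to the caller.
    """
    n = design.y.shape[0]
    p, q = design.X_mean.shape[1], design.X_var.shape[1]
    if n <= p + q:
        raise ValueError(f"need n > p + q ({n} rows for {p}+{q} parameters)")
    _check_full_rank(design.X_mean, design.mean_names, "mean")
    _check_full_rank(design.X_var, design.var_names, "variance")

    res = fit_dglm_batch(
        design.X_mean[None], design.X_var[None], design.y[None],
        tol=tol, max_iter=max_iter, record_trace=True,
    )
    return DglmFit(
        beta=res["beta"][0],
        se_beta=np.sqrt(np.diag(res["cov_beta"][0])),
        theta=res["theta"][0],
        se_theta=np.sqrt(np.diag(res["cov_theta"][0])),
        loglik=float(res["loglik"][0]),
        n_iter=int(res["n_iter"][0]),
        converged=bool(res["converged"][0]),
        fitted_means=res["fitted_means"][0],
        fitted_sds=res["fitted_sds"][0],
        cov_beta=res["cov_beta"][0],
        cov_theta=res["cov_theta"][0],
        mean_names=design.mean_names,
        var_names=design.var_names,
        loglik_trace=res["loglik_trace"][0],
    )
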