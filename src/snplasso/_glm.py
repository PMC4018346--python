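"""Internal maximum-likelihood solvers.

A small Newton-Raphson logistic fitter (fast enough to sit inside
permutation and bootstrap loops) and a multinomial logit fitter that
supports tying a coefficient across outcome categories, which is what
the subtype-heterogeneity likelihood-ratio test needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special

# Newton convergence policy: hard iteration cap with a gradient-norm
# criterion; fits beyond the cap are flagged, never raised.
MAX_ITER = 100
GRAD_TOL = 1e-8
#: |beta| beyond this is treated as quasi-separation.
SEPARATION_BOUND = 30.0


@dataclass
class LogisticFit:
    beta: np.ndarray
    loglik: float
    cov: np.ndarray  # inverse observed information
    converged: bool
    n_iter: int
    flags: list[str] = field(default_factory=list)


def _loglik(eta: np.ndarray, y: np.ndarray, w: np.ndarray | None) -> float:
    ll = y * eta - np.logaddexp(0.0, eta)
    return float(ll.sum() if w is None else (w * ll).sum())


def logistic_fit(
    X: np.ndarray,
    y: np.ndarray,
    sample_weight: np.ndarray | None = None,
    max_iter: int = MAX_ITER,
    tol: float = GRAD_TOL,
) -> LogisticFit:
    """Newton-Raphson fit of a binary logistic model.

    ``X`` must already include the intercept column. Uses step-halving
    on log-likelihood decreases and a pseudoinverse fallback when the
    observed information is singular (collinear design).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    w = None if sample_weight is None else np.asarray(sample_weight, dtype=float)
    beta = np.zeros(p)
    eta = X @ beta
    ll = _loglik(eta, y, w)
    flags: list[str] = []
    converged = False
    it = 0
    singular = False
    for it in range(1, max_iter + 1):
        mu = special.expit(eta)
        resid = y - mu
        wvar = mu * (1.0 - mu)
        if w is not None:
            resid = w * resid
            wvar = w * wvar
        grad = X.T @ resid
        if np.linalg.norm(grad, ord=np.inf) < tol:
            converged = True
            break
        hess = X.T @ (wvar[:, None] * X)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]
            singular = True
        # step halving
        scale = 1.0
        for _ in range(30):
            beta_new = beta + scale * step
            eta_new = X @ beta_new
            ll_new = _loglik(eta_new, y, w)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        beta, eta, ll = beta_new, eta_new, ll_new
    if singular:
        flags.append("singular_information")
    if not converged:
        flags.append("nonconverged")
    if np.abs(beta).max() > SEPARATION_BOUND:
        flags.append("separation")
    mu = special.expit(eta)
    wvar = mu * (1.0 - mu)
    if w is not None:
        wvar = w * wvar
    hess = X.T @ (wvar[:, None] * X)
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(hess)
        if "singular_information" not in flags:
            flags.append("singular_information")
    return LogisticFit(beta, ll, cov, converged, it, flags)


def intercept_only_loglik(y: np.ndarray, sample_weight: np.ndarray | None = None) -> float:
    """Closed-form log-likelihood of the intercept-only logistic model."""
    y = np.asarray(y, dtype=float)
    if sample_weight is None:
        n1 = y.sum()
        n = y.size
    else:
        w = np.asarray(sample_weight, dtype=float)
        n1 = float(w @ y)
        n = float(w.sum())
    n0 = n - n1
    if n1 == 0 or n0 == 0:
        return 0.0
    return float(n1 * np.log(n1 / n) + n0 * np.log(n0 / n))


# ---------------------------------------------------------------------------
# Multinomial logit with optional coefficient tying
# ---------------------------------------------------------------------------


@dataclass
class MultinomialFit:
    #: (p, K-1) coefficient matrix; reference category is code 0.
    coef: np.ndarray
    loglik: float
    converged: bool
    n_categories: int
    tied_cols: tuple[int, ...]


def multinomial_fit(
    X: np.ndarray,
    y_codes: np.ndarray,
    tied_cols: tuple[int, ...] = (),
    max_iter: int = 500,
) -> MultinomialFit:
    """Fit a multinomial logit of ``y_codes`` (0 = reference) on ``X``.

    Columns listed in ``tied_cols`` get a single coefficient shared by
    every non-reference category; all other columns get one coefficient
    per category. Optimized with L-BFGS on the exact likelihood with an
    analytic gradient.
    """
    X = np.asarray(X, dtype=float)
    y_codes = np.asarray(y_codes, dtype=int)
    n, p = X.shape
    K = int(y_codes.max()) + 1
    if K < 2:
        raise ValueError("need at least two outcome categories")
    m = K - 1
    tied = tuple(sorted(set(tied_cols)))
    free = tuple(j for j in range(p) if j not in tied)
    Xf = X[:, list(free)]
    Xt = X[:, list(tied)]
    Y = np.zeros((n, m))
    for k in range(1, K):
        Y[:, k - 1] = y_codes == k

    n_free = len(free) * m
    n_tied = len(tied)

    def unpack(theta: np.ndarray) -> np.ndarray:
        B = np.zeros((p, m))
        if free:
            B[list(free), :] = theta[:n_free].reshape(len(free), m)
        if tied:
            B[list(tied), :] = theta[n_free:, None]
        return B

    def nll_grad(theta: np.ndarray) -> tuple[float, np.ndarray]:
        Bf = theta[:n_free].reshape(len(free), m) if free else np.zeros((0, m))
        bt = theta[n_free:]
        eta = Xf @ Bf
        if n_tied:
            eta = eta + (Xt @ bt)[:, None]
        # log-softmax with implicit 0 column for the reference
        denom = np.logaddexp.reduce(
            np.concatenate([np.zeros((n, 1)), eta], axis=1), axis=1
        )
        ll = float((Y * eta).sum() - denom.sum())
        P = np.exp(eta - denom[:, None])
        R = Y - P
        parts = []
        if free:
            parts.append((Xf.T @ R).ravel())
        if n_tied:
            parts.append(Xt.T @ R.sum(axis=1))
        grad = np.concatenate(parts) if parts else np.zeros(0)
        return -ll, -grad

    theta0 = np.zeros(n_free + n_tied)
    res = optimize.minimize(
        nll_grad,
        theta0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-9},
    )
    return MultinomialFit(
        coef=unpack(res.x),
        loglik=-float(res.fun),
        converged=bool(res.success),
        n_categories=K,
        tied_cols=tied,
    )
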