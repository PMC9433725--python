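"""Maximum-likelihood logistic regression by iteratively reweighted least squares.

Small, self-contained fitter used by the stepwise conditional procedure. It
implements exactly the semantics the decomposition needs: complete-case
input, explicit collinearity and separation detection (callers treat a term
from a non-converged fit as fully explained by the conditioning set), and
per-term Wald P-values from (beta/SE)^2 against chi-square(1).
"""

from __future__ import annotations

import numpy as np
from scipy.stats import chi2

from .datatypes import LogisticFit

_SCORE_TOL = 1e-8
_LL_RTOL = 1e-10
_MAX_ITER = 100
_SEPARATION_BETA = 30.0  # |slope| beyond this on dosage scale => separation


def _log_likelihood(y: np.ndarray, eta: np.ndarray) -> float:
    # numerically stable Bernoulli log-likelihood: sum y*eta - log(1+exp(eta))
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def logistic_fit(y: np.ndarray, X: np.ndarray) -> LogisticFit:
    """Fit logit P(y=1) = b0 + X b on complete cases.

    Parameters
    ----------
    y : (n,) array of 0/1 outcomes.
    X : (n, p) array of predictor columns (dosages); an intercept is added
        internally and reported first.

    Returns
    -------
    LogisticFit with ``converged=False`` when the design is rank-deficient,
    the data are separated, or IRLS fails; coefficients/SEs are then NaN and
    callers decide the fallback (the stepwise procedure uses conditional
    P := 1 for the term of interest).
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.shape[0]:
        X = X.T
    n, p = X.shape
    k = p + 1
    bad = LogisticFit(
        coefficients=np.full(k, np.nan),
        standard_errors=np.full(k, np.nan),
        wald_p=np.full(k, np.nan),
        converged=False,
        n_used=n,
    )
    if n == 0 or y.min() == y.max():
        return bad
    A = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(A) < k:
        return bad

    beta = np.zeros(k)
    ll_old = _log_likelihood(y, A @ beta)
    converged = False
    for _ in range(_MAX_ITER):
        eta = A @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        score = A.T @ (y - mu)
        if np.max(np.abs(score)) < _SCORE_TOL:
            converged = True
            break
        AW = A * w[:, None]
        info = A.T @ AW
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            return bad
        # step-halving keeps the likelihood monotone near separation
        for _ in range(25):
            cand = beta + step
            ll_new = _log_likelihood(y, A @ cand)
            if ll_new >= ll_old - 1e-12:
                break
            step *= 0.5
        beta = beta + step
        if abs(ll_new - ll_old) < _LL_RTOL * (abs(ll_old) + 1.0):
            beta_ok = np.all(np.abs(beta[1:]) < _SEPARATION_BETA)
            converged = bool(np.max(np.abs(A.T @ (y - (1.0 / (1.0 + np.exp(-(A @ beta))))))) < 1e-3) and beta_ok
            break
        ll_old = ll_new
    if not converged or np.any(np.abs(beta[1:]) >= _SEPARATION_BETA):
        return bad

    eta = A @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    info = A.T @ (A * w[:, None])
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        return bad
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = (beta / se) ** 2
    pvals = np.where(np.isfinite(wald), chi2.sf(wald, df=1), np.nan)
    pvals = np.clip(pvals, np.nextafter(0.0, 1.0), 1.0)
    return LogisticFit(
        coefficients=beta,
        standard_errors=se,
        wald_p=pvals,
        converged=True,
        n_used=n,
    )
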