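"""Independent reference implementations used to cross-check the package.

These deliberately avoid the code paths they validate: dense trapezoid
integration instead of Gauss-Hermite quadrature, an explicit Newton-Raphson
logistic fit instead of statsmodels, and a double python loop instead of the
vectorized PRS scorer.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm


def brute_retrospective_loglik(alpha, cohort_df, baseline, params,
                               n_outer=4000, n_inner=4001, lim=8.0):
    """Retrospective log-likelihood by dense trapezoid integration.

    The integral over the PRS value u uses ``n_outer`` points on [-lim, lim]
    and the inner integral over the residual polygene ``n_inner`` points.
    The double integral factorizes as exp(sigma_u (a*u + b*x)) =
    exp(sigma_u a u) * exp(sigma_u b x), which keeps the dense grids
    tractable without changing the integrand.
    """
    beta = np.sqrt(1.0 - alpha**2)
    sigma = np.sqrt(params.gamma + params.theta * baseline.ages)
    lam0 = baseline.lambda0
    u = np.linspace(-lim, lim, n_outer)
    x = np.linspace(-lim, lim, n_inner)
    phi_u = norm.pdf(u)
    phi_x = norm.pdf(x)

    denom_cache: dict[tuple[int, int], float] = {}
    ll = 0.0
    for row in cohort_df.itertuples():
        st, t, z = int(row.status), int(row.age), float(row.prs_std)
        ti = t - baseline.age_min

        def prob(scores):
            if ti > 0:
                lam_cum = np.exp(np.multiply.outer(scores, sigma[:ti])) @ lam0[:ti]
            else:
                lam_cum = np.zeros_like(scores)
            val = np.exp(-lam_cum)
            if st == 1:
                val = val * lam0[ti] * np.exp(sigma[ti] * scores)
            return val

        p_num = np.trapezoid(prob(alpha * z + beta * x) * phi_x, x)
        key = (st, t)
        if key not in denom_cache:
            if ti > 0:
                a_mat = np.exp(np.multiply.outer(alpha * u, sigma[:ti])) * lam0[:ti]
                b_mat = np.exp(np.multiply.outer(beta * x, sigma[:ti]))
                lam_cum = a_mat @ b_mat.T  # (n_outer, n_inner)
            else:
                lam_cum = np.zeros((u.size, x.size))
            val = np.exp(-lam_cum)
            if st == 1:
                scores = alpha * u[:, None] + beta * x[None, :]
                val = val * (lam0[ti] * np.exp(sigma[ti] * scores))
            inner = np.trapezoid(val * phi_x[None, :], x, axis=1)
            denom_cache[key] = float(np.trapezoid(inner * phi_u, u))
        ll += np.log(p_num) - np.log(denom_cache[key]) + norm.logpdf(z)
    return float(ll)


def newton_logistic(X, y, tol=1e-12, max_iter=100):
    """Logistic regression coefficients by explicit Newton-Raphson.

    ``X`` includes the intercept column.  Returns the coefficient vector.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    b = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ b
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        grad = X.T @ (y - p)
        hess = (X * w[:, None]).T @ X
        step = np.linalg.solve(hess, grad)
        b = b + step
        if np.max(np.abs(step)) < tol:
            break
    return b


def double_loop_prs(dosage, weights):
    """Raw PRS by an explicit double loop over samples and variants."""
    n, m = dosage.shape
    out = np.zeros(n)
    for i in range(n):
        for j in range(m):
            out[i] += weights[j] * dosage[i, j]
    return out
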