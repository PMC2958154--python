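"""Independent oracles used by the test suite.

These deliberately re-derive quantities through a different route than the
package (quadrature instead of Laplace, explicit two-formula CCC, brute
force sums) so agreement is evidence, not tautology.
"""

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize
from scipy.special import expit, logsumexp


def agq_loglik(theta, X, y, area_codes, n_nodes=51):
    """Adaptive Gauss-Hermite marginal log-likelihood of the random-intercept
    logistic model, centred and scaled at each area's conditional mode."""
    phi, beta = theta[0], np.asarray(theta[1:])
    sig = np.exp(phi)
    nodes, weights = hermgauss(n_nodes)
    eta_fix = X @ beta
    total = 0.0
    for i in np.unique(area_codes):
        mask = area_codes == i
        yi, ei = y[mask], eta_fix[mask]
        d = 0.0
        for _ in range(200):
            p = expit(ei + d)
            g = np.sum(yi - p) - d / sig**2
            h = np.sum(p * (1 - p)) + 1 / sig**2
            d += g / h
            if abs(g) < 1e-13:
                break
        s = 1.0 / np.sqrt(h)
        dk = d + np.sqrt(2.0) * s * nodes
        eta_k = ei[:, None] + dk[None, :]
        ll_k = (yi[:, None] * eta_k - np.logaddexp(0.0, eta_k)).sum(axis=0)
        log_prior = -0.5 * np.log(2 * np.pi * sig**2) - dk**2 / (2 * sig**2)
        total += logsumexp(
            ll_k + log_prior + nodes**2 + np.log(weights) + 0.5 * np.log(2.0) + np.log(s)
        )
    return float(total)


def maximize_agq(X, y, area_codes, n_nodes=51):
    """Maximise the quadrature log-likelihood over (log sigma, beta)."""
    theta0 = np.concatenate(([np.log(0.3)], np.zeros(X.shape[1])))
    res = minimize(
        lambda th: -agq_loglik(th, X, y, area_codes, n_nodes),
        theta0,
        method="Nelder-Mead",
        options={"maxiter": 20_000, "xatol": 1e-9, "fatol": 1e-12},
    )
    return -res.fun, res.x


def ccc_two_formula(x, y):
    """Lin's CCC as Pearson correlation times the bias-correction factor C_b."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    sx, sy = x.std(), y.std()
    r = np.corrcoef(x, y)[0, 1]
    u = (x.mean() - y.mean()) / np.sqrt(sx * sy)
    c_b = 2.0 / (sx / sy + sy / sx + u**2)
    return float(r * c_b), float(c_b)
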