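"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — direct summation, grid search,
textbook formulas — and shares no code with the package.
"""

from __future__ import annotations

import math

import numpy as np


def binom_tail(k: int, n: int, p: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p), by direct summation."""
    if k <= 0:
        return 1.0
    total = 0.0
    for j in range(k, n + 1):
        total += math.comb(n, j) * (p ** j) * ((1.0 - p) ** (n - j))
    return min(total, 1.0)


def pearson_r_p(x, y) -> tuple[float, float]:
    """Pearson r and two-sided p from the closed-form t transform."""
    from scipy.stats import t as tdist

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    xm = x - x.mean()
    ym = y - y.mean()
    r = float((xm * ym).sum() / math.sqrt((xm ** 2).sum() * (ym ** 2).sum()))
    t = r * math.sqrt((n - 2) / (1.0 - r ** 2))
    p = 2.0 * tdist.sf(abs(t), n - 2)
    return r, float(p)


def ols_normal_equations(X, y):
    """OLS coefficients, covariance, SEs, t and two-sided p by explicit algebra."""
    from scipy.stats import t as tdist

    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, k = X.shape
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    resid = y - X @ beta
    df = n - k
    sigma2 = float(resid @ resid) / df
    cov = sigma2 * XtX_inv
    se = np.sqrt(np.diag(cov))
    t = beta / se
    p = 2.0 * tdist.sf(np.abs(t), df)
    return {"beta": beta, "cov": cov, "se": se, "t": t, "p": p, "df": df,
            "sigma2": sigma2, "resid": resid}


def elastic_net_cd(X, y, lam: float, alpha: float, n_iter: int = 20000,
                   tol: float = 1e-12):
    """Coordinate descent for (1/2n)||y-Xb||^2 + lam(alpha|b|_1 + (1-alpha)/2|b|^2).

    X is used as given (no standardisation); the intercept is handled by
    centring y and X columns first.  Returns (intercept, coefficients) on the
    input scale.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    xm = X.mean(axis=0)
    ym = y.mean()
    Xc = X - xm
    yc = y - ym
    b = np.zeros(p)
    z = (Xc ** 2).sum(axis=0) / n
    for _ in range(n_iter):
        b_old = b.copy()
        for j in range(p):
            r = yc - Xc @ b + Xc[:, j] * b[j]
            rho = (Xc[:, j] * r).sum() / n
            thresh = max(abs(rho) - lam * alpha, 0.0)
            b[j] = math.copysign(thresh, rho) / (z[j] + lam * (1.0 - alpha)) if z[j] > 0 else 0.0
        if np.abs(b - b_old).max() < tol:
            break
    intercept = ym - float(xm @ b)
    return intercept, b


def binomial_loglik(y, n, eta):
    """Binomial log-likelihood (up to the constant) at logits eta."""
    y = np.asarray(y, float)
    n = np.asarray(n, float)
    eta = np.asarray(eta, float)
    return float((y * eta - n * np.log1p(np.exp(eta))).sum())


def logistic_grid_fit(y, n, x, b0_range, b1_range, steps=201):
    """Grid-search maximum of the binomial-logit likelihood over two params."""
    best = (-np.inf, None, None)
    for b0 in np.linspace(*b0_range, steps):
        for b1 in np.linspace(*b1_range, steps):
            ll = binomial_loglik(y, n, b0 + b1 * np.asarray(x, float))
            if ll > best[0]:
                best = (ll, b0, b1)
    return best  # (loglik, b0, b1)


def cox_partial_loglik(times, events, z, beta: float) -> float:
    """Breslow partial log-likelihood for a single binary covariate (no ties)."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    z = np.asarray(z, float)
    ll = 0.0
    for i in np.flatnonzero(events == 1):
        at_risk = times >= times[i]
        ll += beta * z[i] - math.log(np.sum(np.exp(beta * z[at_risk])))
    return ll


def km_product_limit(times, events):
    """Hand product-limit estimate: (event_times, S, greenwood_var)."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    uniq = np.unique(times[events == 1])
    s = 1.0
    gw = 0.0
    out_t, out_s, out_v = [], [], []
    for t in uniq:
        at_risk = int((times >= t).sum())
        d = int(((times == t) & (events == 1)).sum())
        s *= (at_risk - d) / at_risk
        if at_risk > d:
            gw += d / (at_risk * (at_risk - d))
        out_t.append(t)
        out_s.append(s)
        out_v.append(s ** 2 * gw)
    return np.array(out_t), np.array(out_s), np.array(out_v)
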