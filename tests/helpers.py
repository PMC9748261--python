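"""Independent oracles used by the test suite.

These deliberately avoid the code paths they validate: the concordance
oracle uses a dense two-dimensional grid (or scipy's multivariate normal
CDF), the threshold oracle inverts the normal CDF by bisection, and the
implied-logistic-slope oracle solves the population score equations by
Gauss-Hermite quadrature.
"""

import numpy as np
from scipy.optimize import brentq, fsolve
from scipy.stats import norm


def bisect_threshold(K, lo=-10.0, hi=10.0):
    """Invert the standard normal upper tail by bisection."""
    return brentq(lambda t: norm.sf(t) - K, lo, hi, xtol=1e-12)


def grid_concordance(r, q, span=8.5, step=0.005):
    """Brute-force bivariate-normal conditional exceedance on a dense grid."""
    z = norm.ppf(q)
    x = np.arange(z, span, step)
    y = np.arange(z, span, step)
    xx, yy = np.meshgrid(x, y, indexing="ij")
    det = 1.0 - r * r
    dens = np.exp(-(xx**2 - 2 * r * xx * yy + yy**2) / (2 * det)) / (
        2 * np.pi * np.sqrt(det)
    )
    upper = np.trapezoid(np.trapezoid(dens, y, axis=1), x)
    return upper / (1.0 - q)


def mvn_concordance(r, q):
    """Cross-check via scipy's multivariate normal CDF (lower orthant at -z)."""
    from scipy.stats import multivariate_normal

    z = norm.ppf(q)
    joint = multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, r], [r, 1.0]]).cdf([-z, -z])
    return joint / (1.0 - q)


def implied_logistic_slope(rho2, K, n_nodes=80):
    """Pseudo-true per-SD logistic slope for liability-threshold data.

    Disease risk given a standardized score p is the probit
    P(D|p) = Phi-bar((T - sqrt(rho2) p) / sqrt(1 - rho2)); the logistic
    maximum-likelihood estimate converges to the (a, b) solving the
    population score equations, evaluated here with Gauss-Hermite
    quadrature over p ~ N(0, 1).
    """
    T = bisect_threshold(K)
    x, w = np.polynomial.hermite_e.hermegauss(n_nodes)
    w = w / np.sqrt(2.0 * np.pi)
    pr = norm.sf((T - np.sqrt(rho2) * x) / np.sqrt(1.0 - rho2))

    def score(ab):
        a, b = ab
        e = 1.0 / (1.0 + np.exp(-(a + b * x)))
        return [np.sum(w * (pr - e)), np.sum(w * x * (pr - e))]

    a, b = fsolve(score, [np.log(K / (1.0 - K)), np.sqrt(rho2)], full_output=False)
    return float(b)


def contingency_or(n11, n10, n01, n00):
    """Odds ratio from a 2x2 table: exposed cases/controls, unexposed cases/controls."""
    return (n11 * n00) / (n10 * n01)


def km_by_hand(times_events):
    """Product-limit survival worked straight from the definition.

    ``times_events``: list of (time, event) with event 1/0; returns
    {event_time: survival} stepping only at event times.
    """
    out = {}
    s = 1.0
    for t in sorted({t for (t, e) in times_events if e == 1}):
        at_risk = sum(1 for (u, _) in times_events if u >= t)
        d = sum(1 for (u, e) in times_events if u == t and e == 1)
        s *= 1.0 - d / at_risk
        out[t] = s
    return out
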