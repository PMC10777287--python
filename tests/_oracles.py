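"""Independent oracles used only by the test suite.

These deliberately take different computational routes than the package:
the WHAM cross-check solves the equivalent convex maximum-likelihood problem
with a quasi-Newton optimizer instead of self-consistent iteration; the
overlap oracle integrates Gaussian densities numerically; the melting
temperatures are frozen values from a direct hand evaluation of the
two-state formula.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

R_KCAL = 1.987204e-3


def wham_maximum_likelihood(counts, metas, grid, half_factor=True):
    """PMF via direct minimization of the WHAM negative log-likelihood.

    With per-window dimensionless offsets g_i, the unbiased histogram
    probabilities that maximize the multinomial likelihood are
    p_b ∝ M_b / Σ_i N_i exp(−u_ib − g_i), and the optimal offsets minimize

        A(g) = Σ_b M_b ln Σ_i N_i exp(−u_ib − g_i) + Σ_i N_i g_i ,

    a convex function whose stationary points are exactly the WHAM
    self-consistency conditions.  Solved with L-BFGS-B and an analytic
    gradient — no self-consistent iteration anywhere.
    """
    temperature = metas[0].temperature
    rt = R_KCAL * temperature
    factor = 0.5 if half_factor else 1.0
    centers = grid.bin_centers
    c0 = np.array([m.bias_center for m in metas])
    k = np.array([m.bias_constant for m in metas])
    u = factor * k[:, None] * (centers[None, :] - c0[:, None]) ** 2 / rt
    counts = np.asarray(counts, dtype=float)
    n_i = counts.sum(axis=1)
    m_b = counts.sum(axis=0)
    occ = m_b > 0
    log_n = np.log(n_i)

    def objective(g):
        a = log_n[:, None] - u - g[:, None]
        lse = logsumexp(a, axis=0)
        val = float(np.sum(m_b[occ] * lse[occ]) + np.sum(n_i * g))
        soft = np.exp(a - lse[None, :])          # (n_win, n_bins) softmax
        grad = n_i - soft[:, occ] @ m_b[occ]
        return val, grad

    res = minimize(
        objective,
        x0=np.zeros(len(n_i)),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 5000, "ftol": 1e-15, "gtol": 1e-9},
    )
    g = res.x
    with np.errstate(divide="ignore"):
        log_den = logsumexp(log_n[:, None] - u - g[:, None], axis=0)
        log_p = np.where(occ, np.log(np.where(occ, m_b, 1.0)) - log_den, -np.inf)
    log_p -= logsumexp(log_p[occ])
    pmf = np.where(occ, -rt * log_p, np.inf)
    return pmf


def gaussian_overlap_coefficient(mu1, mu2, sigma, lo, hi, n=200_001):
    """∫ min(φ_1, φ_2) by direct numerical integration on [lo, hi]."""
    x = np.linspace(lo, hi, n)
    p1 = np.exp(-((x - mu1) ** 2) / (2 * sigma**2))
    p2 = np.exp(-((x - mu2) ** 2) / (2 * sigma**2))
    norm = sigma * np.sqrt(2 * np.pi)
    return float(np.trapezoid(np.minimum(p1, p2) / norm, x))


# Two-state bimolecular melting temperatures computed by hand from
# Tm(K) = 1000*dH / (dS + R ln(Ct/m)) − frozen before wiring into the test.
# Keys: (dH kcal/mol, dS cal/(mol·K), Ct mol/L, m).
TM_CELSIUS_EXPECTED = {
    (-60.0, -160.0, 1e-5, 4): 50.06772948773437,
    (-60.0, -160.0, 2e-5, 4): 52.483977739487386,
    (-45.0, -125.0, 1e-5, 4): 25.588563995394395,
    (-80.0, -220.0, 1e-6, 4): 46.5825915927644,
    (-60.0, -160.0, 1e-5, 1): 54.93662392551181,
    (-60.0, -160.0, 4.0, 4): 101.85000000000002,
}
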