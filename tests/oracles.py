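"""Independent oracles shared by the test modules.

Everything here is built from first principles (logistic algebra, quadrature,
Monte Carlo) and never calls the closed-form code paths it is used to check.
"""

import numpy as np
from scipy.special import expit


def posterior_quadrature_max_err(schedule, rng, n_tuples=20, grid_pts=4001):
    """Max |closed-form posterior density - grid-quadrature Bayes density|.

    The numeric side multiplies prior q(z_s|x) by likelihood q(z_t|z_s) on a
    1-D grid and renormalizes; both factors are rebuilt from logistic algebra.
    """
    from medvdm import posterior_params

    grid = np.linspace(-8, 8, grid_pts)
    dz = grid[1] - grid[0]
    worst = 0.0
    for _ in range(n_tuples):
        s = rng.uniform(0, 0.85)
        t = rng.uniform(s + 0.1, 1.0)
        x = rng.normal(0, 1.5)
        z_t = rng.normal(0, 1.5)
        g_s, g_t = float(schedule.gamma(s)), float(schedule.gamma(t))
        a_s, s2_s = np.sqrt(expit(-g_s)), expit(g_s)
        a_t, s2_t = np.sqrt(expit(-g_t)), expit(g_t)
        a_ts = a_t / a_s
        s2_ts = s2_t - a_ts**2 * s2_s
        numeric = np.exp(-0.5 * (grid - a_s * x) ** 2 / s2_s) \
            * np.exp(-0.5 * (z_t - a_ts * grid) ** 2 / s2_ts)
        numeric /= numeric.sum() * dz
        post = posterior_params(np.array(z_t), np.array(x), s, t, schedule)
        closed = np.exp(-0.5 * (grid - post.mean) ** 2 / post.variance)
        closed /= np.sqrt(2 * np.pi * post.variance)
        worst = max(worst, float(np.max(np.abs(closed - numeric))))
    return worst


def exact_chain_kl(x, a, b, T, schedule):
    """Gaussian-chain KL oracle for a linear noise predictor eps_hat = a z + b.

    Sums E_{z_t}[ KL(q(z_s|z_t,x) || q(z_s|z_t,x_hat)) ] over the T steps,
    with posterior moments from logistic first principles and the expectation
    over z_t by Gauss-Hermite quadrature.
    """
    nodes, wts = np.polynomial.hermite.hermgauss(120)
    eps = np.sqrt(2.0) * nodes
    w = wts / np.sqrt(np.pi)
    total = 0.0
    for i in range(1, T + 1):
        s, t = (i - 1) / T, i / T
        g_s, g_t = float(schedule.gamma(s)), float(schedule.gamma(t))
        a_s, s2_s = np.sqrt(expit(-g_s)), expit(g_s)
        a_t, s2_t = np.sqrt(expit(-g_t)), expit(g_t)
        a_ts = a_t / a_s
        s2_ts = s2_t - a_ts**2 * s2_s
        var_post = s2_ts * s2_s / s2_t
        z = a_t * x + np.sqrt(s2_t) * eps
        eps_hat = a * z + b
        x_hat = (z - np.sqrt(s2_t) * eps_hat) / a_t
        coef_x = a_s * s2_ts / s2_t
        kl = (coef_x * (x - x_hat)) ** 2 / (2 * var_post)
        total += np.sum(w * kl)
    return total


def gaussian_data_denoiser(mu0, sigma0, schedule):
    """Closed-form optimal noise predictor for data x ~ N(mu0, sigma0^2)."""
    from medvdm import marginal_params

    def denoise(z, g):
        mp = marginal_params(g)
        a = mp.alpha.reshape(mp.alpha.shape + (1,) * (z.ndim - 1))
        s = mp.sigma.reshape(mp.sigma.shape + (1,) * (z.ndim - 1))
        x_hat = (a * sigma0**2 * z + s**2 * mu0) / (a**2 * sigma0**2 + s**2)
        return (z - a * x_hat) / s

    return denoise


def z0_marginal_moments(mu0, sigma0, schedule):
    """Exact mean/variance of q(z_0) for Gaussian data."""
    from medvdm import marginal_params

    mp0 = marginal_params(schedule.gamma(0.0))
    return float(mp0.alpha) * mu0, float(mp0.alpha) ** 2 * sigma0**2 + float(mp0.sigma) ** 2
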