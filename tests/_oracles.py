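"""Independent closed-form oracles for estimator tests.

When only the final rate ``a`` is uncertain (``b``, ``c``, and the noise
std fixed), the Gompertz measurement y = a*m(t) + eps is linear in ``a``
with regressor m(t) = exp(-b*exp(-c*t)), so the posterior of ``a`` and
the predictive distribution of a new measurement are available in closed
form.  These formulas are derived independently of the package's
estimator code paths.
"""

import numpy as np

import germisample as gs
from germisample.priors import PriorLibrary


def regressor(t, b, c):
    return np.exp(-b * np.exp(-c * np.asarray(t, dtype=float)))


def conjugate_posterior_a(kept_t, kept_y, b, c, sigma, mu0=None, tau0=None):
    """Posterior (mean, var) of ``a``; flat prior when mu0/tau0 are None."""
    m = regressor(kept_t, b, c)
    y = np.asarray(kept_y, dtype=float)
    prec = np.sum(m**2) / sigma**2
    num = np.sum(m * y) / sigma**2
    if mu0 is not None:
        prec += 1.0 / tau0**2
        num += mu0 / tau0**2
    return num / prec, 1.0 / prec


def conjugate_predictive(t_query, b, c, sigma, post_mean, post_var):
    """Predictive (mean, std) of a new noisy measurement at t_query."""
    mq = regressor(t_query, b, c)
    return mq * post_mean, np.sqrt(mq**2 * post_var + sigma**2)


def a_only_priors(
    mu0, tau0, b, c, sigma, timeline, n_particles=4000, seed=0, a_bound_halfwidth=20.0
):
    """PriorLibrary describing pure final-rate variation around mu0.

    The parameter covariance, particle set, and grid covariance all
    encode a ~ N(mu0, tau0^2) with b, c, sigma fixed; the uniform bounds
    pin every coordinate but ``a``.
    """
    rng = np.random.default_rng(seed)
    a_draws = mu0 + tau0 * rng.standard_normal(n_particles)
    a_draws = a_draws[a_draws > 0]
    samples = [gs.GompertzParams(a, b, c) for a in a_draws]
    m = regressor(timeline.times, b, c)
    return PriorLibrary(
        param_samples=samples,
        param_mean=np.array([mu0, b, c]),
        param_cov=np.diag([tau0**2, 0.0, 0.0]),
        param_bounds=np.array(
            [[mu0 - a_bound_halfwidth, mu0 + a_bound_halfwidth], [b, b], [c, c]]
        ),
        sigma_eta_mean=sigma,
        sigma_eta_bounds=np.array([sigma, sigma]),
        curve_mean=mu0 * m,
        curve_cov=tau0**2 * np.outer(m, m),
        timeline=timeline,
        n_train=len(samples),
    )


# A fixed a-only scenario shared by the conjugate tests: true a = 93,
# measurements at hours reaching into the plateau so the likelihood is
# informative, noise draws frozen for reproducibility.
A_ONLY = dict(mu0=95.0, tau0=3.0, b=8.0, c=0.08, sigma=2.0, a_true=93.0)
A_ONLY_T = np.array([0.0, 8.0, 16.0, 24.0, 40.0, 60.0])


def a_only_data():
    p = A_ONLY
    m = regressor(A_ONLY_T, p["b"], p["c"])
    noise = np.random.default_rng(5).normal(0.0, p["sigma"], A_ONLY_T.size)
    return A_ONLY_T, p["a_true"] * m + noise
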