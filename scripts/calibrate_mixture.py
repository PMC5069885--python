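"""One-time calibration of the generator's fold-change mixture.

The tethering response is a four-class mixture (silenced 18 %, strong
repression 52 %, mild 29.73 %, upregulated 0.27 %) with truncated-
lognormal fold changes within each class. This script solves for the
strong-class location so that the non-silenced mixture has mean 0.23
(its sd then lands at ~0.274, inside the 0.25 +/- 0.03 band — the moment
constraints leave no lower-sd solution with a non-degenerate mild class),
and calibrates the logistic slope that tilts strong-vs-mild membership by
the occupancy z-score inside pericentromeric state 7 until occupancy and
fold change correlate at Pearson r = -0.35.

All normal-tail arithmetic uses survival functions: the mild window
[0.5, 2) sits ~7.5 sigma into its lognormal's tail, where cdf/ppf
differences lose all precision.

Run:  python scripts/calibrate_mixture.py
The printed constants are frozen in tripkit.simulate.
"""
import numpy as np
from scipy import optimize
from scipy.stats import norm, pearsonr

P_SIL, P_STRONG, P_MILD, P_UP = 0.18, 0.52, 0.2973, 0.0027
WS, WM, WU = (p / (1 - P_SIL) for p in (P_STRONG, P_MILD, P_UP))

SIG_S = 0.80
MU_M, SIG_M = -4.840187, 0.55
MU_U, SIG_U = np.log(2.2), 0.20


def trunc_ln_moment(k, mu, sigma, a, b):
    al = -np.inf if a <= 0 else (np.log(a) - mu) / sigma
    be = np.inf if np.isinf(b) else (np.log(b) - mu) / sigma
    z = norm.sf(al) - norm.sf(be)
    return np.exp(k * mu + 0.5 * k * k * sigma * sigma) * (
        norm.sf(al - k * sigma) - norm.sf(be - k * sigma)
    ) / z


def sample_trunc_ln(mu, sigma, a, b, u):
    al = np.full_like(mu, -np.inf) if a <= 0 else (np.log(a) - mu) / sigma
    be = np.full_like(mu, np.inf) if np.isinf(b) else (np.log(b) - mu) / sigma
    sf_a, sf_b = norm.sf(al), norm.sf(be)
    return np.exp(mu + sigma * norm.isf(sf_b + u * (sf_a - sf_b)))


def main():
    up1 = trunc_ln_moment(1, MU_U, SIG_U, 2, np.inf)
    up2 = trunc_ln_moment(2, MU_U, SIG_U, 2, np.inf)
    mild1 = trunc_ln_moment(1, MU_M, SIG_M, 0.5, 2.0)
    mild2 = trunc_ln_moment(2, MU_M, SIG_M, 0.5, 2.0)

    target_strong_mean = (0.23 - WM * mild1 - WU * up1) / WS
    mu_s = optimize.brentq(
        lambda mu: trunc_ln_moment(1, mu, SIG_S, 0, 0.5) - target_strong_mean, -12, -1
    )
    m2 = WS * trunc_ln_moment(2, mu_s, SIG_S, 0, 0.5) + WM * mild2 + WU * up2
    print(f"mu_strong = {mu_s:.4f} (sigma {SIG_S}); strong median {np.exp(mu_s):.4f}")
    print(f"mild mean {mild1:.4f}; mixture mean 0.2300, sd {np.sqrt(m2 - 0.23**2):.4f}")

    # occupancy coupling: strong-vs-mild membership tilted by the z-score,
    # intercept preserving the marginal mixture; common random numbers make
    # the bisection smooth
    p_strong_sm = P_STRONG / (P_STRONG + P_MILD)
    zq = np.linspace(-8, 8, 4001)
    wq = norm.pdf(zq)
    wq /= wq.sum()

    def intercept(g):
        return optimize.brentq(
            lambda a: np.sum(wq / (1 + np.exp(-(a + g * zq)))) - p_strong_sm, -40, 40
        )

    n = 600_000
    rng = np.random.default_rng(777)
    z = rng.standard_normal(n)
    u, u2 = rng.random(n), rng.random(n)
    is_up = rng.random(n) < WU

    def r_of(g):
        p = 1 / (1 + np.exp(-(intercept(g) + g * z)))
        strong = (~is_up) & (u2 < p)
        mild = (~is_up) & ~strong
        fc = np.empty(n)
        fc[strong] = sample_trunc_ln(
            np.full(strong.sum(), mu_s - np.log(2)), SIG_S, 0, 0.5, u[strong])
        fc[mild] = sample_trunc_ln(
            np.full(mild.sum(), MU_M - np.log(2)), SIG_M, 0.5, 2.0, u[mild])
        fc[is_up] = sample_trunc_ln(
            np.full(is_up.sum(), MU_U), SIG_U, 2.0, np.inf, u[is_up])
        return pearsonr(4.0 + 0.75 * z, fc)[0]

    g = optimize.brentq(lambda g: r_of(g) + 0.35, 0.2, 3.0, xtol=1e-3)
    print(f"occupancy_coupling = {g:.4f} (r = {r_of(g):.4f})")


if __name__ == "__main__":
    main()
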