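"""Independent brute-force oracles shared by the test modules.

These deliberately take different computational routes from the package:
the correlation Bayes factor integrates the exact sampling density of the
Pearson correlation over the prior, and the t-test Bayes factor uses the
inverse-gamma mixture over the g parameter.
"""

import numpy as np
from scipy import integrate, special, stats


def correlation_bf01(n, r, kappa=1.0):
    a = 1.0 / kappa

    def density(r_, rho):
        lognum = (np.log(n - 2) + special.gammaln(n - 1)
                  + 0.5 * (n - 1) * np.log1p(-rho**2)
                  + 0.5 * (n - 4) * np.log1p(-r_**2))
        logden = (0.5 * np.log(2 * np.pi) + special.gammaln(n - 0.5)
                  + (n - 1.5) * np.log1p(-rho * r_))
        return np.exp(lognum - logden) * special.hyp2f1(0.5, 0.5, n - 0.5,
                                                        (rho * r_ + 1) / 2)

    norm = special.beta(a, a) * 2 ** (2 * a - 1)
    num, _ = integrate.quad(lambda rho: density(r, rho) * (1 - rho**2) ** (a - 1) / norm,
                            -1, 1, limit=300, epsabs=1e-13, epsrel=1e-13)
    return density(r, 0.0) / num


def jzs_bf01(t, n, scale=0.707):
    df = n - 1

    def integrand(g):
        return ((1 + n * g) ** -0.5
                * (1 + t**2 / ((1 + n * g) * df)) ** (-(df + 1) / 2)
                * stats.invgamma.pdf(g, 0.5, scale=scale**2 / 2))

    num, _ = integrate.quad(integrand, 0, np.inf, limit=400, epsabs=1e-14, epsrel=1e-13)
    return (1 + t**2 / df) ** (-(df + 1) / 2) / num
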