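"""Independent reference implementations used to check the package.

These deliberately avoid the package's vectorized code paths: the
relative-risk oracle evaluates the exposure–response function scalar by
scalar with the ``math`` module, and the burden oracle loops over grid
cells with no numpy vectorization.
"""

import math


def gemm_rr_oracle(c, theta, alpha, mu, nu, cmin=2.4):
    """Step-by-step scalar evaluation of the GEMM relative risk."""
    z = c - cmin
    if z <= 0:
        return 1.0
    log_term = math.log(z / alpha + 1.0)
    logistic = 1.0 / (1.0 + math.exp(-(z - mu) / nu))
    return math.exp(theta * log_term * logistic)


def brute_force_burden(conc_cells, pop_cells, i_rate, theta, alpha, mu, nu, cmin=2.4):
    """Cell-by-cell attributable deaths: weighted mean RR, underlying
    incidence, then the grid sum — all in plain Python loops."""
    rr = []
    for c in conc_cells:
        rr.append(gemm_rr_oracle(c, theta, alpha, mu, nu, cmin))
    num = 0.0
    den = 0.0
    for r, p in zip(rr, pop_cells):
        num += p * r
        den += p
    rr_bar = num / den
    i_hat = i_rate / rr_bar
    deaths = 0.0
    for r, p in zip(rr, pop_cells):
        deaths += p * i_hat * (r - 1.0)
    return deaths
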