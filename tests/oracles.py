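"""Independent brute-force oracles the fast implementations are checked
against.  These deliberately use naive loops over the definitions."""

import numpy as np


def brute_flux(R: np.ndarray):
    """Triple-loop influx/outflux straight from the pairwise definition."""
    n, p = R.shape
    tot_obs = sum(R[i, k] for i in range(n) for k in range(p))
    tot_mis = n * p - tot_obs
    influx = np.full(p, np.nan)
    outflux = np.full(p, np.nan)
    for j in range(p):
        i_num = 0
        o_num = 0
        for k in range(p):
            for i in range(n):
                if R[i, j] == 0 and R[i, k] == 1:
                    i_num += 1
                if R[i, j] == 1 and R[i, k] == 0:
                    o_num += 1
        if tot_obs > 0:
            influx[j] = i_num / tot_obs
        if tot_mis > 0:
            outflux[j] = o_num / tot_mis
    return influx, outflux


def brute_nrmse(imputed, truth, delta):
    total = 0.0
    for a, b in zip(imputed, truth):
        total += (a - b) ** 2
    return (total / len(truth)) ** 0.5 / delta
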