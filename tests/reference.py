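"""Independent brute-force kurtosis fit used as a cross-check oracle.

Deliberately naive: the design matrix is accumulated by looping over all
3^2 / 3^4 index combinations (no precomputed multiplicity tables), and the
system is solved with a plain unweighted lstsq. Shares no code with the
package's vectorized path.
"""
from itertools import product

import numpy as np

# unique component orders derived here from scratch: sorted index tuples
D_KEYS = sorted({tuple(sorted(t)) for t in product(range(3), repeat=2)})
W_KEYS = sorted({tuple(sorted(t)) for t in product(range(3), repeat=4)})


def naive_design_matrix(bvals, bvecs):
    rows = []
    for b, n in zip(bvals, bvecs):
        drow = dict.fromkeys(D_KEYS, 0.0)
        for i, j in product(range(3), repeat=2):
            drow[tuple(sorted((i, j)))] += -b * n[i] * n[j]
        wrow = dict.fromkeys(W_KEYS, 0.0)
        for i, j, k, l in product(range(3), repeat=4):
            wrow[tuple(sorted((i, j, k, l)))] += (b * b / 6.0) * n[i] * n[j] * n[k] * n[l]
        rows.append([1.0] + [drow[k] for k in D_KEYS] + [wrow[k] for k in W_KEYS])
    return np.asarray(rows)


def naive_fit(signal, bvals, bvecs):
    """OLS log-linear fit; returns (s0, D as dict, W as dict)."""
    X = naive_design_matrix(bvals, bvecs)
    beta = np.linalg.lstsq(X, np.log(np.asarray(signal, float)), rcond=None)[0]
    s0 = float(np.exp(beta[0]))
    D = dict(zip(D_KEYS, beta[1:7]))
    md = (D[(0, 0)] + D[(1, 1)] + D[(2, 2)]) / 3.0
    W = {k: u / md ** 2 for k, u in zip(W_KEYS, beta[7:])}
    return s0, D, W


def naive_axis_values(signal, bvals, bvecs):
    """(dxx, dyy, dzz, wxxxx, wyyyy, wzzzz) from the naive fit."""
    _, D, W = naive_fit(signal, bvals, bvecs)
    return np.array([D[(0, 0)], D[(1, 1)], D[(2, 2)],
                     W[(0, 0, 0, 0)], W[(1, 1, 1, 1)], W[(2, 2, 2, 2)]])
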