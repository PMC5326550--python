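"""Independent brute-force oracles used by the tests.

These deliberately avoid the recursions they are checking: path scores are
enumerated exhaustively, and the gap transition matrix is advanced by
literal repeated multiplication of the per-bp matrix in extended
precision.
"""

from itertools import product

import numpy as np
from scipy.special import logsumexp

from panelcnv.cnv_hmm import initial_distribution, transition_matrix


def enumerate_paths(emissions, gaps, model, states=(0, 1, 2, 3)):
    """Score every state path of a block exhaustively.

    Returns (max log-joint, posterior matrix) computed by direct
    summation over all k^n paths.
    """
    n, k = emissions.shape
    log_pi = np.log(initial_distribution(model, states))
    log_T = [
        np.log(transition_matrix(max(int(g), 1), model, states)) for g in gaps
    ]
    paths = np.array(list(product(range(k), repeat=n)))
    scores = log_pi[paths[:, 0]] + emissions[0, paths[:, 0]]
    for t in range(1, n):
        scores = scores + log_T[t - 1][paths[:, t - 1], paths[:, t]]
        scores = scores + emissions[t, paths[:, t]]
    total = logsumexp(scores)
    post = np.empty((n, k))
    for t in range(n):
        for s in range(k):
            sel = scores[paths[:, t] == s]
            post[t, s] = np.exp(logsumexp(sel) - total) if sel.size else 0.0
    return float(scores.max()), post


def per_bp_matrix_longdouble(model, states=(0, 1, 2, 3)):
    """The elementary 1-bp matrix built directly from the rates in
    extended precision (float64 rounding of the 1-a / 1-b diagonal is
    amplified linearly over large gaps)."""
    a = np.longdouble(model.p_cnv_prior) * np.longdouble(model.p_cnv_to_wt_per_bp)
    b = np.longdouble(model.p_cnv_to_wt_per_bp)
    k = len(states)
    wt = states.index(2)
    M = np.zeros((k, k), dtype=np.longdouble)
    for i in range(k):
        for j in range(k):
            if i == wt and j == wt:
                M[i, j] = 1 - a
            elif i == wt:
                M[i, j] = a / (k - 1)
            elif j == wt:
                M[i, j] = b
            elif i == j:
                M[i, j] = 1 - b
    return M


def repeated_multiplication(model, gap, states=(0, 1, 2, 3)):
    """gap-fold product of the per-bp matrix, accumulated in longdouble."""
    M = per_bp_matrix_longdouble(model, states)
    result = np.eye(len(states), dtype=np.longdouble)
    step = M.copy()
    g = int(gap)
    while g:  # binary powering: exact same product, fewer roundings
        if g & 1:
            result = result @ step
        step = step @ step
        g >>= 1
    return result.astype(float)
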