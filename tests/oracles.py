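"""Independent brute-force oracles used only by the tests.

Everything here is written in the most literal way possible (explicit
loops, no shared code with the package) so that agreement with the
implementation is meaningful.
"""

import math

import numpy as np


def brute_force_embed(signal, dim, delay):
    """Delay embedding by explicit index arithmetic."""
    x = list(signal)
    n_points = len(x) - delay * (dim - 1)
    return [[x[i + d * delay] for d in range(dim)] for i in range(n_points)]


def brute_force_divergence(signal, params):
    """O(n²) divergence analysis: neighbor sets, curve and slope.

    Returns (pairs, curve, slope) where pairs is the ordered list of
    (reference index, neighbor index) tuples actually tracked.
    """
    E = brute_force_embed(signal, params.embedding_dim, params.delay)
    n_points = len(E)
    n_valid = n_points - params.horizon + 1
    theiler = max(params.theiler_window, 1)

    def dist(a, b):
        return math.sqrt(sum((ai - bi) ** 2 for ai, bi in zip(a, b)))

    pairs = []
    for i in range(n_valid):
        cands = []
        for j in range(n_valid):
            if abs(i - j) >= theiler:
                cands.append((dist(E[i], E[j]), j))
        cands.sort(key=lambda t: (t[0], t[1]))  # ties -> smaller index
        if len(cands) < params.n_neighbors:
            continue
        for _, j in cands[: params.n_neighbors]:
            pairs.append((i, j))

    curve = []
    for k in range(params.horizon):
        acc = 0.0
        for i, j in pairs:
            acc += math.log(max(dist(E[i + k], E[j + k]), params.min_distance))
        curve.append(acc / len(pairs))

    ks = list(range(params.fit_range))
    kb = sum(ks) / len(ks)
    cb = sum(curve[: params.fit_range]) / len(ks)
    slope = sum((k - kb) * (c - cb) for k, c in zip(ks, curve)) / sum(
        (k - kb) ** 2 for k in ks
    )
    return pairs, np.array(curve), slope


def normal_equations_ols(y, x1, x2):
    """Closed-form OLS of demeaned y on demeaned (x1, x2) with intercept."""
    y = np.asarray(y, float) - np.mean(y)
    x1 = np.asarray(x1, float) - np.mean(x1)
    x2 = np.asarray(x2, float) - np.mean(x2)
    X = np.column_stack([np.ones(y.size), x1, x2])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    r2 = 1.0 - float(resid @ resid) / float(y @ y)
    sd = math.sqrt(float(resid @ resid) / (y.size - 1))
    return beta, r2, sd
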