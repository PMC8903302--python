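"""Independent oracles: direct transcriptions and brute-force fits.

These deliberately avoid the package's own code paths so they can serve as
cross-checks for the estimators.
"""

import numpy as np


def ipw_ht_transcription(y, sp, p):
    """Direct sum-by-sum transcription of the 1/n IPW difference."""
    n = len(y)
    acc_t = 0.0
    acc_c = 0.0
    for i in range(n):
        if sp[i] == 1:
            acc_t += y[i] / p[i]
        else:
            acc_c += y[i] / (1.0 - p[i])
    return acc_t / n - acc_c / n


def hajek_transcription(y, sp, p):
    t_num = t_den = c_num = c_den = 0.0
    for i in range(len(y)):
        if sp[i] == 1:
            w = 1.0 / p[i]
            t_num += w * y[i]
            t_den += w
        else:
            w = 1.0 / (1.0 - p[i])
            c_num += w * y[i]
            c_den += w
    return t_num / t_den - c_num / c_den


def logit_grid_mle(x, y, rounds=6, width=8.0, points=41):
    """Two-parameter logistic MLE by iteratively refined grid search.

    Maximizes the Bernoulli log-likelihood of y on (1, x) over a
    (b0, b1) grid, shrinking the grid around the argmax each round.
    Returns the fitted per-unit probabilities.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    c0 = c1 = 0.0
    w = width
    for _ in range(rounds):
        b0 = np.linspace(c0 - w, c0 + w, points)
        b1 = np.linspace(c1 - w, c1 + w, points)
        B0, B1 = np.meshgrid(b0, b1, indexing="ij")
        eta = B0[..., None] + B1[..., None] * x  # (points, points, n)
        ll = (y * eta - np.logaddexp(0.0, eta)).sum(axis=-1)
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        c0, c1 = b0[i], b1[j]
        w = 2.0 * w / (points - 1) * 2.0  # keep a small search margin
    eta = c0 + c1 * x
    return 1.0 / (1.0 + np.exp(-eta))


def random_ipw_instance(rng, max_units=10):
    """Small random instance with both groups present and interior scores."""
    while True:
        n = int(rng.integers(2, max_units + 1))
        sp = rng.integers(0, 2, n)
        if 0 < sp.sum() < n:
            break
    p = rng.uniform(0.05, 0.95, n)
    y = rng.normal(10.0, 20.0, n)
    return y, sp, p
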