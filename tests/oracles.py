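"""Independent brute-force oracles used by the test suite.

These deliberately re-derive every quantity with explicit loops and
textbook formulas, sharing no code path with the package internals.
"""

from __future__ import annotations

import math

import numpy as np


def oracle_weight(rho: float, decay: float) -> float:
    if decay == 0.0:
        return 1.0 if rho >= 1.0 - 1e-12 else 0.0
    return math.exp(-((1.0 - min(rho, 1.0)) ** 2) / (2.0 * decay * decay))


def oracle_predict_loo(values, rho_c, rho_d, sigma, tau):
    """Explicit double-loop leave-target-out weighted average."""
    arr = np.asarray(values, dtype=float)
    mask = np.isfinite(arr)
    gmean = arr[mask].mean()
    obs_pairs = [(k, l) for k in range(arr.shape[0]) for l in range(arr.shape[1]) if mask[k, l]]
    pred = np.empty_like(arr)
    defined = np.zeros(arr.shape, dtype=bool)
    for i in range(arr.shape[0]):
        wc = [oracle_weight(rho_c[i, k], sigma) for k in range(arr.shape[0])]
        for j in range(arr.shape[1]):
            wd = [oracle_weight(rho_d[j, l], tau) for l in range(arr.shape[1])]
            num = 0.0
            den = 0.0
            for k, l in obs_pairs:
                if k == i and l == j:
                    continue
                w = wc[k] * wd[l]
                num += w * arr[k, l]
                den += w
            if den > 0.0:
                pred[i, j] = num / den
                defined[i, j] = True
            else:
                pred[i, j] = gmean
    return pred, defined


def oracle_predict_new(values, rho_sample, rho_d, sigma, tau):
    """Explicit double-loop new-sample prediction (no pair exclusion)."""
    arr = np.asarray(values, dtype=float)
    mask = np.isfinite(arr)
    gmean = arr[mask].mean()
    obs_pairs = [(k, l) for k in range(arr.shape[0]) for l in range(arr.shape[1]) if mask[k, l]]
    ws = [oracle_weight(rho_sample[k], sigma) for k in range(arr.shape[0])]
    pred = np.empty(arr.shape[1])
    defined = np.zeros(arr.shape[1], dtype=bool)
    for j in range(arr.shape[1]):
        wd = [oracle_weight(rho_d[j, l], tau) for l in range(arr.shape[1])]
        num = 0.0
        den = 0.0
        for k, l in obs_pairs:
            w = ws[k] * wd[l]
            num += w * arr[k, l]
            den += w
        if den > 0.0:
            pred[j] = num / den
            defined[j] = True
        else:
            pred[j] = gmean
    return pred, defined


def oracle_objective(values, rho_c, rho_d, sigma, tau) -> float:
    arr = np.asarray(values, dtype=float)
    mask = np.isfinite(arr)
    pred, _ = oracle_predict_loo(arr, rho_c, rho_d, sigma, tau)
    return float(((arr - pred) ** 2)[mask].sum())


def oracle_pearson(x, y) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc * yc).sum() / math.sqrt((xc * xc).sum() * (yc * yc).sum()))


def random_similarity(rng, n: int) -> np.ndarray:
    """A random valid correlation-like similarity matrix with unit diagonal."""
    X = rng.normal(size=(n, max(2 * n, 8)))
    rho = np.corrcoef(X)
    np.fill_diagonal(rho, 1.0)
    return rho
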