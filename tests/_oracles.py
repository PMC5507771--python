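"""Independent oracles used by the test suite.

These are deliberately naive re-implementations (iterative NIPALS with
deflation, explicit leave-one-out loops, exhaustive permutation
enumeration, brute-force threshold evaluation) kept separate from the
package so the code paths under test share nothing with them.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.stats import rankdata


def nipals_pls1(X, y, n_components=1, scale=True, max_iter=500, tol=1e-12):
    """Textbook NIPALS PLS1 with component-wise deflation.

    Returns training predictions for ``n_components`` components.
    """
    X = np.asarray(X, dtype=float).copy()
    y = np.asarray(y, dtype=float).ravel().copy()
    x_mean = X.mean(axis=0)
    x_sd = X.std(axis=0, ddof=1)
    x_sd[x_sd == 0] = 1.0
    if not scale:
        x_sd = np.ones_like(x_sd)
    E = (X - x_mean) / x_sd
    y_mean = y.mean()
    f = y - y_mean
    yhat = np.zeros_like(f)
    for _ in range(n_components):
        w = E.T @ f
        w = w / np.linalg.norm(w)
        for _ in range(max_iter):
            t = E @ w
            q = f @ t / (t @ t)
            w_new = E.T @ f
            w_new = w_new / np.linalg.norm(w_new)
            if np.linalg.norm(w_new - w) < tol:
                w = w_new
                break
            w = w_new
        t = E @ w
        p = E.T @ t / (t @ t)
        q = f @ t / (t @ t)
        yhat = yhat + t * q
        E = E - np.outer(t, p)
        f = f - t * q
    return yhat + y_mean


def loo_cv_oracle(X, y, fit_predict):
    """Explicit leave-one-out loop; fit_predict(Xtr, ytr, Xte) -> yhat."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    preds = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        preds[i] = fit_predict(X[mask], y[mask], X[[i]])[0]
    press = float(((y - preds) ** 2).sum())
    tss = float(((y - y.mean()) ** 2).sum())
    return preds, 1.0 - press / tss


def spearman_exact_p(x, y):
    """Exact two-sided permutation p for |Spearman rho| by full enumeration."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rx = rankdata(x)
    ry = rankdata(y)

    def rho(a, b):
        a = a - a.mean()
        b = b - b.mean()
        return a @ b / np.sqrt((a @ a) * (b @ b))

    obs = abs(rho(rx, ry))
    count = 0
    total = 0
    for perm in itertools.permutations(range(len(y))):
        total += 1
        if abs(rho(rx, ry[list(perm)])) >= obs - 1e-12:
            count += 1
    return count / total


def enumerate_statistic(y, stat_fn):
    """Exact one-sided permutation p for a deterministic statistic of y."""
    y = np.asarray(y, dtype=float)
    obs = stat_fn(y)
    vals = []
    for perm in itertools.permutations(range(len(y))):
        vals.append(stat_fn(y[list(perm)]))
    vals = np.asarray(vals)
    return obs, float((vals >= obs - 1e-12).mean()), vals


def brute_force_stratify(table, g_col, b_col, k_sd, lng_q):
    """Row-by-row re-evaluation of the 2-SD rule with explicit arithmetic."""
    g = table[g_col].to_numpy(dtype=float)
    b = table[b_col].to_numpy(dtype=float)
    tg = g.mean() + k_sd * g.std(ddof=1)
    tb = b.mean() + k_sd * b.std(ddof=1)
    qg = np.quantile(g, lng_q)
    qb = np.quantile(b, lng_q)
    out = []
    for gi, bi in zip(g, b):
        if gi > tg and bi > tb:
            out.append("Ob-IGT")
        elif gi > tg:
            out.append("L-IGT")
        elif gi <= qg and bi <= qb:
            out.append("LNG")
        else:
            out.append("midgroup")
    return out
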