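"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from the definitions, without
reusing the package's algorithms: double loops, dense covariance matrices
and generic numerical optimization, checked against the fast
implementations.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize, stats


def bh_stepup(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up from the definition."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p[i] * m / rank)
        adj[i] = running_min
    return adj


def greedy_clump(stats_df, dosages, snp_index, r2_max=0.1, window_kb=1000.0):
    """Greedy clumping by the rule, one pair at a time via np.corrcoef.

    ``stats_df`` needs columns snp_id, chrom, bp, p; ``snp_index`` maps
    snp_id -> dosage column.
    """
    recs = stats_df.sort_values(["p", "chrom", "bp", "snp_id"], kind="mergesort")
    recs = list(recs[["snp_id", "chrom", "bp"]].itertuples(index=False, name=None))
    removed = set()
    kept = []
    for snp, chrom, bp in recs:
        if snp in removed:
            continue
        kept.append((snp, chrom, bp))
        for other, ochrom, obp in recs:
            if other == snp or other in removed or any(other == k for k, _, _ in kept):
                continue
            if ochrom != chrom or abs(obp - bp) > window_kb * 1000:
                continue
            a = dosages[:, snp_index[snp]]
            b = dosages[:, snp_index[other]]
            if a.var() == 0 or b.var() == 0:
                continue
            r = np.corrcoef(a, b)[0, 1]
            if r * r >= r2_max:
                removed.add(other)
    kept.sort(key=lambda t: (t[1], t[2], t[0]))
    return [k for k, _, _ in kept]


def enumerate_pairs(data, predictor, outcome, covariates=()):
    """Exhaustive double-loop construction of within-day (t, t+1) pairs."""
    pairs = []
    rows = list(data.itertuples())
    for a in rows:
        for b in rows:
            if a.subject_id != b.subject_id or a.day != b.day:
                continue
            if b.beep != a.beep + 1:
                continue
            vals_t = [getattr(a, predictor)] + [getattr(a, c) for c in covariates]
            if any(np.isnan(v) for v in vals_t):
                continue
            if np.isnan(getattr(b, outcome)):
                continue
            pairs.append(
                (a.subject_id, a.day, getattr(a, predictor), getattr(b, outcome))
            )
    return sorted(pairs)


def dense_mvn_ml(X, y, codes, n_starts=4, seed=0):
    """ML of the random-intercept model by generic optimization of the dense
    multivariate-normal log-likelihood over (beta, log sigma_u, log sigma_e).

    Returns (loglik, beta).  Only feasible for tiny instances.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    codes = np.asarray(codes)
    n, p = X.shape
    Z = (codes[:, None] == np.unique(codes)[None, :]).astype(float)

    def negll(theta):
        beta = theta[:p]
        su2 = np.exp(2 * theta[p])
        se2 = np.exp(2 * theta[p + 1])
        V = su2 * (Z @ Z.T) + se2 * np.eye(n)
        try:
            return -stats.multivariate_normal.logpdf(y, mean=X @ beta, cov=V)
        except np.linalg.LinAlgError:
            return np.inf

    rng = np.random.default_rng(seed)
    beta0 = np.linalg.lstsq(X, y, rcond=None)[0]
    resid = y - X @ beta0
    s0 = max(resid.std(), 1e-3)
    best = None
    for k in range(n_starts):
        jitter = rng.normal(0, 0.3, size=p + 2) if k else 0.0
        x0 = np.r_[beta0, np.log(s0), np.log(s0)] + jitter
        res = optimize.minimize(negll, x0, method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12,
                                         "maxiter": 20000, "maxfev": 20000})
        res = optimize.minimize(negll, res.x, method="Nelder-Mead",
                                options={"xatol": 1e-11, "fatol": 1e-13,
                                         "maxiter": 20000, "maxfev": 20000})
        if best is None or res.fun < best.fun:
            best = res
    return -best.fun, best.x[:p]


def cronbach_alpha_def(x) -> float:
    """Cronbach's alpha straight from the variance decomposition."""
    x = np.asarray(x, float)
    x = x[~np.isnan(x).any(axis=1)]
    k = x.shape[1]
    cov = np.cov(x, rowvar=False)
    return k / (k - 1) * (1 - np.trace(cov) / cov.sum())
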