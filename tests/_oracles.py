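"""Independent reference implementations used only by the tests.

Deliberately naive (explicit loops, brute-force searches, closed forms) so
they share no code path with the package.
"""

import numpy as np


def naive_efron_loglik(beta, X, exit_age, event, entry_age=None, weights=None):
    """Weighted Efron log partial likelihood by explicit loops."""
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] == 1 and len(exit_age) != 1:
        X = X.T
    n = X.shape[0]
    beta = np.atleast_1d(np.asarray(beta, float))
    entry_age = np.zeros(n) if entry_age is None else np.asarray(entry_age, float)
    weights = np.ones(n) if weights is None else np.asarray(weights, float)
    eta = X @ beta
    r = weights * np.exp(eta)
    ll = 0.0
    for t in sorted({exit_age[i] for i in range(n) if event[i] == 1}):
        D = [i for i in range(n) if exit_age[i] == t and event[i] == 1]
        R = [i for i in range(n) if entry_age[i] < t <= exit_age[i]]
        s0r = sum(r[i] for i in R)
        s0d = sum(r[i] for i in D)
        wbar = sum(weights[i] for i in D) / len(D)
        ll += sum(weights[i] * eta[i] for i in D)
        for k in range(len(D)):
            ll -= wbar * np.log(s0r - (k / len(D)) * s0d)
    return ll


def grid_maximize(fn, n_params, lo=-4.0, hi=4.0, rounds=6, points=25):
    """Iteratively refined dense grid search; final spacing < 1e-5."""
    centre = np.zeros(n_params)
    half = (hi - lo) / 2.0
    best = None
    for _ in range(rounds):
        axes = [np.linspace(c - half, c + half, points) for c in centre]
        grids = np.meshgrid(*axes, indexing="ij")
        flat = np.column_stack([g.ravel() for g in grids])
        vals = np.array([fn(b) for b in flat])
        best = flat[int(np.argmax(vals))]
        centre = best
        half = half * 2.0 / (points - 1)  # keep neighbours inside next window
    return best


def brute_clump(stats_rows, r2_fn, p_index, r2_max, window_bp):
    """Exhaustive greedy clumping; re-scans all pairs every round.

    ``stats_rows``: list of dicts with variant_id, chr, pos, p.
    ``r2_fn(a, b)``: pairwise dosage r² (may raise on degenerate input).
    """
    todo = [r for r in stats_rows if r["p"] < p_index]
    clumps = []
    while todo:
        best = min(todo, key=lambda r: (r["p"], r["chr"], r["pos"]))
        todo = [r for r in todo if r is not best]
        members = []
        rest = []
        for r in todo:
            close = (r["chr"] == best["chr"]
                     and abs(r["pos"] - best["pos"]) <= window_bp)
            linked = False
            if close:
                try:
                    linked = r2_fn(best["variant_id"], r["variant_id"]) >= r2_max
                except Exception:
                    linked = False
            (members if linked else rest).append(r)
        todo = rest
        clumps.append((best["variant_id"],
                       [m["variant_id"] for m in members]))
    return clumps


def hwe_enumeration_p(n_het, n_hom_minor, n_hom_major):
    """Exact HWE test by full enumeration of heterozygote counts (log-space)."""
    from math import lgamma, log
    n = n_het + n_hom_minor + n_hom_major
    minor = 2 * n_hom_minor + n_het
    if minor > n:
        minor = 2 * n - minor
    if minor == 0 or n == 0:
        return 1.0

    def logpmf(h):
        hm = (minor - h) // 2
        hmaj = n - h - hm
        return (h * log(2) + lgamma(n + 1)
                - lgamma(hm + 1) - lgamma(h + 1) - lgamma(hmaj + 1))

    hs = list(range(minor % 2, min(minor, n) + 1, 2))
    lps = np.array([logpmf(h) for h in hs])
    lps -= lps.max()
    ps = np.exp(lps)
    ps /= ps.sum()
    p_obs = ps[hs.index(n_het)]
    return float(min(1.0, ps[ps <= p_obs * (1 + 1e-12)].sum()))


def ivw_closed_form(beta_exp, se_exp, beta_out, se_out):
    """Weighted least squares through the origin of Wald ratios."""
    r = np.asarray(beta_out, float) / np.asarray(beta_exp, float)
    s = np.asarray(se_out, float) / np.abs(np.asarray(beta_exp, float))
    w = 1.0 / s ** 2
    est = (w * r).sum() / w.sum()
    se = np.sqrt(1.0 / w.sum())
    return est, se


def egger_closed_form(beta_exp, se_exp, beta_out, se_out):
    """Weighted regression with intercept, normal-equation closed form."""
    sign = np.sign(beta_exp)
    x = np.abs(np.asarray(beta_exp, float))
    y = np.asarray(beta_out, float) * sign
    w = 1.0 / np.asarray(se_out, float) ** 2
    W = np.diag(w)
    X = np.column_stack([np.ones_like(x), x])
    coef = np.linalg.solve(X.T @ W @ X, X.T @ W @ y)
    resid = y - X @ coef
    dof = len(x) - 2
    sigma2 = (w * resid ** 2).sum() / dof
    cov = sigma2 * np.linalg.inv(X.T @ W @ X)
    return coef[0], coef[1], np.sqrt(cov[0, 0]), np.sqrt(cov[1, 1])


def mann_whitney_auc(scores_cases, scores_controls):
    wins = 0.0
    for a in scores_cases:
        for b in scores_controls:
            if a > b:
                wins += 1.0
            elif a == b:
                wins += 0.5
    return wins / (len(scores_cases) * len(scores_controls))
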