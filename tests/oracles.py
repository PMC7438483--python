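"""Independent oracle implementations used only by the test suite.

Each oracle is written as a direct, loop-based transcription of the defining
formula or procedure, deliberately sharing no code path with the package.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import hypergeom


# ---------------------------------------------------------------------------
# Weir & Cockerham (1984) variance components, general r-population loop form
# ---------------------------------------------------------------------------

def wc_fst_oracle(genotype_counts):
    """theta, a, b, c from per-population (hom_ref, het, hom_alt) counts.

    Literal r-population transcription: n_i, p_i, h_i per population, then
    n_bar, n_c, p_bar, s^2, h_bar and the three components.
    """
    r = len(genotype_counts)
    n, p, h = [], [], []
    for (aa, ab, bb) in genotype_counts:
        ni = aa + ab + bb
        n.append(ni)
        p.append((ab + 2 * bb) / (2 * ni))
        h.append(ab / ni)
    n_bar = sum(n) / r
    n_c = (r * n_bar - sum(ni**2 for ni in n) / (r * n_bar)) / (r - 1)
    p_bar = sum(ni * pi for ni, pi in zip(n, p)) / (r * n_bar)
    s2 = sum(ni * (pi - p_bar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * n_bar)
    h_bar = sum(ni * hi for ni, hi in zip(n, h)) / (r * n_bar)

    a = (n_bar / n_c) * (
        s2 - 1.0 / (n_bar - 1) * (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4.0)
    )
    b = n_bar / (n_bar - 1) * (
        p_bar * (1 - p_bar) - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
    )
    c = h_bar / 2.0
    denom = a + b + c
    theta = a / denom if denom != 0 else float("nan")
    return theta, a, b, c


# ---------------------------------------------------------------------------
# Fisher exact test by exhaustive hypergeometric enumeration
# ---------------------------------------------------------------------------

def fisher_two_sided_oracle(table):
    """Sum of probabilities of all tables (fixed margins) with
    P(table) <= P(observed) * (1 + 1e-7)."""
    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    p_obs = hypergeom.pmf(a, n, col1, row1)
    total = 0.0
    for k in range(lo, hi + 1):
        pk = hypergeom.pmf(k, n, col1, row1)
        if pk <= p_obs * (1 + 1e-7):
            total += pk
    return min(total, 1.0)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg step-up, literal rule
# ---------------------------------------------------------------------------

def bh_oracle(pvalues):
    p = list(pvalues)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * m / rank, 1.0)
        q[i] = val
        prev = val
    return q


# ---------------------------------------------------------------------------
# greedy LD clumping, plain-python re-enumeration
# ---------------------------------------------------------------------------

def clump_oracle(snps, dosages, r2_threshold, window_bp):
    """snps: list of dicts (snp_id, chrom, pos, pvalue); dosages: dict
    snp_id -> list of dosages (no missing). Returns retained snp_ids sorted
    by (chrom, pos)."""

    def r2(x, y):
        n = len(x)
        mx, my = sum(x) / n, sum(y) / n
        sxy = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y))
        sxx = sum((xi - mx) ** 2 for xi in x)
        syy = sum((yi - my) ** 2 for yi in y)
        if sxx == 0 or syy == 0:
            return 0.0
        return sxy * sxy / (sxx * syy)

    pending = sorted(snps, key=lambda s: (s["pvalue"], s["pos"], s["snp_id"]))
    removed = set()
    retained = []
    for s in pending:
        if s["snp_id"] in removed:
            continue
        retained.append(s)
        for other in pending:
            if other["snp_id"] == s["snp_id"] or other["snp_id"] in removed:
                continue
            if other["chrom"] != s["chrom"] or abs(other["pos"] - s["pos"]) > window_bp:
                continue
            if r2(dosages[s["snp_id"]], dosages[other["snp_id"]]) > r2_threshold:
                removed.add(other["snp_id"])
    retained.sort(key=lambda s: (s["chrom"], s["pos"]))
    return [s["snp_id"] for s in retained]


# ---------------------------------------------------------------------------
# Poisson regression (log link) by Newton-Raphson + HC0 sandwich
# ---------------------------------------------------------------------------

def poisson_irls_oracle(y, X, tol=1e-12, max_iter=200):
    """Returns (beta, robust_se) for a log-link Poisson fit."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        mu = np.exp(X @ beta)
        score = X.T @ (y - mu)
        info = X.T @ (X * mu[:, None])
        step = np.linalg.solve(info, score)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    mu = np.exp(X @ beta)
    bread = np.linalg.inv(X.T @ (X * mu[:, None]))
    meat = X.T @ (X * ((y - mu) ** 2)[:, None])
    cov = bread @ meat @ bread
    return beta, np.sqrt(np.diag(cov))


# ---------------------------------------------------------------------------
# Cox partial-likelihood score for one binary covariate, no ties
# ---------------------------------------------------------------------------

def cox_score_no_ties(beta, times, events, x):
    """Score U(beta) = sum over events of (x_i - weighted mean of x over the
    risk set). All event times must be distinct."""
    order = sorted(range(len(times)), key=lambda i: times[i])
    total = 0.0
    for idx in order:
        if not events[idx]:
            continue
        risk = [j for j in range(len(times)) if times[j] >= times[idx]]
        w = [math.exp(beta * x[j]) for j in risk]
        total += x[idx] - sum(wi * x[j] for wi, j in zip(w, risk)) / sum(w)
    return total


# ---------------------------------------------------------------------------
# Kaplan-Meier product-limit, hand loop
# ---------------------------------------------------------------------------

def km_oracle(times, events):
    """Returns list of (time, survival) at each distinct event time."""
    pairs = sorted(zip(times, events))
    out = []
    s = 1.0
    distinct = sorted({t for t, e in pairs if e})
    for t in distinct:
        at_risk = sum(1 for ti, _ in pairs if ti >= t)
        d = sum(1 for ti, ei in pairs if ti == t and ei)
        s *= 1.0 - d / at_risk
        out.append((t, s))
    return out


# ---------------------------------------------------------------------------
# OLS by normal equations
# ---------------------------------------------------------------------------

def ols_oracle(y, X):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    return np.linalg.solve(X.T @ X, X.T @ y)


# ---------------------------------------------------------------------------
# histogram binning for the frequency spectrum
# ---------------------------------------------------------------------------

def spectrum_oracle(freqs):
    counts = {"rare": 0, "low_frequency": 0, "common": 0}
    for f in freqs:
        if f < 0.01:
            counts["rare"] += 1
        elif f < 0.05:
            counts["low_frequency"] += 1
        else:
            counts["common"] += 1
    return counts
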