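"""Shared statistical primitives.

Fisher's exact test (each tail), Welch's t, Spearman/Pearson correlation
with t-test p-values, Benjamini-Hochberg and Storey multiple-testing
correction, and Ward agglomerative clustering.  Standard tests are routed
through scipy/statsmodels; the exact-sample Otsu threshold and the Storey
q-value smoother are implemented here because no installed package provides
them in the form the pipeline requires.

All functions are pure: same input, same output, no hidden state.
"""

from __future__ import annotations

import numpy as np
import scipy.cluster.hierarchy as sch
import scipy.stats as st
from statsmodels.stats.multitest import multipletests

#: default lambda grid for Storey pi0 estimation
STOREY_LAMBDA_GRID = np.round(np.arange(0.05, 0.96, 0.05), 2)
#: below this many p-values the pi0 smoother is unstable; fall back to lambda=0.5
STOREY_SMOOTHER_MIN_N = 100


def fisher_exact(table, tail: str = "right") -> float:
    """Exact hypergeometric p-value for a 2x2 contingency table.

    ``tail="right"`` tests enrichment of the top-left cell ``a`` (the count
    shared by both classifications), ``"left"`` depletion, ``"two"`` the
    usual two-sided test.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or np.any(t != np.floor(t)):
        raise ValueError("table entries must be non-negative integers")
    if t.sum() < 1:
        raise ValueError("degenerate table: total count is zero")
    alternative = {"right": "greater", "left": "less", "two": "two-sided"}.get(tail)
    if alternative is None:
        raise ValueError(f"unknown tail {tail!r}")
    return float(st.fisher_exact(t.astype(int), alternative=alternative).pvalue)


def welch_t(a, b) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test; returns (t, Satterthwaite df, two-sided p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite values")
    res = st.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman rank correlation on mid-ranks with t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors, n >= 3")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("zero variance in ranks: rho undefined")
    rho, p = st.spearmanr(x, y)
    return float(rho), float(p)


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson correlation with t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors, n >= 3")
    r, p = st.pearsonr(x, y)
    return float(r), float(p)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, clipped to [0, 1])."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def storey_pi0(pvalues, lambdas=None) -> float:
    """Estimate the null proportion pi0 from a p-value vector.

    Uses the smoother method: pi0(lambda) = #{p > lambda} / (n (1 - lambda))
    on a lambda grid, extrapolated to lambda = 1 by a cubic polynomial fit.
    For small n (< 100) the smoother is noisy and a fixed lambda = 0.5
    estimate is used instead.  The result is clipped to (0, 1].
    """
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    lam = STOREY_LAMBDA_GRID if lambdas is None else np.asarray(lambdas, float)
    n = p.size
    if n == 0:
        return 1.0
    if n < STOREY_SMOOTHER_MIN_N or lam.size < 4:
        pi0 = np.mean(p > 0.5) / 0.5
    else:
        pi0_lam = np.array([(p > l).mean() / (1.0 - l) for l in lam])
        coef = np.polyfit(lam, pi0_lam, deg=3)
        pi0 = float(np.polyval(coef, 1.0))
    return float(min(max(pi0, 1.0 / n), 1.0))


def storey_qvalue(pvalues, lambdas=None, pi0: float | None = None) -> np.ndarray:
    """Storey q-values: q_i = min over p_j >= p_i of pi0 * n * p_j / rank(p_j).

    ``pi0=1`` reduces exactly to Benjamini-Hochberg.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if pi0 is None:
        pi0 = storey_pi0(p, lambdas)
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n * pi0 / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def squeeze_var(s2, df: float) -> tuple[np.ndarray, float]:
    """Empirical-Bayes squeeze of per-unit sample variances toward a common
    prior, returning (posterior variances, prior df d0).

    Hyperparameters (s0^2, d0) are fitted by moment matching on log s^2
    using digamma/trigamma inversion; d0 = inf (full pooling) when the
    observed variances are less variable than chi-squared sampling alone.
    """
    from scipy.special import digamma, polygamma

    s2 = np.asarray(s2, dtype=float)
    e = np.log(s2)
    e_var = e.var(ddof=1) if e.size > 1 else 0.0
    target = e_var - polygamma(1, df / 2.0)
    if target <= 0:
        s0 = np.exp(e.mean() - digamma(df / 2.0) + np.log(df / 2.0))
        return np.full_like(s2, s0), np.inf
    d0 = 2.0 * _inv_trigamma(target)
    s0 = np.exp(e.mean() + digamma(d0 / 2.0) - digamma(df / 2.0) - np.log(d0 / df))
    return (d0 * s0 + df * s2) / (d0 + df), float(d0)


def _inv_trigamma(y: float, iters: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    from scipy.special import polygamma

    x = 0.5 + 1.0 / y
    for _ in range(iters):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x = x - dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def ward_cluster(vectors, k: int = 2) -> np.ndarray:
    """Agglomerative Ward clustering (Euclidean), tree cut at k clusters.

    Returns integer labels 0..k-1 in order of first appearance.
    """
    X = np.asarray(vectors, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if k > n:
        raise ValueError("k > number of points")
    if k == n:
        return np.arange(n)
    Z = sch.linkage(X, method="ward")
    raw = sch.fcluster(Z, t=k, criterion="maxclust")
    # relabel deterministically by first appearance
    labels = np.empty(n, dtype=int)
    seen: dict[int, int] = {}
    for i, r in enumerate(raw):
        labels[i] = seen.setdefault(int(r), len(seen))
    return labels


def ward_linkage_order(vectors) -> list[tuple[int, int]]:
    """Sequence of (smaller_cluster_rep, larger_cluster_rep) index pairs merged
    by Ward linkage, with clusters identified by their smallest member index.
    Used for merge-order comparisons against brute-force oracles."""
    X = np.asarray(vectors, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    Z = sch.linkage(X, method="ward")
    reps = {i: i for i in range(n)}
    order = []
    for step, (i, j, _, _) in enumerate(Z):
        a, b = reps[int(i)], reps[int(j)]
        order.append((min(a, b), max(a, b)))
        reps[n + step] = min(a, b)
    return order
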