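"""Expression filtering and two-group negative-binomial differential testing.

A gene counts as expressed when its read count is positive in at least
``min_reps`` replicates (default 6 of 11) in at least one tissue.  The
two-group test works on raw counts with median-of-ratios library-size
normalization, per-gene method-of-moments dispersions shrunk toward a
fitted mean-dispersion trend, a likelihood-ratio numerator and a
quasi-likelihood F reference whose denominator is an empirical-Bayes
moderated deviance dispersion.  q-values are Benjamini-Hochberg; DEGs are
q < 0.01 with the label set by fold-change sign.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import f as f_dist

from tissuedom.stats_core import bh_adjust, pearson_r, squeeze_var

DEFAULT_MIN_REPS = 6
DEFAULT_Q_CUT = 0.01
# dispersion floor; kept well above 0 so gammaln(y + 1/phi) differences stay
# numerically accurate (variance inflation at the floor is negligible)
_PHI_MIN = 1e-4
_SHRINK_PRIOR_DF = 10.0  # weight of the mean-dispersion trend in shrinkage


def filter_expressed(
    counts_a: pd.DataFrame, counts_b: pd.DataFrame, min_reps: int = DEFAULT_MIN_REPS
) -> pd.Series:
    """Expressed iff count > 0 in >= min_reps replicates in either tissue."""
    if not counts_a.index.equals(counts_b.index):
        raise ValueError("count matrices must share the gene index")
    pos_a = (counts_a > 0).sum(axis=1)
    pos_b = (counts_b > 0).sum(axis=1)
    return (pos_a >= min_reps) | (pos_b >= min_reps)


def size_factors(counts: pd.DataFrame) -> np.ndarray:
    """Median-of-ratios size factors (geometric-mean reference).

    Invariant to rescaling any column by a constant up to that constant;
    genes with a zero count anywhere are excluded from the reference.
    """
    with np.errstate(divide="ignore"):
        logc = np.log(counts.to_numpy(dtype=float))
    finite = np.all(np.isfinite(logc), axis=1)
    if not finite.any():
        raise ValueError("no gene with all-positive counts for normalization")
    ref = logc[finite].mean(axis=1)
    sf = np.exp(np.median(logc[finite] - ref[:, None], axis=0))
    return sf / np.exp(np.mean(np.log(sf)))


def _nb_loglik(y, mu, phi):
    """NB log-likelihood, fixed dispersion phi (variance mu + phi*mu^2)."""
    mu = np.maximum(mu, 1e-10)
    r = 1.0 / max(phi, _PHI_MIN)
    return (
        gammaln(y + r) - gammaln(r) - gammaln(y + 1)
        + y * np.log(phi * mu / (1.0 + phi * mu))
        + r * np.log1p(-phi * mu / (1.0 + phi * mu))
    ).sum()


def _nb_fit_mean(y: np.ndarray, sf: np.ndarray, phi: float, iters: int = 25) -> float:
    """ML of the common mean for NB counts with offsets ``sf`` and fixed phi.

    Solves sum (y - mu*sf) / (1 + phi*mu*sf) = 0 by damped Newton.
    """
    mu = max(y.sum() / sf.sum(), 1e-8)
    if phi <= _PHI_MIN:
        return mu  # Poisson ML is the weighted mean
    for _ in range(iters):
        denom = 1.0 + phi * mu * sf
        g = np.sum((y - mu * sf) / denom)
        gp = np.sum(-sf * (1.0 + phi * y) / denom**2)
        step = g / gp if gp != 0 else 0.0
        mu_new = mu - step
        if mu_new <= 0:
            mu_new = mu / 2.0
        if abs(mu_new - mu) < 1e-10 * (1 + mu):
            mu = mu_new
            break
        mu = mu_new
    return mu


def estimate_dispersions(z_a: np.ndarray, z_b: np.ndarray, inv_sf_mean: float) -> dict:
    """Method-of-moments per-gene NB dispersions shrunk toward a trend.

    ``z_*`` are size-factor-normalized counts.  Raw phi-hat comes from the
    pooled within-group moments; the trend phi(mu) = a/mu + b is fitted by
    least squares and the final estimate is a df-weighted average of raw
    and trend values.
    """
    mu = np.concatenate([z_a, z_b], axis=1).mean(axis=1)
    df_a, df_b = z_a.shape[1] - 1, z_b.shape[1] - 1
    var_pooled = (z_a.var(axis=1, ddof=1) * df_a + z_b.var(axis=1, ddof=1) * df_b) / (df_a + df_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi_raw = (var_pooled - mu * inv_sf_mean) / mu**2
    phi_raw = np.where(np.isfinite(phi_raw), phi_raw, 0.0)
    ok = mu > 0
    X = np.column_stack([1.0 / mu[ok], np.ones(ok.sum())])
    coef, *_ = np.linalg.lstsq(X, np.clip(phi_raw[ok], 0, None), rcond=None)
    a, b = coef
    with np.errstate(divide="ignore"):
        phi_trend = np.clip(a / np.maximum(mu, 1e-10) + b, _PHI_MIN, None)
    resid_df = df_a + df_b
    w = _SHRINK_PRIOR_DF / (_SHRINK_PRIOR_DF + resid_df)
    phi = np.clip(w * phi_trend + (1 - w) * phi_raw, _PHI_MIN, None)
    return {"phi": phi, "phi_raw": phi_raw, "phi_trend": phi_trend, "mu": mu}


def deg_test(
    counts_a: pd.DataFrame,
    counts_b: pd.DataFrame,
    tissues: tuple[str, str] = ("liver", "muscle"),
    q_cut: float = DEFAULT_Q_CUT,
) -> pd.DataFrame:
    """Two-group NB quasi-likelihood test on expressed genes.

    Returns per gene: log2fc (``a``/``b``, 0.5 pseudo-count for reporting
    only), F statistic, p, BH q, and the DEG label.
    """
    ta, tb = tissues
    if counts_a.shape[1] < 2 or counts_b.shape[1] < 2:
        raise ValueError("need >= 2 replicates per tissue (dispersion unidentifiable)")
    if not counts_a.index.equals(counts_b.index):
        raise ValueError("count matrices must share the gene index")
    ya = counts_a.to_numpy(dtype=float)
    yb = counts_b.to_numpy(dtype=float)
    all_counts = pd.concat([counts_a, counts_b], axis=1)
    sf = size_factors(all_counts)
    sfa, sfb = sf[: ya.shape[1]], sf[ya.shape[1]:]
    za, zb = ya / sfa, yb / sfb
    disp = estimate_dispersions(za, zb, float(np.mean(1.0 / sf)))
    n_genes = ya.shape[0]
    lr = np.zeros(n_genes)
    dev = np.zeros(n_genes)
    mu_a_hat = np.zeros(n_genes)
    mu_b_hat = np.zeros(n_genes)
    for i in range(n_genes):
        phi = disp["phi"][i]
        mu_a = _nb_fit_mean(ya[i], sfa, phi)
        mu_b = _nb_fit_mean(yb[i], sfb, phi)
        mu_0 = _nb_fit_mean(np.concatenate([ya[i], yb[i]]), sf, phi)
        ll1 = _nb_loglik(ya[i], mu_a * sfa, phi) + _nb_loglik(yb[i], mu_b * sfb, phi)
        ll0 = _nb_loglik(np.concatenate([ya[i], yb[i]]), mu_0 * sf, phi)
        llsat = _nb_loglik(ya[i], np.maximum(ya[i], 1e-10), phi) + _nb_loglik(
            yb[i], np.maximum(yb[i], 1e-10), phi
        )
        lr[i] = max(2.0 * (ll1 - ll0), 0.0)
        dev[i] = max(2.0 * (llsat - ll1), 0.0)
        mu_a_hat[i], mu_b_hat[i] = mu_a, mu_b
    resid_df = ya.shape[1] + yb.shape[1] - 2
    s2 = dev / resid_df
    s2_shrunk, d0 = squeeze_var(np.maximum(s2, 1e-8), resid_df)
    denom_df = resid_df + d0
    F = lr / np.maximum(s2_shrunk, 1e-8)
    p = f_dist.sf(F, 1, denom_df if np.isfinite(denom_df) else 1e9)
    q = bh_adjust(p)
    log2fc = np.log2((mu_a_hat + 0.5) / (mu_b_hat + 0.5))
    label = np.where(
        (q < q_cut) & (log2fc > 0), f"{ta}_deg", np.where(q < q_cut, f"{tb}_deg", "non_deg")
    )
    return pd.DataFrame(
        {
            "gene_id": counts_a.index,
            "log2fc": log2fc,
            "statistic": F,
            "p": p,
            "q": q,
            "label": label,
            "expressed": True,
        }
    ).set_index("gene_id")


def fc_methylation_correlation(
    degs: pd.DataFrame,
    window_meth: pd.DataFrame,
    expression_fc: pd.Series | None = None,
    tissues: tuple[str, str] = ("liver", "muscle"),
) -> dict:
    """Pearson correlation between expression and methylation log2 fold
    changes over DEGs.

    Uses log2(ratio_a/ratio_b) of the TSS-window methylation against the
    DEG table's expression log2fc (or ``expression_fc``, e.g. a TPM-based
    fold change) for DEGs with positive window ratios in both tissues.
    """
    ta, tb = tissues
    wr = window_meth.pivot(index="gene_id", columns="tissue", values="mean_ratio")
    deg_only = degs[degs["label"] != "non_deg"]
    fc_expr = expression_fc if expression_fc is not None else deg_only["log2fc"]
    joint = pd.concat(
        {"expr_fc": fc_expr, "ra": wr[ta], "rb": wr[tb]}, axis=1
    ).loc[deg_only.index].dropna()
    joint = joint[(joint["ra"] > 0) & (joint["rb"] > 0)]
    if len(joint) < 3:
        raise ValueError("fewer than 3 DEGs with valid window ratios in both tissues")
    meth_fc = np.log2(joint["ra"] / joint["rb"])
    r, p = pearson_r(joint["expr_fc"].to_numpy(), meth_fc.to_numpy())
    return {"r": r, "p": p, "n": len(joint)}
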