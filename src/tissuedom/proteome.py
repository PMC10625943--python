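"""Protein detection, arcsinh variance-stabilizing normalization, moderated
differential testing, and the protein/mRNA-ratio outlier criterion.

A protein counts as detected in a tissue when its intensity is present in
at least 3 of 5 replicates.  Intensities of proteins detected in both
tissues are normalized with h(x) = gamma * arcsinh(a + b*x); (a, b, gamma)
are estimated by a robust profile maximum likelihood in which the
transformed values are modelled as Gaussian around per-protein means with
unit variance (gamma absorbs the noise scale) and a least-trimmed-squares
loop down-weights outlier proteins.  Differential abundance uses an
empirical-Bayes moderated t; proteins detected in only one tissue are DEPs
by definition and bypass the test.

Post-transcriptional differences are scored on the per-tissue
log(protein/mRNA) ratio: the liver ratio is regressed on the muscle ratio
and a protein is a DRP when removing it lets the refit mean squared error
drop below the full-fit MSE.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import t as t_dist

from tissuedom.stats_core import bh_adjust, fisher_exact, squeeze_var

DEFAULT_MIN_REPS = 3
DEFAULT_Q_CUT = 0.01
VSN_TRIM_FRACTION = 0.10


def detect_proteins(intensities: pd.DataFrame, min_reps: int = DEFAULT_MIN_REPS) -> pd.Series:
    """Detected iff non-missing intensity in >= min_reps replicates."""
    if min_reps > intensities.shape[1]:
        raise ValueError("min_reps exceeds the number of replicates")
    return intensities.notna().sum(axis=1) >= min_reps


@dataclass(frozen=True)
class VsnParams:
    """Parameters of h(x) = gamma * arcsinh(a + b*x); b, gamma > 0."""

    a: float
    b: float
    gamma: float

    def __post_init__(self):
        if self.b <= 0 or self.gamma <= 0:
            raise ValueError("b and gamma must be positive")

    def transform(self, x):
        return self.gamma * np.arcsinh(self.a + self.b * np.asarray(x, dtype=float))


def _vsn_nll_ab(a: float, b: float, X: np.ndarray, keep: np.ndarray):
    """Profile negative log-likelihood over (a, b) with per-protein means and
    gamma profiled out in closed form; returns (nll, gamma)."""
    sub = X[keep]
    u = np.arcsinh(a + b * sub)
    m = np.nanmean(u, axis=1)
    resid = u - m[:, None]
    ss = np.nansum(resid**2)
    n_obs = np.isfinite(sub).sum()
    if ss <= 0:
        return np.inf, 1.0
    gamma = np.sqrt(n_obs / ss)
    # -log-likelihood with unit latent variance: quadratic term = n/2 after
    # profiling, so only the Jacobian sum(log h'(x)) varies with (a, b, gamma)
    jac = n_obs * np.log(gamma * b) - 0.5 * np.nansum(np.log1p((a + b * sub) ** 2))
    nll = 0.5 * gamma**2 * ss - jac
    return nll, gamma


def vsn_fit(
    intensities: pd.DataFrame,
    trim: float = VSN_TRIM_FRACTION,
    lts_iters: int = 3,
) -> tuple[VsnParams, pd.DataFrame]:
    """Fit h(x) = gamma*arcsinh(a + b*x) by robust profile ML.

    ``intensities`` holds proteins detected in both tissues (rows) by all
    replicates of both tissues (columns); missing values are ignored.  The
    least-trimmed-squares loop refits on the (1 - trim) fraction of proteins
    with the smallest mean squared transformed residual.  Returns the
    parameters and the transformed matrix.
    """
    X = intensities.to_numpy(dtype=float)
    if X.shape[0] < 20:
        raise ValueError("need >= 20 proteins detected in both tissues")
    med = np.nanmedian(X)
    keep = np.ones(X.shape[0], dtype=bool)
    a0, logb0 = 0.0, float(np.log(1.0 / med))
    result = None
    for _ in range(max(lts_iters, 1)):
        res = minimize(
            lambda p: _vsn_nll_ab(p[0], np.exp(p[1]), X, keep)[0],
            x0=np.array([a0, logb0]),
            method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000},
        )
        if not np.isfinite(res.fun):
            raise RuntimeError("VSN profile likelihood did not converge")
        a0, logb0 = float(res.x[0]), float(res.x[1])
        gamma = _vsn_gamma(a0, np.exp(logb0), X, keep, trim)
        result = VsnParams(a0, float(np.exp(logb0)), float(gamma))
        # trim proteins with the largest residual mean squares
        h = result.transform(X)
        resid = h - np.nanmean(h, axis=1)[:, None]
        rms = np.nanmean(resid**2, axis=1)
        cut = np.nanquantile(rms, 1.0 - trim)
        keep = rms <= cut
    transformed = pd.DataFrame(
        result.transform(X), index=intensities.index, columns=intensities.columns
    )
    return result, transformed


def _vsn_gamma(a: float, b: float, X: np.ndarray, keep: np.ndarray, trim: float) -> float:
    """Latent-scale gain so that transformed residuals have unit variance.

    Corrects the naive n/SS estimate for (i) the degrees of freedom consumed
    by the per-protein means and (ii) the downward bias of least-trimmed
    scale estimation (chi-square partial-expectation consistency factor).
    """
    from scipy.stats import chi2 as chi2_dist

    u = np.arcsinh(a + b * X[keep])
    resid = u - np.nanmean(u, axis=1)[:, None]
    ss = np.nansum(resid**2)
    n_obs = np.isfinite(X[keep]).sum()
    n_rows = keep.sum()
    dfree = max(n_obs - n_rows, 1)
    if trim > 0:
        d = max(dfree / n_rows, 1.0)  # average residual df per protein row
        q = chi2_dist.ppf(1.0 - trim, d)
        consistency = chi2_dist.cdf(q, d + 2) / (1.0 - trim)
    else:
        consistency = 1.0
    return float(np.sqrt(dfree * consistency / ss))


def moderated_test(
    h_a: pd.DataFrame,
    h_b: pd.DataFrame,
    tissues: tuple[str, str] = ("liver", "muscle"),
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Two-group moderated t on VSN-transformed intensities.

    Per-protein pooled variances are squeezed toward an empirical-Bayes
    prior (moment-matched s0^2 and d0); with d0 = 0 the statistic reduces
    to the ordinary pooled-variance two-sample t.  Missing replicates are
    dropped per protein; q is Benjamini-Hochberg.  ``prior_df`` overrides
    the fitted d0 (0 disables moderation, giving the ordinary pooled t).
    """
    ta, tb = tissues
    if not h_a.index.equals(h_b.index):
        raise ValueError("matrices must share the protein index")
    A, B = h_a.to_numpy(float), h_b.to_numpy(float)
    na = np.isfinite(A).sum(axis=1)
    nb = np.isfinite(B).sum(axis=1)
    df = na + nb - 2
    if np.any(df <= 0):
        raise ValueError("zero residual degrees of freedom for some protein")
    mean_a = np.nanmean(A, axis=1)
    mean_b = np.nanmean(B, axis=1)
    var_a = np.nanvar(A, axis=1, ddof=1)
    var_b = np.nanvar(B, axis=1, ddof=1)
    s2 = ((na - 1) * var_a + (nb - 1) * var_b) / df
    df_common = float(np.median(df))
    if prior_df is None:
        s2_tilde, d0 = squeeze_var(np.maximum(s2, 1e-12), df_common)
    elif prior_df == 0:
        s2_tilde, d0 = s2, 0.0
    else:
        d0 = float(prior_df)
        s0 = float(np.exp(np.log(np.maximum(s2, 1e-12)).mean()))
        s2_tilde = (d0 * s0 + df * s2) / (d0 + df)
    diff = mean_a - mean_b
    se = np.sqrt(s2_tilde * (1.0 / na + 1.0 / nb))
    t_stat = diff / se
    total_df = df + (d0 if np.isfinite(d0) else 1e9)
    p = 2.0 * t_dist.sf(np.abs(t_stat), total_df)
    q = bh_adjust(p)
    return pd.DataFrame(
        {
            "diff": diff,
            f"mean_{ta}": mean_a,
            f"mean_{tb}": mean_b,
            "t": t_stat,
            "df": total_df,
            "p": p,
            "q": q,
        },
        index=h_a.index,
    )


def call_deps(
    detected_a: pd.Series,
    detected_b: pd.Series,
    test: pd.DataFrame | None,
    tissues: tuple[str, str] = ("liver", "muscle"),
    q_cut: float = DEFAULT_Q_CUT,
) -> pd.DataFrame:
    """DEP labels per protein.

    Both-tissue proteins with q < q_cut are ``<tissue>_dominant`` by the
    sign of the difference; proteins detected in exactly one tissue are
    ``<tissue>_only``; other both-tissue proteins are non_dep; proteins
    detected in neither tissue are dropped.
    """
    ta, tb = tissues
    idx = detected_a.index
    labels = {}
    for pid in idx:
        da, db = bool(detected_a[pid]), bool(detected_b[pid])
        if not (da or db):
            continue
        if da and not db:
            labels[pid] = f"{ta}_only"
        elif db and not da:
            labels[pid] = f"{tb}_only"
        else:
            lab = "non_dep"
            if test is not None and pid in test.index:
                row = test.loc[pid]
                if row["q"] < q_cut:
                    lab = f"{ta}_dominant" if row["diff"] > 0 else f"{tb}_dominant"
            labels[pid] = lab
    out = pd.DataFrame({"label": pd.Series(labels)})
    out.index.name = "protein_id"
    out[f"detected_{ta}"] = detected_a.reindex(out.index)
    out[f"detected_{tb}"] = detected_b.reindex(out.index)
    if test is not None:
        out["q"] = test["q"].reindex(out.index)
    return out


def protein_mrna_ratio(
    intensities: pd.DataFrame, tpm: pd.Series, detected: pd.Series
) -> pd.Series:
    """Per-protein log(mean intensity / TPM) for one tissue.

    Missing when the protein is not detected or the gene's TPM is not
    positive.  The ratio direction is protein over mRNA; a global flip only
    swaps DRP direction labels.
    """
    mean_int = intensities.mean(axis=1, skipna=True)
    tpm = tpm.reindex(intensities.index)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.log(mean_int / tpm)
    ratio[~detected.reindex(intensities.index).fillna(False) | ~(tpm > 0)] = np.nan
    return ratio


def call_drps(
    ratio_a: pd.Series,
    ratio_b: pd.Series,
    tissues: tuple[str, str] = ("liver", "muscle"),
    compare_to: str = "full",
) -> pd.DataFrame:
    """Leave-one-out MSE criterion for protein/mRNA-ratio outliers.

    The ``<a>`` log-ratio is regressed on the ``<b>`` log-ratio over all
    proteins with both ratios; for each protein the line is refitted
    without it and the refit's MSE on the remaining n-1 points is compared
    with the MSE of the full fit on all n points (``compare_to="full"``,
    the default literal reading) or with the refit's MSE recomputed on all
    n points (``compare_to="refit_all"``).  A strict decrease flags the
    protein; residual above the full line -> ``<a>_drp``, below ->
    ``<b>_drp``.
    """
    ta, tb = tissues
    joint = pd.concat({"y": ratio_a, "x": ratio_b}, axis=1).dropna()
    n = len(joint)
    if n < 10:
        raise ValueError("need >= 10 proteins with both-tissue ratios")
    x = joint["x"].to_numpy()
    y = joint["y"].to_numpy()
    if np.ptp(x) == 0:
        raise ValueError("degenerate regressor: zero variance in one tissue's ratios")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    mse_full = float(np.mean(resid**2))
    flagged = np.zeros(n, dtype=bool)
    # an (effectively) perfect fit has nothing to improve on
    exact = mse_full <= 1e-12 * max(float(np.var(y)), 1e-12)
    for i in range(n if not exact else 0):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        xi, yi = x[mask], y[mask]
        if np.ptp(xi) == 0:
            continue
        b1, b0 = np.polyfit(xi, yi, 1)
        if compare_to == "full":
            mse_ref = float(np.mean((yi - (b1 * xi + b0)) ** 2))
        elif compare_to == "refit_all":
            mse_ref = float(np.mean((y - (b1 * x + b0)) ** 2))
        else:
            raise ValueError("compare_to must be 'full' or 'refit_all'")
        flagged[i] = mse_ref < mse_full
    label = np.where(flagged & (resid > 0), f"{ta}_drp", np.where(flagged, f"{tb}_drp", "none"))
    return pd.DataFrame(
        {
            f"log_ratio_{ta}": y,
            f"log_ratio_{tb}": x,
            "residual": resid,
            "label": label,
        },
        index=joint.index,
    )


def top_motif_overlap(
    drp_labels: pd.Series, gene_set: set, direction: str, universe=None
) -> dict:
    """Fisher enrichment of one DRP direction inside a gene set (e.g. the
    5'-TOP-motif mRNAs).

    Universe defaults to the proteins carrying a DRP call.  Returns the 2x2
    table (a = flagged-in-direction and in set) and right-tailed p.
    """
    if not gene_set:
        raise ValueError("empty gene set")
    idx = drp_labels.index if universe is None else pd.Index(universe)
    in_dir = drp_labels.reindex(idx).eq(direction)
    in_set = idx.isin(gene_set)
    a = int((in_dir & in_set).sum())
    b = int((in_dir & ~in_set).sum())
    c = int((~in_dir & in_set).sum())
    d = int((~in_dir & ~in_set).sum())
    return {
        "table": [[a, b], [c, d]],
        "p_right": fisher_exact([[a, b], [c, d]], tail="right"),
    }
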