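"""Per-CpG differential methylation between two tissues and DMG calling.

The per-site test is a beta-binomial likelihood-ratio test on the
replicate-level (n_meth, n_total) pairs: H0 one shared mean, H1 one mean
per tissue, with a dispersion shared between tissues.  The dispersion
(precision ``s``; counts are Binomial(n, p) with p ~ Beta(mu*s, (1-mu)*s))
is estimated once across all tested sites by maximum likelihood with the
pooled per-tissue ratios plugged in as means, which keeps the chi2(1)
reference distribution well calibrated even at 3 replicates per tissue.
Per-site means are profiled by vectorized golden-section search.  With a
single replicate per tissue the test falls back to Fisher's exact test on
the pooled counts.

Genes are called DMGs when they are hypomethylated in at least one tissue,
carry at least one directional DMCpG (Storey q < 0.01) inside the
strand-aware TSS window, and show a consistent window-mean difference.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import betaln
from scipy.stats import chi2

from tissuedom import stats_core
from tissuedom.annotation import GeneModel
from tissuedom.methylome import (
    DEFAULT_MIN_COVERAGE,
    WINDOW_DOWNSTREAM,
    WINDOW_UPSTREAM,
    MethylomeData,
    pooled_ratio,
)

DEFAULT_Q_CUT = 0.01
_MU_LO, _MU_HI = 1e-6, 1.0 - 1e-6
_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0


def _bb_loglik(m: np.ndarray, t: np.ndarray, mu: np.ndarray, s: float) -> np.ndarray:
    """Beta-binomial log-likelihood per site (summed over replicate axis 1),
    dropping the mu-free binomial coefficient."""
    a = mu * s
    b = (1.0 - mu) * s
    return (betaln(m + a[:, None], t - m + b[:, None]) - betaln(a, b)[:, None]).sum(axis=1)


def _golden_max(f, n_sites: int, iters: int = 40):
    """Vectorized golden-section maximization of f(mu) over (0,1) per site."""
    lo = np.full(n_sites, _MU_LO)
    hi = np.full(n_sites, _MU_HI)
    for _ in range(iters):
        x1 = hi - _GOLDEN * (hi - lo)
        x2 = lo + _GOLDEN * (hi - lo)
        take = f(x1) < f(x2)  # maximum lies in [x1, hi]
        lo = np.where(take, x1, lo)
        hi = np.where(take, hi, x2)
    mid = (lo + hi) / 2.0
    return mid, f(mid)


def estimate_dispersion(
    meth_a, total_a, meth_b, total_b, bounds: tuple[float, float] = (0.5, 5000.0)
) -> float:
    """Global beta-binomial precision ``s`` by a pooled moment estimator.

    The intraclass correlation rho = 1/(1+s) is solved from the identity
    E[var of replicate ratios] = mu(1-mu) * (rho + (1-rho) * E[1/n]),
    pooled over all sites and both tissues.  Profile/plug-in ML is avoided
    deliberately: with few replicates the per-site nuisance means bias the
    dispersion downward (Neyman-Scott), which would make the LR test
    anticonservative.
    """
    num = 0.0
    den = 0.0
    base = 0.0
    for m, n in ((np.asarray(meth_a, float), np.asarray(total_a, float)),
                 (np.asarray(meth_b, float), np.asarray(total_b, float))):
        if m.shape[1] < 2:
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            r = m / n
        ok_rep = np.isfinite(r)
        ok = ok_rep.sum(axis=1) >= 2
        r = np.where(ok_rep, r, np.nan)
        v = np.nanvar(r[ok], axis=1, ddof=1)
        mu = m[ok].sum(axis=1) / n[ok].sum(axis=1)
        d = mu * (1.0 - mu)
        with np.errstate(divide="ignore"):
            c = np.nanmean(np.where(n[ok] > 0, 1.0 / n[ok], np.nan), axis=1)
        informative = d > 1e-6
        num += v[informative].sum() - (d * c)[informative].sum()
        den += (d * (1.0 - c))[informative].sum()
        base += informative.sum()
    if den <= 0 or base == 0:
        return float(bounds[1])
    rho = num / den
    s = (1.0 - rho) / rho if rho > 0 else bounds[1]
    return float(np.clip(s, bounds[0], bounds[1]))


def dmcpg_test_all(
    data: MethylomeData,
    tissues: tuple[str, str] = ("liver", "muscle"),
    min_coverage: int = DEFAULT_MIN_COVERAGE,
    dispersion: float | None = None,
) -> pd.DataFrame:
    """Beta-binomial LR test at every CpG site with sufficient coverage.

    Returns one row per CpG-context site: chrom, pos, ratio_<a>, ratio_<b>,
    statistic, p, tested.  Sites below ``min_coverage`` pooled reads in
    either tissue are kept but flagged untested (p = NaN).
    """
    ta, tb = tissues
    is_cpg = (data.sites["context"] == "CpG").to_numpy()
    ma, na = data.meth[ta][is_cpg], data.total[ta][is_cpg]
    mb, nb = data.meth[tb][is_cpg], data.total[tb][is_cpg]
    ra = pooled_ratio(ma, na, min_coverage)
    rb = pooled_ratio(mb, nb, min_coverage)
    tested = ~np.isnan(ra) & ~np.isnan(rb)
    stat = np.full(ra.shape, np.nan)
    p = np.full(ra.shape, np.nan)
    if tested.any():
        tma, tna, tmb, tnb = ma[tested], na[tested], mb[tested], nb[tested]
        if tna.shape[1] == 1 and tnb.shape[1] == 1:
            # single replicate: Fisher's exact on the pooled 2x2 counts
            p_t = np.array(
                [
                    stats_core.fisher_exact(
                        [[m1, t1 - m1], [m2, t2 - m2]], tail="two"
                    )
                    for m1, t1, m2, t2 in zip(
                        tma[:, 0], tna[:, 0], tmb[:, 0], tnb[:, 0]
                    )
                ]
            )
            stat_t = np.full(p_t.shape, np.nan)
        else:
            stat_t, p_t = _lr_test(tma, tna, tmb, tnb, dispersion)
        stat[tested] = stat_t
        p[tested] = p_t
    return pd.DataFrame(
        {
            "chrom": data.sites.loc[is_cpg, "chrom"].to_numpy(),
            "pos": data.sites.loc[is_cpg, "pos"].to_numpy(),
            f"ratio_{ta}": ra,
            f"ratio_{tb}": rb,
            "statistic": stat,
            "p": p,
            "tested": tested,
        }
    )


def _lr_test(ma, na, mb, nb, dispersion: float | None):
    s = estimate_dispersion(ma, na, mb, nb) if dispersion is None else float(dispersion)
    n_sites = ma.shape[0]
    mc = np.concatenate([ma, mb], axis=1)
    nc = np.concatenate([na, nb], axis=1)
    _, ll_a = _golden_max(lambda mu: _bb_loglik(ma, na, mu, s), n_sites)
    _, ll_b = _golden_max(lambda mu: _bb_loglik(mb, nb, mu, s), n_sites)
    _, ll_0 = _golden_max(lambda mu: _bb_loglik(mc, nc, mu, s), n_sites)
    lr = np.maximum(2.0 * (ll_a + ll_b - ll_0), 0.0)
    return lr, chi2.sf(lr, df=1)


def dmcpg_test(
    meth_a, total_a, meth_b, total_b, dispersion: float | None = None
) -> tuple[float, float]:
    """Single-site convenience wrapper; returns (LR statistic, p).

    Arguments are per-replicate count vectors for the two tissues.  With one
    replicate per tissue the statistic is NaN and p comes from Fisher's
    exact test on the 2x2 pooled counts.
    """
    ma = np.asarray(meth_a, dtype=float)[None, :]
    na = np.asarray(total_a, dtype=float)[None, :]
    mb = np.asarray(meth_b, dtype=float)[None, :]
    nb = np.asarray(total_b, dtype=float)[None, :]
    if ma.shape[1] == 1 and mb.shape[1] == 1:
        p = stats_core.fisher_exact(
            [[ma[0, 0], na[0, 0] - ma[0, 0]], [mb[0, 0], nb[0, 0] - mb[0, 0]]], tail="two"
        )
        return float("nan"), p
    # a lone site gives the dispersion estimator nothing to work with;
    # default to a weakly informative precision unless one is supplied
    disp = 50.0 if dispersion is None else dispersion
    lr, p = _lr_test(ma, na, mb, nb, disp)
    return float(lr[0]), float(p[0])


def call_dmcpgs(
    results: pd.DataFrame,
    q_cut: float = DEFAULT_Q_CUT,
    tissues: tuple[str, str] = ("liver", "muscle"),
) -> pd.DataFrame:
    """Flag DMCpGs at Storey q < ``q_cut`` among tested sites.

    Direction is the tissue with the lower pooled ratio (``<a>_hypo`` or
    ``<b>_hypo``).
    """
    ta, tb = tissues
    out = results.copy()
    out["q"] = np.nan
    tested = out["tested"].to_numpy() & ~out["p"].isna().to_numpy()
    if tested.any():
        out.loc[tested, "q"] = stats_core.storey_qvalue(out.loc[tested, "p"].to_numpy())
    out["is_dmcpg"] = (out["q"] < q_cut).fillna(False)
    direction = np.where(
        out[f"ratio_{ta}"] < out[f"ratio_{tb}"], f"{ta}_hypo", f"{tb}_hypo"
    )
    out["direction"] = np.where(out["is_dmcpg"], direction, "")
    return out


def call_dmgs(
    models: list[GeneModel],
    dmcpgs: pd.DataFrame,
    window_states: pd.DataFrame,
    tissues: tuple[str, str] = ("liver", "muscle"),
    upstream: int = WINDOW_UPSTREAM,
    downstream: int = WINDOW_DOWNSTREAM,
) -> pd.DataFrame:
    """Per-gene DMG labels from window states and in-window DMCpGs.

    A gene is ``<a>_dmg`` iff it is hypomethylated (state == hypo) in at
    least one tissue, has >= 1 DMCpG with direction ``<a>_hypo`` inside the
    strand-aware TSS window, and its ``<a>`` window mean ratio is below the
    ``<b>`` one; symmetric for ``<b>``; otherwise ``non_dmg``.  Genes with
    no covered window CpG are non_dmg and flagged untested.
    """
    ta, tb = tissues
    ws = window_states.pivot(index="gene_id", columns="tissue", values="state")
    wr = window_states.pivot(index="gene_id", columns="tissue", values="mean_ratio")
    hits = dmcpgs[dmcpgs["is_dmcpg"]]
    by_chrom: dict[str, pd.DataFrame] = {c: g for c, g in hits.groupby("chrom")}
    rows = []
    for m in models:
        gid = m.transcript_id
        state_a = ws.at[gid, ta] if gid in ws.index else "NA"
        state_b = ws.at[gid, tb] if gid in ws.index else "NA"
        r_a = wr.at[gid, ta] if gid in wr.index else np.nan
        r_b = wr.at[gid, tb] if gid in wr.index else np.nan
        untested = state_a == "NA" and state_b == "NA"
        if m.strand == "+":
            g_lo, g_hi = m.tss - upstream, m.tss + downstream
        else:
            g_lo, g_hi = m.tss + 1 - downstream, m.tss + 1 + upstream
        sub = by_chrom.get(m.chrom)
        n_a = n_b = 0
        if sub is not None:
            inwin = sub[(sub["pos"] >= g_lo) & (sub["pos"] < g_hi)]
            n_a = int((inwin["direction"] == f"{ta}_hypo").sum())
            n_b = int((inwin["direction"] == f"{tb}_hypo").sum())
        hypo_any = state_a == "hypo" or state_b == "hypo"
        label = "non_dmg"
        if hypo_any and n_a >= 1 and np.isfinite(r_a) and np.isfinite(r_b) and r_a < r_b:
            label = f"{ta}_dmg"
        elif hypo_any and n_b >= 1 and np.isfinite(r_a) and np.isfinite(r_b) and r_b < r_a:
            label = f"{tb}_dmg"
        rows.append((gid, label, n_a + n_b, state_a, state_b, untested))
    return pd.DataFrame(
        rows,
        columns=["gene_id", "label", "n_dmcpg_in_window", f"state_{ta}", f"state_{tb}", "untested"],
    )
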