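"""Methylation ratios, TSS-window summaries, correlation scans, and the
hypo/hyper split.

Per-CpG methylation is summarized as the pooled ratio sum(meth)/sum(total)
across replicates of one tissue (missing below ``min_coverage`` total
reads).  Gene-level promoter methylation is the mean of pooled per-CpG
ratios inside the strand-aware TSS window (default -200..+400 bp).  The
pooled window ratios of both tissues form a bimodal distribution that is
split into hypo- and hypermethylated genes by an exact-sample Otsu
threshold; bimodality itself is assessed with Silverman's critical-bandwidth
bootstrap test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from tissuedom.annotation import GeneModel, strand_offset
from tissuedom.stats_core import spearman_rho

#: minimum pooled reads per tissue for a per-CpG ratio to count
DEFAULT_MIN_COVERAGE = 5

WINDOW_UPSTREAM = 200
WINDOW_DOWNSTREAM = 400
SCAN_LO = -1500
SCAN_HI = 2000
SCAN_WIN = 100


class MethylomeData:
    """Replicate-level cytosine counts for several tissues on shared sites.

    ``sites`` is a DataFrame (chrom, pos, context) with one row per
    cytosine; ``meth[tissue]`` and ``total[tissue]`` are (n_sites, n_reps)
    integer arrays aligned to it.
    """

    def __init__(self, sites: pd.DataFrame, meth: dict, total: dict):
        self.sites = sites.reset_index(drop=True)
        self.meth = {t: np.asarray(m) for t, m in meth.items()}
        self.total = {t: np.asarray(m) for t, m in total.items()}
        for t in self.meth:
            if self.meth[t].shape != self.total[t].shape:
                raise ValueError(f"{t}: meth/total shape mismatch")
            if self.meth[t].shape[0] != len(self.sites):
                raise ValueError(f"{t}: row count does not match sites")
            if np.any(self.meth[t] > self.total[t]) or np.any(self.meth[t] < 0):
                raise ValueError(f"{t}: need 0 <= n_meth <= n_total")

    @property
    def tissues(self) -> list[str]:
        return list(self.meth)

    def subset(self, mask) -> "MethylomeData":
        idx = np.asarray(mask)
        return MethylomeData(
            self.sites.loc[idx],
            {t: m[idx] for t, m in self.meth.items()},
            {t: m[idx] for t, m in self.total.items()},
        )

    @classmethod
    def from_tables(cls, tables: dict[str, list[pd.DataFrame]], collapse_strands: bool = True):
        """Build from per-tissue lists of replicate tables with columns
        chrom, pos, strand, context, n_meth, n_total.

        Minus-strand CpG records are collapsed onto the + strand position of
        the dyad (pos - 1) so counts are strand-symmetric; CHG/CHH records
        keep their own positions.
        """
        frames = {}
        keys = None
        for tissue, reps in tables.items():
            agg = []
            for df in reps:
                df = df.copy()
                if collapse_strands:
                    flip = (df["context"] == "CpG") & (df["strand"] == "-")
                    df.loc[flip, "pos"] = df.loc[flip, "pos"] - 1
                g = df.groupby(["chrom", "pos", "context"], sort=True)[["n_meth", "n_total"]].sum()
                agg.append(g)
            merged = pd.concat(agg, axis=1, keys=range(len(agg))).fillna(0).astype(int)
            frames[tissue] = merged
            keys = merged.index if keys is None else keys.union(merged.index)
        sites = pd.DataFrame(list(keys), columns=["chrom", "pos", "context"])
        meth, total = {}, {}
        for tissue, merged in frames.items():
            merged = merged.reindex(keys, fill_value=0)
            n_reps = merged.columns.levels[0].size
            meth[tissue] = np.stack(
                [merged[(r, "n_meth")].to_numpy() for r in range(n_reps)], axis=1
            )
            total[tissue] = np.stack(
                [merged[(r, "n_total")].to_numpy() for r in range(n_reps)], axis=1
            )
        return cls(sites, meth, total)


def pooled_ratio(
    meth: np.ndarray, total: np.ndarray, min_coverage: int = DEFAULT_MIN_COVERAGE
) -> np.ndarray:
    """Pooled methylation ratio sum(n_meth)/sum(n_total) across replicates.

    Works on (n_sites, n_reps) arrays or single-site 1-D arrays; sites whose
    pooled coverage is below ``min_coverage`` get NaN (missing, not error).
    """
    meth = np.atleast_2d(np.asarray(meth, dtype=float))
    total = np.atleast_2d(np.asarray(total, dtype=float))
    m = meth.sum(axis=1)
    t = total.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(t >= max(min_coverage, 1), m / t, np.nan)
    return r


def site_offsets(data: MethylomeData, models: list[GeneModel], lo: int, hi: int) -> pd.DataFrame:
    """Map CpG sites to strand-aware TSS offsets in [lo, hi) for every gene.

    Returns a DataFrame (gene_id, site_idx, offset); one row per (gene,
    site) pair.  Only context == CpG sites are mapped.
    """
    out_gene, out_idx, out_off = [], [], []
    is_cpg = (data.sites["context"] == "CpG").to_numpy()
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, sub in data.sites.groupby("chrom"):
        mask = is_cpg[sub.index.to_numpy()]
        idx = sub.index.to_numpy()[mask]
        pos = sub["pos"].to_numpy()[mask]
        order = np.argsort(pos)
        by_chrom[chrom] = (pos[order], idx[order])
    for m in models:
        if m.chrom not in by_chrom:
            continue
        pos, idx = by_chrom[m.chrom]
        if m.strand == "+":
            g_lo, g_hi = m.tss + lo, m.tss + hi
        else:
            g_lo, g_hi = m.tss + 1 - hi, m.tss + 1 - lo
        a, b = np.searchsorted(pos, [g_lo, g_hi])
        for p, i in zip(pos[a:b], idx[a:b]):
            out_gene.append(m.transcript_id)
            out_idx.append(int(i))
            out_off.append(strand_offset(m, int(p)))
    return pd.DataFrame({"gene_id": out_gene, "site_idx": out_idx, "offset": out_off})


def window_methylation(
    data: MethylomeData,
    models: list[GeneModel],
    upstream: int = WINDOW_UPSTREAM,
    downstream: int = WINDOW_DOWNSTREAM,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
) -> pd.DataFrame:
    """Mean pooled CpG ratio per gene per tissue inside the TSS window.

    Output columns: gene_id, tissue, mean_ratio, n_cpg.  Genes without a
    covered CpG in the window get NaN ratio and n_cpg = 0.
    """
    offs = site_offsets(data, models, -upstream, downstream)
    ratios = {t: pooled_ratio(data.meth[t], data.total[t], min_coverage) for t in data.tissues}
    rows = []
    grouped = offs.groupby("gene_id")["site_idx"].apply(np.asarray) if len(offs) else pd.Series(dtype=object)
    for m in models:
        idx = grouped.get(m.transcript_id)
        for tissue in data.tissues:
            if idx is None:
                rows.append((m.transcript_id, tissue, np.nan, 0))
                continue
            r = ratios[tissue][idx]
            r = r[~np.isnan(r)]
            rows.append((m.transcript_id, tissue, r.mean() if r.size else np.nan, int(r.size)))
    return pd.DataFrame(rows, columns=["gene_id", "tissue", "mean_ratio", "n_cpg"])


def region_decile_correlation(
    expression: pd.Series, region_ratios: pd.Series, region_name: str = ""
) -> dict:
    """Expression-decile summary and Spearman correlation for one region.

    Genes are split into 10 equal-size sets by expression rank (low to
    high); returns the decile assignment, per-decile ratio summaries, and
    the Spearman rho (with t-test p) between per-gene expression and
    per-gene region mean methylation ratio.
    """
    joint = pd.concat({"expr": expression, "ratio": region_ratios}, axis=1).dropna()
    n = len(joint)
    if n < 10:
        raise ValueError(f"need >= 10 genes to form deciles, got {n}")
    ranks = joint["expr"].rank(method="first")
    decile = np.minimum((10 * (ranks - 1) / n).astype(int), 9)
    summaries = joint.groupby(decile)["ratio"].agg(["mean", "median", "count"])
    rho, p = spearman_rho(joint["expr"].to_numpy(), joint["ratio"].to_numpy())
    return {
        "region": region_name,
        "decile": pd.Series(decile, index=joint.index),
        "decile_summary": summaries,
        "rho": rho,
        "p": p,
        "n": n,
    }


def sliding_window_scan(
    expression: pd.Series,
    data: MethylomeData,
    models: list[GeneModel],
    tissue: str,
    win: int = SCAN_WIN,
    lo: int = SCAN_LO,
    hi: int = SCAN_HI,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
    p_cut: float = 1e-3,
) -> dict:
    """Spearman rho profile in ``win``-bp strand-aware bins around the TSS.

    For each bin, rho is computed between per-gene expression and the bin's
    mean pooled CpG ratio over genes with >= 1 covered CpG in the bin.
    Reports the bin minimizing rho and the maximal contiguous run of bins
    with rho < 0 and p < ``p_cut``.
    """
    offs = site_offsets(data, models, lo, hi)
    ratios = pooled_ratio(data.meth[tissue], data.total[tissue], min_coverage)
    offs = offs.assign(ratio=ratios[offs["site_idx"].to_numpy()]).dropna(subset=["ratio"])
    offs["bin"] = (offs["offset"] - lo) // win
    n_bins = (hi - lo) // win
    rows = []
    for b in range(n_bins):
        sub = offs[offs["bin"] == b]
        gene_means = sub.groupby("gene_id")["ratio"].mean()
        joint = pd.concat({"expr": expression, "ratio": gene_means}, axis=1).dropna()
        if len(joint) < 3 or joint["ratio"].nunique() < 2 or joint["expr"].nunique() < 2:
            rows.append((lo + b * win, lo + (b + 1) * win, np.nan, np.nan, len(joint)))
            continue
        rho, p = spearman_rho(joint["expr"], joint["ratio"])
        rows.append((lo + b * win, lo + (b + 1) * win, rho, p, len(joint)))
    profile = pd.DataFrame(rows, columns=["bin_start", "bin_end", "rho", "p", "n_genes"])
    valid = profile.dropna(subset=["rho"])
    argmin = valid.loc[valid["rho"].idxmin()] if len(valid) else None
    sig = (profile["rho"] < 0) & (profile["p"] < p_cut)
    best_run = _longest_run(sig.to_numpy())
    sig_range = None
    if best_run is not None:
        s, e = best_run
        sig_range = (int(profile.loc[s, "bin_start"]), int(profile.loc[e, "bin_end"]))
    return {
        "profile": profile,
        "argmin_bin": (int(argmin["bin_start"]), int(argmin["bin_end"])) if argmin is not None else None,
        "significant_range": sig_range,
    }


def _longest_run(mask: np.ndarray) -> tuple[int, int] | None:
    best, cur = None, None
    for i, v in enumerate(mask):
        if v:
            cur = (cur[0], i) if cur else (i, i)
            if best is None or cur[1] - cur[0] > best[1] - best[0]:
                best = cur
        else:
            cur = None
    return best


def otsu_threshold(values) -> float:
    """Otsu threshold computed on the exact sample.

    Candidate cut-points are the midpoints between consecutive sorted unique
    values; the returned threshold maximizes the between-class variance
    w0*w1*(mu0-mu1)^2, ties broken toward the smaller threshold.  Exact and
    deterministic — no histogram binning.
    """
    v = np.sort(np.asarray(values, dtype=float))
    v = v[~np.isnan(v)]
    if v.size < 2:
        raise ValueError("need at least 2 values")
    uniq = np.unique(v)
    if uniq.size < 2:
        raise ValueError("degenerate distribution: all values identical")
    cuts = (uniq[:-1] + uniq[1:]) / 2.0
    n = v.size
    csum = np.cumsum(v)
    total = csum[-1]
    k = np.searchsorted(v, cuts, side="right")  # observations below each cut
    w0 = k / n
    w1 = 1.0 - w0
    mu0 = csum[k - 1] / k
    mu1 = (total - csum[k - 1]) / (n - k)
    between = w0 * w1 * (mu0 - mu1) ** 2
    return float(cuts[int(np.argmax(between))])  # first tie -> smaller threshold


# --- Silverman critical-bandwidth bootstrap test -------------------------

_GRID_N = 512  # KDE evaluation grid; configurable via silverman_test(grid_n=...)


def _count_modes(x: np.ndarray, h: float, grid: np.ndarray) -> int:
    """Number of local maxima of the Gaussian KDE of ``x`` at bandwidth ``h``
    evaluated by binned convolution on ``grid``."""
    dx = grid[1] - grid[0]
    hist, _ = np.histogram(x, bins=np.append(grid - dx / 2, grid[-1] + dx / 2))
    dens = gaussian_filter1d(hist.astype(float), sigma=h / dx, mode="constant")
    eps = dens.max() * 1e-10
    d = np.diff(dens)
    rising = d > eps
    falling = d < -eps
    # a mode is a rising->falling transition ignoring flat stretches
    modes, state = 0, False
    for r, f in zip(rising, falling):
        if r:
            state = True
        elif f and state:
            modes += 1
            state = False
    if state:
        modes += 1
    return modes


def _make_grid(x: np.ndarray, h_max: float, grid_n: int) -> np.ndarray:
    lo = x.min() - 3 * h_max
    hi = x.max() + 3 * h_max
    return np.linspace(lo, hi, grid_n)


def critical_bandwidth(values, k_modes: int = 1, grid_n: int = _GRID_N, rtol: float = 1e-3) -> float:
    """Smallest Gaussian-kernel bandwidth at which the KDE of ``values`` has
    at most ``k_modes`` modes, found by geometric bisection."""
    x = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values")
    span = x.max() - x.min()
    if span == 0:
        return 0.0
    hi = span
    grid = _make_grid(x, hi, grid_n)
    lo = (grid[1] - grid[0]) * 0.5
    if _count_modes(x, lo, grid) <= k_modes:
        return float(lo)
    while _count_modes(x, hi, grid) > k_modes:
        hi *= 2
        grid = _make_grid(x, hi, grid_n)
    while hi / lo > 1 + rtol:
        mid = np.sqrt(lo * hi)
        if _count_modes(x, mid, grid) <= k_modes:
            hi = mid
        else:
            lo = mid
    return float(hi)


def silverman_test(
    values, k_modes: int = 1, B: int = 200, seed: int = 0, grid_n: int = _GRID_N
) -> float:
    """Silverman's bootstrap test of H0: the density has <= ``k_modes`` modes.

    The critical bandwidth h_k of the sample is found by bisection; B
    variance-rescaled smoothed-bootstrap resamples are drawn with bandwidth
    h_k, and p is the fraction of resamples whose KDE at h_k still shows
    more than ``k_modes`` modes (equivalently whose critical bandwidth
    exceeds h_k).  Small p rejects <= k modes.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 10:
        raise ValueError("need n >= 10")
    if B < 100:
        raise ValueError("need B >= 100 bootstrap replicates")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values")
    h_k = critical_bandwidth(x, k_modes, grid_n)
    rng = np.random.default_rng(seed)
    n = x.size
    var = x.var()
    shrink = 1.0 / np.sqrt(1.0 + h_k**2 / var) if var > 0 else 1.0
    xbar = x.mean()
    exceed = 0
    for _ in range(B):
        samp = x[rng.integers(0, n, n)]
        y = xbar + shrink * (samp - xbar + h_k * rng.standard_normal(n))
        grid = _make_grid(y, h_k, grid_n)
        if _count_modes(y, h_k, grid) > k_modes:
            exceed += 1
    return exceed / B


@dataclass(frozen=True)
class HypoHyperCall:
    gene_id: str
    tissue: str
    state: str  # hypo | hyper | NA


def classify_hypo_hyper(window_meth: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Label each (gene, tissue) hypo/hyper by the window mean ratio.

    Ratio < threshold -> hypo; ratio >= threshold -> hyper (fixed boundary
    rule); missing ratio -> NA.
    """
    out = window_meth.copy()
    state = np.where(out["mean_ratio"] < threshold, "hypo", "hyper")
    out["state"] = np.where(out["mean_ratio"].isna(), "NA", state)
    return out
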