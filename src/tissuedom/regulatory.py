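"""Peak-to-gene assignment, differential TF-binding calls (DTGs), and
generic peak/gene-class overlap tests.

A TF is bound to a gene when at least one of its peaks intersects the
strand-agnostic flank [TSS-1000, TSS+1000).  The per-gene binding state is
the set of bound TFs per tissue.  Expression effects of binding states are
scored two ways, both on log2(TPM+1) over (gene, tissue) observations:
per-TF marginal Welch tests (bound vs unbound) feeding the combination
rule, and pairwise Welch tests between observed states; Storey q-values
are computed within each family.  A gene whose states differ between
tissues is a DTG when its own state pair tests significant (direct) or
when the state difference decomposes into individually significant TFs
(combination inference).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from tissuedom.annotation import GeneModel
from tissuedom.stats_core import fisher_exact, storey_qvalue, welch_t

DEFAULT_FLANK = 1000
DEFAULT_Q_CUT = 0.01
MIN_GROUP = 3


def read_bed(path: str) -> pd.DataFrame:
    """Read a BED3+/BED6 peak file (0-based half-open intervals)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            rows.append((f[0], int(f[1]), int(f[2])))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def assign_binding(
    peaks: dict[str, dict[str, pd.DataFrame]],
    models: list[GeneModel],
    flank: int = DEFAULT_FLANK,
) -> pd.DataFrame:
    """Binding-state matrix: one row per (gene, tissue), columns per TF.

    ``peaks[tf][tissue]`` is a BED DataFrame.  A TF is bound when any of
    its peaks intersects [TSS-flank, TSS+flank) (half-open, strand
    agnostic); multiple peaks collapse to one bound flag.  A missing
    ``peaks[tf][tissue]`` entry means no data, i.e. unbound everywhere.
    """
    model_chroms = {m.chrom for m in models}
    tissues = sorted({t for per_t in peaks.values() for t in per_t})
    sorted_peaks: dict[tuple, dict] = {}
    for tf, per_tissue in peaks.items():
        for tissue, bed in per_tissue.items():
            peak_chroms = set(bed["chrom"].unique())
            if len(bed) and model_chroms and not (peak_chroms & model_chroms):
                raise ValueError(
                    f"{tf}/{tissue}: no shared chromosomes with the gene models"
                )
            per_chrom = {}
            for chrom, sub in bed.groupby("chrom"):
                iv = sub.sort_values("start")[["start", "end"]].to_numpy()
                per_chrom[chrom] = (iv[:, 0], iv[:, 1])
            sorted_peaks[(tf, tissue)] = per_chrom
    rows = []
    for m in models:
        lo, hi = m.tss - flank, m.tss + flank
        for tissue in tissues:
            bound = {}
            for tf in peaks:
                per_chrom = sorted_peaks.get((tf, tissue), {})
                starts_ends = per_chrom.get(m.chrom)
                hit = False
                if starts_ends is not None:
                    starts, ends = starts_ends
                    j = np.searchsorted(starts, hi)  # peaks starting before window end
                    hit = bool(np.any(ends[:j] > lo))
                bound[tf] = hit
            rows.append({"gene_id": m.transcript_id, "tissue": tissue, **bound})
    return pd.DataFrame(rows)


def binding_states(binding: pd.DataFrame) -> pd.DataFrame:
    """Collapse a binding matrix to one frozenset state per (gene, tissue)."""
    tf_cols = [c for c in binding.columns if c not in ("gene_id", "tissue")]
    state = binding.apply(
        lambda r: frozenset(tf for tf in tf_cols if r[tf]), axis=1
    )
    return pd.DataFrame(
        {"gene_id": binding["gene_id"], "tissue": binding["tissue"], "state": state}
    )


def binding_group_tests(
    states: pd.DataFrame,
    expression: pd.DataFrame,
    min_group: int = MIN_GROUP,
) -> dict:
    """Welch tests of expression between binding-state gene groups.

    ``states``: (gene_id, tissue, state); ``expression``: genes x tissues
    log2(TPM+1).  Two families are computed and Storey-corrected
    separately: per-TF marginal tests (bound vs unbound observations) and
    pairwise tests between every pair of observed states that differ.
    Comparisons with a group below ``min_group`` observations are skipped
    and recorded.
    """
    obs = states.copy()
    obs["expr"] = [
        expression.at[g, t] if g in expression.index else np.nan
        for g, t in zip(obs["gene_id"], obs["tissue"])
    ]
    obs = obs.dropna(subset=["expr"])
    tfs = sorted({tf for s in obs["state"] for tf in s})
    marginal_rows, skipped = [], []
    for tf in tfs:
        mask = obs["state"].map(lambda s: tf in s)
        a = obs.loc[mask, "expr"].to_numpy()
        b = obs.loc[~mask, "expr"].to_numpy()
        if len(a) < min_group or len(b) < min_group:
            skipped.append(("marginal", tf))
            continue
        t, df, p = welch_t(a, b)
        marginal_rows.append((tf, len(a), len(b), t, p))
    marginal = pd.DataFrame(
        marginal_rows, columns=["tf", "n_bound", "n_unbound", "t", "p"]
    )
    if len(marginal):
        marginal["q"] = storey_qvalue(marginal["p"].to_numpy())
    else:
        marginal["q"] = []
    by_state = obs.groupby("state")["expr"].apply(np.asarray)
    state_list = sorted(by_state.index, key=lambda s: (len(s), sorted(s)))
    pair_rows = []
    for i, s1 in enumerate(state_list):
        for s2 in state_list[i + 1:]:
            a, b = by_state[s1], by_state[s2]
            if len(a) < min_group or len(b) < min_group:
                skipped.append(("pair", (s1, s2)))
                continue
            t, df, p = welch_t(a, b)
            pair_rows.append((s1, s2, len(a), len(b), t, p))
    pairs = pd.DataFrame(pair_rows, columns=["state_a", "state_b", "n_a", "n_b", "t", "p"])
    if len(pairs):
        pairs["q"] = storey_qvalue(pairs["p"].to_numpy())
    else:
        pairs["q"] = []
    return {"marginal": marginal, "pairs": pairs, "skipped": skipped}


def call_dtgs(
    states: pd.DataFrame,
    tests: dict,
    tissues: tuple[str, str] = ("liver", "muscle"),
    q_cut: float = DEFAULT_Q_CUT,
) -> pd.DataFrame:
    """DTG labels from binding states and the group-test results.

    Genes with identical states in both tissues are non_dtg regardless of
    tests.  Otherwise: significant state-pair test -> dtg (direct_test);
    else, if every TF in the symmetric state difference is individually
    significant -> dtg (combination_inference).
    """
    ta, tb = tissues
    piv = states.pivot(index="gene_id", columns="tissue", values="state")
    sig_pairs = set()
    pairs = tests.get("pairs", pd.DataFrame())
    if len(pairs):
        for _, row in pairs[pairs["q"] < q_cut].iterrows():
            sig_pairs.add(frozenset((row["state_a"], row["state_b"])))
    marginal = tests.get("marginal", pd.DataFrame())
    sig_tfs = set(marginal.loc[marginal["q"] < q_cut, "tf"]) if len(marginal) else set()
    rows = []
    for gid, row in piv.iterrows():
        sa, sb = row[ta], row[tb]
        if not isinstance(sa, frozenset) or not isinstance(sb, frozenset) or sa == sb:
            rows.append((gid, "non_dtg", "", set()))
            continue
        differing = sa ^ sb
        if frozenset((sa, sb)) in sig_pairs:
            rows.append((gid, "dtg", "direct_test", differing))
        elif differing and differing <= sig_tfs:
            rows.append((gid, "dtg", "combination_inference", differing))
        else:
            rows.append((gid, "non_dtg", "", differing))
    return pd.DataFrame(rows, columns=["gene_id", "label", "basis", "differing_tfs"])


def peak_class_overlap(
    class_members: set, peak_gene_set: set, universe: set, tail: str = "right"
) -> dict:
    """2x2 Fisher test of a gene class against a peak-derived gene set.

    ``tail="right"`` tests enrichment (e.g. hypomethylated genes in open
    chromatin), ``"left"`` depletion.  All three sets live in the same gene
    universe.
    """
    if not universe:
        raise ValueError("empty gene universe")
    uni = set(universe)
    A = set(class_members) & uni
    S = set(peak_gene_set) & uni
    a = len(A & S)
    b = len(A - S)
    c = len(S - A)
    d = len(uni - A - S)
    return {"table": [[a, b], [c, d]], "p": fisher_exact([[a, b], [c, d]], tail=tail)}


def consistent_peak_genes(
    gene_sets_per_file: list[set], min_files: int | None = None
) -> set:
    """Genes peaked consistently across replicate peak files of one mark.

    Default requires presence in every provided file.
    """
    if not gene_sets_per_file:
        return set()
    k = len(gene_sets_per_file) if min_files is None else min_files
    counts: dict = {}
    for s in gene_sets_per_file:
        for g in s:
            counts[g] = counts.get(g, 0) + 1
    return {g for g, c in counts.items() if c >= k}


def peak_gene_set(
    bed: pd.DataFrame, models: list[GeneModel], flank: int = DEFAULT_FLANK
) -> set:
    """Genes whose [TSS-flank, TSS+flank) window intersects any BED peak."""
    per_chrom = {}
    for chrom, sub in bed.groupby("chrom"):
        iv = sub.sort_values("start")[["start", "end"]].to_numpy()
        per_chrom[chrom] = (iv[:, 0], iv[:, 1])
    out = set()
    for m in models:
        se = per_chrom.get(m.chrom)
        if se is None:
            continue
        starts, ends = se
        lo, hi = m.tss - flank, m.tss + flank
        j = np.searchsorted(starts, hi)
        if np.any(ends[:j] > lo):
            out.add(m.transcript_id)
    return out
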