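"""Gene-level integration: composite classes, overlap statistics, CpG
density, and gene-set enrichment.

Transcript- and protein-level calls are collapsed to gene IDs; the
composite classes are direction-consistent intersections — DM-DEG (DMG and
DEG in the same tissue), DM-DEP (DM-DEG whose protein is a DEP in that
tissue), DR-DEP (DRP and DEP, same tissue) and DT-DEP (DTG and DEG and
DEP).  Overlap significance uses Fisher's exact test; cross-direction
overlaps are tested as depletion (left tail).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from tissuedom.annotation import GeneModel
from tissuedom.methylome import WINDOW_DOWNSTREAM, WINDOW_UPSTREAM, MethylomeData, site_offsets
from tissuedom.stats_core import bh_adjust, fisher_exact, ward_cluster, welch_t

DENSITY_BIN_BP = 40

_DIRECTIONAL = {
    "dmg": ("{t}_dmg", "non_dmg"),
    "deg": ("{t}_deg", "non_deg"),
    "drp": ("{t}_drp", "none"),
}


def collapse_to_gene(
    calls: dict[str, pd.Series], id_map: pd.Series, tissues=("liver", "muscle")
) -> pd.DataFrame:
    """Collapse per-transcript/per-protein label series to gene level.

    ``calls`` maps a layer name (dmg, deg, dep, drp, dtg) to a label
    Series indexed by transcript or protein ID; ``id_map`` maps those IDs
    to gene IDs.  Within one gene, agreeing labels collapse to one;
    contradictory directional labels are flagged ``conflict`` (excluded
    from directional overlaps); unmapped IDs are dropped with a warning.
    """
    gene_ids = sorted(set(id_map.dropna()))
    out = pd.DataFrame(index=pd.Index(gene_ids, name="gene_id"))
    for layer, series in calls.items():
        unmapped = series.index.difference(id_map.index)
        if len(unmapped):
            warnings.warn(f"{layer}: {len(unmapped)} unmapped IDs excluded: "
                          f"{list(unmapped[:5])}")
        mapped = series.loc[series.index.intersection(id_map.index)]
        genes = id_map.loc[mapped.index]
        collapsed = {}
        for gid, labels in mapped.groupby(genes.to_numpy()):
            informative = {l for l in labels if l not in ("non_dmg", "non_deg", "non_dep", "none", "non_dtg", "")}
            if not informative:
                collapsed[gid] = sorted(set(labels))[0]
            elif len(informative) == 1:
                collapsed[gid] = informative.pop()
            else:
                collapsed[gid] = "conflict"
        out[layer] = pd.Series(collapsed).reindex(out.index)
    return out


def derive_composites(table: pd.DataFrame, tissues=("liver", "muscle")) -> pd.DataFrame:
    """Direction-consistent composite flags and their non-X counterparts.

    Adds per-tissue boolean columns dm_deg_<t>, dm_dep_<t>, dr_dep_<t>,
    dt_dep_<t>, plus non_dm_non_deg and non_composite flags used by the
    depletion tests.
    """
    out = table.copy()
    for t in tissues:
        dmg = out.get("dmg", pd.Series(index=out.index, dtype=object)).eq(f"{t}_dmg")
        deg = out.get("deg", pd.Series(index=out.index, dtype=object)).eq(f"{t}_deg")
        dep = out.get("dep", pd.Series(index=out.index, dtype=object)).isin(
            [f"{t}_dominant", f"{t}_only"]
        )
        drp = out.get("drp", pd.Series(index=out.index, dtype=object)).eq(f"{t}_drp")
        dtg = out.get("dtg", pd.Series(index=out.index, dtype=object)).eq("dtg")
        out[f"dm_deg_{t}"] = dmg & deg
        out[f"dm_dep_{t}"] = out[f"dm_deg_{t}"] & dep
        out[f"dr_dep_{t}"] = drp & dep
        out[f"dt_dep_{t}"] = dtg & deg & dep
    if "dmg" in out and "deg" in out:
        out["non_dm_non_deg"] = out["dmg"].eq("non_dmg") & out["deg"].eq("non_deg")
    return out


def venn_counts(table: pd.DataFrame, tissues=("liver", "muscle")) -> dict:
    """Pairwise overlap counts among the class columns, per tissue."""
    counts: dict = {}
    for t in tissues:
        sets = {}
        if "dmg" in table:
            sets["dmg"] = set(table.index[table["dmg"] == f"{t}_dmg"])
        if "deg" in table:
            sets["deg"] = set(table.index[table["deg"] == f"{t}_deg"])
        if "dep" in table:
            sets["dep"] = set(
                table.index[table["dep"].isin([f"{t}_dominant", f"{t}_only"])]
            )
        if "drp" in table:
            sets["drp"] = set(table.index[table["drp"] == f"{t}_drp"])
        names = sorted(sets)
        block = {n: len(sets[n]) for n in names}
        for i, n1 in enumerate(names):
            for n2 in names[i + 1:]:
                block[f"{n1}&{n2}"] = len(sets[n1] & sets[n2])
        counts[t] = block
    return counts


def overlap_significance(
    table: pd.DataFrame, class_a: pd.Series, class_b: pd.Series, tail: str = "right"
) -> dict:
    """Fisher test of association between two boolean gene classes over the
    genes where both are defined."""
    joint = pd.concat({"a": class_a, "b": class_b}, axis=1).dropna()
    if len(joint) == 0:
        raise ValueError("empty universe for overlap test")
    a = int((joint["a"] & joint["b"]).sum())
    b = int((joint["a"] & ~joint["b"]).sum())
    c = int((~joint["a"] & joint["b"]).sum())
    d = int((~joint["a"] & ~joint["b"]).sum())
    return {"table": [[a, b], [c, d]], "p": fisher_exact([[a, b], [c, d]], tail=tail)}


def cpg_density_analysis(
    models: list[GeneModel],
    data: MethylomeData,
    dmg_labels: pd.Series | None = None,
    upstream: int = WINDOW_UPSTREAM,
    downstream: int = WINDOW_DOWNSTREAM,
    bin_bp: int = DENSITY_BIN_BP,
) -> dict:
    """Per-gene CpG-density vectors, 2-cluster Ward labels, and the
    DMG-vs-non-DMG CpG-count comparison.

    The TSS window is cut into ``(upstream+downstream)/bin_bp`` strand-aware
    40-bp bins; the vector holds the CpG count per bin.  Ward clustering
    (k=2) splits genes into low/high density classes named by mean total
    count.
    """
    n_bins = (upstream + downstream) // bin_bp
    offs = site_offsets(data, models, -upstream, downstream)
    vectors = pd.DataFrame(
        0, index=pd.Index([m.transcript_id for m in models], name="gene_id"),
        columns=range(n_bins),
    )
    if len(offs):
        offs["bin"] = (offs["offset"] + upstream) // bin_bp
        binned = offs.groupby(["gene_id", "bin"]).size()
        for (gid, b), cnt in binned.items():
            vectors.at[gid, b] = cnt
    totals = vectors.sum(axis=1)
    labels = ward_cluster(vectors.to_numpy(), k=2)
    mean0 = totals[labels == 0].mean() if (labels == 0).any() else 0.0
    mean1 = totals[labels == 1].mean() if (labels == 1).any() else 0.0
    low_label = 0 if mean0 <= mean1 else 1
    density_class = pd.Series(
        np.where(labels == low_label, "low", "high"), index=vectors.index
    )
    result = {
        "vectors": vectors,
        "total_cpg": totals,
        "density_class": density_class,
    }
    if dmg_labels is not None:
        dmg_mask = dmg_labels.reindex(vectors.index).fillna("non_dmg") != "non_dmg"
        if dmg_mask.sum() >= 2 and (~dmg_mask).sum() >= 2:
            t, df, p = welch_t(totals[dmg_mask], totals[~dmg_mask])
            result["dmg_count_test"] = {
                "median_dmg": float(totals[dmg_mask].median()),
                "median_non_dmg": float(totals[~dmg_mask].median()),
                "t": t,
                "p": p,
            }
    return result


def read_gmt(path: str) -> dict[str, set]:
    """Read gene sets from a GMT file (set name, description, members)."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) >= 3:
                sets[f[0]] = set(g for g in f[2:] if g)
    return sets


def enrichment(
    gene_list,
    gene_sets: dict[str, set],
    universe,
    class_map: dict[str, str] | None = None,
    q_cut: float = 0.01,
) -> pd.DataFrame:
    """Right-tailed Fisher enrichment of ``gene_list`` in each gene set.

    The universe is the measured background; the list must be contained in
    it.  q is Benjamini-Hochberg across sets; ``class_map`` (set ->
    category, e.g. KEGG classes) adds a grouping column.
    """
    uni = set(universe)
    lst = set(gene_list)
    stray = lst - uni
    if stray:
        raise ValueError(f"gene list not contained in universe: {sorted(stray)[:5]}")
    empties = [n for n, s in gene_sets.items() if not s]
    if empties:
        raise ValueError(f"empty gene sets: {empties[:5]}")
    rows = []
    for name, members in gene_sets.items():
        S = members & uni
        a = len(lst & S)
        b = len(lst - S)
        c = len(S - lst)
        d = len(uni - S - lst)
        p = fisher_exact([[a, b], [c, d]], tail="right")
        rows.append((name, a, len(S), p))
    out = pd.DataFrame(rows, columns=["set", "overlap", "set_size", "p"]).set_index("set")
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["q"] < q_cut
    if class_map:
        out["category"] = [class_map.get(s, "Unclassified") for s in out.index]
    return out.sort_values("p")
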