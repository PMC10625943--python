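"""End-to-end orchestration: configuration, stage sequencing, reporting.

The pipeline reads the study inputs from plain-text files (GTF, methylation
count TSVs, count/TPM/intensity matrices, BED peak files, GMT gene sets),
executes annotation -> methylome -> differential methylation ->
differential expression -> proteome -> regulatory overlap -> integration,
and writes a master per-gene classification table, per-stage TSVs and a
JSON summary.  All default parameters are the study defaults: TSS window
-200..+400 bp, scan -1500..+2000 bp in 100-bp bins, q cuts 0.01, Fisher cut
0.001, expression filter 6 of 11 replicates, protein detection 3 of 5,
TF/histone flank 1000 bp, minimum CpG coverage 5.

Missing input groups are skipped with an explicit notice (e.g. a run
without proteome files still produces methylation and expression calls).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from tissuedom import (
    annotation as ann_mod,
    diff_expression as de_mod,
    diff_methylation as dm_mod,
    integration as int_mod,
    methylome as me_mod,
    proteome as pr_mod,
    regulatory as reg_mod,
)

TISSUES = ("liver", "muscle")


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration (CLI exit code 2)."""


class DataError(ValueError):
    """Unreadable or inconsistent input data (CLI exit code 3)."""


@dataclass
class RunConfig:
    """Input paths and analysis parameters for one pipeline run."""

    gtf: str
    methylome: dict[str, list[str]]  # tissue -> replicate TSV paths
    rna_counts: dict[str, str] | None = None
    rna_tpm: dict[str, str] | None = None
    protein: dict[str, str] | None = None
    protein_gene_map: str | None = None
    tf_peaks: dict[str, dict[str, str]] | None = None  # tf -> tissue -> BED
    atac: dict[str, str] | None = None
    histone: dict[str, dict[str, list[str]]] | None = None
    cpg_islands: str | None = None
    gene_sets: str | None = None
    gene_set_classes: str | None = None
    outdir: str = "tissuedom_out"
    # parameters (defaults are the study defaults)
    window_upstream: int = 200
    window_downstream: int = 400
    scan_lo: int = -1500
    scan_hi: int = 2000
    scan_win: int = 100
    q_cut: float = 0.01
    fisher_cut: float = 1e-3
    min_reps_rna: int = 6
    min_reps_protein: int = 3
    tf_flank: int = 1000
    min_coverage: int = 5
    merge_tss: bool = True
    seed: int = 0
    silverman_B: int = 200
    run_scan: bool = True

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        stray = set(raw) - known
        if stray:
            raise ConfigError(f"unknown config keys: {sorted(stray)}")
        try:
            return cls(**raw)
        except TypeError as err:
            raise ConfigError(str(err)) from err

    def validate(self) -> None:
        missing = [p for p in self._all_paths() if not os.path.exists(p)]
        if missing:
            raise ConfigError(f"missing input files: {missing[:5]}")

    def _all_paths(self):
        paths = [self.gtf]
        for reps in self.methylome.values():
            paths.extend(reps)
        for group in (self.rna_counts, self.rna_tpm, self.protein):
            if group:
                paths.extend(group.values())
        if self.protein_gene_map:
            paths.append(self.protein_gene_map)
        if self.tf_peaks:
            for per in self.tf_peaks.values():
                paths.extend(per.values())
        if self.atac:
            paths.extend(self.atac.values())
        if self.histone:
            for per in self.histone.values():
                for lst in per.values():
                    paths.extend(lst)
        for p in (self.cpg_islands, self.gene_sets, self.gene_set_classes):
            if p:
                paths.append(p)
        return paths

    def hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("outdir", None)  # output location does not affect results
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def config_from_bundle_paths(paths: dict, outdir: str, **overrides) -> RunConfig:
    """RunConfig pointing at the file manifest written by
    :func:`tissuedom.simulate.write_bundle`."""
    return RunConfig(
        gtf=paths["gtf"],
        methylome=paths["methylome"],
        rna_counts={t: paths[f"rna_counts_{t}"] for t in TISSUES},
        rna_tpm={t: paths[f"rna_tpm_{t}"] for t in TISSUES},
        protein={t: paths[f"protein_{t}"] for t in TISSUES},
        protein_gene_map=paths["protein_gene_map"],
        tf_peaks=paths["tf_peaks"],
        atac=paths["atac"],
        histone=paths["histone"],
        cpg_islands=paths["cpg_islands"],
        gene_sets=paths["gene_sets"],
        gene_set_classes=paths["gene_set_classes"],
        outdir=outdir,
        **overrides,
    )


def _read_matrix(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise DataError(f"{path}: no replicate columns")
    return df


def run_pipeline(config: RunConfig, log=print) -> dict:
    """Execute the full analysis; returns a results dict and writes the
    master table, per-stage TSVs and a JSON summary into ``config.outdir``."""
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    results: dict = {"config_hash": config.hash(), "notices": []}

    def notice(msg: str):
        results["notices"].append(msg)
        log(f"[tissuedom] {msg}")

    # --- annotation -----------------------------------------------------
    models = ann_mod.read_gene_models(config.gtf)
    if config.merge_tss:
        models = ann_mod.merge_same_tss(models)
    results["n_genes"] = len(models)
    notice(f"annotation: {len(models)} transcript units")

    # --- methylome ------------------------------------------------------
    tables = {
        t: [pd.read_csv(p, sep="\t") for p in reps]
        for t, reps in config.methylome.items()
    }
    data = me_mod.MethylomeData.from_tables(tables)
    tissues = tuple(data.tissues)
    if len(tissues) != 2:
        raise DataError(f"need exactly 2 tissues, got {tissues}")
    wm = me_mod.window_methylation(
        data, models, config.window_upstream, config.window_downstream, config.min_coverage
    )
    pooled = wm["mean_ratio"].dropna().to_numpy()
    threshold = me_mod.otsu_threshold(pooled)
    results["otsu_threshold"] = threshold
    sil_n = min(len(pooled), 5000)
    sil_sample = pooled if len(pooled) <= sil_n else np.sort(pooled)[
        np.linspace(0, len(pooled) - 1, sil_n).astype(int)
    ]
    results["silverman_p_unimodal"] = me_mod.silverman_test(
        sil_sample, k_modes=1, B=config.silverman_B, seed=config.seed
    )
    results["silverman_p_bimodal"] = me_mod.silverman_test(
        sil_sample, k_modes=2, B=config.silverman_B, seed=config.seed
    )
    states = me_mod.classify_hypo_hyper(wm, threshold)
    results["window_methylation"] = states

    # --- differential methylation --------------------------------------
    dm_res = dm_mod.dmcpg_test_all(data, tissues, config.min_coverage)
    dmcpgs = dm_mod.call_dmcpgs(dm_res, config.q_cut, tissues)
    dmgs = dm_mod.call_dmgs(
        models, dmcpgs, states, tissues, config.window_upstream, config.window_downstream
    ).set_index("gene_id")
    results["dmcpgs"] = dmcpgs
    results["dmgs"] = dmgs
    notice(f"dmg: {int((dmgs['label'] != 'non_dmg').sum())} DMGs")

    # --- expression -----------------------------------------------------
    degs = None
    tpm_mean = None
    if config.rna_counts:
        counts = {t: _read_matrix(p) for t, p in config.rna_counts.items()}
        expressed = de_mod.filter_expressed(
            counts[tissues[0]], counts[tissues[1]], config.min_reps_rna
        )
        exp_idx = expressed[expressed].index
        degs = de_mod.deg_test(
            counts[tissues[0]].loc[exp_idx], counts[tissues[1]].loc[exp_idx], tissues, config.q_cut
        )
        degs = degs.reindex(counts[tissues[0]].index)
        degs["label"] = degs["label"].fillna("non_deg")
        degs["expressed"] = degs["expressed"].fillna(False)
        results["degs"] = degs
        notice(f"deg: {int((degs['label'] != 'non_deg').sum())} DEGs "
               f"of {int(expressed.sum())} expressed")
        if config.rna_tpm:
            tpm = {t: _read_matrix(p) for t, p in config.rna_tpm.items()}
            tpm_mean = pd.DataFrame({t: m.mean(axis=1) for t, m in tpm.items()})
            with np.errstate(divide="ignore", invalid="ignore"):
                tpm_fc = np.log2(tpm_mean[tissues[0]] / tpm_mean[tissues[1]])
            try:
                results["fc_correlation"] = de_mod.fc_methylation_correlation(
                    degs[degs["expressed"]], states, tpm_fc.replace([np.inf, -np.inf], np.nan), tissues
                )
            except ValueError as err:
                notice(f"fc correlation skipped: {err}")
            # expression-decile and sliding-window correlations per tissue
            results["decile"] = {}
            results["scan"] = {}
            wr = states.pivot(index="gene_id", columns="tissue", values="mean_ratio")
            for t in tissues:
                expr = np.log2(tpm_mean[t] + 1)
                try:
                    results["decile"][t] = me_mod.region_decile_correlation(
                        expr, wr[t], region_name="tss_window"
                    )
                except ValueError as err:
                    notice(f"decile correlation skipped for {t}: {err}")
                if config.run_scan:
                    results["scan"][t] = me_mod.sliding_window_scan(
                        expr, data, models, t,
                        win=config.scan_win, lo=config.scan_lo, hi=config.scan_hi,
                        min_coverage=config.min_coverage,
                    )
    else:
        notice("expression stage skipped: no RNA counts provided")

    # --- proteome -------------------------------------------------------
    deps = drps = None
    id_map = None
    if config.protein and config.protein_gene_map:
        intens = {t: _read_matrix(p) for t, p in config.protein.items()}
        id_map = pd.read_csv(config.protein_gene_map, sep="\t", index_col=0).iloc[:, 0]
        det = {
            t: pr_mod.detect_proteins(intens[t], config.min_reps_protein) for t in tissues
        }
        both = det[tissues[0]] & det[tissues[1]]
        test = None
        if both.sum() >= 20:
            joined = pd.concat(
                [intens[tissues[0]].loc[both], intens[tissues[1]].loc[both]], axis=1
            )
            vsn_params, transformed = pr_mod.vsn_fit(joined)
            results["vsn_params"] = vsn_params
            h_a = transformed.iloc[:, : intens[tissues[0]].shape[1]]
            h_b = transformed.iloc[:, intens[tissues[0]].shape[1]:]
            test = pr_mod.moderated_test(h_a, h_b, tissues)
        else:
            notice("vsn/moderated test skipped: fewer than 20 both-tissue proteins")
        deps = pr_mod.call_deps(det[tissues[0]], det[tissues[1]], test, tissues, config.q_cut)
        results["deps"] = deps
        notice(f"dep: {int((~deps['label'].isin(['non_dep'])).sum())} DEPs "
               f"of {len(deps)} detected proteins")
        if tpm_mean is not None:
            tpm_by_protein = {
                t: tpm_mean[t].reindex(id_map.to_numpy()).set_axis(id_map.index)
                for t in tissues
            }
            ratios = {
                t: pr_mod.protein_mrna_ratio(intens[t], tpm_by_protein[t], det[t])
                for t in tissues
            }
            try:
                drps = pr_mod.call_drps(ratios[tissues[0]], ratios[tissues[1]], tissues)
                results["drps"] = drps
                notice(f"drp: {int((drps['label'] != 'none').sum())} DRPs")
            except ValueError as err:
                notice(f"drp stage skipped: {err}")
    else:
        notice("proteome stage skipped: no protein inputs provided")

    # --- regulatory overlap ---------------------------------------------
    dtgs = None
    if config.tf_peaks and tpm_mean is not None:
        peaks = {
            tf: {t: reg_mod.read_bed(p) for t, p in per.items()}
            for tf, per in config.tf_peaks.items()
        }
        binding = reg_mod.assign_binding(peaks, models, config.tf_flank)
        st = reg_mod.binding_states(binding)
        expr_mat = np.log2(tpm_mean + 1)
        bt = reg_mod.binding_group_tests(st, expr_mat)
        dtgs = reg_mod.call_dtgs(st, bt, tissues, config.q_cut).set_index("gene_id")
        results["binding_tests"] = bt
        results["dtgs"] = dtgs
        notice(f"dtg: {int((dtgs['label'] == 'dtg').sum())} DTGs")
    elif config.tf_peaks:
        notice("dtg stage skipped: requires TPM matrices")

    # peak-class overlaps (ATAC / histone marks / CpG islands)
    overlap_reports = {}
    hypo_sets = {
        t: set(states[(states["tissue"] == t) & (states["state"] == "hypo")]["gene_id"])
        for t in tissues
    }
    hyper_sets = {
        t: set(states[(states["tissue"] == t) & (states["state"] == "hyper")]["gene_id"])
        for t in tissues
    }
    universe = {m.transcript_id for m in models}
    if config.atac:
        for t, p in config.atac.items():
            open_genes = reg_mod.peak_gene_set(reg_mod.read_bed(p), models, config.tf_flank)
            overlap_reports[f"atac_hypo_{t}"] = reg_mod.peak_class_overlap(
                hypo_sets[t], open_genes, universe, tail="right"
            )
            overlap_reports[f"atac_hyper_{t}"] = reg_mod.peak_class_overlap(
                hyper_sets[t], open_genes, universe, tail="left"
            )
    if config.histone:
        for mark, per in config.histone.items():
            for t, files in per.items():
                sets_per_file = [
                    reg_mod.peak_gene_set(reg_mod.read_bed(p), models, config.tf_flank)
                    for p in files
                ]
                consistent = reg_mod.consistent_peak_genes(sets_per_file)
                overlap_reports[f"{mark}_hypo_{t}"] = reg_mod.peak_class_overlap(
                    hypo_sets[t], consistent, universe, tail="right"
                )
    results["peak_overlaps"] = overlap_reports

    # --- integration -----------------------------------------------------
    calls = {"dmg": dmgs["label"]}
    gene_map = pd.Series({m.transcript_id: m.gene_id for m in models})
    if degs is not None:
        calls["deg"] = degs["label"]
    if deps is not None and id_map is not None:
        calls["dep"] = deps["label"]
    if drps is not None and id_map is not None:
        calls["drp"] = drps["label"]
    if dtgs is not None:
        calls["dtg"] = dtgs["label"]
    full_map = pd.concat([gene_map, id_map]) if id_map is not None else gene_map
    master = int_mod.collapse_to_gene(calls, full_map, tissues)
    master = int_mod.derive_composites(master, tissues)
    # annotate window ratios and density
    wr = states.pivot(index="gene_id", columns="tissue", values="mean_ratio")
    for t in tissues:
        master[f"ratio_{t}"] = wr[t].reindex(master.index)
    if degs is not None:
        master["log2fc"] = degs["log2fc"].reindex(master.index)
    density = int_mod.cpg_density_analysis(
        models, data, dmgs["label"], config.window_upstream, config.window_downstream
    )
    master["cpg_count"] = density["total_cpg"].reindex(master.index)
    master["density_class"] = density["density_class"].reindex(master.index)
    results["density"] = density
    results["venn"] = int_mod.venn_counts(master, tissues)
    overlap_sig = {}
    for t in tissues:
        if "deg" in master:
            overlap_sig[f"dmg_deg_{t}"] = int_mod.overlap_significance(
                master, master["dmg"].eq(f"{t}_dmg"), master["deg"].eq(f"{t}_deg"), tail="right"
            )
    results["overlap_significance"] = overlap_sig
    if config.cpg_islands:
        island_genes = reg_mod.peak_gene_set(
            reg_mod.read_bed(config.cpg_islands), models, config.tf_flank
        )
        results["cpg_island_overlap"] = reg_mod.peak_class_overlap(
            {g for g in master.index[master["dmg"] != "non_dmg"]},
            island_genes,
            universe,
            tail="left",
        )
    if config.gene_sets and degs is not None:
        sets = int_mod.read_gmt(config.gene_sets)
        class_map = None
        if config.gene_set_classes:
            class_map = (
                pd.read_csv(config.gene_set_classes, sep="\t", index_col=0).iloc[:, 0].to_dict()
            )
        enr = {}
        uni = set(master.index)
        for t in tissues:
            lst = set(master.index[master[f"dm_deg_{t}"]])
            if lst:
                enr[f"dm_deg_{t}"] = int_mod.enrichment(lst, sets, uni, class_map, config.q_cut)
            if drps is not None:
                lst = set(master.index[master[f"dr_dep_{t}"]])
                if lst:
                    enr[f"dr_dep_{t}"] = int_mod.enrichment(lst, sets, uni, class_map, config.q_cut)
        results["enrichment"] = enr
    results["master"] = master

    _write_outputs(config, results, master)
    return results


def _write_outputs(config: RunConfig, results: dict, master: pd.DataFrame) -> None:
    head = f"# tissuedom master table; config_hash={results['config_hash']}\n"
    mpath = os.path.join(config.outdir, "master_table.tsv")
    with open(mpath, "w") as fh:
        fh.write(head)
        master.to_csv(fh, sep="\t", float_format="%.6g")
    for name in ("dmcpgs", "dmgs", "degs", "deps", "drps", "dtgs"):
        if name in results and results[name] is not None:
            p = os.path.join(config.outdir, f"{name}.tsv")
            with open(p, "w") as fh:
                fh.write(f"# tissuedom {name}; config_hash={results['config_hash']}\n")
                results[name].to_csv(fh, sep="\t", float_format="%.6g")
    summary = summarize(results)
    with open(os.path.join(config.outdir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)


def summarize(results: dict) -> dict:
    """Counts and percentages analogous to the classification pies."""
    s: dict = {"config_hash": results["config_hash"], "n_genes": results["n_genes"]}
    s["otsu_threshold"] = results.get("otsu_threshold")
    s["silverman_p_unimodal"] = results.get("silverman_p_unimodal")
    s["silverman_p_bimodal"] = results.get("silverman_p_bimodal")
    if "dmgs" in results:
        s["dmg_counts"] = results["dmgs"]["label"].value_counts().to_dict()
    if "degs" in results:
        s["deg_counts"] = results["degs"]["label"].value_counts().to_dict()
    if "deps" in results:
        s["dep_counts"] = results["deps"]["label"].value_counts().to_dict()
    if "drps" in results:
        s["drp_counts"] = results["drps"]["label"].value_counts().to_dict()
    if "dtgs" in results:
        s["dtg_counts"] = results["dtgs"]["label"].value_counts().to_dict()
    if "fc_correlation" in results:
        s["fc_correlation_r"] = results["fc_correlation"]["r"]
    if "decile" in results:
        s["decile_rho"] = {t: d["rho"] for t, d in results["decile"].items()}
    if "scan" in results:
        s["scan_argmin_bin"] = {t: d["argmin_bin"] for t, d in results["scan"].items()}
        s["scan_significant_range"] = {
            t: d["significant_range"] for t, d in results["scan"].items()
        }
    master = results.get("master")
    if master is not None:
        for col in master.columns:
            if col.startswith(("dm_deg_", "dm_dep_", "dr_dep_", "dt_dep_")):
                s[f"n_{col}"] = int(master[col].sum())
    return s


def make_fixtures(size: str = "tiny", outdir: str | None = None, seed: int = 0):
    """Bundled synthetic dataset: ``tiny`` (~200 genes, unit tests) or
    ``default`` (~2,000 genes, full-scale runs).  Returns (SimConfig,
    Bundle, paths-or-None)."""
    from tissuedom import simulate

    if size == "tiny":
        cfg = simulate.SimConfig(n_genes=200, n_chromosomes=2, seed=seed)
    elif size == "default":
        cfg = simulate.SimConfig(seed=seed)
    else:
        raise ConfigError("size must be 'tiny' or 'default'")
    bundle = simulate.simulate_study(cfg)
    paths = simulate.write_bundle(bundle, outdir) if outdir else None
    return cfg, bundle, paths
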