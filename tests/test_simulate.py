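"""Synthetic-study generator: determinism, planted structure, round-trips."""

import filecmp
import os

import numpy as np
import pandas as pd
import pytest

from tissuedom import simulate as sim
from tissuedom.methylome import MethylomeData, pooled_ratio, silverman_test, window_methylation
from tissuedom.stats_core import spearman_rho


def small_cfg(**kw):
    base = dict(n_genes=120, n_chromosomes=2, seed=1)
    base.update(kw)
    return sim.SimConfig(**base)


class TestConfigValidation:
    def test_bad_proportions_rejected(self):
        with pytest.raises(ValueError):
            small_cfg(frac_liver_dmg=0.7, frac_muscle_dmg=0.7)

    def test_means_ordering_enforced(self):
        with pytest.raises(ValueError):
            small_cfg(hypo_mean=0.8, hyper_mean=0.2)

    def test_nonpositive_coverage_rejected(self):
        with pytest.raises(ValueError):
            small_cfg(coverage_mean=0.0)

    def test_chromosome_sizing_error(self):
        with pytest.raises(ValueError, match="fit"):
            sim.generate_annotation(small_cfg(chrom_length=10_000))


def test_identical_config_gives_byte_identical_files(tmp_path):
    d1, d2 = tmp_path / "a", tmp_path / "b"
    for d in (d1, d2):
        sim.write_bundle(sim.simulate_study(small_cfg()), str(d))
    for root, _, files in os.walk(d1):
        rel = os.path.relpath(root, d1)
        for f in files:
            p1 = os.path.join(root, f)
            p2 = os.path.join(d2, rel, f)
            assert filecmp.cmp(p1, p2, shallow=False), f"{rel}/{f} differs"


def test_truth_labels_consistent_with_planted_parameters(tiny_bundle):
    sim.validate_truth(tiny_bundle["bundle"].truth)


def test_annotation_geometry_and_density(tiny_bundle):
    bundle = tiny_bundle["bundle"]
    truth = bundle.truth
    models = {m.transcript_id: m for m in bundle.models}
    # both strands represented, genes non-overlapping per chromosome
    assert {m.strand for m in bundle.models} == {"+", "-"}
    by_chrom = {}
    for m in bundle.models:
        by_chrom.setdefault(m.chrom, []).append((m.start, m.end))
    for spans in by_chrom.values():
        spans.sort()
        assert all(a_end <= b_start for (_, a_end), (b_start, _) in zip(spans, spans[1:]))
    # window CpG counts track the density classes
    sites = bundle.annotation.cpg_sites
    win = sites[(sites["context"] == "CpG") & (sites["offset"] >= -200) & (sites["offset"] < 400)]
    counts = win.groupby("gene_idx").size()
    counts.index = truth.index[counts.index]
    low = counts.reindex(truth.index[truth["density_class"] == "low"]).dropna()
    high = counts.reindex(truth.index[truth["density_class"] == "high"]).dropna()
    assert abs(low.median() - 10) <= 2
    assert abs(high.median() - 47) <= 4


def test_methylome_planted_ratios_and_noncpg(tiny_bundle):
    bundle = tiny_bundle["bundle"]
    truth = bundle.truth
    liver_dmg = truth[truth["dmg_label"] == "liver"]
    assert np.allclose(liver_dmg["ratio_liver"], 0.1, atol=0.15)
    assert np.allclose(liver_dmg["ratio_muscle"], 0.8, atol=0.15)
    # non-CpG cytosines hypomethylated everywhere
    data = MethylomeData.from_tables(
        {t: reps for t, reps in bundle.methylome.items()}
    )
    noncpg = data.sites["context"].isin(["CHG", "CHH"]).to_numpy()
    for t in data.tissues:
        r = pooled_ratio(data.meth[t][noncpg], data.total[t][noncpg], 1)
        assert np.nanmean(r) < 0.1


def test_pooled_window_ratios_bimodal(tiny_bundle):
    bundle = tiny_bundle["bundle"]
    data = MethylomeData.from_tables(bundle.methylome)
    wm = window_methylation(data, bundle.models)
    pooled = wm["mean_ratio"].dropna().to_numpy()
    assert silverman_test(pooled, k_modes=1, B=200, seed=1) < 0.01


def test_expression_structure(tiny_bundle):
    bundle = tiny_bundle["bundle"]
    truth = bundle.truth
    for t in ("liver", "muscle"):
        assert bundle.rna[t]["counts"].shape[1] == 11
        assert bundle.rna[t]["tpm"].shape[1] == 11
        log_tpm = np.log2(bundle.rna[t]["tpm"].mean(axis=1) + 1)
        rho, _ = spearman_rho(truth[f"ratio_{t}"], log_tpm.reindex(truth.index))
        assert rho < -0.2  # methylation anticorrelates with expression


def test_null_effect_configs_plant_nothing():
    cfg = small_cfg(deg_log2fc=0.0, tf_effect_log2=0.0, drp_shift=0.0,
                    frac_drp=0.0, dropout_rate=0.0, frac_only=0.0)
    bundle = sim.simulate_study(cfg)
    truth = bundle.truth
    assert (truth["deg_label"] == "none").all()
    assert (truth["drp_label"] == "none").all()
    assert (truth["dep_label"] == "none").all()
    for t in ("liver", "muscle"):
        assert not bundle.proteome["intensities"][t].isna().any().any()


def test_proteome_structure(tiny_bundle):
    bundle = tiny_bundle["bundle"]
    truth = bundle.truth
    for t in ("liver", "muscle"):
        assert bundle.proteome["intensities"][t].shape[1] == 5
    # planted liver DRP: liver protein/mRNA log-ratio exceeds muscle's by ~ drp_shift
    intens = bundle.proteome["intensities"]
    tpm = {t: bundle.rna[t]["tpm"].mean(axis=1) for t in ("liver", "muscle")}
    drp = truth[truth["drp_label"] == "liver"].index
    prot_ids = ["P" + g[1:] for g in drp]
    gap = []
    for g, p in zip(drp, prot_ids):
        rl = np.log(intens["liver"].loc[p].mean() / tpm["liver"][g])
        rm = np.log(intens["muscle"].loc[p].mean() / tpm["muscle"][g])
        gap.append(rl - rm)
    assert np.mean(gap) == pytest.approx(np.log(3), abs=0.15)


def test_peaks_structure(tiny_bundle):
    bundle = tiny_bundle["bundle"]
    truth = bundle.truth
    models = {m.transcript_id: m for m in bundle.models}
    tf_names = sorted(bundle.peaks["tf"])
    for gid, row in truth[truth["dtg_label"] != "none"].iterrows():
        m = models[gid]
        tf = tf_names[int(row["tf_index"])] if f"TF{int(row['tf_index'])+1}" not in tf_names else f"TF{int(row['tf_index'])+1}"
        hits = {}
        for tissue in ("liver", "muscle"):
            bed = bundle.peaks["tf"][tf][tissue]
            hits[tissue] = bool(
                ((bed["chrom"] == m.chrom) & (bed["start"] < m.tss + 1000) & (bed["end"] > m.tss - 1000)).any()
            )
        assert hits[row["dtg_label"]] and not hits["muscle" if row["dtg_label"] == "liver" else "liver"]
    # ATAC coverage enriched on hypomethylated genes
    for tissue in ("liver", "muscle"):
        bed = bundle.peaks["atac"][tissue]
        covered = set()
        for gid, m in models.items():
            if ((bed["chrom"] == m.chrom) & (bed["start"] < m.tss + 1000) & (bed["end"] > m.tss - 1000)).any():
                covered.add(gid)
        hypo = set(truth.index[truth[f"ratio_{tissue}"] < 0.5])
        hyper = set(truth.index) - hypo
        frac_hypo = len(covered & hypo) / len(hypo)
        frac_hyper = len(covered & hyper) / len(hyper)
        assert frac_hypo > frac_hyper


def test_written_files_round_trip_losslessly(tiny_bundle, tmp_path):
    bundle = tiny_bundle["bundle"]
    paths = tiny_bundle["paths"]
    # methylation counts round-trip exactly
    reread = MethylomeData.from_tables(
        {t: [pd.read_csv(p, sep="\t") for p in reps] for t, reps in paths["methylome"].items()}
    )
    direct = MethylomeData.from_tables(bundle.methylome)
    for t in direct.tissues:
        assert np.array_equal(reread.meth[t], direct.meth[t])
        assert np.array_equal(reread.total[t], direct.total[t])
    # counts round-trip exactly; intensity matrices to written precision
    counts = pd.read_csv(paths["rna_counts_liver"], sep="\t", index_col=0)
    assert counts.equals(bundle.rna["liver"]["counts"])
    prot = pd.read_csv(paths["protein_liver"], sep="\t", index_col=0)
    ref = bundle.proteome["intensities"]["liver"]
    assert np.allclose(prot.fillna(-1), ref.fillna(-1), rtol=1e-7)
    # gene models reread from GTF keep TSS and strand
    from tissuedom.annotation import read_gene_models

    models = {m.transcript_id: m for m in read_gene_models(paths["gtf"])}
    for m in bundle.models:
        assert models[m.transcript_id].tss == m.tss
        assert models[m.transcript_id].strand == m.strand
        assert models[m.transcript_id].exons == m.exons
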