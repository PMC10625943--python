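"""Synthetic two-tissue multi-omics study with planted ground truth.

Generates a miniature liver/muscle-style experiment that mirrors the
statistical structure the pipeline assumes: bimodal per-gene TSS-window
methylation with beta-binomial replicate counts, tissue-specific
hypomethylation probabilistically coupled to elevated expression,
negative-binomial RNA counts (11 replicates/tissue), log-normal protein
intensities coupled to mRNA with a planted post-transcriptionally shifted
subset and detection dropout (5 replicates/tissue), and TF peaks whose
presence/absence shifts expression.  Ground truth (TruthTable) records all
planted labels and parameters for recovery tests.

Per-CpG counts use Beta(mu*s, (1-mu)*s) with s = 1/bb_overdispersion; the
per-gene window mean is shared across the gene's window CpGs with a small
gene-level jitter that is common to both tissues, so non-DMG genes are
genuinely null for the differential test.  All outputs are byte-identical
across runs with the same SimConfig.
"""

from __future__ import annotations

import os
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from tissuedom.annotation import GeneModel

TISSUES = ("liver", "muscle")

# window geometry shared with the analysis side
WIN_UP, WIN_DOWN = 200, 400
FLANK_LO, FLANK_HI = -1500, 2000


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic bundle.

    Defaults are the default study conditions: 2,000 genes, planted 10%+10%
    DMGs at a 0.7 methylation-ratio separation with 30x coverage and 3
    methylome replicates, 4-fold expression coupling with 11 RNA
    replicates, 3-fold protein/mRNA shifts with 5 proteome replicates, and
    4-fold TF-binding effects.
    """

    n_genes: int = 2000
    n_chromosomes: int = 4
    seed: int = 0
    frac_liver_dmg: float = 0.10
    frac_muscle_dmg: float = 0.10
    hypo_mean: float = 0.10
    hyper_mean: float = 0.80
    bb_overdispersion: float = 0.02  # beta-binomial precision s = 1/this
    coverage_mean: float = 30.0
    meth_replicates: int = 3
    rna_replicates: int = 11
    prot_replicates: int = 5
    deg_log2fc: float = 2.0
    nb_dispersion: float = 0.1
    drp_shift: float = float(np.log(3.0))
    frac_drp: float = 0.10
    dropout_rate: float = 0.05
    cpg_density_low: float = 10.0
    cpg_density_high: float = 47.0
    tf_effect_log2: float = 2.0
    # coupling / secondary structure
    p_couple: float = 0.8
    frac_dtg: float = 0.10
    n_tfs: int = 3
    frac_bound_both: float = 0.05
    frac_only: float = 0.04  # tissue-absent proteins, per tissue
    prot_noise_sd: float = 0.20
    trans_offset_sd: float = 0.8
    base_log2_tpm_mean: float = 5.0
    base_log2_tpm_sd: float = 1.5
    hypo_expr_bonus: float = 1.5
    ratio_jitter_sd: float = 0.03
    flank_cpgs_per_gene: int = 8
    noncpg_per_gene: int = 5
    noncpg_mean: float = 0.02
    gene_length: int = 1000
    gene_spacing: int = 8000
    chrom_length: int | None = None

    def __post_init__(self):
        props = [
            self.frac_liver_dmg, self.frac_muscle_dmg, self.frac_drp,
            self.dropout_rate, self.p_couple, self.frac_dtg,
            self.frac_bound_both, self.frac_only,
        ]
        if any(p < 0 or p > 1 for p in props):
            raise ValueError("all proportions must lie in [0, 1]")
        if self.frac_liver_dmg + self.frac_muscle_dmg > 1:
            raise ValueError("frac_liver_dmg + frac_muscle_dmg must be <= 1")
        if not (0 <= self.hypo_mean < self.hyper_mean <= 1):
            raise ValueError("need 0 <= hypo_mean < hyper_mean <= 1")
        if min(self.meth_replicates, self.rna_replicates, self.prot_replicates) < 1:
            raise ValueError("replicate counts must be >= 1")
        if self.coverage_mean <= 0:
            raise ValueError("coverage_mean must be positive")
        if self.bb_overdispersion <= 0 or self.nb_dispersion <= 0:
            raise ValueError("dispersions must be positive")

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), stage])


# stage indices for per-stage RNG streams
_S_ANNOT, _S_METH, _S_EXPR, _S_PROT, _S_PEAK, _S_SETS = range(6)


@dataclass
class Annotation:
    models: list[GeneModel]
    # per-site table: chrom, pos, strand, context, gene index, offset
    cpg_sites: pd.DataFrame
    truth: pd.DataFrame


def generate_annotation(cfg: SimConfig) -> Annotation:
    """Place genes on synthetic chromosomes and lay out their CpGs.

    Genes are non-overlapping, strands alternate, and each gene draws a
    Poisson CpG count for the -200..+400 window from its density class
    (DMGs low, others mostly high), plus sparse flank CpGs out to
    -1500/+2000 and a few non-CpG (CHG/CHH) cytosines.
    """
    rng = cfg.rng(_S_ANNOT)
    per_chrom = -(-cfg.n_genes // cfg.n_chromosomes)
    needed = 5000 + per_chrom * cfg.gene_spacing + 5000
    if cfg.chrom_length is not None and cfg.chrom_length < needed:
        raise ValueError(
            f"chromosome length {cfg.chrom_length} cannot fit {per_chrom} genes "
            f"(need {needed} bp)"
        )
    n = cfg.n_genes
    gene_ids = [f"G{i:05d}" for i in range(n)]

    # planted DMG labels and density classes
    n_liver = int(round(cfg.frac_liver_dmg * n))
    n_muscle = int(round(cfg.frac_muscle_dmg * n))
    order = rng.permutation(n)
    dmg_label = np.array(["none"] * n, dtype=object)
    dmg_label[order[:n_liver]] = "liver"
    dmg_label[order[n_liver:n_liver + n_muscle]] = "muscle"
    density = np.where(
        dmg_label != "none", "low", np.where(rng.random(n) < 0.10, "low", "high")
    )

    models = []
    rows_sites = []
    for i, gid in enumerate(gene_ids):
        chrom = f"chr{i % cfg.n_chromosomes + 1}"
        slot = i // cfg.n_chromosomes
        start = 5000 + slot * cfg.gene_spacing
        strand = "+" if i % 2 == 0 else "-"
        L = cfg.gene_length
        exons = [(start, start + 2 * L // 5), (start + 3 * L // 5, start + L)]
        models.append(_mk_model(gid, chrom, strand, exons))

    for i, (gid, m) in enumerate(zip(gene_ids, models)):
        lam = cfg.cpg_density_low if density[i] == "low" else cfg.cpg_density_high
        k_win = max(int(rng.poisson(lam)), 1)
        win_off = np.sort(rng.choice(np.arange(-WIN_UP, WIN_DOWN), size=min(k_win, WIN_UP + WIN_DOWN), replace=False))
        flank_pool = np.concatenate(
            [np.arange(FLANK_LO, -WIN_UP), np.arange(WIN_DOWN, FLANK_HI)]
        )
        k_fl = cfg.flank_cpgs_per_gene
        fl_off = np.sort(rng.choice(flank_pool, size=k_fl, replace=False))
        nc_off = np.sort(rng.choice(np.arange(FLANK_LO, FLANK_HI), size=cfg.noncpg_per_gene, replace=False))
        for off in win_off:
            rows_sites.append((m.chrom, _off_to_pos(m, int(off)), "+", "CpG", i, int(off)))
        for off in fl_off:
            rows_sites.append((m.chrom, _off_to_pos(m, int(off)), "+", "CpG", i, int(off)))
        for j, off in enumerate(nc_off):
            ctx = "CHG" if j % 2 == 0 else "CHH"
            rows_sites.append((m.chrom, _off_to_pos(m, int(off)), "+", ctx, i, int(off)))

    sites = pd.DataFrame(
        rows_sites, columns=["chrom", "pos", "strand", "context", "gene_idx", "offset"]
    ).sort_values(["chrom", "pos", "context"], kind="mergesort").reset_index(drop=True)
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "chrom": [m.chrom for m in models],
            "strand": [m.strand for m in models],
            "tss": [m.tss for m in models],
            "dmg_label": dmg_label,
            "density_class": density,
        }
    ).set_index("gene_id")
    return Annotation(models, sites, truth)


def _mk_model(gid, chrom, strand, exons) -> GeneModel:
    gsort = sorted(exons)
    tss = gsort[0][0] if strand == "+" else gsort[-1][1] - 1
    ordered = gsort if strand == "+" else gsort[::-1]
    return GeneModel(gid, gid, chrom, strand, tss, ordered)


def _off_to_pos(m: GeneModel, off: int) -> int:
    return m.tss + off if m.strand == "+" else m.tss - off


def generate_methylome(cfg: SimConfig, ann: Annotation) -> dict[str, list[pd.DataFrame]]:
    """Beta-binomial replicate count tables per tissue.

    Planted per-gene window ratios: DMG genes are hypomethylated
    (hypo_mean) in their tissue and hypermethylated (hyper_mean) in the
    other; non-DMG genes are concordant hypo/hypo or hyper/hyper (50/50).
    A gene-level jitter shared between tissues makes the pooled window
    ratios a realistic bimodal mixture without breaking the null for
    non-DMG genes.  Flank CpGs get per-(gene, tissue) states independent
    of expression; CHG/CHH sites are uniformly hypomethylated.
    """
    rng = cfg.rng(_S_METH)
    truth = ann.truth
    n = len(truth)
    concordant_hypo = rng.random(n) < 0.5
    jitter = rng.normal(0.0, cfg.ratio_jitter_sd, size=n)
    win_mu = {}
    for tissue in TISSUES:
        state_mean = np.where(
            truth["dmg_label"] == tissue,
            cfg.hypo_mean,
            np.where(
                truth["dmg_label"] != "none",
                cfg.hyper_mean,
                np.where(concordant_hypo, cfg.hypo_mean, cfg.hyper_mean),
            ),
        )
        win_mu[tissue] = np.clip(state_mean + jitter, 0.005, 0.995)
    # flank states independent per (gene, tissue)
    flank_mu = {}
    for tissue in TISSUES:
        fl_state = np.where(rng.random(n) < 0.5, cfg.hypo_mean, cfg.hyper_mean)
        flank_mu[tissue] = np.clip(fl_state + rng.normal(0, cfg.ratio_jitter_sd, n), 0.005, 0.995)

    sites = ann.cpg_sites
    gidx = sites["gene_idx"].to_numpy()
    in_window = (sites["offset"] >= -WIN_UP) & (sites["offset"] < WIN_DOWN)
    is_cpg = sites["context"] == "CpG"
    s = 1.0 / cfg.bb_overdispersion
    out: dict[str, list[pd.DataFrame]] = {}
    for tissue in TISSUES:
        mu_site = np.where(
            ~is_cpg,
            cfg.noncpg_mean,
            np.where(in_window, win_mu[tissue][gidx], flank_mu[tissue][gidx]),
        )
        reps = []
        for _ in range(cfg.meth_replicates):
            p = rng.beta(mu_site * s, (1.0 - mu_site) * s)
            n_tot = rng.poisson(cfg.coverage_mean, size=len(sites))
            n_meth = rng.binomial(n_tot, p)
            reps.append(
                pd.DataFrame(
                    {
                        "chrom": sites["chrom"],
                        "pos": sites["pos"],
                        "strand": sites["strand"],
                        "context": sites["context"],
                        "n_meth": n_meth,
                        "n_total": n_tot,
                    }
                )
            )
        out[tissue] = reps
    for tissue in TISSUES:
        truth[f"ratio_{tissue}"] = win_mu[tissue]
    return out


def generate_expression(
    cfg: SimConfig, truth: pd.DataFrame
) -> dict[str, dict[str, pd.DataFrame]]:
    """Negative-binomial counts and TPM per tissue.

    Baseline log2 expression is Gaussian; genes hypomethylated in both
    tissues get a ubiquitous expression bonus (no differential signal).
    DMG genes are coupled to a +deg_log2fc shift in their hypomethylated
    tissue with probability p_couple; planted DTG genes get a
    +tf_effect_log2 shift in the TF-bound tissue; both mechanisms set the
    planted deg_label when they produce a nonzero shift.
    """
    rng = cfg.rng(_S_EXPR)
    n = len(truth)
    genes = truth.index
    base = rng.normal(cfg.base_log2_tpm_mean, cfg.base_log2_tpm_sd, n)
    hypo_both = (truth["ratio_liver"] < 0.5).to_numpy() & (truth["ratio_muscle"] < 0.5).to_numpy()
    base = base + np.where(hypo_both, cfg.hypo_expr_bonus, 0.0)
    coupled = rng.random(n) < cfg.p_couple

    # DTG planting: among genes, independent of DMG status
    n_dtg = int(round(cfg.frac_dtg * n))
    order = rng.permutation(n)
    dtg_label = np.array(["none"] * n, dtype=object)
    dtg_tissue = np.where(np.arange(n_dtg) % 2 == 0, "liver", "muscle")
    dtg_label[order[:n_dtg]] = dtg_tissue
    tf_assign = np.full(n, -1)
    tf_assign[order[:n_dtg]] = np.arange(n_dtg) % cfg.n_tfs
    # background both-tissue binding (no differential signal)
    both_bound = np.zeros(n, dtype=bool)
    both_tf = np.full(n, -1)
    rest = order[n_dtg:]
    n_both = int(round(cfg.frac_bound_both * n))
    both_bound[rest[:n_both]] = True
    both_tf[rest[:n_both]] = np.arange(n_both) % cfg.n_tfs

    shift = {t: np.zeros(n) for t in TISSUES}
    for tissue in TISSUES:
        dm_hit = (truth["dmg_label"] == tissue).to_numpy() & coupled
        shift[tissue] += np.where(dm_hit, cfg.deg_log2fc, 0.0)
        tf_hit = dtg_label == tissue
        shift[tissue] += np.where(tf_hit, cfg.tf_effect_log2, 0.0)
        shift[tissue] += np.where(both_bound, cfg.tf_effect_log2, 0.0)
    delta = shift["liver"] - shift["muscle"]
    deg_label = np.where(delta > 0, "liver", np.where(delta < 0, "muscle", "none"))

    out: dict[str, dict[str, pd.DataFrame]] = {}
    depth_per_tpm = 10.0  # expected reads per TPM unit
    for tissue in TISSUES:
        mu_tpm = 2.0 ** (base + shift[tissue])
        lib = np.exp(rng.normal(0.0, 0.15, cfg.rna_replicates))
        counts = np.empty((n, cfg.rna_replicates), dtype=int)
        for r in range(cfg.rna_replicates):
            mean = mu_tpm * depth_per_tpm * lib[r]
            # NB via gamma-Poisson with dispersion phi: shape 1/phi
            shape = 1.0 / cfg.nb_dispersion
            lam = rng.gamma(shape, mean / shape)
            counts[:, r] = rng.poisson(lam)
        cols = [f"{tissue}_r{r+1}" for r in range(cfg.rna_replicates)]
        cdf = pd.DataFrame(counts, index=genes, columns=cols)
        rate = cdf.to_numpy() / cfg.gene_length
        tpm = rate / rate.sum(axis=0, keepdims=True) * 1e6
        tdf = pd.DataFrame(tpm, index=genes, columns=cols)
        out[tissue] = {"counts": cdf, "tpm": tdf}
        truth[f"mu_tpm_{tissue}"] = mu_tpm
    truth["deg_label"] = deg_label
    truth["dtg_label"] = dtg_label
    truth["tf_index"] = tf_assign
    truth["both_bound_tf"] = both_tf
    return out


def generate_proteome(
    cfg: SimConfig, truth: pd.DataFrame, rna: dict
) -> dict:
    """Log-normal intensities coupled to the generated mRNA levels.

    log intensity = alpha + log(mean measured TPM of the tissue) + per-gene
    translation offset + drp_shift for the planted DRP subset in its tissue
    + Gaussian noise (protein abundance tracks the cohort's realized mRNA);
    per-cell dropout at ``dropout_rate`` plus a planted tissue-absent
    subset (all replicates missing in the other tissue).  One protein per
    gene; the protein/gene map is the identity renaming P<i> -> G<i>.
    """
    rng = cfg.rng(_S_PROT)
    n = len(truth)
    genes = truth.index
    free = (truth["deg_label"] == "none").to_numpy() & (truth["dtg_label"] == "none").to_numpy()
    free_idx = np.flatnonzero(free)
    rng.shuffle(free_idx)
    n_drp = int(round(cfg.frac_drp * n))
    drp_label = np.array(["none"] * n, dtype=object)
    take = free_idx[:n_drp]
    drp_label[take[::2]] = "liver"
    drp_label[take[1::2]] = "muscle"
    rest = free_idx[n_drp:]
    n_only = int(round(cfg.frac_only * n))
    only_label = np.array(["none"] * n, dtype=object)
    only_label[rest[:n_only]] = "liver"
    only_label[rest[n_only:2 * n_only]] = "muscle"

    alpha = 2.0
    c_gene = rng.normal(0.0, cfg.trans_offset_sd, n)
    intens = {}
    for tissue in TISSUES:
        tpm_obs = np.maximum(rna[tissue]["tpm"].mean(axis=1).to_numpy(), 1e-3)
        y_mean = alpha + np.log(tpm_obs) + c_gene + np.where(drp_label == tissue, cfg.drp_shift, 0.0)
        y = y_mean[:, None] + rng.normal(0.0, cfg.prot_noise_sd, (n, cfg.prot_replicates))
        x = np.exp(y)
        drop = rng.random((n, cfg.prot_replicates)) < cfg.dropout_rate
        x[drop] = np.nan
        absent = np.array([lab != "none" and lab != tissue for lab in only_label])
        x[absent, :] = np.nan
        cols = [f"{tissue}_r{r+1}" for r in range(cfg.prot_replicates)]
        intens[tissue] = pd.DataFrame(
            x, index=[f"P{gid[1:]}" for gid in genes], columns=cols
        )
    # planted DEP label: any planted protein-level difference
    dep = np.array(["none"] * n, dtype=object)
    for tissue in TISSUES:
        dep = np.where((truth["deg_label"] == tissue) | (drp_label == tissue), tissue, dep)
    dep = np.where(only_label != "none", [f"{l}_only" if l != "none" else "" for l in only_label], dep)
    truth["drp_label"] = drp_label
    truth["dep_label"] = dep
    id_map = pd.Series(genes, index=[f"P{gid[1:]}" for gid in genes], name="gene_id")
    return {"intensities": intens, "protein_gene_map": id_map}


def generate_peaks(cfg: SimConfig, ann: Annotation, truth: pd.DataFrame) -> dict:
    """BED peak sets: TFs (per tissue), ATAC, histone marks, CpG islands.

    Planted DTG genes get their TF's peak within the TSS+-1000 flank in
    exactly one tissue; both-bound background genes in both tissues.  ATAC
    and active histone marks preferentially cover genes hypomethylated in
    that tissue; CpG islands cover the windows of high-density genes.
    """
    rng = cfg.rng(_S_PEAK)
    models = {m.transcript_id: m for m in ann.models}
    tf_names = [f"TF{i+1}" for i in range(cfg.n_tfs)]
    tf_beds: dict[str, dict[str, list]] = {tf: {t: [] for t in TISSUES} for tf in tf_names}
    for gid, row in truth.iterrows():
        m = models[gid]
        iv = (m.chrom, m.tss - 100, m.tss + 100)
        if row["dtg_label"] != "none":
            tf_beds[tf_names[int(row["tf_index"])]][row["dtg_label"]].append(iv)
        if row["both_bound_tf"] >= 0:
            for t in TISSUES:
                tf_beds[tf_names[int(row["both_bound_tf"])]][t].append(iv)
    peaks = {
        tf: {t: pd.DataFrame(v, columns=["chrom", "start", "end"]) for t, v in per.items()}
        for tf, per in tf_beds.items()
    }
    open_beds: dict[str, dict] = {}
    hm_beds: dict[str, dict] = {}
    for tissue in TISSUES:
        hypo = truth[f"ratio_{tissue}"].to_numpy() < 0.5
        pr = np.where(hypo, 0.9, 0.2)
        covered = rng.random(len(truth)) < pr
        rows = [
            (models[g].chrom, models[g].tss - 300, models[g].tss + 300)
            for g, c in zip(truth.index, covered)
            if c
        ]
        open_beds[tissue] = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        for mark in ("H3K4me3", "H3K27ac"):
            covered_hm = rng.random(len(truth)) < np.where(hypo, 0.85, 0.15)
            hm_rows = [
                (models[g].chrom, models[g].tss - 500, models[g].tss + 500)
                for g, c in zip(truth.index, covered_hm)
                if c
            ]
            # two replicate files per mark, identical gene support
            hm_beds.setdefault(mark, {})[tissue] = [
                pd.DataFrame(hm_rows, columns=["chrom", "start", "end"]),
                pd.DataFrame(hm_rows, columns=["chrom", "start", "end"]),
            ]
    island_rows = []
    for gid, row in truth.iterrows():
        if row["density_class"] == "high":
            m = models[gid]
            w_lo = m.tss - WIN_UP if m.strand == "+" else m.tss + 1 - WIN_DOWN
            island_rows.append((m.chrom, w_lo, w_lo + WIN_UP + WIN_DOWN))
    islands = pd.DataFrame(island_rows, columns=["chrom", "start", "end"])
    return {"tf": peaks, "atac": open_beds, "histone": hm_beds, "cpg_islands": islands}


def generate_gene_sets(cfg: SimConfig, truth: pd.DataFrame) -> dict:
    """GMT gene sets with one set enriched in liver DRPs (a 5'-TOP-motif
    stand-in), one enriched in liver DM-DEG genes, and random decoys."""
    rng = cfg.rng(_S_SETS)
    genes = np.array(truth.index)
    liver_drp = genes[(truth["drp_label"] == "liver").to_numpy()]
    dm_deg_liver = genes[
        ((truth["dmg_label"] == "liver") & (truth["deg_label"] == "liver")).to_numpy()
    ]
    top = set(liver_drp[rng.random(len(liver_drp)) < 0.7]) | set(
        rng.choice(genes, size=max(5, len(genes) // 100), replace=False)
    )
    liver_path = set(dm_deg_liver[rng.random(len(dm_deg_liver)) < 0.6]) | set(
        rng.choice(genes, size=max(5, len(genes) // 100), replace=False)
    )
    sets = {"TOP_MOTIF": top, "LIVER_PATHWAY": liver_path}
    for i in range(3):
        sets[f"RANDOM_SET_{i+1}"] = set(
            rng.choice(genes, size=max(10, len(genes) // 40), replace=False)
        )
    classes = {
        "TOP_MOTIF": "Genetic Information Processing",
        "LIVER_PATHWAY": "Metabolism",
        "RANDOM_SET_1": "Organismal Systems",
        "RANDOM_SET_2": "Cellular Process",
        "RANDOM_SET_3": "Environmental Information Processing",
    }
    return {"sets": sets, "classes": classes}


@dataclass
class Bundle:
    """A complete in-memory synthetic study."""

    cfg: SimConfig
    annotation: Annotation
    methylome: dict
    rna: dict
    proteome: dict
    peaks: dict
    gene_sets: dict

    @property
    def truth(self) -> pd.DataFrame:
        return self.annotation.truth

    @property
    def models(self):
        return self.annotation.models


def simulate_study(cfg: SimConfig) -> Bundle:
    """Run all generation stages in order and return the bundle."""
    ann = generate_annotation(cfg)
    meth = generate_methylome(cfg, ann)
    rna = generate_expression(cfg, ann.truth)
    prot = generate_proteome(cfg, ann.truth, rna)
    peaks = generate_peaks(cfg, ann, ann.truth)
    sets = generate_gene_sets(cfg, ann.truth)
    validate_truth(ann.truth)
    return Bundle(cfg, ann, meth, rna, prot, peaks, sets)


def validate_truth(truth: pd.DataFrame) -> None:
    """Label/parameter consistency checks; raises on violation."""
    for tissue, other in (("liver", "muscle"), ("muscle", "liver")):
        is_dmg = truth["dmg_label"] == tissue
        if not (truth.loc[is_dmg, f"ratio_{tissue}"] < truth.loc[is_dmg, f"ratio_{other}"]).all():
            raise AssertionError(f"{tissue} DMGs must be hypomethylated in {tissue}")
        if "deg_label" in truth and "mu_tpm_liver" in truth:
            is_deg = truth["deg_label"] == tissue
            if not (
                truth.loc[is_deg, f"mu_tpm_{tissue}"] > truth.loc[is_deg, f"mu_tpm_{other}"]
            ).all():
                raise AssertionError(f"{tissue} DEGs must have higher planted {tissue} expression")


# ---------------------------------------------------------------- writers


def write_bundle(bundle: Bundle, outdir: str) -> dict[str, object]:
    """Write the bundle as plain-text files (GTF, TSV, BED6, GMT) and return
    the path manifest.  Byte-identical for identical SimConfig."""
    os.makedirs(outdir, exist_ok=True)
    paths: dict[str, object] = {}
    gtf = os.path.join(outdir, "annotation.gtf")
    _write_gtf(bundle.models, gtf)
    paths["gtf"] = gtf
    meth_paths: dict[str, list[str]] = {}
    for tissue, reps in bundle.methylome.items():
        meth_paths[tissue] = []
        for r, df in enumerate(reps):
            p = os.path.join(outdir, f"meth_{tissue}_rep{r+1}.tsv")
            df.to_csv(p, sep="\t", index=False)
            meth_paths[tissue].append(p)
    paths["methylome"] = meth_paths
    for tissue, mats in bundle.rna.items():
        for kind, df in mats.items():
            p = os.path.join(outdir, f"rna_{kind}_{tissue}.tsv")
            df.to_csv(p, sep="\t", float_format="%.6g")
            paths[f"rna_{kind}_{tissue}"] = p
    for tissue, df in bundle.proteome["intensities"].items():
        p = os.path.join(outdir, f"protein_{tissue}.tsv")
        df.to_csv(p, sep="\t", float_format="%.8g")
        paths[f"protein_{tissue}"] = p
    p = os.path.join(outdir, "protein_gene_map.tsv")
    bundle.proteome["protein_gene_map"].rename_axis("protein_id").to_csv(p, sep="\t")
    paths["protein_gene_map"] = p
    peak_dir = os.path.join(outdir, "peaks")
    os.makedirs(peak_dir, exist_ok=True)
    tf_paths: dict[str, dict[str, str]] = {}
    for tf, per in bundle.peaks["tf"].items():
        tf_paths[tf] = {}
        for tissue, bed in per.items():
            bp = os.path.join(peak_dir, f"tf_{tf}_{tissue}.bed")
            _write_bed(bed, bp, name=tf)
            tf_paths[tf][tissue] = bp
    paths["tf_peaks"] = tf_paths
    atac_paths = {}
    for tissue, bed in bundle.peaks["atac"].items():
        bp = os.path.join(peak_dir, f"atac_{tissue}.bed")
        _write_bed(bed, bp, name="ATAC")
        atac_paths[tissue] = bp
    paths["atac"] = atac_paths
    hm_paths: dict[str, dict[str, list[str]]] = {}
    for mark, per in bundle.peaks["histone"].items():
        hm_paths[mark] = {}
        for tissue, beds in per.items():
            hm_paths[mark][tissue] = []
            for i, bed in enumerate(beds):
                bp = os.path.join(peak_dir, f"{mark}_{tissue}_{i+1}.bed")
                _write_bed(bed, bp, name=mark)
                hm_paths[mark][tissue].append(bp)
    paths["histone"] = hm_paths
    bp = os.path.join(peak_dir, "cpg_islands.bed")
    _write_bed(bundle.peaks["cpg_islands"], bp, name="CpGisland")
    paths["cpg_islands"] = bp
    gmt = os.path.join(outdir, "gene_sets.gmt")
    with open(gmt, "w") as fh:
        for name, members in bundle.gene_sets["sets"].items():
            fh.write("\t".join([name, "synthetic"] + sorted(members)) + "\n")
    paths["gene_sets"] = gmt
    cls = os.path.join(outdir, "gene_set_classes.tsv")
    pd.Series(bundle.gene_sets["classes"], name="category").rename_axis("set").to_csv(cls, sep="\t")
    paths["gene_set_classes"] = cls
    tp = os.path.join(outdir, "truth.tsv")
    bundle.truth.to_csv(tp, sep="\t", float_format="%.6g")
    paths["truth"] = tp
    return paths


def _write_gtf(models: list[GeneModel], path: str) -> None:
    with open(path, "w") as fh:
        for m in models:
            attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
            fh.write(
                "\t".join(
                    [m.chrom, "tissuedom_sim", "transcript", str(m.start + 1), str(m.end), ".", m.strand, ".", attrs]
                )
                + "\n"
            )
            for s, e in sorted(m.exons):
                fh.write(
                    "\t".join(
                        [m.chrom, "tissuedom_sim", "exon", str(s + 1), str(e), ".", m.strand, ".", attrs]
                    )
                    + "\n"
                )


def _write_bed(bed: pd.DataFrame, path: str, name: str = ".") -> None:
    with open(path, "w") as fh:
        for _, row in bed.sort_values(["chrom", "start"]).iterrows():
            fh.write(f"{row['chrom']}\t{row['start']}\t{row['end']}\t{name}\t0\t.\n")


def config_dict(cfg: SimConfig) -> dict:
    return asdict(cfg)
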