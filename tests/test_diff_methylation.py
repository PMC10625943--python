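"""Beta-binomial differential methylation test and DMG calling."""

import itertools

import numpy as np
import pandas as pd
import pytest

from tissuedom import diff_methylation as dm
from tissuedom.annotation import GeneModel
from tissuedom.methylome import MethylomeData, classify_hypo_hyper, window_methylation
from tissuedom.stats_core import fisher_exact


class TestDmcpgTest:
    def test_identical_counts_give_null_statistic(self):
        lr, p = dm.dmcpg_test([5, 6, 4], [10, 12, 9], [5, 6, 4], [10, 12, 9])
        assert lr == pytest.approx(0.0, abs=1e-6)
        assert p == pytest.approx(1.0, abs=1e-4)

    def test_strong_difference_is_extreme_by_permutation(self):
        """liver 50/100 x3 vs muscle 5/100 x3: the observed split maximizes
        the LR statistic over all relabelings of the 6 replicates."""
        counts = [(50, 100)] * 3 + [(5, 100)] * 3
        lr_obs, p = dm.dmcpg_test([50] * 3, [100] * 3, [5] * 3, [100] * 3)
        assert p < 1e-6
        ge = 0
        total = 0
        for grp in itertools.combinations(range(6), 3):
            rest = [i for i in range(6) if i not in grp]
            ma = [counts[i][0] for i in grp]
            na = [counts[i][1] for i in grp]
            mb = [counts[i][0] for i in rest]
            nb = [counts[i][1] for i in rest]
            lr, _ = dm.dmcpg_test(ma, na, mb, nb)
            total += 1
            ge += lr >= lr_obs - 1e-9
        # only the true split and its mirror reach the observed statistic
        assert ge == 2 and total == 20

    def test_single_replicate_falls_back_to_fisher(self):
        _, p = dm.dmcpg_test([8], [10], [1], [10])
        assert p == pytest.approx(fisher_exact([[8, 2], [1, 9]], "two"), abs=1e-12)

    def test_null_p_values_approximately_uniform(self):
        rng = np.random.default_rng(0)
        n_sites, s = 2000, 50.0
        mu = np.where(rng.random(n_sites) < 0.5, 0.15, 0.75)

        def draw():
            p = rng.beta(mu[:, None] * s, (1 - mu[:, None]) * s, (n_sites, 3))
            n = rng.poisson(30, (n_sites, 3))
            return rng.binomial(n, p), n

        ma, na = draw()
        mb, nb = draw()
        _, p = dm._lr_test(ma, na, mb, nb, None)
        from scipy.stats import kstest

        assert kstest(p, "uniform").statistic < 0.1


def _make_data(ratios_a, ratios_b, rng, reps=3, cov=30):
    n = len(ratios_a)
    sites = pd.DataFrame(
        {"chrom": "chr1", "pos": np.arange(n) * 10, "context": "CpG"}
    )
    s = 50.0

    def draw(mu):
        mu = np.asarray(mu)
        p = rng.beta(mu[:, None] * s, (1 - mu[:, None]) * s, (n, reps))
        tot = rng.poisson(cov, (n, reps))
        return rng.binomial(tot, p), tot

    ma, na = draw(ratios_a)
    mb, nb = draw(ratios_b)
    return MethylomeData(sites, {"liver": ma, "muscle": mb}, {"liver": na, "muscle": nb})


class TestCallDmcpgs:
    def test_all_p_one_gives_no_calls(self):
        res = pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": range(5),
                "ratio_liver": 0.5,
                "ratio_muscle": 0.5,
                "statistic": 0.0,
                "p": 1.0,
                "tested": True,
            }
        )
        out = dm.call_dmcpgs(res)
        assert not out["is_dmcpg"].any()

    def test_planted_sites_recovered_with_high_precision(self, rng):
        n = 1500
        truth = rng.random(n) < 0.15
        ra = np.where(truth, 0.1, 0.5)
        rb = np.full(n, 0.5)
        data = _make_data(ra, rb, rng)
        res = dm.dmcpg_test_all(data)
        out = dm.call_dmcpgs(res)
        called = out["is_dmcpg"].to_numpy()
        recall = (called & truth).sum() / truth.sum()
        precision = (called & truth).sum() / max(called.sum(), 1)
        assert recall >= 0.9 and precision >= 0.9
        # direction is the hypomethylated tissue
        assert set(out.loc[called & truth, "direction"]) == {"liver_hypo"}

    def test_q_monotone_in_p(self, rng):
        data = _make_data(rng.random(300), rng.random(300), rng)
        out = dm.call_dmcpgs(dm.dmcpg_test_all(data))
        sub = out.dropna(subset=["q"]).sort_values("p")
        assert np.all(np.diff(sub["q"]) >= -1e-12)


def _gene(tid, tss, strand="+"):
    exons = [(tss, tss + 500)] if strand == "+" else [(tss - 499, tss + 1)]
    return GeneModel(tid, tid, "chr1", strand, tss, exons)


class TestCallDmgs:
    def _window_states(self, gene_ids, ratios):
        rows = []
        for gid in gene_ids:
            for tissue in ("liver", "muscle"):
                rows.append((gid, tissue, ratios[(gid, tissue)], 5))
        wm = pd.DataFrame(rows, columns=["gene_id", "tissue", "mean_ratio", "n_cpg"])
        return classify_hypo_hyper(wm, 0.4196)

    def _dmcpgs(self, entries):
        return pd.DataFrame(
            [
                {"chrom": "chr1", "pos": pos, "is_dmcpg": True, "direction": d}
                for pos, d in entries
            ]
        )

    def test_dmcpg_at_plus_399_inside_window(self):
        g = _gene("g1", 1000)
        states = self._window_states(["g1"], {("g1", "liver"): 0.1, ("g1", "muscle"): 0.8})
        out = dm.call_dmgs([g], self._dmcpgs([(1399, "liver_hypo")]), states)
        assert out["label"].iloc[0] == "liver_dmg"

    def test_dmcpg_at_plus_401_outside_window(self):
        g = _gene("g1", 1000)
        states = self._window_states(["g1"], {("g1", "liver"): 0.1, ("g1", "muscle"): 0.8})
        out = dm.call_dmgs([g], self._dmcpgs([(1401, "liver_hypo")]), states)
        assert out["label"].iloc[0] == "non_dmg"

    def test_hypermethylated_both_tissues_never_dmg(self):
        g = _gene("g1", 1000)
        states = self._window_states(["g1"], {("g1", "liver"): 0.6, ("g1", "muscle"): 0.9})
        out = dm.call_dmgs([g], self._dmcpgs([(1100, "liver_hypo")]), states)
        assert out["label"].iloc[0] == "non_dmg"

    def test_direction_needs_consistent_window_means(self):
        g = _gene("g1", 1000)
        # liver-hypo DMCpG but the liver window mean is the HIGHER one
        states = self._window_states(["g1"], {("g1", "liver"): 0.3, ("g1", "muscle"): 0.1})
        out = dm.call_dmgs([g], self._dmcpgs([(1100, "liver_hypo")]), states)
        assert out["label"].iloc[0] == "non_dmg"

    def test_minus_strand_window_orientation(self):
        g = _gene("g1", 2000, strand="-")
        states = self._window_states(["g1"], {("g1", "muscle"): 0.1, ("g1", "liver"): 0.8})
        # strand-aware window covers genomic [1601, 2201); 1601 inside, 1600 out
        inside = dm.call_dmgs([g], self._dmcpgs([(1601, "muscle_hypo")]), states)
        outside = dm.call_dmgs([g], self._dmcpgs([(1600, "muscle_hypo")]), states)
        assert inside["label"].iloc[0] == "muscle_dmg"
        assert outside["label"].iloc[0] == "non_dmg"

    def test_labels_partition_and_untested_flag(self):
        genes = [_gene("g1", 1000), _gene("g2", 20000)]
        states = self._window_states(
            ["g1", "g2"],
            {("g1", "liver"): 0.1, ("g1", "muscle"): 0.8,
             ("g2", "liver"): np.nan, ("g2", "muscle"): np.nan},
        )
        out = dm.call_dmgs(genes, self._dmcpgs([(1100, "liver_hypo")]), states)
        assert set(out["label"]) <= {"liver_dmg", "muscle_dmg", "non_dmg"}
        assert out.set_index("gene_id").loc["g2", "untested"]


def test_dmg_false_positives_controlled_on_null_data(rng):
    """With no planted differences, the fraction of genes called DMG stays
    near the q cut."""
    n_genes, cpg_per_gene = 150, 8
    models = [_gene(f"g{i}", 5000 + i * 3000) for i in range(n_genes)]
    mu_gene = np.where(rng.random(n_genes) < 0.5, 0.1, 0.8) + rng.normal(0, 0.02, n_genes)
    mu_gene = np.clip(mu_gene, 0.01, 0.99)
    rows, mu_sites = [], []
    for i, m in enumerate(models):
        for j in range(cpg_per_gene):
            rows.append(("chr1", m.tss - 200 + j * 70, "CpG"))
            mu_sites.append(mu_gene[i])
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "context"])
    mu_sites = np.array(mu_sites)
    s = 50.0

    def draw():
        p = rng.beta(mu_sites[:, None] * s, (1 - mu_sites[:, None]) * s, (len(mu_sites), 3))
        tot = rng.poisson(30, (len(mu_sites), 3))
        return rng.binomial(tot, p), tot

    ma, na = draw()
    mb, nb = draw()
    data = MethylomeData(sites, {"liver": ma, "muscle": mb}, {"liver": na, "muscle": nb})
    wm = window_methylation(data, models)
    states = classify_hypo_hyper(wm, 0.4196)
    dmcpgs = dm.call_dmcpgs(dm.dmcpg_test_all(data))
    out = dm.call_dmgs(models, dmcpgs, states)
    fp_fraction = (out["label"] != "non_dmg").mean()
    assert fp_fraction <= 2 * dm.DEFAULT_Q_CUT + 2 / n_genes
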