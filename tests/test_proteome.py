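"""Protein detection, VSN, moderated testing, and the DRP criterion."""

import numpy as np
import pandas as pd
import pytest

from tissuedom import proteome as pr
from tissuedom.stats_core import fisher_exact


def make_intensities(rng, n=200, reps=5, missing=None):
    x = np.exp(rng.normal(8, 1.5, (n, reps)))
    df = pd.DataFrame(x, index=[f"p{i}" for i in range(n)],
                      columns=[f"r{j}" for j in range(reps)])
    if missing is not None:
        df[rng.random((n, reps)) < missing] = np.nan
    return df


class TestDetect:
    @pytest.mark.parametrize("present,expected", [(3, True), (2, False), (5, True)])
    def test_detection_boundary(self, present, expected):
        row = [1.0] * present + [np.nan] * (5 - present)
        df = pd.DataFrame([row], index=["p"])
        assert pr.detect_proteins(df).iloc[0] == expected

    def test_min_reps_validation(self):
        with pytest.raises(ValueError):
            pr.detect_proteins(pd.DataFrame([[1.0, 2.0]]), min_reps=3)


class TestVsn:
    def test_transform_identities(self):
        params = pr.VsnParams(a=0.0, b=1.0, gamma=1.0)
        assert params.transform(0.0) == pytest.approx(0.0)
        # arcsinh asymptote: h(x) -> gamma*(ln x + ln 2b) for large x
        x = 1e8
        assert params.transform(x) - (np.log(x) + np.log(2.0)) == pytest.approx(0.0, abs=1e-6)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            pr.VsnParams(a=0.0, b=-1.0, gamma=1.0)

    def _simulate(self, rng, a=0.5, b=1e-3, gamma=2.0, n=400, reps=8):
        # latent means span the arcsinh knee so the gain is identifiable
        m = rng.normal(3.0, 2.0, n)
        h = m[:, None] + rng.standard_normal((n, reps))  # unit latent noise
        x = (np.sinh(h / gamma) - a) / b
        return pd.DataFrame(x, index=[f"p{i}" for i in range(n)])

    def test_parameter_recovery_of_gamma(self):
        rng = np.random.default_rng(2)
        gamma = 2.0
        X = self._simulate(rng, gamma=gamma)
        params, transformed = pr.vsn_fit(X)
        assert abs(params.gamma - gamma) / gamma < 0.10

    def test_variance_mean_decoupling_after_transform(self):
        rng = np.random.default_rng(3)
        X = self._simulate(rng)
        _, h = pr.vsn_fit(X)
        mean = h.mean(axis=1)
        resid_mag = (h.sub(mean, axis=0)).abs().mean(axis=1)
        from tissuedom.stats_core import spearman_rho

        rho, _ = spearman_rho(mean.to_numpy(), resid_mag.to_numpy())
        assert abs(rho) < 0.1

    def test_needs_enough_proteins(self):
        with pytest.raises(ValueError):
            pr.vsn_fit(pd.DataFrame(np.ones((5, 4))))


class TestModeratedTest:
    def test_zero_prior_df_equals_pooled_t(self, rng):
        a = pd.DataFrame(rng.normal(0, 1, (50, 5)))
        b = pd.DataFrame(rng.normal(0, 1, (50, 5)))
        out = pr.moderated_test(a, b, prior_df=0)
        from scipy.stats import ttest_ind

        ref = ttest_ind(a, b, axis=1)  # pooled-variance two-sample t
        assert np.allclose(out["t"], ref.statistic, atol=1e-10)
        assert np.allclose(out["p"], ref.pvalue, atol=1e-10)

    def test_null_fdr_controlled_across_seeds(self):
        false_disc, disc = 0, 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            a = pd.DataFrame(rng.normal(0, 1, (400, 5)))
            b = pd.DataFrame(rng.normal(0, 1, (400, 5)))
            out = pr.moderated_test(a, b)
            false_disc += (out["q"] < 0.01).sum()
            disc += len(out)
        assert false_disc / disc <= 0.01

    def test_planted_threefold_recovered(self):
        rng = np.random.default_rng(11)
        n = 500
        truth = rng.random(n) < 0.2
        a = pd.DataFrame(rng.normal(0, 0.3, (n, 5)) + np.where(truth, np.log(3), 0)[:, None])
        b = pd.DataFrame(rng.normal(0, 0.3, (n, 5)))
        out = pr.moderated_test(a, b)
        called = (out["q"] < 0.01) & (out["diff"] > 0)
        assert (called & truth).sum() / truth.sum() >= 0.85


class TestCallDeps:
    def test_label_rules(self):
        det_l = pd.Series({"p1": True, "p2": True, "p3": False, "p4": True, "p5": False})
        det_m = pd.Series({"p1": True, "p2": False, "p3": True, "p4": True, "p5": False})
        test = pd.DataFrame(
            {"q": [0.005, np.nan, np.nan, 0.5], "diff": [1.0, np.nan, np.nan, 0.2]},
            index=["p1", "p2", "p3", "p4"],
        )
        out = pr.call_deps(det_l, det_m, test)
        assert out.loc["p1", "label"] == "liver_dominant"
        assert out.loc["p2", "label"] == "liver_only"
        assert out.loc["p3", "label"] == "muscle_only"
        assert out.loc["p4", "label"] == "non_dep"
        assert "p5" not in out.index  # detected in neither tissue: dropped

    def test_labels_partition_detected_proteins(self, rng):
        det_l = pd.Series(rng.random(50) < 0.8, index=[f"p{i}" for i in range(50)])
        det_m = pd.Series(rng.random(50) < 0.8, index=[f"p{i}" for i in range(50)])
        out = pr.call_deps(det_l, det_m, None)
        allowed = {"liver_dominant", "muscle_dominant", "liver_only", "muscle_only", "non_dep"}
        assert set(out["label"]) <= allowed


class TestProteinMrnaRatio:
    def test_arithmetic_direction(self):
        intens = pd.DataFrame({"r1": [1000.0], "r2": [1000.0]}, index=["p"])
        ratio = pr.protein_mrna_ratio(intens, pd.Series({"p": 10.0}), pd.Series({"p": True}))
        assert ratio.iloc[0] == pytest.approx(np.log(100.0))

    def test_zero_tpm_missing(self):
        intens = pd.DataFrame({"r1": [1000.0]}, index=["p"])
        ratio = pr.protein_mrna_ratio(intens, pd.Series({"p": 0.0}), pd.Series({"p": True}))
        assert np.isnan(ratio.iloc[0])

    def test_scale_cancellation(self):
        intens = pd.DataFrame({"r1": [500.0]}, index=["p"])
        r1 = pr.protein_mrna_ratio(intens, pd.Series({"p": 5.0}), pd.Series({"p": True}))
        r2 = pr.protein_mrna_ratio(intens * 2, pd.Series({"p": 10.0}), pd.Series({"p": True}))
        assert r1.iloc[0] == pytest.approx(r2.iloc[0])


class TestCallDrps:
    def test_collinear_points_give_no_drps(self):
        x = pd.Series(np.linspace(0, 5, 30), index=[f"p{i}" for i in range(30)])
        y = 2 * x + 1
        out = pr.call_drps(y, x)
        assert (out["label"] == "none").all()

    def test_planted_outlier_flagged_with_direction(self):
        rng = np.random.default_rng(4)
        n = 100
        x = pd.Series(rng.normal(0, 1, n), index=[f"p{i}" for i in range(n)])
        y = x + rng.normal(0, 0.05, n)
        sigma = 0.05
        y.iloc[0] += 5 * sigma * 20  # far above the line
        out = pr.call_drps(y, x)
        assert out.loc["p0", "label"] == "liver_drp"

    def test_shuffled_null_flags_symmetric_and_bounded(self, tiny_bundle):
        # shuffled pairing of the synthetic bundle's planted ratio structure
        truth = tiny_bundle["bundle"].truth
        rng = np.random.default_rng(0)
        resid = np.where(truth["drp_label"] == "liver", 1.1, 0.0) + rng.normal(0, 0.1, len(truth))
        y = pd.Series(resid, index=truth.index)
        x = pd.Series(rng.permutation(resid), index=truth.index)
        out = pr.call_drps(y, x)
        frac_l = (out["label"] == "liver_drp").mean()
        frac_m = (out["label"] == "muscle_drp").mean()
        assert frac_l < 0.15 and frac_m < 0.15

    def test_invariant_to_constant_shift_in_one_tissue(self, rng):
        n = 80
        x = pd.Series(rng.normal(0, 1, n), index=[f"p{i}" for i in range(n)])
        y = x + rng.normal(0, 0.2, n)
        base = pr.call_drps(y, x)
        shifted = pr.call_drps(y + 3.0, x)
        assert (base["label"] == shifted["label"]).all()

    def test_degenerate_regressor_errors(self):
        y = pd.Series(np.arange(20.0), index=[f"p{i}" for i in range(20)])
        x = pd.Series(np.ones(20), index=y.index)
        with pytest.raises(ValueError, match="degenerate"):
            pr.call_drps(y, x)

    def test_refit_all_variant_never_flags(self, rng):
        n = 50
        x = pd.Series(rng.normal(0, 1, n), index=[f"p{i}" for i in range(n)])
        y = x + rng.normal(0, 0.3, n)
        out = pr.call_drps(y, x, compare_to="refit_all")
        assert (out["label"] == "none").all()


class TestTopMotifOverlap:
    def test_counts_match_exhaustive_membership(self, rng):
        labels = pd.Series(
            rng.choice(["liver_drp", "muscle_drp", "none"], 60),
            index=[f"g{i}" for i in range(60)],
        )
        gene_set = {f"g{i}" for i in range(0, 60, 3)}
        res = pr.top_motif_overlap(labels, gene_set, "liver_drp")
        a = sum(1 for g in labels.index if labels[g] == "liver_drp" and g in gene_set)
        b = sum(1 for g in labels.index if labels[g] == "liver_drp" and g not in gene_set)
        c = sum(1 for g in labels.index if labels[g] != "liver_drp" and g in gene_set)
        d = sum(1 for g in labels.index if labels[g] != "liver_drp" and g not in gene_set)
        assert res["table"] == [[a, b], [c, d]]
        assert res["p_right"] == pytest.approx(fisher_exact([[a, b], [c, d]], "right"))

    def test_disjoint_set_zero_overlap(self):
        labels = pd.Series({"g1": "liver_drp", "g2": "none"})
        res = pr.top_motif_overlap(labels, {"gX"}, "liver_drp")
        assert res["table"][0][0] == 0

    def test_empty_set_errors(self):
        with pytest.raises(ValueError):
            pr.top_motif_overlap(pd.Series({"g1": "none"}), set(), "liver_drp")
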