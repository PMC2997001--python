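import numpy as np
import pandas as pd
import pytest
from scipy import stats

import statsmodels.formula.api as smf

from psfarray.arrays import summarize_probesets
from psfarray.homoeolog import (
    FITS_1TO1_ONLY,
    FITS_1TO2_ONLY,
    MID_PARENT,
    NON_ADDITIVE,
    RatioTable,
    bh_adjust,
    call_direction,
    classify_expression,
    compute_ep_et,
    concordance_filter,
    fit_ratio_model,
    parental_divergence,
    summarize_calls,
    summarize_counts,
)
from psfarray.homoeolog import test_contrasts as contrast_tests

from psfarray.psf import AT_SPECIFIC, TC_SPECIFIC
from psfarray.simulate import SimConfig, generate_experiment, truth_evaluation

from conftest import make_matrix, make_sheet


def psf_record(pairs_classes):
    idx = pd.MultiIndex.from_tuples(list(pairs_classes), names=("probeset_id", "probe_index"))
    return pd.DataFrame({"class": list(pairs_classes.values())}, index=idx)


class TestEpEt:
    def test_powers_of_two(self):
        m = make_matrix([[1024.0], [256.0], [256.0], [256.0]])
        rt = compute_ep_et(m, psf_record({("PS0", 1): AT_SPECIFIC}))
        assert rt.values.iloc[0, 0] == pytest.approx(2.0)
        assert rt.n_nonpsf.iloc[0] == 3

    def test_psf_at_nonpsf_mean_gives_zero(self):
        m = make_matrix([[300.0], [200.0], [400.0]])
        rt = compute_ep_et(m, psf_record({("PS0", 1): TC_SPECIFIC}))
        assert rt.values.iloc[0, 0] == pytest.approx(0.0)

    def test_arithmetic_mean_on_linear_scale(self):
        m = make_matrix([[512.0], [100.0], [200.0], [400.0]])
        rt = compute_ep_et(m, psf_record({("PS0", 1): AT_SPECIFIC}))
        assert rt.values.iloc[0, 0] == pytest.approx(9 - np.log2(233.333333), abs=1e-3)

    def test_log2_input_converted(self):
        m = make_matrix(np.log2([[1024.0], [256.0], [256.0], [256.0]]), scale="log2")
        rt = compute_ep_et(m, psf_record({("PS0", 1): AT_SPECIFIC}))
        assert rt.values.iloc[0, 0] == pytest.approx(2.0)

    def test_probeset_without_nonpsf_probe_excluded(self):
        m = make_matrix([[8.0], [4.0]])
        rec = psf_record({("PS0", 1): AT_SPECIFIC, ("PS0", 2): AT_SPECIFIC})
        with pytest.warns(UserWarning, match="zero non-PSF"):
            rt = compute_ep_et(m, rec)
        assert rt.values.empty
        assert rt.n_excluded_probesets == 1


def ratio_table(values, samples):
    idx = pd.MultiIndex.from_tuples([("PS0", 1)], names=("probeset_id", "probe_index"))
    return RatioTable(
        values=pd.DataFrame([values], index=idx, columns=samples),
        n_nonpsf=pd.Series([10], index=idx),
        psf_class=pd.Series([AT_SPECIFIC], index=idx),
    )


class TestRatioModel:
    sheet = make_sheet(["AT", "TC", "SN"], 4)
    values = [0.0, 0.0, 1.0, 1.0, 2.0, 2.0, 3.0, 3.0, 1.0, 1.0, 2.0, 2.0]

    def test_anova_example(self):
        rt = ratio_table(self.values, list(self.sheet["sample_id"]))
        fit = fit_ratio_model(rt, self.sheet)
        np.testing.assert_allclose(fit.means.iloc[0][["AT", "TC", "SN"]], [0.5, 2.5, 1.5])
        assert fit.mse.iloc[0] == pytest.approx(1 / 3)
        assert fit.df == 9

    def test_matches_statsmodels_anova(self):
        rng = np.random.default_rng(11)
        vals = rng.normal(0, 1, 12)
        rt = ratio_table(list(vals), list(self.sheet["sample_id"]))
        fit = fit_ratio_model(rt, self.sheet)
        frame = pd.DataFrame({"y": vals, "g": self.sheet["genotype"]})
        ols = smf.ols("y ~ C(g)", frame).fit()
        assert fit.mse.iloc[0] == pytest.approx(ols.mse_resid)
        assert fit.df == ols.df_resid

    def test_degenerate_all_equal(self):
        rt = ratio_table([1.0] * 12, list(self.sheet["sample_id"]))
        fit = fit_ratio_model(rt, self.sheet)
        assert fit.degenerate.iloc[0]
        tests = contrast_tests(fit)
        assert tests["SN_vs_mid11"]["p"].iloc[0] == 1.0

    def test_replicate_order_irrelevant(self):
        rt = ratio_table(self.values, list(self.sheet["sample_id"]))
        fit = fit_ratio_model(rt, self.sheet)
        shuffled = self.sheet.sample(frac=1, random_state=3)
        fit2 = fit_ratio_model(rt, shuffled)
        pd.testing.assert_frame_equal(fit.means[sorted(fit.means)], fit2.means[sorted(fit2.means)])
        np.testing.assert_allclose(fit.mse, fit2.mse)


class TestContrasts:
    sheet = make_sheet(["AT", "TC", "SN"], 4)
    values = [0.0, 0.0, 1.0, 1.0, 2.0, 2.0, 3.0, 3.0, 1.0, 1.0, 2.0, 2.0]

    def fit(self, values=None):
        rt = ratio_table(values or self.values, list(self.sheet["sample_id"]))
        return fit_ratio_model(rt, self.sheet)

    def test_balanced_means_null_one_to_one(self):
        tests = contrast_tests(self.fit())
        assert tests["SN_vs_mid11"]["estimate"].iloc[0] == pytest.approx(0.0)
        assert tests["SN_vs_mid11"]["p"].iloc[0] == pytest.approx(1.0)

    def test_one_to_two_against_t_oracle(self):
        tests = contrast_tests(self.fit())
        row = tests["SN_vs_mid12"].iloc[0]
        assert row["estimate"] == pytest.approx(-1 / 3, abs=1e-6)
        assert row["se"] == pytest.approx(0.3601, abs=1e-4)
        assert row["t"] == pytest.approx(-0.926, abs=1e-3)
        assert row["p"] == pytest.approx(0.379, abs=1e-3)
        # independent route: statsmodels t_test on the one-way model
        frame = pd.DataFrame({"y": self.values, "g": self.sheet["genotype"]})
        ols = smf.ols("y ~ 0 + C(g)", frame).fit()
        order = [n.split("[")[1].rstrip("]") for n in ols.params.index]
        weights = {"AT": -1 / 3, "SN": 1.0, "TC": -2 / 3}
        tt = ols.t_test([weights[g] for g in order])
        assert row["p"] == pytest.approx(float(tt.pvalue), abs=1e-10)

    def test_shift_linearity(self):
        shifted = self.values[:8] + [v + 0.7 for v in self.values[8:]]
        t0 = contrast_tests(self.fit())["SN_vs_mid11"]["estimate"].iloc[0]
        t1 = contrast_tests(self.fit(shifted))["SN_vs_mid11"]["estimate"].iloc[0]
        assert t1 - t0 == pytest.approx(0.7)


class TestBH:
    def test_all_ones_nothing_significant(self):
        reject, q = bh_adjust([1.0, 1.0, 1.0])
        assert not reject.any()

    def test_step_up_example(self):
        reject, q = bh_adjust([0.01, 0.02, 0.04, 0.8], alpha=0.05)
        assert reject.tolist() == [True, True, False, False]

    def test_adjusted_monotone_in_raw_p(self):
        rng = np.random.default_rng(12)
        p = rng.uniform(0, 1, 40)
        _, q = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_matches_manual_step_up(self):
        rng = np.random.default_rng(13)
        p = rng.uniform(0, 1, 25)
        reject, _ = bh_adjust(p, alpha=0.05)
        # oracle: largest k with p_(k) <= k/m * alpha
        srt = np.sort(p)
        ks = np.nonzero(srt <= (np.arange(1, 26) / 25) * 0.05)[0]
        n_reject = (ks[-1] + 1) if ks.size else 0
        assert reject.sum() == n_reject


class TestCategoriesAndDirections:
    def test_category_table(self):
        cats = classify_expression([False, True, True, False], [False, True, False, True])
        assert cats.tolist() == [MID_PARENT, NON_ADDITIVE, FITS_1TO2_ONLY, FITS_1TO1_ONLY]

    def test_direction_sign_and_attribution(self):
        idx = pd.MultiIndex.from_tuples(
            [("A", 1), ("A", 2), ("B", 1)], names=("probeset_id", "probe_index")
        )
        calls = pd.DataFrame(
            {
                "psf_class": [AT_SPECIFIC, TC_SPECIFIC, AT_SPECIFIC],
                "category": [NON_ADDITIVE, NON_ADDITIVE, MID_PARENT],
                "est11": [0.8, -0.8, 0.9],
            },
            index=idx,
        )
        out = call_direction(calls)
        assert out["direction"].tolist() == ["up", "down", "none"]

    def test_direction_antisymmetry(self):
        idx = pd.MultiIndex.from_tuples([("A", 1)], names=("probeset_id", "probe_index"))
        base = dict(psf_class=[AT_SPECIFIC], category=[NON_ADDITIVE])
        up = call_direction(pd.DataFrame({**base, "est11": [0.8]}, index=idx))
        down = call_direction(pd.DataFrame({**base, "est11": [-0.8]}, index=idx))
        assert up["direction"].iloc[0] == "up" and down["direction"].iloc[0] == "down"


class TestConcordanceFilter:
    @staticmethod
    def calls(rows):
        idx = pd.MultiIndex.from_tuples(
            [(r[0], i + 1) for i, r in enumerate(rows)], names=("probeset_id", "probe_index")
        )
        return pd.DataFrame(
            {
                "psf_class": [r[1] for r in rows],
                "category": [NON_ADDITIVE if r[2] != "none" else MID_PARENT for r in rows],
                "est11": [1.0 if r[2] == "up" else (-1.0 if r[2] == "down" else 0.0) for r in rows],
                "direction": [r[2] for r in rows],
            },
            index=idx,
        )

    def test_agreeing_probeset_retained(self):
        calls = self.calls([("A", AT_SPECIFIC, "up"), ("A", AT_SPECIFIC, "up")])
        kept, removed = concordance_filter(calls)
        assert len(kept) == 2 and removed == 0

    def test_disagreeing_probeset_removed(self):
        calls = self.calls([("A", AT_SPECIFIC, "up"), ("A", AT_SPECIFIC, "down")])
        kept, removed = concordance_filter(calls)
        assert kept.empty and removed == 1

    def test_cross_class_disagreement_retained(self):
        calls = self.calls([("A", AT_SPECIFIC, "up"), ("A", TC_SPECIFIC, "down")])
        kept, removed = concordance_filter(calls)
        assert len(kept) == 2 and removed == 0

    def test_single_psf_probesets_never_removed(self):
        calls = self.calls([("A", AT_SPECIFIC, "up"), ("B", AT_SPECIFIC, "down")])
        kept, removed = concordance_filter(calls)
        assert len(kept) == 2 and removed == 0


class TestSummaries:
    def test_study_scale_proportions(self):
        counts = pd.DataFrame(
            {"down": [705, 406], "up": [1601, 3718], "mid_parent": [13840, 14399]},
            index=["AT_type", "TC_type"],
        )
        pct = summarize_counts(counts)
        assert pct["AT_type_down_pct"] == pytest.approx(30.6, abs=0.05)
        assert pct["AT_type_up_pct"] == pytest.approx(69.4, abs=0.05)
        assert pct["TC_type_up_pct"] == pytest.approx(90.2, abs=0.05)
        assert pct["TC_type_share_of_up_pct"] == pytest.approx(69.9, abs=0.05)
        assert pct["up_share_of_nonadditive_pct"] == pytest.approx(82.7, abs=0.05)

    def test_shares_sum_to_hundred(self):
        counts = pd.DataFrame(
            {"down": [3, 7], "up": [5, 11], "mid_parent": [20, 30]},
            index=["AT_type", "TC_type"],
        )
        pct = summarize_counts(counts)
        assert pct["AT_type_down_pct"] + pct["AT_type_up_pct"] == pytest.approx(100.0)
        assert (
            pct["AT_type_share_of_up_pct"] + pct["TC_type_share_of_up_pct"]
        ) == pytest.approx(100.0)
        assert (
            pct["up_share_of_nonadditive_pct"] + pct["down_share_of_nonadditive_pct"]
        ) == pytest.approx(100.0)


class TestParentalDivergence:
    def test_identical_parents_no_divergence(self):
        sheet = make_sheet(["AT", "TC", "SN"], 4)
        rng = np.random.default_rng(14)
        base = rng.normal(8, 1, 50)
        expr = pd.DataFrame(
            np.tile(base[:, None], 12) + rng.normal(0, 0.01, (50, 12)),
            index=pd.Index([f"PS{i}" for i in range(50)], name="probeset_id"),
            columns=list(sheet["sample_id"]),
        )
        res = parental_divergence(expr, sheet)
        assert res.frac_divergent <= 0.05

    def test_recovers_fixed_one_log2_divergence(self):
        cfg = SimConfig(
            seed=21,
            n_probesets=600,
            parental_divergence_fraction=0.5,
            divergence_log2_effect=1.0,
        )
        m, sheet, truth = generate_experiment(cfg)
        expr = summarize_probesets(m)
        res = parental_divergence(expr, sheet)
        assert res.frac_divergent == pytest.approx(0.5, abs=0.05)
        # detected sets match the generated divergent genes
        agree = (res.divergent == truth.genes["divergent"]).mean()
        assert agree >= 0.9

    def test_crosstab_partitions_nonadditive_calls(self, recovery_sim, recovery_classification):
        m, sheet, _ = recovery_sim
        expr = summarize_probesets(m)
        calls = recovery_classification.calls
        res = parental_divergence(expr, sheet, calls=calls)
        n_nonadd = int((calls["category"] == NON_ADDITIVE).sum())
        assert res.crosstab["n"].sum() == n_nonadd


class TestLabelSwap:
    def test_swapping_parent_labels_flips_class_and_preserves_one_to_one(self, small_sim):
        m, sheet, truth = small_sim
        from psfarray.psf import SamConfig, discover_psfs

        res = discover_psfs(m, sheet, SamConfig(target_fdr=0.1, seed=1))
        swapped_sheet = sheet.copy()
        swapped_sheet["genotype"] = sheet["genotype"].map(
            {"AT": "TC", "TC": "AT", "SN": "SN", "MIX": "MIX"}
        )
        res2 = discover_psfs(m, swapped_sheet, SamConfig(target_fdr=0.1, seed=1))
        np.testing.assert_allclose(res2.records["d"], -res.records["d"], atol=1e-10)
        sig = res.records["significant"]
        flipped = res.records.loc[sig, "class"].map(
            {AT_SPECIFIC: TC_SPECIFIC, TC_SPECIFIC: AT_SPECIFIC}
        )
        assert (res2.records.loc[sig, "class"] == flipped).all()
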