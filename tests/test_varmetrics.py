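"""Positional-variability diagnostics."""

import numpy as np
import pandas as pd
import pytest

import methvar as mv
from methvar import batchcorrect, synth, varmetrics
from methvar.core import ValidationError
from methvar.varmetrics import (
    bead_cv,
    boxplot_stats,
    chamber_profile,
    grubbs_test,
    intensity_bin_bias,
    lowlevel_correlations,
    oneway_f,
    pca_cluster,
    sd_ratio,
    variance_decomposition,
    within_subject_zscores,
)


def _sheet(rows):
    return mv.SampleSheet(
        pd.DataFrame(
            rows, columns=["sample_id", "subject", "slide", "chamber", "pooled"]
        )
    )


class TestZScores:
    def test_unit_example(self):
        sheet = _sheet([(f"s{i}", "A", "sl", i + 1, True) for i in range(3)])
        mat = pd.DataFrame([[1.0, 2.0, 3.0]], index=["p"], columns=["s0", "s1", "s2"])
        z = within_subject_zscores(mat, sheet)
        np.testing.assert_allclose(z.to_numpy(), [[-1.0, 0.0, 1.0]])

    def test_constant_probe_is_omitted(self):
        sheet = _sheet([(f"s{i}", "A", "sl", i + 1, True) for i in range(3)])
        mat = pd.DataFrame([[0.5, 0.5, 0.5]], index=["p"], columns=["s0", "s1", "s2"])
        assert within_subject_zscores(mat, sheet).isna().all().all()

    def test_centering_within_each_subject(self, biased_betas, biased_dataset):
        _, sheet, _, _ = biased_dataset
        pooled = sheet.pooled_only()
        z = within_subject_zscores(biased_betas[pooled.sample_ids], pooled)
        for subject, samples in pooled.groups("subject").items():
            means = z[samples].mean(axis=1).dropna()
            assert np.abs(means.to_numpy()).max() < 1e-12

    def test_single_replicate_subject_raises(self):
        sheet = _sheet([("s0", "A", "sl", 1, True), ("s1", "B", "sl", 2, True),
                        ("s2", "B", "sl", 3, True)])
        mat = pd.DataFrame([[0.1, 0.2, 0.3]], columns=["s0", "s1", "s2"])
        with pytest.raises(ValidationError, match="'A'"):
            within_subject_zscores(mat, sheet)


class TestChamberProfile:
    def test_null_data_profiles_center_at_zero(self, null_dataset):
        _, sheet, _, lowlevel = null_dataset
        beta = mv.clean_matrix(mv.betas_from_lowlevel(lowlevel))
        pooled = sheet.pooled_only()
        z = within_subject_zscores(beta[pooled.sample_ids], pooled)
        prof = chamber_profile(z, pooled)
        zstats = prof.summary["mean"].abs() / prof.summary["sem"]
        assert zstats.max() < 4.0

    def test_dim_chamber_shows_negative_fi_profile(self, biased_dataset):
        _, sheet, _, lowlevel = biased_dataset
        probes = lowlevel.manifest.type_ii_probes()
        fi = lowlevel.mean_fi["green"].loc[probes]
        pooled = sheet.pooled_only()
        z = within_subject_zscores(fi[pooled.sample_ids], pooled)
        prof = chamber_profile(z, pooled)
        z1 = prof.summary.loc[1, "mean"] / prof.summary.loc[1, "sem"]
        assert z1 < -6.0
        others = prof.summary.drop(index=1)
        assert (others["mean"] / others["sem"]).abs().max() < z1 * -0.5

    def test_chamber_bias_does_not_leak_into_slide_profile(self, biased_dataset):
        """Grouping by slide on chamber-biased data shows no slide effect."""
        _, sheet, _, lowlevel = biased_dataset
        probes = lowlevel.manifest.type_ii_probes()
        fi = lowlevel.mean_fi["green"].loc[probes]
        pooled = sheet.pooled_only()
        z = within_subject_zscores(fi[pooled.sample_ids], pooled)
        prof = chamber_profile(z, pooled, group_by="slide")
        # every slide hosts each chamber equally often, so the dim chamber
        # averages out: slide means stay within a few SE of zero
        zstats = prof.summary["mean"].abs() / prof.summary["sem"]
        assert zstats.max() < 4.0

    def test_completeness_filter(self):
        sheet = _sheet([(f"s{i}", "A", "sl", i + 1, True) for i in range(4)])
        mat = pd.DataFrame(
            np.random.default_rng(0).uniform(size=(10, 4)),
            columns=[f"s{i}" for i in range(4)],
        )
        z = within_subject_zscores(mat, sheet)
        z.iloc[0, :2] = np.nan  # 50% completeness -> excluded at 0.9
        prof = chamber_profile(z, sheet, min_completeness=0.9)
        assert len(prof.profile) == 9


class TestSDRatio:
    def test_identical_values_give_zero(self):
        sheet = _sheet(
            [("a1", "A", "sl1", 1, True), ("a2", "A", "sl1", 2, True),
             ("b1", "B", "sl1", 3, True), ("b2", "B", "sl1", 4, True)]
        )
        mat = pd.DataFrame([[0.3] * 4], columns=["a1", "a2", "b1", "b2"])
        assert sd_ratio(mat, sheet).iloc[0] == 0.0

    def test_constructed_equal_within_and_across_sd(self):
        """Within-subject SD = overall SD = 0.1 -> ratio 0.1 / 0.1001."""
        d = 0.1 / np.sqrt(2)
        a, b = 0.5, 0.4  # (a-b)^2 + 4 d^2 = 0.03 -> overall variance 0.01
        sheet = _sheet(
            [("a1", "A", "sl1", 1, True), ("a2", "A", "sl1", 2, True),
             ("b1", "B", "sl1", 3, True), ("b2", "B", "sl1", 4, True)]
        )
        mat = pd.DataFrame(
            [[a - d, a + d, b - d, b + d]], columns=["a1", "a2", "b1", "b2"]
        )
        within = np.mean([mat[["a1", "a2"]].std(axis=1), mat[["b1", "b2"]].std(axis=1)])
        across = float(mat.std(axis=1).iloc[0])
        assert within == pytest.approx(0.1, abs=1e-12)
        assert across == pytest.approx(0.1, abs=1e-12)
        assert sd_ratio(mat, sheet).iloc[0] == pytest.approx(0.1 / 0.1001, abs=1e-12)

    def test_scale_relation(self, biased_betas, biased_dataset):
        """Scaling all values by c scales numerator and (denominator - offset)."""
        _, sheet, _, _ = biased_dataset
        mat = biased_betas.iloc[:50]
        r1 = sd_ratio(mat, sheet, offset=0.0)
        r2 = sd_ratio(mat * 3.0, sheet, offset=0.0)
        pd.testing.assert_series_equal(r1, r2, rtol=1e-10)

    def test_requires_two_subjects(self):
        sheet = _sheet([("a1", "A", "sl1", 1, True), ("a2", "A", "sl1", 2, True)])
        mat = pd.DataFrame([[0.1, 0.2]], columns=["a1", "a2"])
        with pytest.raises(ValidationError):
            sd_ratio(mat, sheet)


class TestBeadCV:
    def test_cv_arithmetic(self, biased_dataset):
        _, sheet, _, lowlevel = biased_dataset
        result = bead_cv(lowlevel, sheet)
        probes = lowlevel.manifest.type_ii_probes()
        p, s = probes[0], lowlevel.sample_ids[0]
        expected = (
            lowlevel.sd_fi["green"].loc[p, s] / lowlevel.mean_fi["green"].loc[p, s]
        )
        assert result.cv["green"].loc[p, s] == pytest.approx(expected)

    def test_noisy_chamber_ranks_highest_in_red(self, biased_dataset):
        _, sheet, _, lowlevel = biased_dataset
        summary = bead_cv(lowlevel, sheet).summary
        red = summary[summary["channel"] == "red"].set_index("chamber")["median"]
        assert red.idxmax() == 8
        green = summary[summary["channel"] == "green"].set_index("chamber")["median"]
        assert green.idxmax() != 8 or green[8] < red[8]

    def test_zero_mean_excluded_and_counted(self):
        from conftest import make_lowlevel

        green = np.array([[0.0, 100.0], [200.0, 300.0]])
        sd = np.array([[5.0, 10.0], [20.0, 30.0]])
        lowlevel = make_lowlevel(green, green + 1, sd=sd)
        sheet = _sheet([("s0", "A", "sl", 1, True), ("s1", "A", "sl", 2, True)])
        result = bead_cv(lowlevel, sheet)
        assert np.isnan(result.cv["green"].iloc[0, 0])
        assert result.summary["n_excluded"].sum() > 0

    def test_boxplot_stats_hides_far_values(self):
        vals = np.concatenate([np.random.default_rng(1).normal(0, 1, 1000), [50.0]])
        stats = boxplot_stats(vals)
        assert stats["n_hidden"] >= 1
        assert stats["whisker_hi"] < 50.0


class TestIntensityBins:
    def test_multiplicative_gain_gives_proportional_fi_deviation(self):
        cfg = synth.biased_scenario(n_probes=8000, seed=2)
        sheet, truth, lowlevel = synth.simulate_dataset(cfg)
        fi = lowlevel.mean_fi["green"].loc[lowlevel.manifest.type_ii_probes()]
        table = intensity_bin_bias(fi, lowlevel, sheet, "green", "fi_deviation")
        slope = np.polyfit(
            table["bin_median_fi"].to_numpy(), table[1].to_numpy(), 1
        )[0]
        # chamber 1 sits 0.8x below the within-subject median -> slope ~ -0.2
        assert slope == pytest.approx(-0.2, rel=0.10)

    def test_null_bins_center_at_zero(self, null_dataset):
        _, sheet, _, lowlevel = null_dataset
        fi = lowlevel.mean_fi["green"].loc[lowlevel.manifest.type_ii_probes()]
        table = intensity_bin_bias(fi, lowlevel, sheet, "green", "fi_deviation")
        dev = table.drop(columns="bin_median_fi")
        z = dev.mean(axis=0) / (dev.std(axis=0, ddof=1) / np.sqrt(len(dev)))
        assert z.abs().max() < 4.0

    def test_green_noise_hits_low_green_fi_betas_hardest(self):
        cfg = synth.SimulationConfig(
            n_probes=8000, seed=3, chamber_cv_inflation={4: {"green": 2.5}}
        )
        sheet, truth, lowlevel = synth.simulate_dataset(cfg)
        beta = mv.clean_matrix(mv.betas_from_lowlevel(lowlevel))
        table = intensity_bin_bias(beta, lowlevel, sheet, "green", "beta_absdev")
        low = table.iloc[:25][4].mean()
        high = table.iloc[-25:][4].mean()
        assert low > high

    def test_few_probes_reduce_bin_count_with_warning(self, null_dataset):
        _, sheet, _, lowlevel = null_dataset
        fi = lowlevel.mean_fi["green"].loc[
            lowlevel.manifest.type_ii_probes()[:60]
        ]
        with pytest.warns(UserWarning, match="bin count"):
            table = intensity_bin_bias(fi, lowlevel, sheet, "green", "fi_deviation")
        assert len(table) <= 30


class TestVarianceDecomposition:
    def test_matches_oneway_anova_when_no_grouping(self):
        """Balanced one-way chamber design with every sample its own subject:
        the mixed-model F equals the classical ANOVA F."""
        rng = np.random.default_rng(41)
        rows = [(f"s{i}", f"u{i}", f"sl{i // 8}", i % 8 + 1, True) for i in range(32)]
        sheet = _sheet(rows)
        mat = pd.DataFrame(
            rng.normal(0.5, 0.1, (40, 32)), columns=[f"s{i}" for i in range(32)]
        )
        vd = variance_decomposition(mat, sheet, fixed_factors=("chamber",))
        chamber = np.array([i % 8 + 1 for i in range(32)])
        # brute-force one-way ANOVA
        data = mat.to_numpy()
        grand = data.mean(axis=1)
        ssb = np.zeros(len(data))
        ssw = np.zeros(len(data))
        for c in range(1, 9):
            idx = np.flatnonzero(chamber == c)
            gm = data[:, idx].mean(axis=1)
            ssb += len(idx) * (gm - grand) ** 2
            ssw += ((data[:, idx] - gm[:, None]) ** 2).sum(axis=1)
        f_expected = (ssb / 7) / (ssw / (32 - 8))
        np.testing.assert_allclose(
            vd.frame["F_chamber"].to_numpy(), f_expected, atol=1e-6
        )

    def test_zero_subject_variance_recovered_at_boundary(self):
        cfg = synth.SimulationConfig(
            n_probes=500, seed=13, subject_effect_sd=0.0, prep_noise_sd=0.0
        )
        sheet, truth, lowlevel = synth.simulate_dataset(cfg)
        beta = mv.clean_matrix(mv.betas_from_lowlevel(lowlevel))
        vd = variance_decomposition(beta, sheet)
        ratio = vd.frame["sigma2_subject"] / vd.frame["sigma2_resid"]
        assert ratio.median() < 0.1

    def test_chamber_bias_raises_chamber_f_not_slide_f(
        self, biased_betas, biased_dataset
    ):
        _, sheet, _, _ = biased_dataset
        vd = variance_decomposition(biased_betas, sheet)
        assert vd.frame["F_chamber"].median() > 1.5 * vd.frame["F_slide"].median()

    def test_aliased_fixed_design_rejected(self):
        # slide is a function of chamber -> rank deficient
        rows = [
            (f"s{i}", f"u{i}", f"sl{i % 2}", i % 2 + 1, True) for i in range(8)
        ]
        # make cells unique by spreading chambers 1..8 over two slides keyed
        # to parity, then alias slide with chamber parity
        rows = [
            (f"s{i}", f"u{i}", f"sl{(i % 8) + 1}", (i % 8) + 1, True)
            for i in range(16)
        ]
        sheet = _sheet(rows[:8])
        mat = pd.DataFrame(
            np.random.default_rng(5).normal(size=(3, 8)),
            columns=[f"s{i}" for i in range(8)],
        )
        with pytest.raises(ValidationError):
            variance_decomposition(mat, sheet)

    def test_agrees_with_oneway_f_helper(self):
        rng = np.random.default_rng(55)
        mat = pd.DataFrame(
            rng.normal(size=(20, 12)), columns=[f"s{i}" for i in range(12)]
        )
        labels = pd.Series([1] * 4 + [2] * 4 + [3] * 4, index=mat.columns)
        from scipy import stats as st

        groups = [mat.loc[:, labels == g].to_numpy() for g in (1, 2, 3)]
        expected = st.f_oneway(*groups, axis=1).statistic
        np.testing.assert_allclose(oneway_f(mat, labels), expected, rtol=1e-10)


class TestPCACluster:
    def test_duplicate_samples_merge_first(self):
        rng = np.random.default_rng(61)
        mat = pd.DataFrame(
            rng.normal(size=(50, 6)), columns=[f"s{i}" for i in range(6)]
        )
        mat["s5"] = mat["s4"]  # exact duplicates
        sheet = _sheet([(f"s{i}", "A" if i < 3 else "B", "sl", i + 1, True)
                        for i in range(6)])
        res = pca_cluster(mat, sheet, n_components=3)
        assert res.linkage_matrix[0, 2] == pytest.approx(0.0, abs=1e-9)
        assert {int(res.linkage_matrix[0, 0]), int(res.linkage_matrix[0, 1])} == {4, 5}

    def test_component_truncation_warns(self, null_dataset):
        _, sheet, _, lowlevel = null_dataset
        beta = mv.clean_matrix(mv.betas_from_lowlevel(lowlevel))
        with pytest.warns(UserWarning, match="n_components"):
            res = pca_cluster(beta, sheet, n_components=200)
        assert res.scores.shape[1] == len(beta.columns) - 1

    def test_purity_invariant_to_sample_order(self, biased_betas, biased_dataset):
        _, sheet, _, _ = biased_dataset
        res1 = pca_cluster(biased_betas, sheet)
        cols = list(np.random.default_rng(8).permutation(biased_betas.columns))
        res2 = pca_cluster(biased_betas[cols], sheet)
        assert res1.purity == res2.purity


class TestGrubbs:
    def test_worked_example(self):
        G, p = grubbs_test([1.0, 2.0, 3.0, 10.0])
        assert G == pytest.approx(6.0 / np.sqrt(50.0 / 3.0), abs=1e-4)
        # hand-derived p: t^2 = n(n-2)G^2 / ((n-1)^2 - nG^2), p = 2n*sf(t, n-2)
        from scipy import stats as st

        t2 = 4 * 2 * G * G / (9 - 4 * G * G)
        assert p == pytest.approx(min(1.0, 8 * st.t.sf(np.sqrt(t2), 2)), abs=1e-12)

    def test_symmetric_data_not_flagged(self):
        _, p = grubbs_test([-1.0, 0.0, 1.0])
        assert p > 0.5

    def test_maximal_statistic_at_n3(self):
        """x = (0, 0, 1) attains the Grubbs bound (n-1)/sqrt(n); p -> 0."""
        G, p = grubbs_test([0.0, 0.0, 1.0])
        assert G == pytest.approx(2.0 / np.sqrt(3.0), abs=1e-12)
        assert p < 1e-6  # the bound is attained up to floating point

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValidationError):
            grubbs_test([1.0, 1.0, 1.0])
        with pytest.raises(ValidationError):
            grubbs_test([1.0, 2.0])


@pytest.fixture(scope="module")
def sparse_bead_dataset():
    cfg = synth.SimulationConfig(
        n_probes=6000, seed=17, bead_count_mean=5.0, background_sd=10.0
    )
    return synth.simulate_dataset(cfg)


class TestLowlevelCorrelations:

    def _beta_sd(self, sheet, lowlevel):
        beta = mv.betas_from_lowlevel(lowlevel)
        groups = sheet.groups("subject")
        return pd.concat(
            [beta[s].std(axis=1, ddof=1) for s in groups.values()], axis=1
        ).mean(axis=1)

    def test_bead_count_inversely_correlated_with_beta_sd(self, sparse_bead_dataset):
        sheet, truth, lowlevel = sparse_bead_dataset
        corr = lowlevel_correlations(lowlevel, self._beta_sd(sheet, lowlevel))
        assert corr.loc["n_beads", "spearman"] < 0

    def test_shuffled_beta_sd_kills_correlations(self, sparse_bead_dataset):
        sheet, truth, lowlevel = sparse_bead_dataset
        beta_sd = self._beta_sd(sheet, lowlevel)
        shuffled = pd.Series(
            np.random.default_rng(9).permutation(beta_sd.to_numpy()),
            index=beta_sd.index,
        )
        corr = lowlevel_correlations(lowlevel, shuffled)
        n = len(lowlevel.manifest.type_ii_probes())
        assert corr[["pearson", "spearman"]].abs().to_numpy().max() < 3 / np.sqrt(n)

    def test_spearman_invariant_under_monotone_transform(self, sparse_bead_dataset):
        sheet, truth, lowlevel = sparse_bead_dataset
        beta_sd = self._beta_sd(sheet, lowlevel)
        a = lowlevel_correlations(lowlevel, beta_sd)
        b = lowlevel_correlations(lowlevel, np.exp(5 * beta_sd))
        np.testing.assert_allclose(a["spearman"], b["spearman"], atol=1e-12)

    def test_zero_variance_feature_flagged(self):
        from conftest import make_lowlevel

        green = np.full((6, 4), 100.0)
        lowlevel = make_lowlevel(green, green.copy())
        beta_sd = pd.Series(
            np.random.default_rng(2).uniform(size=6), index=lowlevel.probe_ids
        )
        corr = lowlevel_correlations(lowlevel, beta_sd)
        assert corr["degenerate"].any()
        assert corr.loc["green_fi", "pearson"] != corr.loc["green_fi", "pearson"]
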