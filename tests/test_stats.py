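"""Biomarker statistics: logistic fits, H-L calibration, group tests, BH."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from apobecsig.stats import (
    bh_adjust,
    compare_predictors,
    exposure_score_association,
    fit_logistic,
    group_compare,
    hosmer_lemeshow,
    immune_score,
    quartile_groups,
)


class TestFitLogistic:
    def test_symmetric_null_gives_zero_slope(self):
        fit = fit_logistic([0, 0, 1, 1], [0, 1, 0, 1])
        assert fit.beta1 == pytest.approx(0.0, abs=1e-8)
        np.testing.assert_allclose(fit.fitted_probabilities, 0.5, atol=1e-8)
        assert not fit.separation_detected

    def test_complete_separation_flagged(self):
        fit = fit_logistic([0, 0, 1, 1], [0, 0, 1, 1])
        assert fit.separation_detected

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic([1, 2, 3], [1, 1, 1])

    def test_parameter_recovery(self):
        rng = np.random.default_rng(321)
        n, b0, b1 = 500, -1.0, 0.05
        x = rng.uniform(0, 100, n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(b0 + b1 * x)))).astype(float)
        fit = fit_logistic(x, y)
        assert fit.converged and not fit.separation_detected
        assert abs(fit.beta1 - b1) < 3 * fit.beta1_se


class TestHosmerLemeshow:
    def perfectly_calibrated(self):
        # four distinct probability levels, exact event fractions
        p = np.repeat([0.2, 0.4, 0.6, 0.8], 10)
        y = np.concatenate([
            np.r_[np.ones(2), np.zeros(8)],
            np.r_[np.ones(4), np.zeros(6)],
            np.r_[np.ones(6), np.zeros(4)],
            np.r_[np.ones(8), np.zeros(2)],
        ])
        return p, y

    def make_fit(self, p):
        from apobecsig.stats import LogisticFit
        return LogisticFit("x", 0.0, 0.0, np.asarray(p, float), True, False)

    def test_perfect_calibration_chi2_zero(self):
        p, y = self.perfectly_calibrated()
        res = hosmer_lemeshow(self.make_fit(p), y, g=4)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_brute_force_bin_table(self):
        """chi2 equals an independent recomputation over the bins."""
        rng = np.random.default_rng(7)
        p = np.sort(rng.uniform(0.05, 0.95, 40))
        y = (rng.random(40) < p).astype(float)
        res = hosmer_lemeshow(self.make_fit(p), y, g=4)
        # brute force: same quantile breaks, explicit python loops
        breaks = np.unique(np.quantile(p, [0.25, 0.5, 0.75]))
        bins = [[] for _ in range(len(breaks) + 1)]
        for pi, yi in zip(p, y):
            k = sum(pi > b for b in breaks)
            bins[k].append((pi, yi))
        chi2 = 0.0
        for members in bins:
            if not members:
                continue
            o1 = sum(yi for _, yi in members)
            e1 = sum(pi for pi, _ in members)
            o0 = len(members) - o1
            e0 = len(members) - e1
            chi2 += (o1 - e1) ** 2 / e1 + (o0 - e0) ** 2 / e0
        assert res.chi2 == pytest.approx(chi2, rel=1e-12)
        assert res.df == res.g - 2
        assert res.bin_table["observed_events"].sum() == y.sum()

    def test_flip_invariance(self):
        """Relabeling events with p -> 1-p leaves chi2 unchanged."""
        rng = np.random.default_rng(17)
        p = rng.uniform(0.1, 0.9, 60)
        y = (rng.random(60) < p).astype(float)
        a = hosmer_lemeshow(self.make_fit(p), y, g=6)
        b = hosmer_lemeshow(self.make_fit(1 - p), 1 - y, g=6)
        assert a.chi2 == pytest.approx(b.chi2, rel=1e-9)

    def test_well_specified_rejection_rate(self):
        """Type-I error of the H-L test near nominal on true models."""
        rng = np.random.default_rng(2024)
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            x = rng.normal(size=300)
            prob = 1 / (1 + np.exp(-(0.2 + 0.8 * x)))
            y = (rng.random(300) < prob).astype(float)
            fit = fit_logistic(x, y)
            res = hosmer_lemeshow(fit, y, g=10)
            rejections += res.p_value < 0.05
        assert 0.02 < rejections / n_rep < 0.10


class TestComparePredictors:
    def cohort(self, seed=5, n=60):
        rng = np.random.default_rng(seed)
        tcw = rng.gamma(0.7, 30, n).round()
        total = tcw + rng.gamma(2.0, 100, n).round()
        p = 1 / (1 + np.exp(-(-1.5 + 0.08 * tcw)))
        benefit = np.where(rng.random(n) < p, "DCB", "NDB")
        tcw_table = pd.DataFrame(
            {"tcw_count": tcw, "total_count": total},
            index=pd.Index([f"S{i}" for i in range(n)], name="sample_id"),
        )
        labels = pd.DataFrame(
            {"benefit": benefit},
            index=pd.Index([f"S{i}" for i in range(n)], name="sample_id"),
        )
        return tcw_table, labels

    def test_report_structure_and_group_means(self):
        tcw_table, labels = self.cohort()
        report = compare_predictors(tcw_table, labels)
        assert report["n_dcb"] + report["n_ndb"] == report["n_samples"]
        tcw_stats = report["predictors"]["tcw_count"]
        # DCB samples carry more TCW mutations by construction
        assert tcw_stats["dcb_mean"] > tcw_stats["ndb_mean"]
        assert tcw_stats["fold_change"] > 1.5
        assert tcw_stats["beta1"] > 0
        assert 0 <= tcw_stats["hl_p_value"] <= 1

    def test_single_class_labels_rejected(self):
        tcw_table, labels = self.cohort()
        labels["benefit"] = "DCB"
        with pytest.raises(ValueError):
            compare_predictors(tcw_table, labels)

    def test_na_labels_excluded(self):
        tcw_table, labels = self.cohort()
        labels.iloc[:5, 0] = "NA"
        report = compare_predictors(tcw_table, labels)
        assert report["n_excluded_na"] == 5
        assert report["n_samples"] == len(labels) - 5

    def test_disjoint_join_rejected(self):
        tcw_table, labels = self.cohort()
        labels.index = "X" + labels.index
        with pytest.raises(ValueError):
            compare_predictors(tcw_table, labels)


class TestQuartileGroups:
    def test_hand_case_one_to_eight(self):
        s = pd.Series([1, 2, 3, 4, 5, 6, 7, 8], index=list("abcdefgh"), dtype=float)
        groups = quartile_groups(s)["group"]
        assert set(groups[groups == "DOWN"].index) == {"a", "b"}
        assert set(groups[groups == "UP"].index) == {"g", "h"}
        assert (groups[list("cdef")] == "MID").all()

    def test_degenerate_ties_all_mid(self):
        s = pd.Series([5.0] * 8)
        with pytest.warns(UserWarning):
            groups = quartile_groups(s)["group"]
        assert (groups == "MID").all()

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            quartile_groups(pd.Series([1.0, 2.0, 3.0]))


class TestGroupCompare:
    def test_identical_groups_null(self):
        res = group_compare([1.0, 2.0, 3.5], [1.0, 2.0, 3.5], method="t")
        assert res.p_value >= 0.99

    def test_zero_variance_identical(self):
        with pytest.warns(UserWarning):
            res = group_compare([2.0, 2.0], [2.0, 2.0], method="t")
        assert res.p_value == 1.0

    def test_wilcoxon_matches_exhaustive_enumeration(self):
        """Exact p over all C(6,3)=20 rank splits of two groups of 3."""
        a, b = [1.0, 5.0, 9.0], [2.0, 3.0, 7.0]
        res = group_compare(a, b, method="wilcoxon")
        pooled = sorted(a + b)
        observed_u = sum(
            sum(1 for y in b if x > y) for x in a
        )
        count_extreme = 0
        splits = 0
        for combo in itertools.combinations(range(6), 3):
            ga = [pooled[i] for i in combo]
            gb = [pooled[i] for i in range(6) if i not in combo]
            u = sum(sum(1 for y in gb if x > y) for x in ga)
            # two-sided: as or more extreme in either direction
            if abs(u - 4.5) >= abs(observed_u - 4.5):
                count_extreme += 1
            splits += 1
        assert splits == 20
        assert res.p_value == pytest.approx(count_extreme / splits)
        assert res.method == "wilcoxon"

    def test_auto_routes_counts_to_wilcoxon_and_continuous_to_t(self):
        counts_res = group_compare([1, 2, 3, 4], [2, 3, 4, 5], method="auto")
        assert counts_res.method == "wilcoxon"
        cont_res = group_compare([1.1, 2.2, 3.3], [2.5, 3.1, 4.9], method="auto")
        assert cont_res.method == "t"

    def test_shifted_normals_detected(self):
        rng = np.random.default_rng(55)
        a = rng.normal(0, 1, 50)
        b = rng.normal(2, 1, 50)
        assert group_compare(a, b, method="t").p_value < 1e-3
        assert group_compare(a, b, method="wilcoxon").p_value < 1e-3


class TestBhAdjust:
    def test_hand_step_up_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_all_ones_capped(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_monotone_in_order_statistics(self):
        rng = np.random.default_rng(77)
        p = np.sort(rng.uniform(size=20))
        q = bh_adjust(p)
        assert np.all(np.diff(q) >= -1e-12)
        assert np.all(q >= p)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestImmuneScore:
    def matrix(self):
        return pd.DataFrame(
            [[1.0, 2.0, 3.0], [3.0, 4.0, 5.0], [10.0, 10.0, 10.0]],
            index=["G1", "G2", "G3"],
            columns=["S1", "S2", "S3"],
        )

    def test_hand_two_gene_means(self):
        score = immune_score(self.matrix(), ["G1", "G2"])
        np.testing.assert_allclose(score.to_numpy(), [2.0, 3.0, 4.0])

    def test_constant_matrix_identical_scores(self):
        m = pd.DataFrame(5.0, index=["G1", "G2"], columns=["S1", "S2", "S3"])
        assert immune_score(m, ["G1", "G2"]).nunique() == 1

    def test_missing_genes_skipped_and_empty_rejected(self):
        score = immune_score(self.matrix(), ["G1", "NOPE"])
        np.testing.assert_allclose(score.to_numpy(), [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            immune_score(self.matrix(), ["NOPE"])

    def test_sample_permutation_equivariance(self):
        m = self.matrix()
        score = immune_score(m, ["G1", "G2"])
        perm = m[["S3", "S1", "S2"]]
        score_p = immune_score(perm, ["G1", "G2"])
        assert list(score_p.index) == ["S3", "S1", "S2"]
        np.testing.assert_allclose(score_p[score.index], score)


class TestExposureScoreAssociation:
    def test_identity_and_antitone(self):
        x = np.arange(10, dtype=float)
        assert exposure_score_association(x, x)[0] == pytest.approx(1.0)
        assert exposure_score_association(x, -x)[0] == pytest.approx(-1.0)

    def test_null_simulation_small_rho(self):
        rng = np.random.default_rng(404)
        small = 0
        n_rep = 50
        for _ in range(n_rep):
            rho, _ = exposure_score_association(
                rng.normal(size=200), rng.normal(size=200)
            )
            small += abs(rho) < 0.15
        assert small / n_rep >= 0.9

    def test_constant_input_flagged(self):
        with pytest.warns(UserWarning):
            rho, p = exposure_score_association(np.ones(12), np.arange(12.0))
        assert np.isnan(rho) and np.isnan(p)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            exposure_score_association(np.arange(5.0), np.arange(5.0))
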