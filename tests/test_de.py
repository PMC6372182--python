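"""Group-means fit, empirical-Bayes moderation, pairwise contrasts and COV."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import covdeg as cd
from covdeg import de
from .conftest import make_labeled_matrix


class TestFitClassMeans:
    def test_two_class_hand_computation(self):
        # values {0,2} vs {4,6}: means (1,5), pooled s2 = (2+2)/2 = 2, df 2
        m = make_labeled_matrix([[0.0, 2.0, 4.0, 6.0]], ["A", "A", "B", "B"])
        fit = de.fit_class_means(m)
        np.testing.assert_allclose(fit.means[0], [1.0, 5.0])
        assert fit.s2[0] == pytest.approx(2.0)
        assert fit.df_resid == 2

    def test_noise_free_fixture_recovers_planted_means(self):
        design = cd.default_design(seed=1, n_genes=50, n_planted=5)
        design.noise_sd = 1e-9
        design.baseline_sd = 0.0
        design.series_spec = [("a", 0.0, 1.0)]
        m, truth = cd.simulate_dataset(design)
        fit = de.fit_class_means(m)
        mu_cols = [f"mu_{c}" for c in fit.classes]
        for _, row in truth.table.iterrows():
            g = fit.gene_ids.index(row.gene_id)
            planted = row[
                [f"mu_{c}" for c in ["HBM", "AML", "ALL", "CML", "CLL"]]
            ].to_numpy(dtype=float)
            fitted = {c: fit.means[g, k] for k, c in enumerate(fit.classes)}
            expect = dict(zip(["HBM", "AML", "ALL", "CML", "CLL"], planted + 8.0))
            for c in fit.classes:
                assert fitted[c] == pytest.approx(expect[c], abs=1e-6)
        assert np.all(fit.s2 < 1e-12)

    def test_sample_permutation_invariance(self, tiny_matrix):
        fit1 = de.fit_class_means(tiny_matrix)
        perm = ["s3", "s1", "s4", "s2"]
        fit2 = de.fit_class_means(tiny_matrix.subset_samples(perm))
        np.testing.assert_allclose(fit1.means, fit2.means)
        np.testing.assert_allclose(fit1.s2, fit2.s2)

    def test_singleton_class_rejected_by_name(self):
        m = make_labeled_matrix([[1.0, 2.0, 3.0]], ["A", "A", "B"])
        with pytest.raises(ValueError, match="'B'"):
            de.fit_class_means(m)


class TestModerateVariances:
    def _fit_with_s2(self, s2, df=10):
        n = len(s2)
        return de.GroupFit(
            gene_ids=[f"G{i}" for i in range(n)],
            classes=["A", "B"],
            means=np.zeros((n, 2)),
            s2=np.asarray(s2, dtype=float),
            df_resid=df,
            n_per_class=np.array([6, 6]),
        )

    def test_equal_variances_give_infinite_prior_df(self):
        eb = de.moderate_variances(self._fit_with_s2([2.0] * 50))
        assert np.isinf(eb.d0)
        np.testing.assert_allclose(eb.s2_post, 2.0)
        assert eb.s02 == pytest.approx(2.0)

    def test_forcing_d0_zero_leaves_variances_untouched(self):
        rng = np.random.default_rng(0)
        s2 = rng.chisquare(5, size=100)
        eb = de.moderate_variances(self._fit_with_s2(s2), d0=0)
        np.testing.assert_array_equal(eb.s2_post, s2)

    def test_hyperparameter_recovery_from_scaled_chi_square(self):
        # s_g^2 ~ s0^2 * F(d, d0) with known d0=4, s0^2=1
        rng = np.random.default_rng(42)
        d, d0, s02 = 10, 4.0, 1.0
        true_var = s02 * d0 / rng.chisquare(d0, size=5000)
        s2 = true_var * rng.chisquare(d, size=5000) / d
        eb = de.moderate_variances(self._fit_with_s2(s2, df=d))
        assert eb.d0 == pytest.approx(d0, rel=0.15)
        assert eb.s02 == pytest.approx(s02, rel=0.15)

    def test_posterior_lies_between_gene_and_prior_variance(self):
        rng = np.random.default_rng(3)
        s2 = rng.chisquare(5, size=200)
        eb = de.moderate_variances(self._fit_with_s2(s2))
        lo = np.minimum(s2, eb.s02)
        hi = np.maximum(s2, eb.s02)
        assert np.all(eb.s2_post >= lo - 1e-12)
        assert np.all(eb.s2_post <= hi + 1e-12)

    def test_all_zero_variances_rejected(self):
        with pytest.raises(ValueError):
            de.moderate_variances(self._fit_with_s2([0.0] * 10))

    def test_matches_limma_squeeze_var(self, tmp_path):
        """Independent oracle: Bioconductor limma's squeezeVar."""
        import subprocess

        rng = np.random.default_rng(5)
        # heterogeneous truth (finite prior df) so the trigamma inversion
        # path is exercised, not just the zero-excess-dispersion branch
        true_var = 4.0 / rng.chisquare(4.0, size=200)
        s2 = (true_var * rng.chisquare(8, size=200) / 8).round(6)
        eb = de.moderate_variances(self._fit_with_s2(s2, df=8))

        np.savetxt(tmp_path / "s2.txt", s2)
        script = tmp_path / "sv.R"
        script.write_text(
            "suppressMessages(library(limma))\n"
            f's2 <- scan("{tmp_path}/s2.txt")\n'
            "sv <- squeezeVar(s2, df=8)\n"
            "cat(sv$df.prior, sv$var.prior, sep='\\n')\n"
            f'write.table(sv$var.post, "{tmp_path}/post.txt", row.names=FALSE, col.names=FALSE)\n'
        )
        out = subprocess.run(
            ["Rscript", str(script)], check=True, capture_output=True, text=True
        )
        d0_ref, s02_ref = (float(v) for v in out.stdout.split())
        post_ref = np.loadtxt(tmp_path / "post.txt")
        assert eb.d0 == pytest.approx(d0_ref, rel=1e-4)
        assert eb.s02 == pytest.approx(s02_ref, rel=1e-4)
        np.testing.assert_allclose(eb.s2_post, post_ref, rtol=1e-4)


class TestPairwiseStats:
    def test_identical_class_means_give_t_zero_p_one(self):
        m = make_labeled_matrix(
            [[1.0, 3.0, 1.0, 3.0], [0.0, 1.0, 2.0, 3.0]], ["A", "A", "B", "B"]
        )
        fit = de.fit_class_means(m)
        eb = de.moderate_variances(fit, d0=0)
        ps = de.pairwise_stats(fit, eb)
        assert ps.lfc[0, 0] == 0.0
        assert ps.t[0, 0] == 0.0
        assert ps.p[0, 0] == 1.0

    def test_two_class_hand_formula(self):
        # means 1 and 5, s2=2, n=(2,2), d0=0: t = 4/sqrt(2*(1/2+1/2)) = 2.828...
        m = make_labeled_matrix([[0.0, 2.0, 4.0, 6.0], [0.0, 2.0, 1.0, 3.0]],
                                ["A", "A", "B", "B"])
        fit = de.fit_class_means(m)
        eb = de.moderate_variances(fit, d0=0)
        ps = de.pairwise_stats(fit, eb)
        g = 0
        t_expected = -4.0 / np.sqrt(fit.s2[g] * (0.5 + 0.5))
        assert ps.pairs[0] == ("A", "B")
        assert ps.t[g, 0] == pytest.approx(t_expected, abs=1e-12)
        assert ps.p[g, 0] == pytest.approx(
            2 * stats.t.sf(abs(t_expected), df=2), abs=1e-12
        )

    def test_d0_zero_two_class_p_equals_classical_pooled_t(self):
        """With no moderation and N=2 the pipeline reproduces the classical
        pooled two-sample t-test exactly."""
        rng = np.random.default_rng(10)
        x = rng.normal(size=(40, 12))
        labels = ["A"] * 5 + ["B"] * 7
        m = make_labeled_matrix(x, labels)
        fit = de.fit_class_means(m)
        eb = de.moderate_variances(fit, d0=0)
        ps = de.pairwise_stats(fit, eb)
        a, b = x[:, :5], x[:, 5:]
        t_ref, p_ref = stats.ttest_ind(a, b, axis=1, equal_var=True)
        np.testing.assert_allclose(ps.t[:, 0], t_ref, atol=1e-10)
        np.testing.assert_allclose(ps.p[:, 0], p_ref, atol=1e-10)

    def test_pair_count_and_sign_antisymmetry(self, default_fixture):
        m, _ = default_fixture
        fit = de.fit_class_means(m)
        eb = de.moderate_variances(fit)
        ps = de.pairwise_stats(fit, eb)
        assert ps.n_pairs == de.cov_max(5) == 10
        # swapping a pair's class order flips lfc and t; p unchanged
        k = ps.pairs.index(("ALL", "AML"))
        i, j = fit.classes.index("ALL"), fit.classes.index("AML")
        flipped = fit.means[:, j] - fit.means[:, i]
        np.testing.assert_allclose(ps.lfc[:, k], -flipped)
        assert np.all((ps.t[:, k] >= 0) == (ps.lfc[:, k] >= 0))
        assert np.all((ps.p > 0) & (ps.p <= 1))


class TestCovMax:
    def test_five_classes_give_ten_pairs(self):
        assert de.cov_max(5) == 10

    def test_two_classes_give_one_pair(self):
        assert de.cov_max(2) == 1

    def test_seven_classes_match_pair_enumeration(self):
        from itertools import combinations

        assert de.cov_max(7) == len(list(combinations(range(7), 2))) == 21

    def test_fewer_than_two_classes_rejected(self):
        with pytest.raises(ValueError):
            de.cov_max(1)


@pytest.fixture(scope="module")
def fixture_stats(default_fixture):
    m, truth = default_fixture
    fit = de.fit_class_means(m)
    eb = de.moderate_variances(fit)
    return de.pairwise_stats(fit, eb), truth


class TestCoverageAndSelection:
    def test_null_genes_have_zero_coverage(self, fixture_stats):
        ps, truth = fixture_stats
        cov = de.compute_coverage(ps, 2.5, 0.001)
        null_cov = cov[truth.null_genes]
        assert (null_cov == 0).mean() > 0.99

    def test_coverage_matches_planted_cov_on_default_fixture(self, fixture_stats):
        ps, truth = fixture_stats
        cov = de.compute_coverage(ps, 2.5, 0.001)
        match = np.mean(
            [cov[r.gene_id] == r.expected_cov for _, r in truth.table.iterrows()]
        )
        assert match >= 0.95

    def test_coverage_monotone_in_lfc_threshold(self, fixture_stats):
        ps, _ = fixture_stats
        prev = de.compute_coverage(ps, 1.0, 0.001)
        for thr in (1.5, 2.0, 2.5, 3.0):
            cur = de.compute_coverage(ps, thr, 0.001)
            assert (cur <= prev).all()
            prev = cur

    def test_coverage_monotone_in_p_threshold(self, fixture_stats):
        ps, _ = fixture_stats
        loose = de.compute_coverage(ps, 2.5, 0.01)
        tight = de.compute_coverage(ps, 2.5, 0.0001)
        assert (tight <= loose).all()

    def test_selection_nested_as_cov_threshold_rises(self, fixture_stats):
        ps, _ = fixture_stats
        prev = set(de.select_degs(ps, 2.5, 0.001, 2)["gene_id"])
        for cov_thr in (3, 4, 5):
            cur = set(de.select_degs(ps, 2.5, 0.001, cov_thr)["gene_id"])
            assert cur <= prev
            prev = cur

    def test_selected_summaries_average_covered_pairs_only(self, fixture_stats):
        ps, _ = fixture_stats
        table = de.select_degs(ps, 2.5, 0.001, 5)
        gidx = {g: i for i, g in enumerate(ps.gene_ids)}
        row = table.iloc[0]
        i = gidx[row.gene_id]
        sel = (np.abs(ps.lfc[i]) >= 2.5) & (ps.p[i] <= 0.001)
        assert row["cov"] == sel.sum()
        assert row["mean_abs_lfc"] == pytest.approx(np.abs(ps.lfc[i, sel]).mean())
        assert row["mean_abs_t"] == pytest.approx(np.abs(ps.t[i, sel]).mean())
        assert row["mean_p"] == pytest.approx(ps.p[i, sel].mean())
        assert (table["cov"] <= de.cov_max(5)).all()

    def test_sort_order_cov_then_t(self, fixture_stats):
        ps, _ = fixture_stats
        table = de.select_degs(ps, 2.5, 0.001, 5)
        assert (table["cov"].diff().dropna() <= 0).all()
        for _, grp in table.groupby("cov"):
            assert (grp["mean_abs_t"].diff().dropna() <= 1e-12).all()

    def test_noise_free_single_planted_gene_selected_alone(self):
        design = cd.default_design(seed=2, n_genes=30, n_planted=1)
        design.noise_sd = 1e-4
        design.baseline_sd = 0.0
        design.series_spec = [("a", 0.0, 1.0)]
        m, truth = cd.simulate_dataset(design)
        fit = de.fit_class_means(m)
        eb = de.moderate_variances(fit, d0=0)
        ps = de.pairwise_stats(fit, eb)
        table = de.select_degs(ps, 2.5, 0.001, 1)
        assert list(table["gene_id"]) == truth.planted_genes

    def test_out_of_range_cov_threshold_rejected(self, fixture_stats):
        ps, _ = fixture_stats
        with pytest.raises(ValueError):
            de.select_degs(ps, 2.5, 0.001, de.cov_max(5) + 1)
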