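"""Per-gene MK statistics and the class-level alpha estimators."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import fisher_exact

from castemk import MKSimConfig, sim_mk_counts
from castemk.mk import (
    ClassComparison,
    MKAlphaModel,
    UndefinedEstimateError,
    bootstrap_alpha,
    compare_classes,
    mk_test,
    ml_alpha,
    pooled_alpha,
)


def counts(pn, ps, dn, ds, gene="g0"):
    return {"gene_id": gene, "Pn": pn, "Ps": ps, "Dn": dn, "Ds": ds}


class TestMKTest:
    def test_balanced_table_is_neutral(self):
        r = mk_test(counts(2, 2, 2, 2))
        assert r.ni == 1.0
        assert r.fisher_p == pytest.approx(1.0, abs=1e-12)
        assert r.direction == "balanced"

    def test_zero_pn_signals_excess_divergence(self):
        r = mk_test(counts(0, 5, 5, 5))
        assert r.ni == 0.0
        assert r.direction == "excess_divergence"

    def test_ni_undefined_when_margins_vanish(self):
        assert math.isnan(mk_test(counts(3, 0, 2, 2)).ni)
        assert math.isnan(mk_test(counts(3, 3, 0, 2)).ni)
        assert math.isnan(mk_test(counts(3, 3, 2, 0)).ni)

    def test_degenerate_table_has_p_one(self):
        assert mk_test(counts(0, 0, 0, 0)).fisher_p == 1.0

    def test_fisher_matches_independent_implementation(self):
        """Two-sided exact p agrees with scipy's enumeration on (10,10,30,10)."""
        r = mk_test(counts(10, 10, 30, 10))
        assert r.ni == pytest.approx(1 / 3)
        ref = fisher_exact([[10, 10], [30, 10]]).pvalue
        assert r.fisher_p == pytest.approx(ref, abs=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            mk_test(counts(-1, 2, 3, 4))


class TestPooledAlpha:
    def test_equal_sums_give_zero(self):
        df = pd.DataFrame([counts(3, 3, 3, 3), counts(2, 2, 2, 2, "g1")])
        assert pooled_alpha(df) == pytest.approx(0.0)

    def test_forced_arithmetic(self):
        df = pd.DataFrame([counts(10, 10, 20, 10)])
        assert pooled_alpha(df) == pytest.approx(0.5)

    def test_no_nonsyn_polymorphism_gives_one(self):
        df = pd.DataFrame([counts(0, 10, 20, 10)])
        assert pooled_alpha(df) == pytest.approx(1.0)

    def test_zero_denominator_named_in_error(self):
        with pytest.raises(UndefinedEstimateError, match="Dn"):
            pooled_alpha(pd.DataFrame([counts(1, 2, 0, 3)]))
        with pytest.raises(UndefinedEstimateError, match="Ps"):
            pooled_alpha(pd.DataFrame([counts(1, 0, 2, 3)]))


class TestMLAlpha:
    def test_equal_ratios_give_zero_alpha(self):
        """When polymorphism and divergence ratios coincide, alpha = 0."""
        df = pd.DataFrame(
            [counts(2, 4, 3, 6), counts(5, 10, 1, 2, "g1"), counts(1, 2, 4, 8, "g2")]
        )
        res = ml_alpha(df)
        assert res.alpha_hat == pytest.approx(0.0, abs=1e-6)
        assert res.f_hat == pytest.approx(0.5, abs=1e-6)

    def test_parameter_recovery_from_forward_model(self):
        cfg = MKSimConfig(n_genes=5000, alpha_true=0.3, f_true=0.7, seed=11)
        df, _ = sim_mk_counts(cfg)
        res = ml_alpha(df)
        assert res.alpha_hat == pytest.approx(0.3, abs=0.05)
        assert res.f_hat == pytest.approx(0.7, abs=0.05)

    def test_excess_polymorphism_drives_alpha_negative(self):
        """Aggregate Dn/Ds below Pn/Ps forces a negative estimate."""
        df = pd.DataFrame([counts(20, 10, 5, 10), counts(18, 9, 4, 9, "g1")])
        assert ml_alpha(df).alpha_hat < 0

    def test_fit_dominates_every_grid_point(self):
        df, _ = sim_mk_counts(MKSimConfig(n_genes=200, alpha_true=-0.4,
                                          f_true=0.4, seed=3))
        model = MKAlphaModel(df)
        res = model.fit()
        aa, ff = np.meshgrid(model.ALPHA_GRID, model.F_GRID, indexing="ij")
        grid = model.profile_loglike(aa, ff)
        assert res.log_likelihood >= grid.max() - 1e-8

    def test_single_gene_fixed_constraint_matches_pooled(self):
        """With f pinned at 1 and balanced polymorphism, the ML optimum is
        the pooled estimator of that gene's counts."""
        df = pd.DataFrame([counts(6, 6, 20, 10)])
        res = MKAlphaModel(df).fit(fix_f=1.0)
        assert res.alpha_hat == pytest.approx(pooled_alpha(df), abs=1e-6)

    def test_duplicating_genes_leaves_alpha_unchanged(self):
        df, _ = sim_mk_counts(MKSimConfig(n_genes=100, alpha_true=0.2,
                                          f_true=0.5, seed=8))
        res1 = ml_alpha(df)
        res3 = ml_alpha(pd.concat([df] * 3, ignore_index=True))
        assert res3.alpha_hat == pytest.approx(res1.alpha_hat, abs=1e-9)

    def test_pooled_and_ml_agree_on_homogeneous_data(self):
        """With a single shared (theta, lambda) the two estimators coincide
        up to the f <= 1 constraint."""
        cfg = MKSimConfig(n_genes=3000, alpha_true=0.25, f_true=0.5,
                          intensity_dispersion=0.0, seed=21)
        df, _ = sim_mk_counts(cfg)
        assert ml_alpha(df).alpha_hat == pytest.approx(pooled_alpha(df), abs=1e-6)

    def test_all_zero_genes_dropped_and_counted(self):
        df = pd.DataFrame([counts(2, 3, 4, 5), counts(0, 0, 0, 0, "g1")])
        res = ml_alpha(df)
        assert res.n_genes == 1
        assert res.n_dropped_allzero == 1

    def test_summary_mentions_estimates(self):
        df = pd.DataFrame([counts(5, 5, 10, 5)])
        text = ml_alpha(df).summary()
        assert "alpha_hat" in text and "f_hat" in text


class TestBootstrap:
    def test_fixed_seed_reproducible(self, small_counts):
        r1 = bootstrap_alpha(small_counts, B=200, seed=5)
        r2 = bootstrap_alpha(small_counts, B=200, seed=5)
        assert (r1.ci_low, r1.ci_high) == (r2.ci_low, r2.ci_high)
        assert np.array_equal(r1.bootstrap_draws, r2.bootstrap_draws)

    def test_ci_brackets_point_estimate(self):
        df, _ = sim_mk_counts(MKSimConfig(n_genes=500, alpha_true=0.2,
                                          f_true=0.5, seed=4))
        r = bootstrap_alpha(df, B=300, seed=9)
        assert r.ci_low <= r.alpha_hat <= r.ci_high

    def test_requires_minimum_replicates(self, small_counts):
        with pytest.raises(ValueError):
            bootstrap_alpha(small_counts, B=50, seed=1)

    def test_ci_width_shrinks_with_more_genes(self):
        """Median CI width strictly decreases when n doubles."""
        widths = {}
        for n in (500, 1000):
            ws = []
            for i in range(10):
                df, _ = sim_mk_counts(
                    MKSimConfig(n_genes=n, alpha_true=0.3, f_true=0.7, seed=100 + i)
                )
                r = bootstrap_alpha(df, B=200, seed=i)
                ws.append(r.ci_high - r.ci_low)
            widths[n] = np.median(ws)
        assert widths[1000] < widths[500]

    def test_coverage_of_true_alpha(self):
        """Percentile 95% CI covers the planted alpha ~95% of the time
        (200 meta-replicates, n = 2000 genes, default B)."""
        cov = 0
        for i in range(200):
            df, _ = sim_mk_counts(
                MKSimConfig(n_genes=2000, alpha_true=0.3, f_true=0.7, seed=i)
            )
            r = bootstrap_alpha(df, B=1000, seed=10_000 + i)
            cov += r.ci_low <= 0.3 <= r.ci_high
        assert 0.92 <= cov / 200 <= 0.98


class TestCompareClasses:
    def test_identical_classes_not_significant(self, small_counts):
        """Comparing a class with itself yields p near 1 (median over seeds)."""
        ps = [
            compare_classes(small_counts, small_counts, B=200, seed=s).bootstrap_p
            for s in range(9)
        ]
        assert np.median(ps) > 0.5

    def test_planted_contrast_detected(self):
        a, _ = sim_mk_counts(MKSimConfig(n_genes=5000, alpha_true=0.30,
                                         f_true=0.25, seed=1))
        b, _ = sim_mk_counts(MKSimConfig(n_genes=5000, alpha_true=0.15,
                                         f_true=0.25, seed=2))
        r = compare_classes(a, b, B=300, seed=3)
        assert r.delta_hat > 0
        assert r.bootstrap_p < 0.01

    def test_versus_zero_with_empty_second_class(self):
        a, _ = sim_mk_counts(MKSimConfig(n_genes=3000, alpha_true=0.3,
                                         f_true=0.5, seed=6))
        r = compare_classes(a, None, B=300, seed=7)
        assert isinstance(r, ClassComparison)
        assert r.alpha_b == 0.0
        assert r.bootstrap_p < 0.05

    def test_null_alpha_not_distinguishable_from_zero(self):
        a, _ = sim_mk_counts(MKSimConfig(n_genes=2000, alpha_true=0.0,
                                         f_true=0.5, seed=12))
        r = compare_classes(a, None, B=300, seed=13)
        assert r.bootstrap_p > 0.05
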