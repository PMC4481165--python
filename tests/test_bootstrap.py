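import numpy as np
import pytest

from corrflag.bootstrap import (
    BootstrapComparison,
    bootstrap_resample_plan,
    diff_ci,
    diff_ci_pairs,
    exclusion_rate,
    naive_vs_uninformative,
)
from corrflag.errors import DegeneratePairError, ValidationError
from corrflag.io import FlagPolicy

from conftest import make_compendium


def bivariate_comp(rho, n, seed, name="c"):
    rng = np.random.default_rng(seed)
    data = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], n).T
    return make_compendium(data, gene_ids=["g1", "g2"], name=name)


class TestResamplePlan:
    def test_shape_and_range(self):
        plan = bootstrap_resample_plan(50, 1000, seed=3)
        assert plan.shape == (1000, 50)
        assert plan.min() >= 0 and plan.max() < 50

    def test_deterministic_and_seed_sensitive(self):
        a = bootstrap_resample_plan(20, 100, seed=5)
        b = bootstrap_resample_plan(20, 100, seed=5)
        c = bootstrap_resample_plan(20, 100, seed=6)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_minimum_samples(self):
        with pytest.raises(ValidationError):
            bootstrap_resample_plan(2, 10, seed=0)


class TestDiffCi:
    def test_identical_genes_give_degenerate_zero_ci(self):
        x = np.arange(30.0)
        comp = make_compendium(np.vstack([x, x]), gene_ids=["g1", "g2"])
        result = diff_ci(comp, comp, ("g1", "g2"), "pearson",
                         FlagPolicy(bootstrap_reps=200), seed=0)
        assert result.r_k == pytest.approx(1.0, abs=1e-12)
        assert result.r_l == pytest.approx(1.0, abs=1e-12)
        assert result.ci_low == pytest.approx(0.0, abs=1e-12)
        assert result.ci_high == pytest.approx(0.0, abs=1e-12)
        assert not result.excludes_zero

    def test_ci_brackets_median_difference(self):
        comp_k = bivariate_comp(0.7, 60, seed=1, name="k")
        comp_l = bivariate_comp(0.2, 60, seed=2, name="l")
        res = diff_ci(comp_k, comp_l, ("g1", "g2"), "pearson",
                      FlagPolicy(bootstrap_reps=500), seed=4)
        assert res.ci_low <= res.ci_high
        # the point difference should sit inside the interval here
        assert res.ci_low <= res.r_k - res.r_l <= res.ci_high

    def test_distinct_true_correlations_detected(self):
        hits = 0
        for i in range(20):
            comp_k = bivariate_comp(0.9, 100, seed=100 + i, name="k")
            comp_l = bivariate_comp(0.0, 100, seed=200 + i, name="l")
            res = diff_ci(comp_k, comp_l, ("g1", "g2"), "pearson",
                          FlagPolicy(bootstrap_reps=500), seed=i)
            hits += res.excludes_zero
        assert hits >= 19

    def test_width_shrinks_with_sample_size(self):
        widths = {}
        for n in (50, 200):
            w = []
            for i in range(15):
                comp_k = bivariate_comp(0.5, n, seed=10 + i, name="k")
                comp_l = bivariate_comp(0.5, n, seed=50 + i, name="l")
                res = diff_ci(comp_k, comp_l, ("g1", "g2"), "pearson",
                              FlagPolicy(bootstrap_reps=400), seed=i)
                w.append(res.ci_high - res.ci_low)
            widths[n] = np.mean(w)
        assert widths[200] < widths[50]

    def test_reproducible_comparisons(self):
        comp_k = bivariate_comp(0.5, 40, seed=1, name="k")
        comp_l = bivariate_comp(0.5, 40, seed=2, name="l")
        a = diff_ci(comp_k, comp_l, ("g1", "g2"), seed=9)
        b = diff_ci(comp_k, comp_l, ("g1", "g2"), seed=9)
        assert a == b

    def test_constant_gene_degenerate(self):
        comp = make_compendium(
            np.vstack([np.arange(10.0), np.full(10, 2.0)]), gene_ids=["g1", "g2"]
        )
        with pytest.raises(DegeneratePairError):
            diff_ci(comp, comp, ("g1", "g2"), "pearson",
                    FlagPolicy(bootstrap_reps=100), seed=0)

    def test_spearman_and_mi_metrics_run(self):
        comp_k = bivariate_comp(0.6, 50, seed=3, name="k")
        comp_l = bivariate_comp(0.6, 50, seed=4, name="l")
        for metric in ("spearman", "mutual_information"):
            res = diff_ci(comp_k, comp_l, ("g1", "g2"), metric,
                          FlagPolicy(bootstrap_reps=100), seed=5)
            assert res.ci_low <= res.ci_high

    def test_shared_plan_across_pairs(self):
        """All pairs of one call see the same resample of each compendium."""
        rng = np.random.default_rng(12)
        base = rng.normal(size=40)
        values = np.vstack([base, base, base + rng.normal(0, 0.1, 40)])
        comp = make_compendium(values, gene_ids=["g1", "g2", "g3"])
        res = diff_ci_pairs(comp, comp, [("g1", "g3"), ("g2", "g3")],
                            policy=FlagPolicy(bootstrap_reps=100), seed=3)
        # identical rows g1 and g2 must produce identical bootstrap CIs
        assert res[0].ci_low == res[1].ci_low
        assert res[0].ci_high == res[1].ci_high


class TestExclusionRate:
    def make(self, excludes):
        return BootstrapComparison("a", "b", "k", "l", "pearson",
                                   0.5, 0.5, -0.1, 0.1, excludes, 100)

    def test_arithmetic(self):
        comps = [self.make(True)] * 3 + [self.make(False)]
        assert exclusion_rate(comps) == pytest.approx(0.75)
        assert exclusion_rate([self.make(False)] * 4) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            exclusion_rate([])


class TestNaiveVsUninformative:
    def test_consistent_compendia_favour_naive(self):
        # same r per pair across compendia, distinct across pairs
        rng = np.random.default_rng(7)
        shared = rng.normal(size=(4, 200))
        comp_k = make_compendium(shared, name="k")
        comp_l = make_compendium(shared, name="l")
        frac = naive_vs_uninformative(
            comp_k, comp_l, [("g0", "g1"), ("g0", "g2"), ("g1", "g3")],
            n_draws=200, seed=1,
        )
        assert frac == 0.0

    def test_ties_count_for_naive(self):
        x = np.arange(6.0)
        comp = make_compendium(np.vstack([x, x * 2, x * 3]))
        # every correlation is exactly 1.0 in both compendia: all ties
        frac = naive_vs_uninformative(
            comp, comp, [("g0", "g1"), ("g0", "g2"), ("g1", "g2")],
            n_draws=100, seed=2,
        )
        assert frac == 0.0

    def test_needs_two_pairs(self):
        comp = make_compendium(np.random.default_rng(0).normal(size=(2, 20)))
        with pytest.raises(ValidationError):
            naive_vs_uninformative(comp, comp, [("g0", "g1")], n_draws=10, seed=0)

    def test_reproducible(self):
        rng = np.random.default_rng(3)
        comp_k = make_compendium(rng.normal(size=(4, 50)), name="k")
        comp_l = make_compendium(rng.normal(size=(4, 50)), name="l")
        pairs = [("g0", "g1"), ("g2", "g3"), ("g0", "g3")]
        a = naive_vs_uninformative(comp_k, comp_l, pairs, n_draws=300, seed=8)
        b = naive_vs_uninformative(comp_k, comp_l, pairs, n_draws=300, seed=8)
        assert a == b
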