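import subprocess

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from corrflag.errors import FitError, ValidationError
from corrflag.io import FlagPolicy
from corrflag.mixture import (
    GMMFit,
    classify_by_threshold,
    classify_states,
    fit_gene_states,
    fit_gmm,
    joint_on_fraction,
    select_m,
)

from conftest import make_compendium


def bimodal_sample(rng, n_off, n_on, mu_off=4.0, mu_on=11.0, sd=0.3):
    x = np.concatenate([rng.normal(mu_off, sd, n_off), rng.normal(mu_on, sd, n_on)])
    rng.shuffle(x)
    return x


class TestFitGmm:
    def test_single_component_closed_form(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        fit = fit_gmm(x, 1, seed=0)
        assert fit.means[0] == pytest.approx(3.0)
        assert fit.variances[0] == pytest.approx(np.var(x))  # MLE, not n-1
        assert fit.bic == pytest.approx(
            2 * fit.log_likelihood - 2 * np.log(5), abs=1e-9
        )

    def test_parameter_recovery_bimodal(self):
        rng = np.random.default_rng(21)
        x = bimodal_sample(rng, 100, 100)
        fit = fit_gmm(x, 2, seed=1)
        assert fit.means == pytest.approx([4.0, 11.0], abs=0.2)
        assert fit.weights.sum() == pytest.approx(1.0, abs=1e-8)
        assert np.all(fit.variances > 0)

    def test_bimodal_bic_prefers_two_by_margin(self):
        rng = np.random.default_rng(21)
        x = bimodal_sample(rng, 100, 100)
        bic1 = fit_gmm(x, 1, seed=1).bic
        bic2 = fit_gmm(x, 2, seed=1).bic
        assert bic2 - bic1 > 10

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(8)
        x = bimodal_sample(rng, 60, 60)
        a = fit_gmm(x, 3, seed=99)
        b = fit_gmm(x, 3, seed=99)
        np.testing.assert_array_equal(a.means, b.means)
        assert a.log_likelihood == b.log_likelihood

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValidationError):
            fit_gmm(np.arange(9.0), 2, seed=0)

    def test_constant_vector_fails(self):
        with pytest.raises(FitError):
            fit_gmm(np.full(50, 3.0), 1, seed=0)

    def test_matches_sklearn_em(self):
        """Independent EM implementation agrees on a well-separated fit."""
        import sklearn.mixture as sklearn_mixture

        rng = np.random.default_rng(4)
        x = bimodal_sample(rng, 150, 100)
        ours = fit_gmm(x, 2, seed=0)
        gm = sklearn_mixture.GaussianMixture(
            n_components=2, covariance_type="full", n_init=3, tol=1e-6,
            max_iter=500, reg_covar=1e-10, random_state=0,
        ).fit(x[:, None])
        theirs_ll = gm.score(x[:, None]) * x.size
        assert ours.log_likelihood == pytest.approx(theirs_ll, abs=0.01)
        assert np.sort(gm.means_.ravel()) == pytest.approx(ours.means, abs=0.01)

    def test_matches_mclust_bic(self, tmp_path):
        """BIC agrees with the R mclust 'V' model (the field's reference)."""
        rng = np.random.default_rng(7)
        x = np.concatenate([rng.normal(5, 0.4, 60), rng.normal(9, 0.5, 60)])
        data = tmp_path / "x.txt"
        np.savetxt(data, x)
        r_code = (
            "suppressMessages(library(mclust));"
            f'x <- scan("{data}", quiet=TRUE);'
            'b <- mclustBIC(x, G=1:2, modelNames="V", verbose=FALSE);'
            'cat(b[1,"V"], b[2,"V"], sep="\\n")'
        )
        out = subprocess.run(
            ["Rscript", "-e", r_code], capture_output=True, text=True, check=True
        )
        mclust_bic = [float(v) for v in out.stdout.split()]
        assert fit_gmm(x, 1, seed=0).bic == pytest.approx(mclust_bic[0], abs=0.01)
        assert fit_gmm(x, 2, seed=0).bic == pytest.approx(mclust_bic[1], abs=0.01)


class TestSelectM:
    @pytest.mark.parametrize(
        "bic, expected",
        [
            ({1: -100, 2: -95, 3: -96}, 2),
            ({1: -80, 2: -95}, 1),
            ({1: -100, 2: -95, 3: -90}, 2),  # 3 wins BIC but not by >10
            ({1: -100, 2: -95, 3: -84}, 3),  # 3 wins by 11: strong evidence
            ({1: -90, 3: -90}, 1),  # no m=2 fit: argmax, ties -> smallest
        ],
    )
    def test_rule(self, bic, expected):
        assert select_m(bic) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            select_m({})

    @given(
        st.dictionaries(
            st.integers(1, 9),
            st.floats(-1e4, 0, allow_nan=False),
            min_size=1,
        ).filter(lambda d: 2 in d)
    )
    def test_selected_within_margin_of_max(self, bic):
        chosen = select_m(bic, margin=10)
        assert bic[chosen] >= max(bic.values()) - 10

    @given(st.floats(-1e4, 0, allow_nan=False))
    def test_weak_candidate_never_displaces_two(self, extra):
        bic = {1: -200.0, 2: -100.0}
        assert select_m(bic) == 2
        bic[5] = min(extra, bic[2])  # candidate no better than m=2
        assert select_m(bic) == 2


class TestClassifyStates:
    def fit_30_70(self):
        rng = np.random.default_rng(2)
        x = bimodal_sample(rng, 350, 150)  # 30% on
        return fit_gmm(x, 2, seed=0), x

    def test_occupancy_recovery(self):
        fit, x = self.fit_30_70()
        _, p_on, min_pct = classify_states(fit, x)
        assert p_on == pytest.approx(0.30, abs=0.03)
        assert min_pct == pytest.approx(p_on, abs=1e-12)

    def test_all_samples_off(self):
        fit, _ = self.fit_30_70()
        low = np.full(20, fit.means[0])
        _, p_on, min_pct = classify_states(fit, low)
        assert p_on == 0.0
        assert min_pct == 0.0

    def test_label_switching_safe(self):
        """Permuting component order never changes p_on (on = larger mean)."""
        fit, x = self.fit_30_70()
        swapped = GMMFit(
            weights=fit.weights[::-1].copy(),
            means=fit.means[::-1].copy(),
            variances=fit.variances[::-1].copy(),
            log_likelihood=fit.log_likelihood,
            bic=fit.bic,
        )
        _, p_orig, _ = classify_states(fit, x)
        _, p_swap, _ = classify_states(swapped, x)
        assert p_orig == p_swap

    def test_requires_two_components(self):
        x = np.arange(10.0)
        with pytest.raises(ValidationError):
            classify_states(fit_gmm(x, 1, seed=0), x)


class TestClassifyByThreshold:
    def test_strictly_above(self):
        assignment, p_on = classify_by_threshold([10, 11.5, 12], 11)
        np.testing.assert_array_equal(assignment, [0, 1, 1])
        assert p_on == pytest.approx(2 / 3)

    def test_threshold_above_max(self):
        _, p_on = classify_by_threshold([1.0, 2.0], 5.0)
        assert p_on == 0.0

    def test_joint_on_fraction_uses_both_genes(self):
        # both genes must exceed their own thresholds simultaneously
        lex = np.array([10.0, 12.0, 12.0, 12.0])
        din = np.array([9.0, 9.0, 10.0, 10.0])
        assert joint_on_fraction(lex, 11, din, 9.5) == pytest.approx(0.5)
        _, p_lex = classify_by_threshold(lex, 11)
        assert p_lex == pytest.approx(0.75)  # marginal > joint


class TestFitGeneStates:
    def test_bimodal_gene_is_two_state(self, bimodal_gene_comp):
        fit = fit_gene_states(bimodal_gene_comp, "gBim", seed=3)
        assert fit.two_state_valid
        assert fit.m_selected == 2
        assert fit.p_on == pytest.approx(0.4, abs=0.03)
        assert fit.min_state_pct == pytest.approx(0.4, abs=0.03)

    def test_unimodal_gene_rejects_two_state(self):
        rng = np.random.default_rng(14)
        comp = make_compendium(rng.normal(7.0, 0.6, 500)[None, :])
        fit = fit_gene_states(comp, "g0", seed=3)
        assert fit.m_selected == 1
        assert not fit.two_state_valid
        assert fit.p_on is None and fit.min_state_pct is None

    def test_trimodal_gene_selects_three(self):
        rng = np.random.default_rng(15)
        x = np.concatenate(
            [rng.normal(4, 0.3, 200), rng.normal(8, 0.3, 200), rng.normal(12, 0.3, 200)]
        )
        rng.shuffle(x)
        fit = fit_gene_states(make_compendium(x[None, :]), "g0", seed=3)
        assert fit.m_selected == 3

    def test_selected_bic_within_margin_of_max(self, bimodal_gene_comp):
        policy = FlagPolicy()
        fit = fit_gene_states(bimodal_gene_comp, "gBim", policy, seed=3)
        assert fit.bic[fit.m_selected] >= max(fit.bic.values()) - policy.bic_margin

    def test_small_n_skips_large_candidates(self):
        rng = np.random.default_rng(16)
        comp = make_compendium(rng.normal(7, 1, 12)[None, :])
        fit = fit_gene_states(comp, "g0", seed=0)
        assert max(fit.bic) <= 2  # only m with n >= 5m were tried
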