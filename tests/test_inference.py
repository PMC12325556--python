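import math

import numpy as np
import pandas as pd
import pytest

import emgchrono.inference as inf
import emgchrono.recovery as rec


@pytest.fixture(scope="module")
def small_tables():
    return rec.simulate_analysis_tables(8, seed=5)


@pytest.fixture(scope="module")
def small_fit(small_tables):
    return inf.fit(inf.ModelSpec("pmt"), small_tables["chronometric"])


def two_group_data(n_per=400, n_participants=8, delta=25.0, seed=3):
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_participants):
        u = rng.normal(0, 10)
        for lex, shift in (("word", 0.0), ("pseudoword", delta)):
            y = 500.0 + shift + u + rng.normal(0, 30, n_per)
            rows.append(pd.DataFrame({
                "participant": f"s{p}", "lexicality": lex, "y": y,
            }))
    return pd.concat(rows, ignore_index=True)


class TestFit:
    def test_balanced_two_group_estimate_matches_cell_means(self):
        """Closed-form oracle: with a balanced design the fixed effect equals
        the difference of group means (within 1%)."""
        data = two_group_data()
        spec = inf.ModelSpec("y", fixed="lexicality",
                             random=(inf.RandomTerm("participant"),))
        fitted = inf.fit(spec, data,
                         factors={"lexicality": ["word", "pseudoword"]})
        means = data.groupby("lexicality")["y"].mean()
        observed = means["pseudoword"] - means["word"]
        assert fitted.estimate("lexicalitypseudoword") == pytest.approx(
            observed, rel=0.01)
        assert fitted.converged

    def test_agrees_with_statsmodels_mixedlm(self):
        """Independent cross-check: statsmodels MixedLM on the same data and
        random-intercept structure reproduces the fixed effects."""
        import statsmodels.formula.api as smf

        data = two_group_data(n_per=100)
        spec = inf.ModelSpec("y", fixed="lexicality",
                             random=(inf.RandomTerm("participant"),))
        ours = inf.fit(spec, data,
                       factors={"lexicality": ["word", "pseudoword"]})
        sm_fit = smf.mixedlm(
            "y ~ C(lexicality, levels=['word','pseudoword'])",
            data, groups=data["participant"],
        ).fit(reml=True)
        np.testing.assert_allclose(
            ours.fixed_effects["estimate"].to_numpy(),
            sm_fit.fe_params.to_numpy(), rtol=1e-4,
        )

    def test_statistic_is_estimate_over_se(self, small_fit):
        fe = small_fit.fixed_effects
        np.testing.assert_allclose(
            fe["statistic"], fe["estimate"] / fe["se"], rtol=1e-6)

    def test_bic_identity(self, small_tables):
        """BIC = −2 logLik + p log n for an ML fit."""
        fitted = inf.fit(inf.ModelSpec("pmt", reml=False),
                         small_tables["chronometric"])
        expected = -2 * fitted.loglik + fitted.n_params * math.log(fitted.n_obs)
        assert fitted.bic == pytest.approx(expected, rel=1e-9)

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError):
            inf.fit(inf.ModelSpec("pmt"), pd.DataFrame())

    def test_formula_rendering(self):
        spec = inf.maximal_spec("pmt")
        assert spec.formula() == (
            "pmt ~ bias * lexicality + (1 + bias + lexicality | participant)"
            " + (1 + bias | item)"
        )
        uncorr = inf.RandomTerm("participant", ("bias",), correlated=False)
        assert uncorr.to_formula() == "(1 + bias || participant)"


class TestCafModel:
    def test_caf_glme_has_full_three_way_term_structure(self):
        """bias x lexicality x (linear + quadratic quantile) with treatment
        coding yields 18 fixed-effect rows; random intercepts only."""
        from emgchrono.caf import add_polynomial_covariates, bin_quantiles

        tables = rec.simulate_analysis_tables(5, seed=17)
        acc = tables["accuracy"].rename(columns={"true_rt": "rt",
                                                 "participant": "participant_id"})
        acc["block"] = acc["bias"]
        binned = add_polynomial_covariates(bin_quantiles(acc))
        binned = binned.rename(columns={"participant_id": "participant"})
        fitted = inf.fit(inf.caf_spec(), binned)
        assert len(fitted.fixed_effects) == 18
        assert {"quantile_linear", "quantile_quadratic"} <= set(
            t.split(":")[-1] for t in fitted.fixed_effects.index
        )
        assert fitted.converged


class TestSimplify:
    def test_zero_slope_variance_dropped(self, small_tables):
        """The generative truth has intercepts only; the maximal structure
        must shed its (zero-variance) bias slopes."""
        final, fitted, audit = inf.simplify(
            inf.maximal_spec("mt"), small_tables["chronometric"])
        assert fitted.converged
        participant_term = [t for t in final.random if t.group == "participant"][0]
        assert "bias" not in participant_term.slopes
        assert audit  # something was simplified

    def test_intercept_truth_keeps_intercepts(self, small_tables):
        final, fitted, _ = inf.simplify(
            inf.ModelSpec("pmt"), small_tables["chronometric"])
        assert {t.group for t in final.random} == {"participant", "item"}
        assert fitted.converged and not fitted.singular

    def test_converged_nonsingular_fit_unchanged(self, small_fit, small_tables):
        spec = inf.ModelSpec("pmt")
        final, fitted, audit = inf.simplify(spec, small_tables["chronometric"])
        assert final == spec
        assert audit == []


class TestContrasts:
    def test_neutral_contrast_is_minus_lexicality_coefficient(self, small_fit):
        con = inf.lexicality_contrasts(small_fit)
        assert con.loc["neutral", "estimate"] == pytest.approx(
            -small_fit.estimate("lexicalitypseudoword"))

    def test_biased_contrasts_add_interaction_terms(self, small_fit):
        con = inf.lexicality_contrasts(small_fit)
        for level, term in [("word_bias", "biasword_bias:lexicalitypseudoword"),
                            ("pseudoword_bias",
                             "biaspseudoword_bias:lexicalitypseudoword")]:
            expected = -(small_fit.estimate("lexicalitypseudoword")
                         + small_fit.estimate(term))
            assert con.loc[level, "estimate"] == pytest.approx(expected)

    def test_missing_term_rejected(self, small_fit):
        with pytest.raises(ValueError):
            inf.linear_contrast(small_fit, {"nonexistent": 1.0})

    def test_tukey_never_smaller_than_unadjusted(self, small_fit):
        adj = inf.pairwise_bias_contrasts(small_fit, adjust="tukey")
        raw = inf.pairwise_bias_contrasts(small_fit, adjust="none")
        assert (adj["p_value"].to_numpy() >= raw["p_value"].to_numpy() - 1e-12).all()


class TestBayesFactor:
    def _mk(self, bic, reml=False, n=100):
        fe = pd.DataFrame({"estimate": [0.0], "se": [1.0], "statistic": [0.0]},
                          index=["(Intercept)"])
        return inf.FitResult(fe, pd.DataFrame([[1.0]], index=["(Intercept)"],
                                              columns=["(Intercept)"]),
                             pd.DataFrame(), 0.0, bic, n, 1, True, False,
                             reml, "y ~ 1", "gaussian")

    def test_closed_forms(self):
        assert inf.bic_bayes_factor(self._mk(100.0), self._mk(100.0)) == 1.0
        assert inf.bic_bayes_factor(self._mk(102.0), self._mk(100.0)) == \
            pytest.approx(math.exp(-1.0))
        assert inf.bic_bayes_factor(self._mk(114.53), self._mk(100.0)) == \
            pytest.approx(0.0007, rel=0.03)

    def test_reml_fits_refused(self):
        with pytest.raises(ValueError):
            inf.bic_bayes_factor(self._mk(100.0, reml=True), self._mk(99.0))

    def test_mismatched_data_refused(self):
        with pytest.raises(ValueError):
            inf.bic_bayes_factor(self._mk(100.0), self._mk(99.0, n=50))
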