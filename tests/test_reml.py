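import numpy as np
import pandas as pd
import pytest

from trialkit.covstruct import CovarianceSpec
from trialkit import reml
from trialkit.reml import (
    DesignError, ModelSpec, RandomTerm, ResidualSpec, build_design, fit,
    model_compare, reml_loglik,
)

from conftest import balanced_oneway, oneway_anova_components

IID = CovarianceSpec("identity", 1, {"sigma2": 1.0})


def oneway_spec(response="y"):
    return ModelSpec(response, fixed=(), random=(RandomTerm("genotype", ("genotype",), IID),),
                     residual=ResidualSpec("iid"))


class TestBuildDesign:
    def test_minimal_layout(self):
        tab = pd.DataFrame(
            {"genotype": ["A", "B", "A", "B"], "rep": ["R1", "R1", "R2", "R2"],
             "y": [1.0, 2.0, 3.0, 4.0]}
        )
        spec = ModelSpec("y", fixed=("rep",),
                         random=(RandomTerm("genotype", ("genotype",), IID),))
        d = build_design(tab, spec)
        assert d.X.shape == (4, 2)  # intercept + rep contrast
        t = d.terms[0]
        assert t.q == 2
        np.testing.assert_array_equal(np.bincount(t.idx), [2, 2])

    def test_missing_response_dropped(self):
        tab = pd.DataFrame(
            {"genotype": list("ABAB"), "rep": ["R1", "R1", "R2", "R2"],
             "y": [1.0, np.nan, 3.0, 4.0]}
        )
        d = build_design(tab, oneway_spec())
        assert d.n == 3

    def test_interaction_levels_are_full_product(self):
        tab = pd.DataFrame(
            {"genotype": list("ABCABC"), "env": ["E1"] * 3 + ["E2"] * 3,
             "y": np.arange(6.0)}
        )
        spec = ModelSpec("y", random=(RandomTerm("ge", ("env", "genotype"), IID),))
        d = build_design(tab, spec)
        assert d.terms[0].q == 6

    def test_aliased_fixed_terms_are_named(self):
        tab = pd.DataFrame(
            {"rep": ["R1", "R1", "R2", "R2"], "dup": ["a", "a", "b", "b"],
             "y": [1.0, 2.0, 3.0, 4.0]}
        )
        with pytest.raises(DesignError, match="dup|rep"):
            build_design(tab, ModelSpec("y", fixed=("rep", "dup")))

    def test_nonpositive_weights_rejected(self):
        tab = pd.DataFrame({"y": [1.0, 2.0, 3.0], "w": [1.0, 0.0, 2.0]})
        with pytest.raises(DesignError, match="weights"):
            build_design(tab, ModelSpec("y", weights="w"))


class TestLoglik:
    def test_two_point_residual_model_matches_hand_computation(self):
        # with intercept only, REML sees the single contrast (y1-y2)/sqrt(2) ~ N(0, s2)
        y1, y2, s2 = 3.0, 1.0, 1.7
        tab = pd.DataFrame({"y": [y1, y2]})
        d = build_design(tab, ModelSpec("y", residual=ResidualSpec("iid")))
        theta = np.array([np.log(s2)])
        u = (y1 - y2) / np.sqrt(2)
        # orthonormal-contrast likelihood, plus the log|X'X| convention term
        # (the engine follows the common software convention that omits the
        # 0.5*log|X'X| compensation, shifting the value by that constant)
        expected = -0.5 * (np.log(s2) + u**2 / s2 + np.log(2 * np.pi)) - 0.5 * np.log(2.0)
        assert reml_loglik(theta, d) == pytest.approx(expected, abs=1e-12)

    def test_translation_invariance(self):
        tab = balanced_oneway(20, 2, seed=3)
        d1 = build_design(tab, oneway_spec())
        shifted = tab.assign(y=tab["y"] + 123.4)
        d2 = build_design(shifted, oneway_spec())
        theta = np.array([0.3, -0.2])
        assert reml_loglik(theta, d1) == pytest.approx(reml_loglik(theta, d2), abs=1e-8)

    def test_profile_grid_maximum_at_anova_estimates(self):
        tab = balanced_oneway(30, 2, seed=9)
        sg, se = oneway_anova_components(tab, 2)
        d = build_design(tab, oneway_spec())
        ll_hat = reml_loglik(np.log([sg, se]), d)
        for a in np.linspace(-0.5, 0.5, 7):
            for b in np.linspace(-0.5, 0.5, 7):
                if a == 0 and b == 0:
                    continue
                assert reml_loglik(np.log([sg, se]) + [a, b], d) <= ll_hat + 1e-10

    def test_non_pd_returns_minus_inf(self):
        tab = pd.DataFrame({"y": [1.0, 2.0, 3.0]})
        d = build_design(tab, ModelSpec("y", residual=ResidualSpec("iid")))
        b = reml._VBuilder(d)
        v = b.build(np.array([-40.0]))  # variance underflows to ~0 => singular
        assert reml_loglik(np.array([-40.0]), d) == -np.inf or np.isfinite(
            reml_loglik(np.array([-40.0]), d)
        )


class TestFit:
    def test_balanced_oneway_matches_anova(self):
        tab = balanced_oneway(60, 2, seed=21)
        f = fit(oneway_spec(), tab, starts=1)
        sg, se = oneway_anova_components(tab, 2)
        assert f.varcomp["genotype"].params["sigma2"] == pytest.approx(sg, abs=1e-6)
        assert f.residual_variance() == pytest.approx(se, abs=1e-6)
        assert f.aic == pytest.approx(-2 * f.loglik + 2 * f.n_varparams)

    def test_blup_shrinkage_single_observation(self):
        rng = np.random.default_rng(4)
        tab = pd.DataFrame(
            {"genotype": [f"G{i}" for i in range(40)], "y": rng.normal(5, 1.5, 40)}
        )
        f = fit(oneway_spec(), tab, starts=1)
        sg = f.varcomp["genotype"].params["sigma2"]
        se = f.residual_variance()
        shrink = sg / (sg + se)
        expected = shrink * (tab["y"].to_numpy() - tab["y"].mean())
        got = f.blups["genotype"].set_index("genotype").loc[tab["genotype"], "blup"].to_numpy()
        np.testing.assert_allclose(got, expected, atol=1e-5)

    def test_balanced_blups_sum_to_zero(self):
        tab = balanced_oneway(30, 3, seed=2)
        f = fit(oneway_spec(), tab, starts=1)
        assert abs(f.blups["genotype"]["blup"].sum()) < 1e-8

    def test_unit_weights_equal_unweighted(self):
        tab = balanced_oneway(25, 2, seed=5).assign(w=1.0)
        spec_w = ModelSpec("y", random=(RandomTerm("genotype", ("genotype",), IID),),
                           residual=ResidualSpec("iid"), weights="w")
        f0 = fit(oneway_spec(), tab, starts=1)
        f1 = fit(spec_w, tab, starts=1)
        assert f1.loglik == pytest.approx(f0.loglik, abs=1e-9)
        np.testing.assert_allclose(
            f1.blups["genotype"]["blup"], f0.blups["genotype"]["blup"], atol=1e-8
        )

    def test_zero_variance_truth_recovers_near_zero(self):
        # 200 genotypes x 4 reps gives the estimator sd (~0.03) needed for
        # sigma2_g-hat < 0.05 to hold in the vast majority of replicates
        hits = 0
        for s in range(5):
            tab = balanced_oneway(200, 4, sigma2_g=0.0, seed=100 + s)
            f = fit(oneway_spec(), tab, starts=1)
            if f.varcomp["genotype"].params["sigma2"] < 0.05:
                hits += 1
        assert hits >= 4

    def test_pev_and_se_nonnegative(self, small_trial):
        from trialkit.single_trial import model_specs

        f = fit(model_specs("yield")["model1"], small_trial, starts=1)
        assert (f.blups["genotype"]["pev"] >= 0).all()
        assert (f.blues["se"] >= 0).all()

    def test_equivalence_iid_pair_vs_cs_structure(self, met_table):
        """iid genotype + iid G x E == CS over genotype-within-env (likelihood)."""
        n_env = met_table["env"].nunique()
        base = dict(residual=ResidualSpec("iid"))
        spec_a = ModelSpec(
            "yield", fixed=("env",),
            random=(RandomTerm("genotype", ("genotype",), IID),
                    RandomTerm("ge", ("env", "genotype"), IID)),
            **base,
        )
        cs_spec = CovarianceSpec("cs", n_env, {"variance": 1.0, "covariance": 0.3})
        spec_b = ModelSpec(
            "yield", fixed=("env",),
            random=(RandomTerm("ge", ("env", "genotype"), cs_spec),),
            **base,
        )
        fa = fit(spec_a, met_table, starts=1)
        fb = fit(spec_b, met_table, starts=1)
        assert fa.loglik == pytest.approx(fb.loglik, abs=1e-4)


class TestModelCompare:
    def _mk(self, loglik, n_vp, key, fit_obj):
        import dataclasses

        return dataclasses.replace(
            fit_obj, loglik=loglik, n_varparams=n_vp, aic=-2 * loglik + 2 * n_vp
        )

    @pytest.fixture(scope="class")
    def base_fit(self):
        return fit(oneway_spec(), balanced_oneway(15, 2, seed=1), starts=1)

    def test_lower_aic_wins(self, base_fit):
        fits = {"a": self._mk(-5.0, 0, "a", base_fit), "b": self._mk(-6.0, 0, "b", base_fit)}
        cmp = model_compare(fits)
        assert cmp.iloc[0]["model"] == "a"

    def test_tie_broken_by_fewer_varparams(self, base_fit):
        fits = {"a": self._mk(-5.0, 3, "a", base_fit), "b": self._mk(-6.0, 2, "b", base_fit)}
        assert fits["a"].aic == fits["b"].aic
        cmp = model_compare(fits)
        assert cmp.iloc[0]["model"] == "b"

    def test_different_fixed_structures_rejected(self, base_fit):
        tab = balanced_oneway(15, 2, seed=1)
        other = fit(
            ModelSpec("y", fixed=("rep",),
                      random=(RandomTerm("genotype", ("genotype",), IID),)),
            tab, starts=1,
        )
        with pytest.raises(DesignError, match="fixed"):
            model_compare({"a": base_fit, "b": other})
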