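import numpy as np
import pandas as pd
import pytest

from trialkit import qc
from trialkit.qc import QCConfig, QCError
from trialkit.reml import fit
from trialkit.single_trial import model_specs
from trialkit.synthdata import SimConfig, inject_outliers, make_alpha_lattice, simulate_trial

from conftest import balanced_oneway


def _met_frame(props, per_env=20, seed=0):
    """Frame with one env per requested missing proportion."""
    rng = np.random.default_rng(seed)
    frames = []
    for i, p in enumerate(props):
        n_miss = int(round(p * per_env))
        y = rng.normal(10, 1, per_env)
        y[:n_miss] = np.nan
        frames.append(pd.DataFrame({"env": f"E{i}", "y": y}))
    return pd.concat(frames, ignore_index=True)


class TestMissingness:
    def test_over_threshold_dropped(self):
        tab = _met_frame([0.25, 0.05])
        kept, rep = qc.missingness_filter(tab, "y")
        assert set(kept["env"]) == {"E1"}
        dec = rep.decisions_frame()
        assert dec[dec.env == "E0"].iloc[0]["action"] == "drop"

    def test_exactly_at_threshold_kept(self):
        # the rule is strictly greater than the threshold
        tab = _met_frame([0.20, 0.0])
        kept, _ = qc.missingness_filter(tab, "y")
        assert set(kept["env"]) == {"E0", "E1"}

    def test_all_dropped_raises(self):
        tab = _met_frame([0.5, 0.9])
        with pytest.raises(QCError, match="no data survives"):
            qc.missingness_filter(tab, "y")

    @pytest.mark.parametrize("seed", range(5))
    def test_partition_matches_brute_force_recount(self, seed):
        rng = np.random.default_rng(seed)
        props = rng.uniform(0, 0.4, 6)
        tab = _met_frame(props, per_env=40, seed=seed)
        kept, rep = qc.missingness_filter(tab, "y")
        expected_keep = {
            env for env, s in tab.groupby("env")["y"]
            if s.isna().mean() <= 0.20
        }
        assert set(kept["env"]) == expected_keep
        frame = rep.missingness.set_index("env")["missing_proportion"]
        for env, s in tab.groupby("env")["y"]:
            assert frame[env] == pytest.approx(round(s.isna().mean(), 4))


class TestDescriptives:
    def test_constant_data(self):
        tab = pd.DataFrame({"env": ["A"] * 5, "y": [3.0] * 5})
        row = qc.descriptive_stats(tab, "y").iloc[0]
        assert row["sd"] == 0 and row["cv"] == 0

    def test_two_point_arithmetic(self):
        tab = pd.DataFrame({"env": ["A", "A"], "y": [2.0, 4.0]})
        row = qc.descriptive_stats(tab, "y").iloc[0]
        assert row["mean"] == pytest.approx(3.0)
        assert row["sd"] == pytest.approx(np.sqrt(2))
        assert row["cv"] == pytest.approx(47.14, abs=0.01)

    def test_zero_mean_cv_undefined(self):
        tab = pd.DataFrame({"env": ["A"] * 4, "y": [-1.0, 1.0, -2.0, 2.0]})
        assert np.isnan(qc.descriptive_stats(tab, "y").iloc[0]["cv"])

    def test_matches_independent_two_pass(self):
        rng = np.random.default_rng(3)
        tab = pd.DataFrame({"env": np.repeat(["A", "B"], 50), "y": rng.normal(5, 2, 100)})
        out = qc.descriptive_stats(tab, "y").set_index("env")
        for env, s in tab.groupby("env")["y"]:
            v = s.to_numpy()
            mean = v.sum() / len(v)
            sd = np.sqrt(((v - mean) ** 2).sum() / (len(v) - 1))
            assert out.loc[env, "mean"] == pytest.approx(mean)
            assert out.loc[env, "sd"] == pytest.approx(sd)
            assert out.loc[env, "cv"] == pytest.approx(100 * sd / mean)


class TestFieldHeatmap:
    def _tab(self):
        return pd.DataFrame(
            {"env": ["E"] * 4, "row": [1, 1, 2, 2], "col": [1, 2, 1, 2],
             "y": [1.0, 2.0, 3.0, 4.0]}
        )

    def test_complete_layout(self):
        grid = qc.field_heatmap_matrix(self._tab(), "y", "E")
        np.testing.assert_allclose(grid, [[1, 2], [3, 4]])

    def test_absent_plot_is_missing(self):
        grid = qc.field_heatmap_matrix(self._tab().iloc[:3], "y", "E")
        assert np.isnan(grid[1, 1]) and np.isfinite(grid).sum() == 3

    def test_duplicate_plot_rejected(self):
        tab = self._tab()
        tab.loc[3, ["row", "col"]] = [1, 1]
        with pytest.raises(QCError, match="duplicate"):
            qc.field_heatmap_matrix(tab, "y", "E")

    def test_flattening_recovers_records(self):
        tab = self._tab()
        grid = qc.field_heatmap_matrix(tab, "y", "E")
        for _, r in tab.iterrows():
            assert grid[int(r["row"]) - 1, int(r["col"]) - 1] == r["y"]


class TestDistributionSummaries:
    def test_symmetric_no_outliers(self):
        tab = pd.DataFrame({"y": [1.0, 2.0, 3.0, 4.0, 5.0]})
        s = qc.distribution_summaries(tab, "y")
        assert s["boxplot"]["median"] == 3 and s["boxplot"]["iqr"] == 2
        assert len(s["boxplot"]["outliers"]) == 0

    def test_extreme_point_flagged(self):
        tab = pd.DataFrame({"y": [1.0, 2.0, 3.0, 4.0, 100.0]})
        s = qc.distribution_summaries(tab, "y")
        assert list(s["boxplot"]["outliers"]) == [100.0]
        assert s["boxplot"]["whisker_high"] <= 4.0

    def test_too_few_values_omitted(self):
        assert qc.distribution_summaries(pd.DataFrame({"y": [1.0, 2.0, 3.0]}), "y") is None

    def test_qq_near_identity_for_normal_sample(self):
        rng = np.random.default_rng(8)
        tab = pd.DataFrame({"y": rng.standard_normal(2000)})
        s = qc.distribution_summaries(tab, "y")
        inner = slice(50, -50)  # tails are noisy at plotting-position error
        resid = s["qq"]["sample"][inner] - s["qq"]["theoretical"][inner]
        assert np.abs(resid).max() < 0.25


@pytest.fixture(scope="module")
def null_fit(small_trial):
    return fit(model_specs("yield")["model1"], small_trial, starts=1)


class TestHolmOutliers:
    def test_holm_flags_subset_of_unadjusted(self, null_fit):
        out = qc.holm_outliers(null_fit, alpha=0.05)
        raw = set(out.loc[out["p_raw"] < 0.05, "record"])
        holm = set(out.loc[out["flagged"], "record"])
        assert holm <= raw

    def test_gross_outlier_detected(self, small_cfg):
        tab = simulate_trial(make_alpha_lattice(small_cfg), small_cfg)
        spiked, ids = inject_outliers(tab, "yield", count=1, magnitude_sd=8.0, seed=1)
        f = fit(model_specs("yield")["model1"], spiked, starts=1)
        out = qc.holm_outliers(f, alpha=0.05)
        assert set(out.loc[out["flagged"], "record"]) >= set(ids)

    def test_degenerate_residuals_not_flagged(self, null_fit):
        import dataclasses

        degenerate = dataclasses.replace(null_fit, residuals=np.zeros(null_fit.n_obs))
        out = qc.holm_outliers(degenerate, alpha=0.05)
        assert len(out) == 0

    def test_refit_without_outliers_reduces_residual_variance(self, small_cfg):
        tab = simulate_trial(make_alpha_lattice(small_cfg), small_cfg)
        spiked, ids = inject_outliers(tab, "yield", count=2, magnitude_sd=8.0, seed=3)
        f = fit(model_specs("yield")["model1"], spiked, starts=1)
        out = qc.holm_outliers(f, alpha=0.05)
        cleaned = spiked.copy()
        cleaned.loc[out.loc[out["flagged"], "record"], "yield"] = np.nan
        f2 = fit(model_specs("yield")["model1"], cleaned, starts=1)
        assert f2.residual_variance() <= f.residual_variance() + 1e-9


class TestReliability:
    def test_zero_genotype_variance_dropped(self):
        tab = balanced_oneway(80, 2, sigma2_g=0.0, sigma2_e=1.0, seed=31)
        from trialkit.reml import ModelSpec, RandomTerm, ResidualSpec
        from trialkit.covstruct import CovarianceSpec

        iid = CovarianceSpec("identity", 1, {"sigma2": 1.0})
        f = fit(ModelSpec("y", random=(RandomTerm("genotype", ("genotype",), iid),)),
                tab, starts=1)
        value, keep = qc.trial_reliability(f)
        assert not keep
        if f.varcomp["genotype"].params["sigma2"] <= 1e-8:
            assert value == 0.0
        else:  # boundary estimate slightly above the collapse cutoff
            assert value < 0.01

    def test_balanced_closed_form(self):
        # sigma2_g = sigma2_e = 1, 2 reps -> reliability ~2/3 -> kept
        from trialkit.covstruct import CovarianceSpec
        from trialkit.reml import ModelSpec, RandomTerm

        tab = balanced_oneway(120, 2, sigma2_g=1.0, sigma2_e=1.0, seed=17)
        iid = CovarianceSpec("identity", 1, {"sigma2": 1.0})
        f = fit(ModelSpec("y", random=(RandomTerm("genotype", ("genotype",), iid),)),
                tab, starts=1)
        value, keep = qc.trial_reliability(f)
        sg = f.varcomp["genotype"].params["sigma2"]
        se = f.residual_variance()
        assert value == pytest.approx(sg / (sg + se / 2), abs=1e-6)
        assert keep

    def test_low_signal_trial_dropped(self):
        # 400 genotypes keep the sampling sd of sigma2_g-hat (~0.05) well
        # below the 0.125 value at which H_c would cross the 0.2 threshold
        drops = 0
        for s in range(5):
            tab = balanced_oneway(400, 2, sigma2_g=0.05, sigma2_e=1.0, seed=700 + s)
            from trialkit.reml import ModelSpec, RandomTerm
            from trialkit.covstruct import CovarianceSpec

            iid = CovarianceSpec("identity", 1, {"sigma2": 1.0})
            f = fit(ModelSpec("y", random=(RandomTerm("genotype", ("genotype",), iid),)),
                    tab, starts=1)
            _, keep = qc.trial_reliability(f)
            drops += (not keep)
        assert drops >= 4
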