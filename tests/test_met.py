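import numpy as np
import pandas as pd
import pytest

from trialkit import met
from trialkit.covstruct import CovarianceSpec
from trialkit.reml import ModelSpec, RandomTerm, ResidualSpec, fit
from trialkit.synthdata import SimConfig, simulate_met


@pytest.fixture(scope="module")
def met_result(met_table):
    return met.fit_met_single_stage(
        met_table, "yield", model_ids=(1, 2, 3, 6, 7, 8), starts=1
    )


@pytest.fixture(scope="module")
def fa_met():
    cfg = SimConfig(
        n_geno=40, n_rep=2, n_block=4, rows=10, cols=8, n_env=4,
        fa_loadings=np.array([[1.2], [1.0], [0.8], [0.6]]), fa_psi=np.full(4, 0.2),
        sigma2_block=0.1, rho_r=0.0, rho_c=0.0, seed=31,
    )
    tab, truth = simulate_met(cfg, return_truth=True)
    res = met.fit_met_single_stage(tab, "yield", model_ids=(8,), starts=2)
    return cfg, tab, truth, res


class TestSingleStage:
    def test_cs_equivalence_of_models_1_and_2(self, met_result):
        assert met_result.fits[1].loglik == pytest.approx(
            met_result.fits[2].loglik, abs=1e-4
        )

    def test_nesting_chain(self, met_result):
        # diagonal G is nested in corh and FA(1); CS is nested in corh
        tol = 1e-4
        assert met_result.fits[7].loglik >= met_result.fits[6].loglik - tol
        assert met_result.fits[8].loglik >= met_result.fits[6].loglik - tol
        assert met_result.fits[7].loglik >= met_result.fits[3].loglik - tol

    def test_best_is_minimum_aic(self, met_result):
        conv = met_result.comparison[met_result.comparison["converged"]]
        assert met_result.best == conv.iloc[0]["model"]

    def test_gxe_blup_table_covers_all_cells(self, met_result, met_table):
        wide = met_result.gxe_blups
        assert wide.shape == (met_table["genotype"].nunique(), met_table["env"].nunique())
        assert not wide.isna().any().any()

    def test_cs_recovery_of_between_env_covariance(self):
        # CS truth: covariance between envs = sigma2_g
        diffs = []
        for s in range(10):
            cfg = SimConfig(n_geno=50, n_rep=2, n_block=5, rows=10, cols=10,
                            n_env=2, sigma2_g=0.7, sigma2_ge=0.3,
                            rho_r=0.0, rho_c=0.0, seed=400 + s)
            tab = simulate_met(cfg)
            res = met.fit_met_single_stage(tab, "yield", model_ids=(2,), starts=1)
            diffs.append(res.env_cov.iloc[0, 1] - 0.7)
        assert abs(np.mean(diffs)) < 0.1


class TestEnvCorrelation:
    def _fake_fit(self, g_spec, met_table):
        spec = ModelSpec(
            "yield", fixed=("env_rep",),
            random=(RandomTerm("ge", ("env", "genotype"), g_spec),),
        )
        data = met._prepare(met_table)
        return fit(spec, data, starts=1, max_iter=0)

    def test_identical_fa_loadings_give_unit_correlation(self):
        spec = CovarianceSpec("fa", 2, {"loadings": np.ones((2, 1)), "psi": np.zeros(2)})
        cov = spec.realize()
        sd = np.sqrt(np.diag(cov))
        np.testing.assert_allclose(cov / np.outer(sd, sd), np.ones((2, 2)))

    def test_diagonal_g_gives_identity_correlation(self, met_table):
        res = met.fit_met_single_stage(met_table, "yield", model_ids=(6,), starts=1)
        cor = res.env_cor.to_numpy()
        np.testing.assert_allclose(cor, np.eye(len(cor)), atol=1e-10)

    def test_psd_and_unit_diagonal(self, met_result):
        cov = met_result.env_cov.to_numpy()
        assert np.linalg.eigvalsh(cov).min() > -1e-8
        np.testing.assert_allclose(np.diag(met_result.env_cor.to_numpy()), 1.0)


class TestFAExtractors:
    def test_fa_recovers_env_covariance(self, fa_met):
        cfg, tab, truth, res = fa_met
        true_cov = truth["genetic_covariance"]
        est = res.env_cov.to_numpy()
        rel = np.linalg.norm(est - true_cov) / np.linalg.norm(true_cov)
        assert rel < 0.5  # single replicate; the tight bound is a mean property

    def test_latent_slopes_track_factor_scores(self):
        # six environments, three replicates: per-genotype slope reliability
        # is replication-limited, so the recovery bound scales with the design
        lam_true = np.array([[1.3], [1.1], [1.0], [0.9], [0.7], [0.5]])
        cfg = SimConfig(
            n_geno=60, n_rep=3, n_block=4, rows=12, cols=15, n_env=6,
            fa_loadings=lam_true, fa_psi=np.full(6, 0.2),
            sigma2_block=0.1, rho_r=0.0, rho_c=0.0, seed=97,
        )
        tab, truth = simulate_met(cfg, return_truth=True)
        res = met.fit_met_single_stage(tab, "yield", model_ids=(8,), starts=1)
        slopes = met.latent_regression(res, top_n=None)
        lam = lam_true[:, 0]
        gv = truth["genetic_values"]
        true_slopes = (gv.to_numpy() @ lam) / (lam @ lam)
        s = slopes.set_index("genotype")["slope"].reindex(gv.index)
        assert np.corrcoef(s, true_slopes)[0, 1] > 0.85

    def test_top_n_selects_highest_mean_value(self, fa_met):
        *_, res = fa_met
        all_rows = met.latent_regression(res, top_n=None)
        top = met.latent_regression(res, top_n=10)
        assert len(top) == 10
        expected = all_rows.nlargest(10, "mean_value")["genotype"].tolist()
        assert top["genotype"].tolist() == expected

    def test_biplot_k1_fallback_axes(self, fa_met):
        *_, res = fa_met
        bp = met.fa_biplot(res)
        env = bp["env_vectors"]
        assert list(env.columns) == ["axis1", "axis2"]
        assert (env["axis2"] >= 0).all()  # sqrt(psi) fallback axis
        scores = bp["genotype_scores"]
        assert scores["selected"].sum() == max(1, int(np.ceil(len(scores) / 10)))

    def test_biplot_requires_fa(self, met_table):
        res = met.fit_met_single_stage(met_table, "yield", model_ids=(1, 2), starts=1)
        with pytest.raises(ValueError, match="factor-analytic"):
            met.fa_biplot(res)

    def test_biplot_scores_reconstruct_values(self, fa_met):
        *_, res = fa_met
        bp = met.fa_biplot(res)
        fa_fit = res.fa_fit()
        values = met.gxe_blup_table(fa_fit)
        A = bp["env_vectors"].to_numpy()
        S = bp["genotype_scores"][["axis1", "axis2"]].to_numpy()
        recon = S @ A.T
        resid = values.to_numpy() - recon
        assert np.linalg.norm(resid) / np.linalg.norm(values.to_numpy()) < 0.5


class TestTwoStage:
    def test_weight_is_reciprocal_squared_se(self, met_table):
        s1, _ = met.two_stage(met_table, "yield", stage1_models=("model1",), starts=1)
        np.testing.assert_allclose(s1.table["weight"], 1.0 / s1.table["se"] ** 2)

    def test_stage1_covers_all_nonempty_cells(self, met_table):
        s1, _ = met.two_stage(met_table, "yield", stage1_models=("model1",), starts=1)
        cells = met_table.groupby(["env", "genotype"])["yield"].count()
        expected = int((cells > 0).sum())
        assert len(s1.table) == expected

    def test_matches_single_stage_under_balance(self):
        # the near-equivalence of the two routes holds for balanced iid data
        cfg = SimConfig(n_geno=40, n_rep=2, n_block=4, rows=10, cols=8, n_env=3,
                        sigma2_g=0.8, sigma2_ge=0.3, sigma2_block=0.1,
                        rho_r=0.0, rho_c=0.0, seed=61)
        met_table = simulate_met(cfg)
        s1, s2 = met.two_stage(met_table, "yield", stage1_models=("model1",), starts=1)
        res = met.fit_met_single_stage(met_table, "yield", model_ids=(1,), starts=1)
        a = s2.blups["genotype"].set_index("genotype")["blup"]
        b = res.fits[1].blups["genotype"].set_index("genotype")["blup"]
        assert a.corr(b.reindex(a.index)) > 0.99

    def test_equal_weights_match_unweighted_up_to_rescaling(self):
        rng = np.random.default_rng(9)
        genos = [f"G{i}" for i in range(30)]
        envs = ["E1", "E2", "E3"]
        rows = [
            {"env": e, "genotype": g,
             "blue": rng.normal(10, 1), "se": 0.5, "weight": 4.0}
            for e in envs for g in genos
        ]
        tab = pd.DataFrame(rows)
        iid = CovarianceSpec("identity", 1, {"sigma2": 1.0})
        random = (
            RandomTerm("genotype", ("genotype",), iid),
            RandomTerm("env", ("env",), iid),
            RandomTerm("ge", ("env", "genotype"), iid),
        )
        weighted = fit(
            ModelSpec("blue", random=random,
                      residual=ResidualSpec("iid", fixed_sigma2=1.0), weights="weight"),
            tab, starts=1,
        )
        free = fit(ModelSpec("blue", random=random, residual=ResidualSpec("iid")),
                   tab, starts=1)
        a = weighted.blups["genotype"]["blup"]
        b = free.blups["genotype"]["blup"]
        assert np.corrcoef(a, b)[0, 1] > 0.999
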