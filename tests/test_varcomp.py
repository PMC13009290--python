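import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from growvar import (
    SimConfig,
    build_design,
    compute_grm,
    heritability,
    predict_ebv,
    reml_bivariate,
    reml_loglik,
    reml_univariate,
    simulate_genotypes,
    simulate_trait_pair,
)
from growvar.varcomp import RemlError


def _sim_pheno(grm, sa, se, seed, mu=0.0):
    rng = np.random.default_rng(seed)
    n = grm.n
    L = np.linalg.cholesky(grm.G)
    return mu + np.sqrt(sa) * (L @ rng.standard_normal(n)) + np.sqrt(se) * rng.standard_normal(n)


@pytest.fixture(scope="module")
def family_grm():
    cfg = SimConfig(n_fish_per_pond=(100, 100), n_sires=10, n_dams=25, n_snps=1500, seed=21)
    ped, dos = simulate_genotypes(cfg, seed=21)
    return compute_grm(dos, ped["fish_id"])


class TestBuildDesign:
    @staticmethod
    def _table(grm, n=24):
        rng = np.random.default_rng(0)
        return pd.DataFrame(
            {
                "fish_id": grm.ids[:n],
                "pond": "aerated",
                "hapa": 1 + np.arange(n) % 4,
                "sex": np.array(["male", "female", "unknown"])[np.arange(n) % 3],
                "start_weight": rng.uniform(30, 50, n),
                "w5": rng.uniform(400, 900, n),
            }
        )

    def test_full_rank_coding_columns(self, family_grm):
        tab = self._table(family_grm)
        y, X, ids, names = build_design(tab, "w5", family_grm)
        # mean + 3 hapa contrasts + 2 sex contrasts
        assert X.shape[1] == 6
        assert np.linalg.matrix_rank(X) == 6

    def test_single_sex_level_collapses(self, family_grm):
        tab = self._table(family_grm)
        tab["sex"] = "male"
        _, X, _, names = build_design(tab, "w5", family_grm)
        assert X.shape[1] == 4  # mean + 3 hapa

    def test_covariate_and_hand_built_row(self, family_grm):
        tab = self._table(family_grm)
        y, X, ids, names = build_design(tab, "w5", family_grm, covariate_sw=True)
        assert names[-1] == "b_SW"
        i = 5  # hapa 2, sex unknown given the cyclic layout
        row = tab.iloc[i]
        expected = np.zeros(7)
        expected[0] = 1.0
        expected[names.index(f"hapa_{row['hapa']}")] = 1.0
        expected[names.index(f"sex_{row['sex']}")] = 1.0
        expected[-1] = row["start_weight"]
        np.testing.assert_allclose(X[i], expected)

    def test_missing_response_rows_dropped(self, family_grm):
        tab = self._table(family_grm)
        tab.loc[3, "w5"] = np.nan
        y, X, ids, _ = build_design(tab, "w5", family_grm)
        assert len(y) == len(tab) - 1
        assert tab.loc[3, "fish_id"] not in ids

    def test_fish_absent_from_grm_errors(self, family_grm):
        tab = self._table(family_grm)
        tab.loc[0, "fish_id"] = "GHOST"
        with pytest.raises(KeyError, match="GHOST"):
            build_design(tab, "w5", family_grm)


class TestUnivariate:
    def test_null_heritability_boundary(self, family_grm):
        y = _sim_pheno(family_grm, sa=0.0, se=1.0, seed=1)
        res = reml_univariate(y, np.ones((family_grm.n, 1)), family_grm, family_grm.ids)
        assert res.h2[res.traits[0]] == pytest.approx(0.0, abs=0.05)
        assert res.boundary["sigma2_a"] or res.h2[res.traits[0]] < 0.05

    def test_matches_derivative_free_oracle_small_n(self, family_grm):
        """AI-REML optimum equals a Nelder-Mead maximization of the same
        restricted likelihood over log-variances, n = 50."""
        idx = list(range(50))
        ids = [family_grm.ids[i] for i in idx]
        sub = family_grm.G[np.ix_(idx, idx)]
        from growvar.grm import RelationshipMatrix

        g50 = RelationshipMatrix(ids=ids, G=sub, blend=family_grm.blend)
        y = _sim_pheno(g50, sa=0.8, se=0.8, seed=2, mu=1.0)
        X = np.ones((50, 1))
        res = reml_univariate(y, X, g50, ids)
        V_parts = [g50.G, np.eye(50)]
        opt = optimize.minimize(
            lambda p: -reml_loglik(np.exp(p), y, X, V_parts),
            np.log([0.5, 0.5]),
            method="Nelder-Mead",
            options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 6000, "maxfev": 6000},
        )
        np.testing.assert_allclose(res.theta, np.exp(opt.x), atol=1e-4)
        assert res.loglik == pytest.approx(-opt.fun, abs=1e-6)

    def test_loglik_monotone_and_convergence_trace(self, family_grm):
        y = _sim_pheno(family_grm, sa=0.5, se=1.0, seed=3)
        res = reml_univariate(y, np.ones((family_grm.n, 1)), family_grm, family_grm.ids)
        ll = res.trace["loglik"].to_numpy()
        assert res.converged
        assert np.all(np.diff(ll) >= -1e-9)

    def test_estimates_invariant_to_fish_order(self, family_grm):
        y = _sim_pheno(family_grm, sa=0.5, se=1.0, seed=4)
        X = np.ones((family_grm.n, 1))
        res1 = reml_univariate(y, X, family_grm, family_grm.ids)
        perm = np.random.default_rng(5).permutation(family_grm.n)
        res2 = reml_univariate(y[perm], X, family_grm, [family_grm.ids[i] for i in perm])
        np.testing.assert_allclose(res1.theta, res2.theta, rtol=1e-6)

    def test_ebv_matches_direct_gls_algebra(self, family_grm):
        """MME/BLUP solution equals sigma2_A G Z' V^-1 (y - X beta_gls)."""
        idx = list(range(30))
        from growvar.grm import RelationshipMatrix

        g = RelationshipMatrix(
            ids=[family_grm.ids[i] for i in idx],
            G=family_grm.G[np.ix_(idx, idx)],
            blend=family_grm.blend,
        )
        y = _sim_pheno(g, sa=1.0, se=0.5, seed=6)
        X = np.ones((30, 1))
        res = reml_univariate(y, X, g, g.ids)
        sa, se = res.theta
        V = sa * g.G + se * np.eye(30)
        Vinv = np.linalg.inv(V)
        beta = np.linalg.solve(X.T @ Vinv @ X, X.T @ Vinv @ y)
        direct = sa * g.G @ Vinv @ (y - X @ beta)
        np.testing.assert_allclose(predict_ebv(res)["ebv"].to_numpy(), direct, atol=1e-8)

    def test_zero_additive_variance_shrinks_ebvs(self, family_grm):
        y = _sim_pheno(family_grm, sa=0.0, se=1.0, seed=7)
        res = reml_univariate(y, np.ones((family_grm.n, 1)), family_grm, family_grm.ids)
        assert np.abs(predict_ebv(res)["ebv"]).max() < 0.1


class TestHeritabilityArithmetic:
    @pytest.mark.parametrize(
        "sa, sp, expected",
        [
            (0.440, 1.563, 0.28),
            (8444.79, 37274.0, 0.23),
            (0.0, 1.0, 0.0),
        ],
    )
    def test_ratio(self, sa, sp, expected):
        h2, _ = heritability(sa, sp)
        assert h2 == pytest.approx(expected, abs=0.005)

    def test_h2_above_one_flagged(self):
        h2, se = heritability(2.0, 1.5)
        assert np.isnan(h2)

    def test_delta_method_se(self):
        cov = np.array([[0.04, -0.01], [-0.01, 0.05]])
        sa, sp = 0.4, 1.5
        h2, se = heritability(sa, sp, cov)
        grad = np.array([sp - sa, -sa]) / sp**2
        assert se == pytest.approx(float(np.sqrt(grad @ cov @ grad)))


class TestBivariate:
    def test_duplicated_trait_r_g_at_upper_boundary(self, family_grm):
        y = _sim_pheno(family_grm, sa=0.8, se=0.4, seed=8)
        X = np.ones((family_grm.n, 1))
        res = reml_bivariate(
            y, X, family_grm.ids, y.copy(), X, family_grm.ids, family_grm,
            residual_cov_free=True,
        )
        # the likelihood diverges toward the singular r = 1 model; the fit
        # must approach that boundary (it can never reach it exactly)
        assert res.r_g > 0.9
        assert res.r_p is not None and res.r_p > 0.9

    def test_same_fish_requires_free_residual_cov(self, family_grm):
        y = _sim_pheno(family_grm, sa=0.5, se=0.5, seed=9)
        X = np.ones((family_grm.n, 1))
        with pytest.raises(ValueError, match="residual covariance"):
            reml_bivariate(y, X, family_grm.ids, y, X, family_grm.ids, family_grm,
                           residual_cov_free=False)

    def test_disjoint_fish_requires_constrained_residual_cov(self, family_grm):
        half = family_grm.n // 2
        ids1 = family_grm.ids[:half]
        ids2 = family_grm.ids[half:]
        y = _sim_pheno(family_grm, sa=0.5, se=0.5, seed=10)
        with pytest.raises(ValueError, match="same fish"):
            reml_bivariate(y[:half], np.ones((half, 1)), ids1,
                           y[half:], np.ones((family_grm.n - half, 1)), ids2,
                           family_grm, residual_cov_free=True)

    def test_matches_derivative_free_oracle_small_n(self, family_grm):
        """Bivariate AI-REML optimum equals Nelder-Mead on the identical
        restricted likelihood (40 fish, both traits observed)."""
        idx = list(range(40))
        from growvar.grm import RelationshipMatrix

        g = RelationshipMatrix(
            ids=[family_grm.ids[i] for i in idx],
            G=family_grm.G[np.ix_(idx, idx)],
            blend=family_grm.blend,
        )
        C = np.array([[0.8, 0.3], [0.3, 0.6]])
        R = np.array([[0.7, 0.1], [0.1, 0.9]])
        df, _ = simulate_trait_pair(40, C, R, g, seed=11)
        X = np.ones((40, 1))
        res = reml_bivariate(
            df["y1"].to_numpy(), X, g.ids, df["y2"].to_numpy(), X, g.ids, g,
            residual_cov_free=True,
        )
        n1 = 40
        N = 80
        V_parts = []
        for block in ("A11", "A12", "A22", "E11", "E12", "E22"):
            M = np.zeros((N, N))
            if block == "A11":
                M[:n1, :n1] = g.G
            elif block == "A12":
                M[:n1, n1:] = g.G
                M[n1:, :n1] = g.G
            elif block == "A22":
                M[n1:, n1:] = g.G
            elif block == "E11":
                M[:n1, :n1] = np.eye(n1)
            elif block == "E12":
                M[:n1, n1:] = np.eye(n1)
                M[n1:, :n1] = np.eye(n1)
            else:
                M[n1:, n1:] = np.eye(n1)
            V_parts.append(M)
        yy = np.concatenate([df["y1"], df["y2"]])
        XX = np.zeros((N, 2))
        XX[:n1, 0] = 1
        XX[n1:, 1] = 1

        def nll(p):
            th = [np.exp(p[0]), p[1], np.exp(p[2]), np.exp(p[3]), p[4], np.exp(p[5])]
            return -reml_loglik(th, yy, XX, V_parts)

        p0 = np.array([np.log(0.7), 0.2, np.log(0.7), np.log(0.7), 0.1, np.log(0.7)])
        opt = optimize.minimize(nll, p0, method="Nelder-Mead",
                                options={"xatol": 1e-12, "fatol": 1e-14,
                                         "maxiter": 20000, "maxfev": 20000})
        theta_nm = np.array(
            [np.exp(opt.x[0]), opt.x[1], np.exp(opt.x[2]),
             np.exp(opt.x[3]), opt.x[4], np.exp(opt.x[5])]
        )
        assert res.loglik == pytest.approx(-opt.fun, abs=1e-5)
        np.testing.assert_allclose(res.theta, theta_nm, atol=1e-4)

    def test_univariate_equals_bivariate_marginal_when_uninformative(self, family_grm):
        """With r_g = r_e = 0 generation, the bivariate fit's trait-1
        components agree with the univariate fit."""
        C = np.diag([0.8, 0.5])
        R = np.diag([0.8, 0.9])
        df, _ = simulate_trait_pair(family_grm.n, C, R, family_grm, seed=12)
        X = np.ones((family_grm.n, 1))
        uni = reml_univariate(df["y1"].to_numpy(), X, family_grm, family_grm.ids)
        biv = reml_bivariate(df["y1"].to_numpy(), X, family_grm.ids,
                             df["y2"].to_numpy(), X, family_grm.ids,
                             family_grm, residual_cov_free=True, traits=("t1", "t2"))
        assert biv.sigma2_a["t1"] == pytest.approx(uni.theta[0], rel=0.15, abs=0.05)
        assert biv.sigma2_e["t1"] == pytest.approx(uni.theta[1], rel=0.15, abs=0.05)

    def test_cross_env_ebv_per_environment(self, family_grm):
        half = family_grm.n // 2
        C = np.array([[0.6, 0.3], [0.3, 0.6]])
        R = np.diag([0.6, 0.6])
        df, _ = simulate_trait_pair(family_grm.n, C, R, family_grm, seed=13, disjoint=True)
        m1 = df["y1"].notna()
        m2 = df["y2"].notna()
        res = reml_bivariate(
            df.loc[m1, "y1"].to_numpy(), np.ones((half, 1)), df.index[m1].tolist(),
            df.loc[m2, "y2"].to_numpy(), np.ones((family_grm.n - half, 1)), df.index[m2].tolist(),
            family_grm, residual_cov_free=False, traits=("env_a", "env_b"),
        )
        ebv = predict_ebv(res)
        # every animal gets a prediction in both environments
        assert ebv.shape == (family_grm.n, 2)
        assert np.isfinite(ebv.to_numpy()).all()

    def test_nonconverged_ebv_prediction_refused(self, family_grm):
        y = _sim_pheno(family_grm, sa=0.5, se=0.5, seed=14)
        X = np.ones((family_grm.n, 1))
        res = reml_univariate(y, X, family_grm, family_grm.ids)
        res.converged = False
        with pytest.raises(RemlError):
            predict_ebv(res)
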