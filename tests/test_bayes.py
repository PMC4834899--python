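"""Bayesian model assembly and Gibbs sampler correctness."""

import numpy as np
import pytest

from poegp import bayes, kinship
from poegp.genotypes import OrderedGenotypes


def make_genotypes(rng, n=30, p=12):
    return OrderedGenotypes(
        ids=np.arange(1, n + 1),
        marker_ids=np.array([f"m{j}" for j in range(p)]),
        maternal=rng.integers(0, 2, size=(n, p)),
        paternal=rng.integers(0, 2, size=(n, p)),
    )


class TestCoding:
    def test_additive_codes(self):
        g = OrderedGenotypes(ids=[1, 2, 3, 4], marker_ids=["m"],
                             maternal=[[0], [1], [0], [1]],
                             paternal=[[0], [0], [1], [1]])
        # A2A2 -> 0, A2A1/A1A2 -> 1, A1A1 -> 2
        assert bayes.code_additive(g).ravel().tolist() == [0, 1, 1, 2]

    def test_w_is_sum_of_indicators(self, rng):
        g = make_genotypes(rng)
        assert np.array_equal(bayes.code_additive(g), g.maternal + g.paternal)

    def test_parental_passthrough_and_validation(self, rng):
        g = make_genotypes(rng)
        mat, pat = bayes.code_parental(g)
        assert np.array_equal(mat, g.maternal) and np.array_equal(pat, g.paternal)
        with pytest.raises(ValueError, match="binary"):
            OrderedGenotypes(ids=[1], marker_ids=["m"], maternal=[[2]],
                             paternal=[[0]])


class TestAssembly:
    def test_poe_doubles_marker_coefficients(self, rng):
        g = make_genotypes(rng, n=40, p=100)
        add = bayes.assemble_model("ADD", g)
        poe = bayes.assemble_model("POE", g)
        assert add.n_marker_coefficients == 100
        assert poe.n_marker_coefficients == 200

    def test_addpoe_column_arithmetic(self, rng):
        g = make_genotypes(rng, n=40, p=50)
        phi = [f"m{j}" for j in range(5)]
        spec = bayes.assemble_model("ADD_POE", g, phi=phi)
        assert spec.n_marker_coefficients == 45 + 10

    def test_addpoe_empty_phi_reduces_to_add(self, rng):
        g = make_genotypes(rng, n=40, p=50)
        spec = bayes.assemble_model("ADD_POE", g, phi=[])
        add = bayes.assemble_model("ADD", g)
        assert len(spec.lasso) == 1
        assert np.allclose(spec.lasso[0].X, add.lasso[0].X)

    def test_unknown_phi_rejected(self, rng):
        g = make_genotypes(rng)
        with pytest.raises(ValueError, match="unknown markers"):
            bayes.assemble_model("ADD_POE", g, phi=["nope"])

    def test_gametic_requires_kinship(self, rng):
        g = make_genotypes(rng)
        with pytest.raises(ValueError, match="relationship"):
            bayes.assemble_model("POE", g, include_gametic=True)

    def test_cage_random_effect_block(self, rng):
        g = make_genotypes(rng, n=30)
        cages = np.repeat(np.arange(6), 5)
        spec = bayes.assemble_model("ADD", g, cage=rng.permutation(cages))
        blk = [b for b in spec.gaussian if b.name == "cage"]
        assert len(blk) == 1
        K = blk[0].K_eff
        # block-diagonal association kernel: 1 within a cage, 0 across
        assert set(np.unique(K)) == {0.0, 1.0}
        assert np.allclose(K.sum(axis=1), 5.0)

    def test_marker_columns_centered(self, rng):
        g = make_genotypes(rng)
        spec = bayes.assemble_model("ADD", g)
        assert np.abs(np.asarray(spec.lasso[0].X).mean(axis=0)).max() < 1e-6


class TestDefaultPriors:
    def _spec(self, rng, n=40):
        g = make_genotypes(rng, n=n)
        return g, bayes.assemble_model("ADD", g)

    def test_residual_scale_formula(self, rng):
        g, spec = self._spec(rng)
        y = rng.normal(size=spec.n)
        y = (y - y.mean()) / y.std()  # var exactly 1
        priors = bayes.default_priors(y, spec)
        assert priors.S_e == pytest.approx(3.5)  # 1 * 0.5 * (5 + 2)

    def test_constant_phenotype_rejected(self, rng):
        g, spec = self._spec(rng)
        with pytest.raises(ValueError, match="variance"):
            bayes.default_priors(np.ones(spec.n), spec)

    def test_scale_equivariance(self, rng):
        g, spec = self._spec(rng)
        y = rng.normal(size=spec.n)
        p1 = bayes.default_priors(y, spec)
        p2 = bayes.default_priors(np.sqrt(2.0) * y, spec)
        assert p2.S_e == pytest.approx(2.0 * p1.S_e)


def ridge_problem(rng, n=50, p=20):
    X = rng.normal(size=(n, p))
    beta = rng.normal(scale=0.5, size=p)
    y = X @ beta + rng.normal(scale=0.7, size=n)
    return X, y


class TestSampler:
    def test_frozen_tau_matches_ridge(self, rng):
        """With tau2 frozen the marker conditional is a ridge penalty, so the
        posterior mean must match the closed-form ridge solution."""
        X, y = ridge_problem(rng)
        n, p = X.shape
        tau2 = 0.5
        Xc, mu = bayes._center(X)
        spec = bayes.ModelSpec(kind="ADD", ids=np.arange(n))
        spec.fixed.append(bayes.FixedBlock("fixed", np.ones((n, 1))))
        spec.lasso.append(bayes.LassoMarkerBlock("m", Xc, mu, np.arange(p),
                                                 fixed_tau2=tau2))
        priors = bayes.default_priors(y, spec)
        mc = bayes.McmcConfig(iterations=8000, burn_in=1000, thin=1, seed=3)
        fit = bayes.run_gibbs(spec, priors, mc, y, update_lambda=False)
        draws = fit.samples["alpha_m"]
        Z = np.hstack([np.ones((n, 1)), np.asarray(Xc, dtype=np.float64)])
        D = np.diag([0.0] + [1.0 / tau2] * p)
        ridge = np.linalg.solve(Z.T @ Z + D, Z.T @ y)[1:]
        # 3 x Monte-Carlo SE with a conservative effective sample size
        ess = len(draws) / 10.0
        mcse = draws.std(axis=0) / np.sqrt(ess)
        assert np.all(np.abs(draws.mean(axis=0) - ridge) < 3 * mcse + 1e-3)

    def test_pedigree_blup_oracle(self, rng):
        """A-kernel-only model at fixed variances equals mixed-model BLUP."""
        n = 40
        ids = np.arange(1, n + 1)
        sire = np.zeros(n, int)
        dam = np.zeros(n, int)
        for i in range(10, n):
            sire[i] = rng.integers(1, i // 2)
            dam[i] = rng.integers(i // 2, i)
        ped = kinship.Pedigree(ids, sire, dam)
        A = kinship.additive_A(ped)
        su2, se2 = 2.0, 1.0
        u = np.linalg.cholesky(A + 1e-10 * np.eye(n)) @ rng.normal(size=n)
        y = 3.0 + np.sqrt(su2) * u + rng.normal(scale=np.sqrt(se2), size=n)
        spec = bayes.ModelSpec(kind="ADD", ids=ids)
        spec.fixed.append(bayes.FixedBlock("fixed", np.ones((n, 1))))
        spec.gaussian.append(bayes.GaussianRandomBlock("u", A, fixed_var=su2))
        priors = bayes.default_priors(y, spec)
        mc = bayes.McmcConfig(iterations=20000, burn_in=2000, thin=1, seed=5)
        fit = bayes.run_gibbs(spec, priors, mc, y, fixed_sigma2_e=se2)
        lhs = np.block([
            [np.full((1, 1), float(n)), np.ones((1, n))],
            [np.ones((n, 1)), np.eye(n) + np.linalg.inv(A) * se2 / su2]])
        sol = np.linalg.solve(lhs, np.concatenate([[y.sum()], y]))
        mu_draws = fit.samples["beta_fixed0"][:, 0]
        mcse_mu = mu_draws.std() / np.sqrt(len(mu_draws) / 20.0)
        assert abs(mu_draws.mean() - sol[0]) < 3 * mcse_mu + 1e-3
        # u has no stored chains; bound the error by the BLUP shrinkage scale
        assert np.abs(fit.means["h_u"] - sol[1:]).max() < 0.12

    def test_retained_count_formula(self):
        mc = bayes.McmcConfig(iterations=60_000, burn_in=10_000, thin=10)
        assert mc.n_retained == 5000
        mc2 = bayes.McmcConfig(iterations=15_000, burn_in=3_000, thin=10)
        assert mc2.n_retained == 1200

    def test_variance_draws_positive(self, rng):
        X, y = ridge_problem(rng, n=40, p=10)
        Xc, mu = bayes._center(X)
        spec = bayes.ModelSpec(kind="ADD", ids=np.arange(40))
        spec.fixed.append(bayes.FixedBlock("fixed", np.ones((40, 1))))
        spec.lasso.append(bayes.LassoMarkerBlock("m", Xc, mu, np.arange(10)))
        spec.gaussian.append(bayes.GaussianRandomBlock("id", np.eye(40)))
        priors = bayes.default_priors(y, spec)
        mc = bayes.McmcConfig(iterations=500, burn_in=100, thin=2, seed=0)
        fit = bayes.run_gibbs(spec, priors, mc, y)
        assert fit.n_retained == mc.n_retained
        assert (fit.samples["sigma2_e"] > 0).all()
        assert (fit.samples["sigma2_id"] > 0).all()
        assert (fit.samples["lambda2_0"] > 0).all()

    def test_masked_prediction_ignores_supplied_values(self, rng):
        g = make_genotypes(rng, n=40, p=8)
        spec = bayes.assemble_model("ADD", g)
        y = rng.normal(size=40)
        obs = np.ones(40, bool)
        obs[30:] = False
        priors = bayes.default_priors(y, spec, mask_observed=obs)
        mc = bayes.McmcConfig(iterations=400, burn_in=100, thin=1, seed=9)
        fit1 = bayes.run_gibbs(spec, priors, mc, y, mask_observed=obs)
        y2 = y.copy()
        y2[30:] = 999.0
        fit2 = bayes.run_gibbs(spec, priors, mc, y2, mask_observed=obs)
        assert np.array_equal(fit1.linpred_mean, fit2.linpred_mean)

    def test_intercept_only_prediction_is_intercept_mean(self, rng):
        n = 25
        y = rng.normal(size=n)
        spec = bayes.ModelSpec(kind="ADD", ids=np.arange(n))
        spec.fixed.append(bayes.FixedBlock("fixed", np.ones((n, 1))))
        priors = bayes.Priors(S_e=1.0, df_e=5.0, gaussian_S={}, gaussian_df={},
                              lambda_shape=1.1, lambda_rate={}, lambda_init={})
        mc = bayes.McmcConfig(iterations=600, burn_in=100, thin=1, seed=2)
        fit = bayes.run_gibbs(spec, priors, mc, y)
        mu_mean = fit.samples["beta_fixed0"].mean()
        assert np.allclose(fit.linpred_mean, mu_mean)

    def test_posterior_predict_lookup(self, rng):
        g = make_genotypes(rng, n=20, p=5)
        spec = bayes.assemble_model("ADD", g)
        y = rng.normal(size=20)
        priors = bayes.default_priors(y, spec)
        mc = bayes.McmcConfig(iterations=300, burn_in=100, thin=1, seed=1)
        fit = bayes.run_gibbs(spec, priors, mc, y)
        sub = bayes.posterior_predict(fit, [3, 1])
        assert sub[0] == fit.linpred_mean[2] and sub[1] == fit.linpred_mean[0]
        with pytest.raises(KeyError):
            bayes.posterior_predict(fit, [999])

    def test_label_symmetry_of_parental_blocks(self, rng):
        """Swapping the maternal and paternal matrices swaps the posterior
        summaries of the two parental effect blocks (up to MC error)."""
        g = make_genotypes(rng, n=60, p=6)
        y = (g.maternal @ np.array([1.0, -0.5, 0, 0.3, 0, 0])
             + g.paternal @ np.array([0, 0.4, -0.8, 0, 0, 0.2])
             + rng.normal(scale=0.3, size=60))
        swapped = OrderedGenotypes(ids=g.ids, marker_ids=g.marker_ids,
                                   maternal=g.paternal, paternal=g.maternal)
        mc = bayes.McmcConfig(iterations=6000, burn_in=1000, thin=1, seed=4)
        res = {}
        for tag, geno in (("orig", g), ("swap", swapped)):
            spec = bayes.assemble_model("POE", geno)
            priors = bayes.default_priors(y, spec)
            fit = bayes.run_gibbs(spec, priors, mc, y)
            res[tag] = (fit.samples["alpha_markers_maternal"],
                        fit.samples["alpha_markers_paternal"])
        for a, b in ((res["orig"][0], res["swap"][1]),
                     (res["orig"][1], res["swap"][0])):
            mcse = a.std(axis=0) / np.sqrt(len(a) / 10.0)
            assert np.all(np.abs(a.mean(axis=0) - b.mean(axis=0)) < 4 * mcse + 5e-3)

    def test_all_masked_rejected(self, rng):
        g = make_genotypes(rng, n=10, p=3)
        spec = bayes.assemble_model("ADD", g)
        y = rng.normal(size=10)
        priors = bayes.default_priors(y, spec)
        with pytest.raises(ValueError, match="observed"):
            bayes.run_gibbs(spec, priors,
                            bayes.McmcConfig(iterations=10, burn_in=1, thin=1),
                            y, mask_observed=np.zeros(10, bool))


class TestCalibration:
    def test_credible_interval_coverage(self):
        """Simulation-based calibration at toy scale: when the data truly come
        from the model's prior, 90% credible intervals for a marker effect
        must cover the truth 90% of the time."""
        n, p = 100, 20
        n_rep = 200
        rng = np.random.default_rng(77)
        X = rng.normal(size=(n, p))
        Xc, mu = bayes._center(X)
        X64 = np.asarray(Xc, dtype=np.float64)
        S_e, df_e = 1.0, 6.0
        shape, rate = 3.0, 2.0
        hits = 0
        for r in range(n_rep):
            lam2 = rng.gamma(shape, 1.0 / rate)
            tau2 = rng.exponential(2.0 / lam2, size=p)
            sigma2_e = S_e / rng.chisquare(df_e)
            alpha = rng.normal(0.0, np.sqrt(tau2 * sigma2_e))
            y = X64 @ alpha + rng.normal(0.0, np.sqrt(sigma2_e), size=n)
            spec = bayes.ModelSpec(kind="ADD", ids=np.arange(n))
            spec.lasso.append(bayes.LassoMarkerBlock("m", Xc, mu, np.arange(p)))
            priors = bayes.Priors(S_e=S_e, df_e=df_e, gaussian_S={},
                                  gaussian_df={}, lambda_shape=shape,
                                  lambda_rate={0: rate}, lambda_init={0: 1.0})
            mc = bayes.McmcConfig(iterations=1500, burn_in=300, thin=2,
                                  seed=1000 + r)
            fit = bayes.run_gibbs(spec, priors, mc, y)
            lo, hi = np.quantile(fit.samples["alpha_m"][:, 0], [0.05, 0.95])
            hits += int(lo <= alpha[0] <= hi)
        cover = hits / n_rep
        se = np.sqrt(0.9 * 0.1 / n_rep)
        assert abs(cover - 0.9) < 3 * se
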