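"""Task-complexity models: mixed-model engine, reparameterized latent-error
model, ability factor model, latent joint model, scale-level analysis."""

import copy

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

from conftest import simulate_mixed_long
from surveycog.tch import (
    AbilityFactorModel,
    BinnedComplexityModel,
    LatentAbilityErrorModel,
    LatentErrorModel,
    ModeratedErrorModel,
    _optimize_nll,
    basis_weights,
    complexity_bin,
    scale_level_correlation,
)

TRUTH = dict(g00=0.42, g01=-0.002, g10=0.016, g11=-0.0003)


def simulate_basis_long(n, true_T, means=(0.35, 0.65, 15.0), sigma=0.16,
                        n_items=50, seed=0, ability_sd=None):
    """Direct draw from the complexity-extreme-basis parameterization:
    (u0, u1, ability) jointly normal with covariance ``true_T``."""
    rng = np.random.default_rng(seed)
    c = rng.integers(0, 10, n_items).astype(float)
    M = rng.multivariate_normal(means, true_T, n)
    B = basis_weights(c)
    Y = M[:, :2] @ B.T + rng.normal(0, sigma, (n, n_items))
    long = pd.DataFrame({
        "person_id": np.repeat(np.arange(n), n_items),
        "item_id": np.tile(np.arange(n_items), n),
        "error": Y.ravel(),
        "complexity": np.tile(c, n),
    })
    ability = pd.Series(M[:, 2], index=np.arange(n))
    long["ability"] = np.repeat(ability.to_numpy(), n_items)
    return long, ability, M


def corr_T(v00, v11, v22, r01, r02, r12):
    s = np.sqrt([v00, v11, v22])
    R = np.array([[1, r01, r02], [r01, 1, r12], [r02, r12, 1]])
    return R * np.outer(s, s)


class TestModeratedModel:
    @pytest.fixture(scope="class")
    def fitted(self):
        long = simulate_mixed_long(n_persons=400, n_items=50, seed=1, **{})
        model = ModeratedErrorModel(long)
        return long, model, model.fit()

    def test_loglik_matches_dense_mvn_oracle(self):
        long = simulate_mixed_long(n_persons=20, n_items=12, seed=2)
        fit = ModeratedErrorModel(long).fit()
        g = fit.params
        wide = long.pivot(index="person_id", columns="item_id", values="error")
        c = long.drop_duplicates("item_id").set_index("item_id")["complexity"]
        c = c.loc[wide.columns].to_numpy()
        a = long.groupby("person_id")["ability"].first().to_numpy()
        W = np.column_stack([np.ones_like(c), c])
        V = W @ fit.tau @ W.T + fit.sigma2 * np.eye(len(c))
        ll = sum(
            multivariate_normal.logpdf(
                wide.iloc[i],
                g["intercept"] + g["ability"] * a[i]
                + (g["complexity"] + g["ability_x_complexity"] * a[i]) * c,
                V)
            for i in range(len(a)))
        assert fit.llf == pytest.approx(ll, abs=1e-6 * max(1, abs(ll)))

    def test_fixed_effects_match_statsmodels(self, fitted):
        import statsmodels.formula.api as smf
        long, _, fit = fitted
        md = smf.mixedlm("error ~ ability*complexity", long,
                         groups="person_id", re_formula="~complexity")
        with np.errstate(all="ignore"):
            mf = md.fit(reml=False, method="lbfgs", maxiter=400)
        assert fit.params["intercept"] == pytest.approx(mf.params["Intercept"], abs=2e-3)
        assert fit.params["ability"] == pytest.approx(mf.params["ability"], abs=2e-4)
        assert fit.params["complexity"] == pytest.approx(mf.params["complexity"], abs=5e-4)
        assert fit.params["ability_x_complexity"] == pytest.approx(
            mf.params["ability:complexity"], abs=5e-5)
        # ML optimum found here is at least as good as statsmodels'
        assert fit.llf >= mf.llf - 1e-3

    def test_parameters_recovered(self, fitted):
        _, _, fit = fitted
        assert fit.params["intercept"] == pytest.approx(TRUTH["g00"], abs=0.03)
        assert fit.params["ability"] == pytest.approx(TRUTH["g01"], abs=0.002)
        assert fit.params["complexity"] == pytest.approx(TRUTH["g10"], abs=0.005)
        assert fit.params["ability_x_complexity"] == pytest.approx(
            TRUTH["g11"], abs=3e-4)
        assert fit.sigma2 == pytest.approx(0.17**2, rel=0.1)
        assert fit.tau[0, 0] == pytest.approx(0.004, rel=0.5)
        assert fit.tau[1, 1] == pytest.approx(0.0001, rel=0.5)
        assert np.all(np.linalg.eigvalsh(fit.tau) > -1e-12)

    def test_null_effects_within_two_se(self):
        long = simulate_mixed_long(n_persons=600, n_items=40, g01=0.0, g11=0.0, seed=3)
        fit = ModeratedErrorModel(long).fit()
        assert abs(fit.params["ability"]) < 2 * fit.bse["ability"]
        assert abs(fit.params["ability_x_complexity"]) < 2 * fit.bse["ability_x_complexity"]

    def test_predicted_surface_monotone_in_ability(self, fitted):
        _, _, fit = fitted
        a_grid = np.linspace(0, 27, 20)
        for c in range(10):
            pred = fit.predict(a_grid, np.full_like(a_grid, c))
            assert np.all(np.diff(pred) <= 1e-12)  # both slopes negative here

    def test_sandwich_se_close_to_person_bootstrap(self):
        long = simulate_mixed_long(n_persons=1000, n_items=40, seed=4)
        model = ModeratedErrorModel(long)
        fit = model.fit()
        st = model._stats
        rng = np.random.default_rng(0)
        reps = []
        phi0 = fit._phi
        for _ in range(500):
            idx = rng.integers(0, st.N, st.N)
            bs = copy.copy(st)
            for name in ("Mzz", "Mzf", "Mff", "vz", "vf", "syy", "nj", "a"):
                setattr(bs, name, getattr(st, name)[idx])
            bs.ntot = int(bs.nj.sum())
            best = _optimize_nll(bs.profile_nll, phi0, restarts=0, polish=False)
            _, parts = bs.profile_nll(best.x, return_parts=True)
            reps.append(parts["gamma"][model._perm])
        boot_se = np.std(np.array(reps), axis=0, ddof=1)
        ratio = fit.bse.to_numpy() / boot_se
        assert np.all(fit.bse > 0)
        assert np.all(np.abs(ratio - 1) < 0.3)

    def test_boundary_slope_variance_triggers_reduced_refit(self):
        long = simulate_mixed_long(n_persons=300, n_items=30, seed=1,
                                   tau=np.array([[0.004, 0.0], [0.0, 1e-14]]))
        with pytest.warns(RuntimeWarning, match="random-slope variance"):
            fit = ModeratedErrorModel(long).fit(restarts=0)
        assert fit.boundary
        red = fit.reduced
        assert red.tau.shape == (1, 1)
        # dropping a zero variance component barely changes the likelihood
        assert 0 <= fit.llf - red.llf < 1.0
        assert list(red.params.index) == list(fit.params.index)

    def test_constant_complexity_rejected(self):
        long = simulate_mixed_long(n_persons=30, n_items=10, seed=5)
        long["complexity"] = 4.0
        with pytest.raises(ValueError, match="complexity"):
            ModeratedErrorModel(long)

    def test_random_effects_track_truth(self):
        rng = np.random.default_rng(6)
        long = simulate_mixed_long(n_persons=500, n_items=60, seed=6)
        model = ModeratedErrorModel(long)
        fit = model.fit()
        u = fit.random_effects()
        assert u.shape == (500, 2)
        # EB intercept effects correlate with realized person means
        pm = long.groupby("person_id")["error"].mean()
        assert np.corrcoef(u["u0"], pm.loc[u.index])[0, 1] > 0.3


class TestReparameterizedModel:
    def test_basis_weights_at_extremes(self):
        assert np.allclose(basis_weights([0]), [[1.0, 0.0]])
        assert np.allclose(basis_weights([9]), [[0.0, 1.0]])
        assert np.allclose(basis_weights([3]), [[6 / 9, 3 / 9]])

    def test_likelihood_equivalence_with_moderated_model(self):
        long = simulate_mixed_long(n_persons=400, n_items=50, seed=7,
                                   center_ability=True)
        mod = ModeratedErrorModel(long).fit()
        ability = long.groupby("person_id")["ability"].first()
        rep = LatentErrorModel(long, ability).fit()
        assert rep.llf_conditional == pytest.approx(mod.llf, abs=1e-4)

    def test_parameter_mapping_identities(self):
        long = simulate_mixed_long(n_persons=400, n_items=50, seed=7,
                                   center_ability=True)
        mod = ModeratedErrorModel(long).fit()
        ability = long.groupby("person_id")["ability"].first()
        rep = LatentErrorModel(long, ability).fit()
        # with centered ability: mean at complexity 0 equals the conditional
        # intercept, and the basis means recover the complexity slope
        g = mod.params
        assert rep.gamma["mean_low_complexity"] == pytest.approx(
            g["intercept"], abs=5e-3)
        slope = (rep.gamma["mean_high_complexity"]
                 - rep.gamma["mean_low_complexity"]) / 9
        assert slope == pytest.approx(g["complexity"], abs=1e-3)

    def test_latent_correlation_recovery(self):
        T = corr_T(0.004, 0.006, 16.0, 0.3, -0.10, -0.40)
        long, ability, _ = simulate_basis_long(3000, T, seed=8)
        res = LatentErrorModel(long, ability).fit()
        assert res.corr_high_ability == pytest.approx(-0.40, abs=0.05)
        assert res.corr_low_ability == pytest.approx(-0.10, abs=0.06)

    def test_correlation_se_plausible(self):
        T = corr_T(0.004, 0.006, 16.0, 0.3, -0.10, -0.40)
        long, ability, _ = simulate_basis_long(800, T, seed=9)
        res = LatentErrorModel(long, ability).fit()
        se = res.corr_se()
        assert 0.005 < se["corr_high_ability"] < 0.1

    def test_incomplete_persons_dropped(self):
        long, ability, _ = simulate_basis_long(120, corr_T(
            0.004, 0.006, 16.0, 0.3, -0.1, -0.4), seed=10)
        long = long[~((long["person_id"] < 15) & (long["item_id"] == 0))]
        res = LatentErrorModel(long, ability).fit()
        assert len(res.model.person_ids) == 105


class TestBinnedModel:
    def test_bin_assignment(self):
        assert complexity_bin([0, 1, 2, 3, 4, 5, 6, 7, 8, 9]).tolist() == \
            [1, 1, 2, 2, 3, 3, 4, 4, 5, 5]

    @pytest.fixture(scope="class")
    def linear_truth(self):
        long = simulate_mixed_long(n_persons=1500, n_items=60, seed=11,
                                   g01=-0.004, g11=-0.0008)
        linfit = ModeratedErrorModel(long).fit()
        bmodel = BinnedComplexityModel(long)
        bfit = bmodel.fit()
        return long, linfit, bmodel, bfit

    def test_bin_slopes_monotone_under_linear_truth(self, linear_truth):
        _, _, bmodel, bfit = linear_truth
        slopes = [bfit.params[f"ability_x_bin_{b}"] for b in bmodel.bins_observed]
        assert np.all(np.diff(slopes) < 0)  # increasingly negative

    def test_pct_changes_positive_under_linear_truth(self, linear_truth):
        _, _, bmodel, bfit = linear_truth
        pct = bmodel.ability_slope_changes(bfit)
        assert (pct > 0).all()
        assert pct.is_monotonic_increasing

    def test_bin_predictions_agree_with_linear_model(self, linear_truth):
        long, linfit, bmodel, bfit = linear_truth
        a = np.linspace(5, 25, 9)
        binpred = bmodel.bin_midpoint_predictions(bfit, a)
        mid = {1: 0.5, 2: 2.5, 3: 4.5, 4: 6.5, 5: 8.5}
        lin = np.column_stack([linfit.predict(a, np.full_like(a, mid[b]))
                               for b in bmodel.bins_observed])
        r = np.corrcoef(binpred.to_numpy().ravel(), lin.ravel())[0, 1]
        assert r > 0.99

    def test_single_bin_rejected(self):
        long = simulate_mixed_long(n_persons=30, n_items=10, seed=12)
        long["complexity"] = (long["complexity"] % 2).astype(float)  # bins all 1
        with pytest.raises(ValueError, match="bins"):
            BinnedComplexityModel(long)


class TestFactorModel:
    def _simulate_subtests(self, n, loadings, resid_cov, seed):
        rng = np.random.default_rng(seed)
        lam = np.asarray(loadings)
        g = rng.normal(size=n)
        psi = 1 - lam**2
        Theta = np.diag(psi)
        Theta[0, 1] = Theta[1, 0] = resid_cov
        E = rng.multivariate_normal(np.zeros(4), Theta, n)
        X = g[:, None] * lam + E
        return pd.DataFrame(X, columns=["t1", "t2", "t3", "t4"]), g

    def test_loading_recovery(self):
        df, _ = self._simulate_subtests(5000, [0.8, 0.8, 0.6, 0.4], 0.15, 13)
        res = AbilityFactorModel(df, recall_pair=(0, 1)).fit()
        assert np.allclose(res.loadings, [0.8, 0.8, 0.6, 0.4], atol=0.05)
        assert res.recall_resid_cov == pytest.approx(0.15, abs=0.04)
        assert res.df == 1

    def test_zero_residual_covariance_recovered(self):
        df, _ = self._simulate_subtests(5000, [0.8, 0.8, 0.6, 0.4], 0.0, 14)
        res = AbilityFactorModel(df, recall_pair=(0, 1)).fit()
        # weakly identified with 4 indicators: judge against its own SE
        assert res.recall_resid_cov_se > 0
        assert abs(res.recall_resid_cov) < 2.5 * res.recall_resid_cov_se

    def test_factor_scores_track_latent(self):
        df, g = self._simulate_subtests(5000, [0.8, 0.8, 0.6, 0.4], 0.15, 15)
        res = AbilityFactorModel(df, recall_pair=(0, 1)).fit()
        scores = res.factor_scores()
        assert np.corrcoef(scores, g)[0, 1] > 0.85
        assert 0 < res.factor_score_se() < 1

    def test_too_few_persons_rejected(self):
        df, _ = self._simulate_subtests(50, [0.8, 0.8, 0.6, 0.4], 0.1, 16)
        with pytest.raises(ValueError):
            AbilityFactorModel(df)


class TestLatentAbilityModel:
    def _simulate_joint(self, n, corr_g_u1, seed, loadings=(0.75, 0.75, 0.6, 0.45),
                        corr_g_u0=-0.10, n_items=40):
        rng = np.random.default_rng(seed)
        tau00, tau11 = 0.004, 0.006
        T = corr_T(tau00, tau11, 1.0, 0.3, corr_g_u0, corr_g_u1)
        M = rng.multivariate_normal([0.35, 0.65, 0.0], T, n)
        g = M[:, 2]
        c = rng.integers(0, 10, n_items).astype(float)
        B = basis_weights(c)
        Y = M[:, :2] @ B.T + rng.normal(0, 0.16, (n, n_items))
        long = pd.DataFrame({
            "person_id": np.repeat(np.arange(n), n_items),
            "item_id": np.tile(np.arange(n_items), n),
            "error": Y.ravel(), "complexity": np.tile(c, n)})
        lam = np.asarray(loadings)
        sub = pd.DataFrame(
            g[:, None] * lam + rng.normal(0, np.sqrt(1 - lam**2), (n, 4)),
            columns=["t1", "t2", "t3", "t4"], index=np.arange(n))
        return long, sub, g

    def test_latent_correlation_recovery(self):
        long, sub, _ = self._simulate_joint(3000, corr_g_u1=-0.5, seed=17)
        res = LatentAbilityErrorModel(long, sub, recall_pair=(0, 1)).fit()
        assert res.corr_high_ability == pytest.approx(-0.5, abs=0.06)

    def test_independent_subtests_give_null_correlations(self):
        long, sub, _ = self._simulate_joint(1500, corr_g_u1=0.0,
                                            corr_g_u0=0.0, seed=18)
        res = LatentAbilityErrorModel(long, sub, recall_pair=(0, 1)).fit()
        se = res.corr_se()
        assert abs(res.corr_high_ability) < 2 * se["corr_high_ability"] + 0.02
        assert abs(res.corr_low_ability) < 2 * se["corr_low_ability"] + 0.02

    def test_disattenuation_vs_manifest_composite(self):
        long, sub, _ = self._simulate_joint(2000, corr_g_u1=-0.5, seed=19)
        composite = sub.sum(axis=1)
        manifest = LatentErrorModel(long, composite).fit()
        latent = LatentAbilityErrorModel(long, sub, recall_pair=(0, 1)).fit()
        assert abs(latent.corr_high_ability) > abs(manifest.corr_high_ability)

    def test_two_step_fallback_close_to_joint(self):
        long, sub, _ = self._simulate_joint(1500, corr_g_u1=-0.5, seed=20)
        joint = LatentAbilityErrorModel(long, sub, recall_pair=(0, 1)).fit()
        two = LatentAbilityErrorModel.two_step(long, sub)
        assert two.approximation == "two_step_factor_scores"
        # attenuated but same sign and ballpark
        assert np.sign(two.corr_high_ability) == np.sign(joint.corr_high_ability)
        assert abs(two.corr_high_ability) <= abs(joint.corr_high_ability) + 0.03


class TestScaleLevel:
    def _toy(self, seed=21, n=400, n_scales=8, link=-0.05):
        rng = np.random.default_rng(seed)
        ability = pd.Series(rng.normal(15, 4, n), index=np.arange(n))
        rows, item_rows = [], []
        for s in range(n_scales):
            comp = rng.integers(0, 10, 4)
            for j, c in enumerate(comp):
                iid = f"S{s}I{j}"
                item_rows.append({"item_id": iid, "complexity": c})
                noise = rng.normal(0, 1, n)
                err = 0.4 + link * c / 9 * (ability - 15) / 4 + 0.5 * noise
                rows.append(pd.DataFrame({
                    "person_id": np.arange(n), "scale_id": f"S{s}",
                    "item_id": iid, "error": err}))
        return pd.concat(rows, ignore_index=True), pd.DataFrame(item_rows), ability

    def test_meta_correlation_matches_hand_computation(self):
        errors, items, ability = self._toy()
        table, meta = scale_level_correlation(errors, items, ability)
        # spreadsheet-style oracle on the per-scale table
        x = table["mean_complexity"].to_numpy()
        y = table["r_ability_error"].to_numpy()
        xm, ym = x - x.mean(), y - y.mean()
        hand = (xm @ ym) / np.sqrt((xm @ xm) * (ym @ ym))
        assert meta["r"] == pytest.approx(hand, abs=1e-12)
        assert meta["ci_low"] < meta["r"] < meta["ci_high"]

    def test_negative_link_gives_negative_meta_correlation(self):
        errors, items, ability = self._toy(seed=22, n=800, n_scales=12, link=-0.3)
        _, meta = scale_level_correlation(errors, items, ability)
        assert meta["r"] < 0

    def test_constant_complexity_undefined(self):
        errors, items, ability = self._toy(seed=23)
        items["complexity"] = 4
        _, meta = scale_level_correlation(errors, items, ability)
        assert np.isnan(meta["r"]) and "undefined" in meta["note"]
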