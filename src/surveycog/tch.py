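"""Task-complexity models: cross-level interaction mixed models and
latent-error / latent-ability variants.

The central model regresses item-level (transformed) response errors on item
complexity with person-level random intercepts and slopes, and moderates both
by cognitive ability:

    Level 1:  error_ij = b0_i + b1_i * complexity_j + r_ij
    Level 2:  b0_i = g00 + g01 * ability_i + u0_i
              b1_i = g10 + g11 * ability_i + u1_i

with r ~ N(0, sigma2) and (u0, u1) ~ MVN(0, T).  The cross-level interaction
g11 tests whether the ability-error association strengthens with complexity.
A reparameterized form replaces intercept and slope by latent error levels at
the complexity extremes,

    error_ij = b0_i * (9 - c_j)/9 + b1_i * c_j/9 + r_ij,

and models ability as a third person-level variable with a free mean and a
full 3x3 person-level covariance, yielding the correlations between ability
and latent response errors at low (c = 0) and high (c = 9) complexity.  Both
parameterizations span the same likelihood (the second conditions jointly on
ability with a saturated Gaussian margin), which the test suite verifies.

Estimation is direct maximum likelihood of the per-person marginal Gaussian
likelihood: fixed effects and the residual scale are profiled out, the random
effect covariance is parameterized by its log-Cholesky factor, and Woodbury
identities reduce everything to small per-person sufficient statistics.
Fixed-effect standard errors are person-clustered sandwich estimates.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize

__all__ = [
    "ModeratedErrorModel",
    "MixedFitResults",
    "BinnedComplexityModel",
    "LatentErrorModel",
    "LatentErrorResults",
    "AbilityFactorModel",
    "FactorResults",
    "scale_level_correlation",
    "COMPLEXITY_MAX",
]

COMPLEXITY_MAX = 9  # highest observed complexity; basis weights use c/9
_BIN_EDGES = ((0, 1), (2, 3), (4, 5), (6, 7), (8, 9))


def complexity_bin(c) -> np.ndarray:
    """Five-level bin of a 0-9 complexity score (0-1, 2-3, ..., 8-9)."""
    return np.clip(np.asarray(c, dtype=int) // 2 + 1, 1, 5)


# --------------------------------------------------------------------------
# core random-slope ML engine
# --------------------------------------------------------------------------

def _log_chol(phi: np.ndarray, q: int) -> np.ndarray:
    """Lower-triangular Cholesky factor from a log-Cholesky vector (diagonal
    entries exponentiated)."""
    L = np.zeros((q, q))
    idx = 0
    for i in range(q):
        for j in range(i + 1):
            L[i, j] = np.exp(phi[idx]) if i == j else phi[idx]
            idx += 1
    return L


def _chol_to_phi(L: np.ndarray) -> np.ndarray:
    q = L.shape[0]
    out = []
    for i in range(q):
        for j in range(i + 1):
            out.append(np.log(max(L[i, j], 1e-8)) if i == j else L[i, j])
    return np.array(out)


class _SuffStats:
    """Per-person sufficient statistics for the random-slope ML engine.

    Rows (items within persons) carry a fixed design F (p cols) and random
    design Z (q cols); the person-level covariate ``a`` interacts with every
    F column, so the full fixed design is X_i = [F_i, a_i F_i].
    """

    def __init__(self, F, Z, y, person_codes, a_person):
        F = np.asarray(F, float)
        Z = np.asarray(Z, float)
        y = np.asarray(y, float)
        codes = np.asarray(person_codes)
        self.N = int(codes.max()) + 1
        self.p = F.shape[1]
        self.q = Z.shape[1]
        self.a = np.asarray(a_person, float)
        self.nj = np.bincount(codes, minlength=self.N)
        self.ntot = len(y)
        self.syy = np.bincount(codes, weights=y * y, minlength=self.N)

        def agg(prod):  # bincount-based per-person sums (fast path)
            return np.bincount(codes, weights=prod, minlength=self.N)

        q, p, N = self.q, self.p, self.N
        self.Mzz = np.empty((N, q, q))
        self.Mzf = np.empty((N, q, p))
        self.Mff = np.empty((N, p, p))
        self.vz = np.column_stack([agg(Z[:, i] * y) for i in range(q)])
        self.vf = np.column_stack([agg(F[:, i] * y) for i in range(p)])
        for i in range(q):
            for jj in range(q):
                self.Mzz[:, i, jj] = self.Mzz[:, jj, i] if jj < i else agg(Z[:, i] * Z[:, jj])
            for jj in range(p):
                self.Mzf[:, i, jj] = agg(Z[:, i] * F[:, jj])
        for i in range(p):
            for jj in range(p):
                self.Mff[:, i, jj] = self.Mff[:, jj, i] if jj < i else agg(F[:, i] * F[:, jj])

    def profile_nll(self, phi, return_parts=False):
        """-2 log L with sigma2 and fixed effects profiled out; phi is the
        log-Cholesky vector of T/sigma2."""
        q, p, N = self.q, self.p, self.N
        L = _log_chol(phi, q)
        try:
            Tinv = np.linalg.inv(L @ L.T)
        except np.linalg.LinAlgError:
            return np.inf
        logdetT = 2 * np.sum(np.log(np.diag(L)))
        K = Tinv[None] + self.Mzz
        sign, logdetK = np.linalg.slogdet(K)
        if np.any(sign <= 0):
            return np.inf
        KiMzf = np.linalg.solve(K, self.Mzf)
        Kivz = np.linalg.solve(K, self.vz[..., None])[..., 0]
        G = self.Mff - np.einsum("nqp,nqr->npr", self.Mzf, KiMzf)
        f = self.vf - np.einsum("nqp,nq->np", self.Mzf, Kivz)
        yy = self.syy - np.einsum("nq,nq->n", self.vz, Kivz)
        a = self.a
        A = np.empty((2 * p, 2 * p))
        A[:p, :p] = G.sum(0)
        A[:p, p:] = np.einsum("n,npr->pr", a, G)
        A[p:, :p] = A[:p, p:]
        A[p:, p:] = np.einsum("n,npr->pr", a * a, G)
        b = np.concatenate([f.sum(0), a @ f])
        try:
            gamma = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            return np.inf
        quad = yy.sum() - b @ gamma
        if quad <= 0:
            return np.inf
        sigma2 = quad / self.ntot
        logdet_omega = logdetT * N + logdetK.sum()
        nll = (self.ntot * (np.log(2 * np.pi) + np.log(sigma2) + 1.0)
               + logdet_omega)
        if not return_parts:
            return nll
        return nll, {"gamma": gamma, "sigma2": sigma2, "A": A, "G": G, "f": f,
                     "K": K, "Kivz": Kivz, "KiMzf": KiMzf}


def _optimize_nll(fun, x0, restarts=3, seed=0, xatol=1e-9, fatol=1e-10,
                  polish=True):
    """L-BFGS-B followed by a Nelder-Mead polish; perturbed restarts on
    failure.  Tight tolerances so that reparameterized fits of the same
    likelihood agree to ~1e-4 in logL.  ``polish=False`` skips the
    Nelder-Mead stage for Monte-Carlo loops where quasi-Newton precision
    suffices."""
    rng = np.random.default_rng(seed)
    best = None
    x_start = np.asarray(x0, float)
    for attempt in range(restarts + 1):
        xs = x_start if attempt == 0 else x_start + rng.normal(0, 0.3, len(x_start))
        res = minimize(fun, xs, method="L-BFGS-B",
                       options={"maxiter": 500, "ftol": 1e-13, "gtol": 1e-9})
        if polish:
            res = minimize(fun, res.x, method="Nelder-Mead",
                           options={"maxiter": 4000, "xatol": xatol, "fatol": fatol})
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun - 1e-8):
            best = res
        if best is not None and attempt == 0 and res.success:
            break
    if best is None:
        raise RuntimeError("variance-parameter optimization failed from all starts")
    return best


class ModeratedErrorModel:
    """Cross-level interaction model of response errors (random intercepts
    and complexity slopes, both regressed on ability).

    Parameters
    ----------
    data : long DataFrame with one row per scored person x item
    error_col, complexity_col, ability_col, person_col : column names;
        ability must be constant within person.
    """

    param_names = ("intercept", "ability", "complexity", "ability_x_complexity")

    def __init__(self, data: pd.DataFrame, error_col="error", complexity_col="complexity",
                 ability_col="ability", person_col="person_id"):
        df = data[[person_col, error_col, complexity_col, ability_col]].dropna()
        if df[complexity_col].nunique() < 2:
            raise ValueError("complexity must vary across items")
        codes, self.person_ids = pd.factorize(df[person_col], sort=True)
        a_person = df.groupby(person_col, sort=True)[ability_col].first().to_numpy(float)
        if not np.allclose(df.groupby(person_col, sort=True)[ability_col].std(ddof=0).fillna(0), 0):
            raise ValueError("ability must be constant within person")
        c = df[complexity_col].to_numpy(float)
        y = df[error_col].to_numpy(float)
        F = np.column_stack([np.ones_like(c), c])
        self._stats = _SuffStats(F, F, y, codes, a_person)
        self._y = y
        self._c = c
        self._codes = codes
        # internal order [1, c, a, a*c] -> public (intercept, ability,
        # complexity, ability x complexity)
        self._perm = np.array([0, 2, 1, 3])

    def _start(self):
        st = self._stats
        Mffinv = np.linalg.pinv(st.Mff + 1e-8 * np.eye(st.p))
        beta = np.einsum("npr,nr->np", Mffinv, st.vf)
        resid_var = max(np.mean(st.syy / np.maximum(st.nj, 1))
                        - np.mean(np.einsum("np,np->n", beta, st.vf) / np.maximum(st.nj, 1)), 1e-3)
        T0 = np.cov(beta, rowvar=False) * 0.5 + 1e-4 * np.eye(st.q)
        try:
            L0 = np.linalg.cholesky(T0 / resid_var)
        except np.linalg.LinAlgError:
            L0 = np.eye(st.q) * 0.3
        return _chol_to_phi(L0)

    def fit(self, restarts: int = 3, seed: int = 0, polish: bool = True) -> "MixedFitResults":
        st = self._stats
        best = _optimize_nll(st.profile_nll, self._start(), restarts=restarts,
                             seed=seed, polish=polish)
        nll, parts = st.profile_nll(best.x, return_parts=True)
        sigma2 = parts["sigma2"]
        L = _log_chol(best.x, st.q)
        tau = (L @ L.T) * sigma2
        gamma = parts["gamma"][self._perm]

        boundary = tau[-1, -1] < 1e-7 * max(tau[0, 0], 1.0) and st.q > 1
        cov_rob = self._sandwich(parts)[np.ix_(self._perm, self._perm)]
        llf = -0.5 * nll
        res = MixedFitResults(self, gamma, cov_rob, tau, sigma2, llf,
                              converged=np.isfinite(nll), boundary=boundary,
                              phi=best.x, parts=parts)
        if boundary:
            warnings.warn("random-slope variance at boundary (~0); "
                          "refitting with a random intercept only",
                          RuntimeWarning)
            res.reduced = self._fit_reduced(best.x, restarts, seed, polish)
        return res

    def _fit_reduced(self, phi_full, restarts, seed, polish):
        """Profile refit with the random slope removed (q = 1)."""
        import copy as _copy

        st = self._stats
        st1 = _copy.copy(st)
        st1.q = 1
        st1.Mzz = st.Mzz[:, :1, :1]
        st1.Mzf = st.Mzf[:, :1, :]
        st1.vz = st.vz[:, :1]
        model1 = _copy.copy(self)
        model1._stats = st1
        best = _optimize_nll(st1.profile_nll, phi_full[:1], restarts=restarts,
                             seed=seed, polish=polish)
        nll, parts = st1.profile_nll(best.x, return_parts=True)
        sigma2 = parts["sigma2"]
        L = _log_chol(best.x, 1)
        tau = (L @ L.T) * sigma2
        gamma = parts["gamma"][self._perm]
        cov_rob = model1._sandwich(parts)[np.ix_(self._perm, self._perm)]
        return MixedFitResults(model1, gamma, cov_rob, tau, sigma2, -0.5 * nll,
                               converged=np.isfinite(nll), boundary=False,
                               phi=best.x, parts=parts)

    def _sandwich(self, parts):
        st = self._stats
        p = st.p
        gamma = parts["gamma"]
        gF, gaF = gamma[:p], gamma[p:]
        # F' Omega^-1 residual per person
        mean_coef = gF[None, :] + st.a[:, None] * gaF[None, :]
        h = parts["f"] - np.einsum("npr,nr->np", parts["G"], mean_coef)
        scores = np.concatenate([h, st.a[:, None] * h], axis=1)
        meat = scores.T @ scores
        Ainv = np.linalg.inv(parts["A"])
        return Ainv @ meat @ Ainv

    def random_effects(self, results: "MixedFitResults") -> pd.DataFrame:
        """Empirical-Bayes person effects (u0, u1)."""
        st = self._stats
        parts = results._parts
        gamma_int = results.params.to_numpy()[np.argsort(self._perm)]
        p = st.p
        gF, gaF = gamma_int[:p], gamma_int[p:]
        mean_coef = gF[None, :] + st.a[:, None] * gaF[None, :]
        # Woodbury: Z'Omega^-1 y and Z'Omega^-1 F
        K = parts["K"]
        KiMzz = np.linalg.solve(K, st.Mzz)
        ZOy = st.vz - np.einsum("nqr,nr->nq", KiMzz.transpose(0, 2, 1), st.vz)
        ZOF = st.Mzf - np.einsum("nqr,nrp->nqp", KiMzz.transpose(0, 2, 1), st.Mzf)
        resid = ZOy - np.einsum("nqp,np->nq", ZOF, mean_coef)
        Ttilde = _log_chol(results._phi, st.q)
        Ttilde = Ttilde @ Ttilde.T
        u = resid @ Ttilde.T
        return pd.DataFrame(u, index=self.person_ids, columns=[f"u{k}" for k in range(st.q)])


class MixedFitResults:
    """ML fit of a moderated random-slope model: fixed effects with robust
    (person-clustered sandwich) SEs, random-effect covariance, residual
    variance and log-likelihood."""

    def __init__(self, model, params, cov_robust, tau, sigma2, llf,
                 converged, boundary, phi, parts):
        self.model = model
        names = list(model.param_names)
        self.params = pd.Series(params, index=names)
        self.cov_robust = pd.DataFrame(cov_robust, index=names, columns=names)
        self.bse = pd.Series(np.sqrt(np.diag(cov_robust)), index=names)
        self.tau = tau
        self.sigma2 = float(sigma2)
        self.llf = float(llf)
        self.converged = bool(converged)
        self.boundary = bool(boundary)
        self._phi = phi
        self._parts = parts

    @property
    def tvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(2 * stats.norm.sf(np.abs(self.tvalues)), index=self.params.index)

    def conf_int(self, alpha=0.05) -> pd.DataFrame:
        q = stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame({"lower": self.params - q * self.bse,
                             "upper": self.params + q * self.bse})

    def predict(self, ability, complexity) -> np.ndarray:
        """Population-mean predicted (transformed) error."""
        a = np.asarray(ability, float)
        c = np.asarray(complexity, float)
        g = self.params
        return (g["intercept"] + g["ability"] * a + g["complexity"] * c
                + g["ability_x_complexity"] * a * c)

    def simple_slopes(self) -> pd.Series:
        """Effect of ability at complexity 0, of complexity at ability 0, and
        the percent change of the ability slope per complexity point."""
        g = self.params
        pct = 100.0 * g["ability_x_complexity"] / g["ability"] if g["ability"] != 0 else np.nan
        return pd.Series({
            "ability_at_complexity0": g["ability"],
            "complexity_at_ability0": g["complexity"],
            "pct_ability_slope_change_per_point": pct,
        })

    def random_effects(self) -> pd.DataFrame:
        return self.model.random_effects(self)

    def summary(self) -> str:
        tab = pd.DataFrame({"coef": self.params, "robust_se": self.bse,
                            "z": self.tvalues, "p": self.pvalues})
        lines = [
            "Moderated random-slope model of response errors (ML)",
            f"  persons: {self.model._stats.N}, observations: {self.model._stats.ntot}",
            f"  log-likelihood: {self.llf:.4f}  converged: {self.converged}",
            tab.round(4).to_string(),
            f"  tau (random intercept/slope cov):\n{np.array_str(self.tau, precision=5)}",
            f"  sigma2 (residual): {self.sigma2:.5f}",
        ]
        if self.boundary:
            lines.append("  note: random-slope variance at boundary")
        return "\n".join(lines)


class BinnedComplexityModel(ModeratedErrorModel):
    """Sensitivity variant: complexity entered as five bins (0-1, 2-3, 4-5,
    6-7, 8-9) with per-bin intercepts and per-bin ability slopes; the random
    structure stays person intercept + linear complexity slope (an audited
    reduction that aids convergence with correlated bin slopes)."""

    def __init__(self, data: pd.DataFrame, error_col="error", complexity_col="complexity",
                 ability_col="ability", person_col="person_id"):
        df = data[[person_col, error_col, complexity_col, ability_col]].dropna()
        bins = complexity_bin(df[complexity_col].to_numpy())
        observed = np.unique(bins)
        if len(observed) < 2:
            raise ValueError("need at least 2 observed complexity bins")
        missing = sorted(set(range(1, 6)) - set(observed.tolist()))
        if missing:
            warnings.warn(f"empty complexity bins dropped: {missing}")
        self.bins_observed = observed.tolist()
        codes, self.person_ids = pd.factorize(df[person_col], sort=True)
        a_person = df.groupby(person_col, sort=True)[ability_col].first().to_numpy(float)
        y = df[error_col].to_numpy(float)
        c = df[complexity_col].to_numpy(float)
        F = (bins[:, None] == observed[None, :]).astype(float)
        Z = np.column_stack([np.ones_like(c), c])
        self._stats = _SuffStats(F, Z, y, codes, a_person)
        self._codes = codes
        p = len(observed)
        self.param_names = tuple(
            [f"bin_{b}" for b in observed] + [f"ability_x_bin_{b}" for b in observed]
        )
        self._perm = np.arange(2 * p)

    def _start(self):
        st = self._stats
        return _chol_to_phi(np.eye(st.q) * 0.3)

    def ability_slope_changes(self, results: MixedFitResults) -> pd.Series:
        """Percent change of the within-bin ability slope relative to the
        lowest observed bin."""
        base = results.params[f"ability_x_bin_{self.bins_observed[0]}"]
        out = {}
        for b in self.bins_observed[1:]:
            s = results.params[f"ability_x_bin_{b}"]
            out[f"bin_{b}_vs_bin_{self.bins_observed[0]}"] = 100.0 * (s / base - 1.0) if base != 0 else np.nan
        return pd.Series(out)

    def bin_midpoint_predictions(self, results: MixedFitResults, ability) -> pd.DataFrame:
        """Predicted error at each observed bin for the given ability values
        (for cross-model agreement with the linear parameterization)."""
        a = np.asarray(ability, float)
        rows = {}
        for b in self.bins_observed:
            rows[b] = results.params[f"bin_{b}"] + results.params[f"ability_x_bin_{b}"] * a
        return pd.DataFrame(rows, index=a)


# --------------------------------------------------------------------------
# reparameterized latent-error models (complexity-extreme basis)
# --------------------------------------------------------------------------

def basis_weights(complexity) -> np.ndarray:
    """Two-column basis [(9-c)/9, c/9]: person coefficients then represent
    latent response errors at complexity 0 and 9."""
    c = np.asarray(complexity, float)
    return np.column_stack([(COMPLEXITY_MAX - c) / COMPLEXITY_MAX, c / COMPLEXITY_MAX])


def _wide_complete(data, error_col, complexity_col, person_col, item_col):
    wide = data.pivot_table(index=person_col, columns=item_col, values=error_col,
                            aggfunc="first")
    complete = wide.dropna()
    if len(complete) < 10:
        raise ValueError("fewer than 10 persons with a complete scored item set")
    cmap = data.drop_duplicates(item_col).set_index(item_col)[complexity_col]
    c = cmap.loc[complete.columns].to_numpy(float)
    return complete, c


class _SharedCovGaussian:
    """ML for a shared-mean/shared-covariance multivariate Gaussian family
    with profiled linear mean: -2logL from (N, mean, scatter) sufficient
    statistics."""

    def __init__(self, Y: np.ndarray, X: np.ndarray):
        self.N, self.d = Y.shape
        self.X = X
        self.ybar = Y.mean(axis=0)
        Yc = Y - self.ybar
        self.S0 = Yc.T @ Yc

    def nll(self, V: np.ndarray, return_parts=False):
        try:
            cf = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return np.inf
        logdet = 2 * np.sum(np.log(np.diag(cf)))
        Vi_X = np.linalg.solve(cf.T, np.linalg.solve(cf, self.X))
        Vi_ybar = np.linalg.solve(cf.T, np.linalg.solve(cf, self.ybar))
        A = self.X.T @ Vi_X
        b = self.X.T @ Vi_ybar
        gamma = np.linalg.solve(A, b)
        resid = self.ybar - self.X @ gamma
        Vi_resid = np.linalg.solve(cf.T, np.linalg.solve(cf, resid))
        Vi_S0 = np.linalg.solve(cf.T, np.linalg.solve(cf, self.S0))
        quad = np.trace(Vi_S0) + self.N * resid @ Vi_resid
        nll = self.N * (self.d * np.log(2 * np.pi) + logdet) + quad
        if not return_parts:
            return nll
        return nll, {"gamma": gamma, "A": A}


def _saturated_gaussian_llf(x: np.ndarray) -> float:
    """Max log-likelihood of an unconstrained Gaussian for a 1-D sample."""
    n = len(x)
    s2 = np.var(x)
    return -0.5 * n * (np.log(2 * np.pi) + np.log(s2) + 1.0)


class LatentErrorModel:
    """Reparameterized latent-error model (complexity-extreme basis) with the
    ability composite as a jointly modeled person-level variable.

    Requires a complete scored item set per person (incomplete persons are
    dropped, with the count recorded on the results).  ``ability`` is a
    Series indexed by person.
    """

    def __init__(self, data: pd.DataFrame, ability: pd.Series, error_col="error",
                 complexity_col="complexity", person_col="person_id", item_col="item_id"):
        wide, c = _wide_complete(data, error_col, complexity_col, person_col, item_col)
        if c.min() > 2 or c.max() < COMPLEXITY_MAX - 2:
            warnings.warn("complexity range does not approach both extremes; "
                          "extrapolated latent errors are less stable")
        ability = ability.reindex(wide.index)
        keep = ability.notna()
        self.n_dropped = int((~keep).sum()) + (len(data[person_col].unique()) - len(wide))
        wide = wide.loc[keep]
        self.person_ids = wide.index
        self.ability = ability.loc[keep].to_numpy(float)
        self.B = basis_weights(c)
        self.Y = np.column_stack([wide.to_numpy(float), self.ability])
        d = self.Y.shape[1]
        X = np.zeros((d, 3))
        X[:-1, :2] = self.B
        X[-1, 2] = 1.0
        self._gauss = _SharedCovGaussian(self.Y, X)
        self._nj = d - 1

    def _cov(self, phi):
        L = _log_chol(phi[:6], 3)
        T = L @ L.T
        sigma2 = np.exp(phi[6])
        d = self._nj + 1
        V = np.empty((d, d))
        V[:-1, :-1] = self.B @ T[:2, :2] @ self.B.T + sigma2 * np.eye(self._nj)
        V[:-1, -1] = self.B @ T[:2, 2]
        V[-1, :-1] = V[:-1, -1]
        V[-1, -1] = T[2, 2]
        return V, T, sigma2

    def _start(self):
        # moment starts: per-person OLS coefficients on the basis + ability
        BtB = np.linalg.inv(self.B.T @ self.B)
        beta = (self.Y[:, :-1] @ self.B) @ BtB.T
        M = np.column_stack([beta, self.ability])
        C = np.cov(M, rowvar=False)
        resid = self.Y[:, :-1] - beta @ self.B.T
        sigma2 = max(resid.var(), 1e-4)
        C[:2, :2] -= sigma2 * BtB  # remove OLS sampling noise from the start
        C += 1e-4 * np.eye(3)
        try:
            L = np.linalg.cholesky(C)
        except np.linalg.LinAlgError:
            L = np.linalg.cholesky(np.diag(np.maximum(np.diag(C), 1e-3)))
        return np.concatenate([_chol_to_phi(L), [np.log(sigma2)]])

    def fit(self, restarts: int = 3, seed: int = 0) -> "LatentErrorResults":
        def fun(phi):
            V, _, _ = self._cov(phi)
            return self._gauss.nll(V)

        best = _optimize_nll(fun, self._start(), restarts=restarts, seed=seed)
        V, T, sigma2 = self._cov(best.x)
        nll, parts = self._gauss.nll(V, return_parts=True)
        llf = -0.5 * nll
        llf_cond = llf - _saturated_gaussian_llf(self.ability)
        return LatentErrorResults(self, parts["gamma"], T, sigma2, llf, llf_cond,
                                  phi=best.x,
                                  names=("low_complexity", "high_complexity", "ability"))


class LatentErrorResults:
    """Latent response-error levels at the complexity extremes, their
    person-level covariance with ability (manifest or latent), and the
    derived correlations."""

    def __init__(self, model, gamma, T, sigma2, llf, llf_conditional, phi, names):
        self.model = model
        self.names = names
        self.gamma = pd.Series(gamma[: len(names)], index=[f"mean_{n}" for n in names])
        self.tau = pd.DataFrame(T, index=names, columns=names)
        self.sigma2 = float(sigma2)
        self.llf = float(llf)
        self.llf_conditional = (float(llf_conditional)
                                if llf_conditional is not None else None)
        self._phi = phi

    @property
    def corr(self) -> pd.DataFrame:
        T = self.tau.to_numpy()
        s = np.sqrt(np.diag(T))
        return pd.DataFrame(T / np.outer(s, s), index=self.names, columns=self.names)

    @property
    def corr_low_ability(self) -> float:
        return float(self.corr.iloc[0, 2])

    @property
    def corr_high_ability(self) -> float:
        return float(self.corr.iloc[1, 2])

    def corr_se(self) -> dict:
        """Delta-method SEs of the two ability correlations from the numeric
        observed information of the profiled likelihood."""
        model = self.model
        phi = np.asarray(self._phi, float)

        def nll_of(p):
            V = model._cov(p)[0] if hasattr(model, "_cov") else model._cov_full(p)[0]
            return 0.5 * model._gauss.nll(V)

        H = _numeric_hessian(nll_of, phi)
        try:
            cov_phi = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            cov_phi = np.linalg.pinv(H)

        def corrs_of(p):
            T = (model._cov(p)[1] if hasattr(model, "_cov") else model._cov_full(p)[1])
            s = np.sqrt(np.diag(T))
            return np.array([T[0, 2] / (s[0] * s[2]), T[1, 2] / (s[1] * s[2])])

        J = _numeric_jacobian(corrs_of, phi)
        cov_c = J @ cov_phi @ J.T
        se = np.sqrt(np.clip(np.diag(cov_c), 0, None))
        return {"corr_low_ability": float(se[0]), "corr_high_ability": float(se[1])}

    def summary(self) -> str:
        lines = [
            "Latent response-error model (complexity-extreme basis)",
            f"  persons: {len(self.model.person_ids)}  log-likelihood: {self.llf:.4f}",
            self.gamma.round(4).to_string(),
            "  person-level covariance:",
            self.tau.round(5).to_string(),
            f"  corr(ability, latent error @ complexity 0): {self.corr_low_ability:.4f}",
            f"  corr(ability, latent error @ complexity 9): {self.corr_high_ability:.4f}",
            f"  sigma2 (residual): {self.sigma2:.5f}",
        ]
        return "\n".join(lines)


def _numeric_hessian(fun, x, h=1e-4):
    n = len(x)
    H = np.empty((n, n))
    f0 = fun(x)
    for i in range(n):
        for j in range(i, n):
            xpp = x.copy(); xpp[i] += h; xpp[j] += h
            xpm = x.copy(); xpm[i] += h; xpm[j] -= h
            xmp = x.copy(); xmp[i] -= h; xmp[j] += h
            xmm = x.copy(); xmm[i] -= h; xmm[j] -= h
            H[i, j] = H[j, i] = (fun(xpp) - fun(xpm) - fun(xmp) + fun(xmm)) / (4 * h * h)
    return H


def _numeric_jacobian(fun, x, h=1e-6):
    f0 = np.atleast_1d(fun(x))
    J = np.empty((len(f0), len(x)))
    for i in range(len(x)):
        xp = x.copy(); xp[i] += h
        xm = x.copy(); xm[i] -= h
        J[:, i] = (np.atleast_1d(fun(xp)) - np.atleast_1d(fun(xm))) / (2 * h)
    return J


# --------------------------------------------------------------------------
# cognitive ability factor model
# --------------------------------------------------------------------------

class AbilityFactorModel:
    """One-factor ML model of the four cognitive subtests with a free
    residual covariance between the two recall subtests; factor variance
    fixed at 1 for identification."""

    def __init__(self, subtests: pd.DataFrame, recall_pair=(0, 1)):
        self.columns = list(subtests.columns)
        if len(self.columns) != 4:
            raise ValueError("expected exactly four subtest columns")
        X = subtests.dropna().to_numpy(float)
        if X.shape[0] < 100:
            raise ValueError("need at least 100 persons")
        self.X = X
        self.n = X.shape[0]
        self.mu = X.mean(axis=0)
        self.S = np.cov(X, rowvar=False, ddof=0)
        self.recall_pair = recall_pair

    def _sigma(self, params):
        lam = params[:4]
        psi = np.exp(params[4:8])
        rho = params[8]
        i, j = self.recall_pair
        psi12 = rho * np.sqrt(psi[i] * psi[j])
        Sigma = np.outer(lam, lam) + np.diag(psi)
        Sigma[i, j] += psi12
        Sigma[j, i] += psi12
        return Sigma, lam, psi, psi12

    def _discrepancy(self, params):
        Sigma, *_ = self._sigma(params)
        try:
            cf = np.linalg.cholesky(Sigma)
        except np.linalg.LinAlgError:
            return np.inf
        logdet = 2 * np.sum(np.log(np.diag(cf)))
        inv_S = np.linalg.solve(cf.T, np.linalg.solve(cf, self.S))
        sign, logdetS = np.linalg.slogdet(self.S)
        return logdet + np.trace(inv_S) - logdetS - 4

    def fit(self, restarts: int = 3, seed: int = 0) -> "FactorResults":
        sd = np.sqrt(np.diag(self.S))
        x0 = np.concatenate([0.7 * sd, np.log(0.5 * np.diag(self.S)), [0.1]])

        def fun(p):
            # tanh keeps the recall residual correlation in (-1, 1)
            q = p.copy()
            q[8] = np.tanh(p[8])
            return self._discrepancy(q)

        best = _optimize_nll(fun, x0, restarts=restarts, seed=seed,
                             xatol=1e-10, fatol=1e-12)
        params = best.x.copy()
        params[8] = np.tanh(params[8])
        Sigma, lam, psi, psi12 = self._sigma(params)
        if np.any(psi < 1e-4 * np.diag(self.S)):
            warnings.warn("near-zero residual variance (Heywood-type boundary)",
                          RuntimeWarning)
        fmin = self._discrepancy(params)
        chi2 = (self.n - 1) * fmin
        df = 1  # 10 moments - 9 free parameters
        cov = self._param_cov(best.x)
        se = np.sqrt(np.clip(np.diag(cov)[:4], 0, None))
        # delta-method SE of the recall residual covariance
        def psi12_of(p):
            return np.array([np.tanh(p[8]) * np.sqrt(np.exp(p[4 + self.recall_pair[0]])
                                                     * np.exp(p[4 + self.recall_pair[1]]))])
        J = _numeric_jacobian(psi12_of, np.asarray(best.x, float))
        psi12_se = float(np.sqrt(max((J @ cov @ J.T)[0, 0], 0.0)))
        res = FactorResults(self, lam, se, psi, psi12, Sigma, chi2, df)
        res.recall_resid_cov_se = psi12_se
        return res

    def _param_cov(self, raw_params):
        def nll(p):
            q = p.copy()
            q[8] = np.tanh(p[8])
            return 0.5 * self.n * self._discrepancy(q)

        H = _numeric_hessian(nll, np.asarray(raw_params, float))
        try:
            return np.linalg.inv(H)
        except np.linalg.LinAlgError:
            return np.linalg.pinv(H)


class FactorResults:
    """Fitted one-factor ability model: loadings, residual (co)variances,
    factor scores and a 1-df goodness-of-fit test."""

    def __init__(self, model, loadings, loadings_se, resid_var, recall_resid_cov,
                 Sigma, chi2, df):
        self.model = model
        self.loadings = pd.Series(loadings, index=model.columns)
        self.loadings_se = pd.Series(loadings_se, index=model.columns)
        self.resid_var = pd.Series(resid_var, index=model.columns)
        self.recall_resid_cov = float(recall_resid_cov)
        self.Sigma = Sigma
        self.chi2 = float(chi2)
        self.df = int(df)
        self.pvalue = float(stats.chi2.sf(chi2, df))

    @property
    def std_loadings(self) -> pd.Series:
        return self.loadings / np.sqrt(np.diag(self.Sigma))

    def factor_scores(self, subtests: pd.DataFrame | None = None) -> pd.Series:
        """Regression-method factor scores lambda' Sigma^-1 (x - mu) with the
        factor variance fixed at 1."""
        X = self.model.X if subtests is None else subtests[self.model.columns].to_numpy(float)
        w = np.linalg.solve(self.Sigma, self.loadings.to_numpy())
        scores = (X - self.model.mu) @ w
        idx = None if subtests is None else subtests.index
        return pd.Series(scores, index=idx, name="g_score")

    def factor_score_se(self) -> float:
        """Common SE of the regression factor scores."""
        w = np.linalg.solve(self.Sigma, self.loadings.to_numpy())
        var = 1.0 - self.loadings.to_numpy() @ w
        return float(np.sqrt(max(var, 0.0)))

    def summary(self) -> str:
        tab = pd.DataFrame({"loading": self.loadings, "se": self.loadings_se,
                            "std_loading": self.std_loadings,
                            "resid_var": self.resid_var})
        return "\n".join([
            "One-factor cognitive ability model (ML, factor variance = 1)",
            f"  n = {self.model.n}",
            tab.round(4).to_string(),
            f"  recall residual covariance: {self.recall_resid_cov:.4f}",
            f"  goodness of fit: chi2({self.df}) = {self.chi2:.3f}, p = {self.pvalue:.3f}",
        ])


class LatentAbilityErrorModel:
    """Multilevel structural variant: latent response errors at the
    complexity extremes correlated with a *latent* ability factor measured by
    the four subtests (joint per-person likelihood over errors and subtests).

    The latent factor g has variance fixed at 1; the person effects are
    u = alpha * g + e with e ~ N(0, Psi), so the implied covariance is
    positive semidefinite by construction and corr(g, u_k) =
    alpha_k / sqrt(tau_kk).
    """

    def __init__(self, data: pd.DataFrame, subtests: pd.DataFrame, error_col="error",
                 complexity_col="complexity", person_col="person_id", item_col="item_id",
                 recall_pair=(0, 1)):
        wide, c = _wide_complete(data, error_col, complexity_col, person_col, item_col)
        sub = subtests.reindex(wide.index).dropna()
        wide = wide.loc[sub.index]
        self.person_ids = wide.index
        self.subtest_cols = list(sub.columns)
        if len(self.subtest_cols) != 4:
            raise ValueError("expected exactly four subtest columns")
        self.recall_pair = recall_pair
        self.B = basis_weights(c)
        self._nj = self.B.shape[0]
        self.Y = np.column_stack([wide.to_numpy(float), sub.to_numpy(float)])
        d = self.Y.shape[1]
        X = np.zeros((d, 2 + 4))
        X[: self._nj, :2] = self.B
        X[self._nj :, 2:] = np.eye(4)
        self._gauss = _SharedCovGaussian(self.Y, X)
        self._sub = sub

    # parameter vector: alpha(2), Psi log-chol(3), lambda(4), log psi(4),
    # atanh recall resid corr(1), log sigma2(1)  -> 15
    def _cov_full(self, phi):
        alpha = phi[:2]
        Lp = _log_chol(phi[2:5], 2)
        Psi = Lp @ Lp.T
        lam = phi[5:9]
        psi = np.exp(phi[9:13])
        rho = np.tanh(phi[13])
        sigma2 = np.exp(phi[14])
        i, j = self.recall_pair
        Theta = np.diag(psi)
        Theta[i, j] = Theta[j, i] = rho * np.sqrt(psi[i] * psi[j])
        Tuu = np.outer(alpha, alpha) + Psi
        nj = self._nj
        d = nj + 4
        V = np.empty((d, d))
        V[:nj, :nj] = self.B @ Tuu @ self.B.T + sigma2 * np.eye(nj)
        V[:nj, nj:] = (self.B @ alpha)[:, None] * lam[None, :]
        V[nj:, :nj] = V[:nj, nj:].T
        V[nj:, nj:] = np.outer(lam, lam) + Theta
        # full 3x3 person-level covariance of (u0, u1, g)
        T = np.empty((3, 3))
        T[:2, :2] = Tuu
        T[:2, 2] = alpha
        T[2, :2] = alpha
        T[2, 2] = 1.0
        return V, T, sigma2

    _cov = _cov_full  # uniform access for corr_se

    def _start(self):
        fr = AbilityFactorModel(self._sub, recall_pair=self.recall_pair).fit(restarts=0)
        g = fr.factor_scores()
        BtB = np.linalg.inv(self.B.T @ self.B)
        beta = (self.Y[:, : self._nj] @ self.B) @ BtB.T
        gv = max(g.var(), 1e-6)
        alpha0 = np.array([np.cov(beta[:, 0], g)[0, 1], np.cov(beta[:, 1], g)[0, 1]]) / gv
        resid = self.Y[:, : self._nj] - beta @ self.B.T
        sigma2 = max(resid.var(), 1e-4)
        Psi0 = np.cov(beta, rowvar=False) - np.outer(alpha0, alpha0) - sigma2 * BtB
        Psi0 = Psi0 + (1e-3 + max(0.0, -np.min(np.linalg.eigvalsh(Psi0)))) * np.eye(2)
        rho0 = 0.99 * np.clip(fr.recall_resid_cov /
                              np.sqrt(fr.resid_var.iloc[self.recall_pair[0]] *
                                      fr.resid_var.iloc[self.recall_pair[1]]), -0.9, 0.9)
        return np.concatenate([
            alpha0,
            _chol_to_phi(np.linalg.cholesky(Psi0)),
            fr.loadings.to_numpy(),
            np.log(np.maximum(fr.resid_var.to_numpy(), 1e-4)),
            [np.arctanh(rho0)],
            [np.log(sigma2)],
        ])

    def fit(self, restarts: int = 2, seed: int = 0) -> LatentErrorResults:
        def fun(phi):
            V = self._cov_full(phi)[0]
            return self._gauss.nll(V)

        best = _optimize_nll(fun, self._start(), restarts=restarts, seed=seed)
        V, T, sigma2 = self._cov_full(best.x)
        nll, parts = self._gauss.nll(V, return_parts=True)
        res = LatentErrorResults(self, parts["gamma"], T, sigma2, -0.5 * nll, None,
                                 phi=best.x,
                                 names=("low_complexity", "high_complexity", "latent_g"))
        res.subtest_means = pd.Series(parts["gamma"][2:], index=self.subtest_cols)
        return res

    @classmethod
    def two_step(cls, data, subtests, **kwargs) -> LatentErrorResults:
        """Approximate fallback: factor scores from the measurement model,
        then the composite-mode latent-error model on those scores.  Reported
        as an approximation (factor-score uncertainty is ignored, so the
        latent correlations are mildly attenuated)."""
        fr = AbilityFactorModel(subtests).fit()
        scores = fr.factor_scores(subtests)
        res = LatentErrorModel(data, scores, **kwargs).fit()
        res.approximation = "two_step_factor_scores"
        return res


# --------------------------------------------------------------------------
# scale-level correlation analysis
# --------------------------------------------------------------------------

def scale_level_correlation(
    errors: pd.DataFrame,
    items: pd.DataFrame,
    ability: pd.Series,
    error_col: str = "error",
    person_col: str = "person_id",
) -> tuple[pd.DataFrame, dict]:
    """Scale-by-scale ability-error correlations vs mean item complexity.

    For each scale: the mean complexity of its items and the Pearson
    correlation between person mean (transformed) error on the scale and
    ability.  Across scales, the meta-correlation between the two quantities
    with a Fisher-z 95% CI.  Scales with zero error variance are excluded
    with a warning; with no complexity variance across scales the
    meta-correlation is undefined (NaN).
    """
    comp = items.set_index(items["item_id"].astype(str))["complexity"]
    rows = []
    for scale, grp in errors.groupby("scale_id", sort=True):
        mean_err = grp.groupby(person_col)[error_col].mean()
        joined = pd.concat([mean_err.rename("err"), ability.rename("ability")],
                           axis=1).dropna()
        if len(joined) < 3 or joined["err"].std() == 0:
            warnings.warn(f"scale {scale} excluded from scale-level analysis "
                          "(too few persons or zero error variance)")
            continue
        r = float(np.corrcoef(joined["err"], joined["ability"])[0, 1])
        c_mean = float(comp.loc[grp["item_id"].astype(str).unique()].mean())
        rows.append({"scale_id": scale, "mean_complexity": c_mean,
                     "r_ability_error": r, "n_persons": len(joined)})
    table = pd.DataFrame(rows)
    if len(table) < 3:
        raise ValueError("need at least 3 usable scales")
    if table["mean_complexity"].std() == 0 or table["r_ability_error"].std() == 0:
        meta = {"r": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                "n_scales": len(table),
                "note": "meta-correlation undefined (zero variance across scales)"}
        return table, meta
    r = float(np.corrcoef(table["mean_complexity"], table["r_ability_error"])[0, 1])
    k = len(table)
    z = np.arctanh(r)
    hw = 1.96 / np.sqrt(k - 3)
    meta = {"r": r, "ci_low": float(np.tanh(z - hw)), "ci_high": float(np.tanh(z + hw)),
            "n_scales": k}
    return table, meta
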