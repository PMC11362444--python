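"""Worst-performance-rule analysis of response-error scores.

Each person's item-level response-error scores are cube-root transformed
(to undo their strong right skew), sorted, and averaged within ten
equal-count bins (deciles of that person's own error distribution).  The ten
decile means are then correlated with cognitive ability across persons; the
worst-performance rule predicts that the largest errors (decile 10) carry the
strongest (most negative) ability correlation.

Because the ten correlations share both the ability variable and highly
dependent decile means, their equality is tested with an omnibus Wald test on
the Fisher-z transformed correlations, using the asymptotic (delta-method)
covariance of dependent correlations estimated from the joint moments of the
eleven variables; a person-level bootstrap covariance is available as an
alternative and as a cross-check.  Post hoc pairwise contrasts use the same
covariance.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "cube_root_transform",
    "per_person_deciles",
    "decile_columns",
    "DecileCorrelationAnalysis",
    "WPRResults",
    "retest_correlations",
]

N_DECILES = 10


def decile_columns(n: int = N_DECILES) -> list[str]:
    return [f"d{k}" for k in range(1, n + 1)]


def cube_root_transform(errors):
    """Elementwise x**(1/3): order preserving, [0,1] -> [0,1]."""
    x = np.asarray(errors, dtype=float)
    if np.any(x[np.isfinite(x)] < 0):
        raise ValueError("error scores must be nonnegative")
    return np.cbrt(x)


def _bin_sizes(n: int, n_bins: int = N_DECILES) -> np.ndarray:
    """Near-equal bin sizes (differ by <= 1); the remainder goes to the
    lowest bins, so larger bins sit at the small-error end."""
    base, rem = divmod(n, n_bins)
    sizes = np.full(n_bins, base, dtype=int)
    sizes[:rem] += 1
    return sizes


def per_person_deciles(
    errors: pd.DataFrame,
    error_col: str = "error",
    person_col: str = "person_id",
    min_items: int = 10,
    transform: str = "cube_root",
) -> pd.DataFrame:
    """Per-person decile means of (transformed) error scores.

    Persons with fewer than ``min_items`` scored items cannot fill ten bins
    and are excluded.  Scores are sorted ascending with a stable sort, so the
    decile membership is identical on the raw and any monotone-transformed
    scale.  Returns a DataFrame indexed by person with columns d1..d10 and
    n_items_scored.
    """
    if transform == "cube_root":
        vals = cube_root_transform(errors[error_col].to_numpy())
    elif transform == "none":
        vals = errors[error_col].to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown transform {transform!r}")
    df = pd.DataFrame({person_col: errors[person_col].to_numpy(), "_v": vals})
    df = df.dropna(subset=["_v"])
    rows = {}
    for pid, grp in df.groupby(person_col, sort=True):
        v = np.sort(grp["_v"].to_numpy(), kind="stable")
        if len(v) < min_items:
            continue
        sizes = _bin_sizes(len(v))
        edges = np.concatenate([[0], np.cumsum(sizes)])
        means = [v[edges[k]:edges[k + 1]].mean() for k in range(N_DECILES)]
        rows[pid] = means + [len(v)]
    out = pd.DataFrame.from_dict(
        rows, orient="index", columns=decile_columns() + ["n_items_scored"]
    )
    out.index.name = person_col
    out["n_items_scored"] = out["n_items_scored"].astype(int)
    return out


def _correlations_and_covariance(D: np.ndarray, x: np.ndarray):
    """Pearson correlations r_k = corr(D[:,k], x) and the asymptotic
    covariance of the vector r from the empirical influence functions
    (delta method over joint moments; robust to non-normality)."""
    n = len(x)
    xs = (x - x.mean()) / x.std()
    Ds = (D - D.mean(axis=0)) / D.std(axis=0)
    r = Ds.T @ xs / n
    # influence function of a correlation coefficient
    psi = Ds * xs[:, None] - 0.5 * r[None, :] * (Ds**2 + (xs**2)[:, None])
    cov_r = psi.T @ psi / n**2
    return r, cov_r


def _fisher_z_cov(r: np.ndarray, cov_r: np.ndarray, n: int):
    r = np.clip(r, -1 + 1e-12, 1 - 1e-12)  # degenerate perfect correlations
    z = np.arctanh(r)
    d = 1.0 / (1.0 - r**2)
    cov_z = cov_r * np.outer(d, d)
    # standard Fisher-z finite-sample scaling
    cov_z *= n / max(n - 3, 1)
    return z, cov_z


class DecileCorrelationAnalysis:
    """Dependent-correlation analysis of decile means against ability.

    Parameters
    ----------
    deciles : output of :func:`per_person_deciles` (index = person)
    ability : Series of cognitive scores indexed by person (or aligned array)
    """

    def __init__(self, deciles: pd.DataFrame, ability: pd.Series):
        cols = decile_columns()
        if isinstance(ability, pd.Series):
            common = deciles.index.intersection(ability.index)
            deciles = deciles.loc[common]
            ability = ability.loc[common]
        else:
            ability = pd.Series(np.asarray(ability, dtype=float), index=deciles.index)
        keep = deciles[cols].notna().all(axis=1) & ability.notna()
        self.deciles = deciles.loc[keep]
        self.ability = ability.loc[keep].astype(float)
        if len(self.deciles) < 3:
            raise ValueError("need at least 3 persons with complete decile summaries")
        D = self.deciles[cols].to_numpy(dtype=float)
        sd = D.std(axis=0)
        zero = [cols[k] for k in np.nonzero(sd == 0)[0]]
        if self.ability.std() == 0:
            zero.append("ability")
        if zero:
            raise ValueError(f"zero variance in column(s): {zero}")
        self._D = D

    def fit(self, cov: str = "delta", n_boot: int = 2000, seed: int | None = None) -> "WPRResults":
        """Estimate the ten correlations and their joint covariance.

        ``cov='delta'`` uses the influence-function (delta-method) covariance;
        ``cov='bootstrap'`` resamples persons ``n_boot`` times.
        """
        x = self.ability.to_numpy()
        n = len(x)
        r, cov_r = _correlations_and_covariance(self._D, x)
        z, cov_z = _fisher_z_cov(r, cov_r, n)
        if cov == "bootstrap":
            rng = np.random.default_rng(seed)
            reps = np.empty((n_boot, N_DECILES))
            for b in range(n_boot):
                idx = rng.integers(0, n, n)
                Db, xb = self._D[idx], x[idx]
                rb = np.corrcoef(np.column_stack([Db, xb]), rowvar=False)[:-1, -1]
                reps[b] = np.arctanh(np.clip(rb, -0.999999, 0.999999))
            cov_z = np.cov(reps, rowvar=False)
        elif cov != "delta":
            raise ValueError("cov must be 'delta' or 'bootstrap'")
        return WPRResults(self, r, z, cov_z, n, cov_method=cov)


class WPRResults:
    """Decile-ability correlations with omnibus and pairwise tests."""

    def __init__(self, model, r, z, cov_z, nobs, cov_method):
        self.model = model
        self.correlations = pd.Series(r, index=decile_columns(), name="r")
        self.z = z
        self.cov_z = cov_z
        self.nobs = int(nobs)
        self.cov_method = cov_method
        self.df = N_DECILES - 1

    def wald_test(self, contrast: str = "successive") -> tuple[float, int, float]:
        """Omnibus Wald test of equal correlations across the ten deciles.

        The statistic is invariant to the choice of full-rank contrast basis;
        'successive' (z_k - z_{k+1}) and 'deviation' (z_k - mean z) are
        provided.
        """
        if contrast == "successive":
            C = np.zeros((9, 10))
            C[np.arange(9), np.arange(9)] = 1.0
            C[np.arange(9), np.arange(1, 10)] = -1.0
        elif contrast == "deviation":
            C = (np.eye(10) - np.full((10, 10), 0.1))[:9]
        else:
            raise ValueError("contrast must be 'successive' or 'deviation'")
        cz = C @ self.z
        V = C @ self.cov_z @ C.T
        if np.allclose(cz, 0.0, atol=1e-12):
            # identical correlations: no evidence against equality
            return 0.0, self.df, 1.0
        try:
            stat = float(cz @ np.linalg.solve(V, cz))
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "singular contrast covariance; consider cov='bootstrap'"
            ) from exc
        p = float(stats.chi2.sf(stat, self.df))
        return stat, self.df, p

    @property
    def wald_statistic(self) -> float:
        return self.wald_test()[0]

    @property
    def wald_pvalue(self) -> float:
        return self.wald_test()[2]

    def pairwise_tests(self) -> pd.DataFrame:
        """Delta-method post hoc contrasts z_k - z_l for every decile pair."""
        rows = []
        for k, l in itertools.combinations(range(N_DECILES), 2):
            diff = self.z[k] - self.z[l]
            var = self.cov_z[k, k] + self.cov_z[l, l] - 2 * self.cov_z[k, l]
            se = np.sqrt(max(var, 0.0))
            zstat = diff / se if se > 0 else 0.0
            p = 2 * stats.norm.sf(abs(zstat)) if se > 0 else 1.0
            rows.append({"decile_a": k + 1, "decile_b": l + 1, "z_diff": diff,
                         "se": se, "z_stat": zstat, "pvalue": p})
        return pd.DataFrame(rows)

    def confidence_intervals(self, alpha: float = 0.05) -> pd.DataFrame:
        se_z = np.sqrt(np.diag(self.cov_z))
        q = stats.norm.ppf(1 - alpha / 2)
        lo = np.tanh(self.z - q * se_z)
        hi = np.tanh(self.z + q * se_z)
        return pd.DataFrame({"r": self.correlations, "ci_low": lo, "ci_high": hi})

    def summary(self) -> str:
        stat, df, p = self.wald_test()
        tab = self.confidence_intervals().round(3)
        return "\n".join([
            "Worst-performance-rule decile analysis",
            f"  persons: {self.nobs}, covariance: {self.cov_method}",
            tab.to_string(),
            f"  omnibus Wald test: chi2({df}) = {stat:.2f}, p = {p:.3g}",
        ])


def retest_correlations(
    wave_summaries: dict,
    columns: list[str] | None = None,
) -> pd.DataFrame:
    """Across-wave Pearson correlations of person-level error summaries.

    ``wave_summaries`` maps wave label -> DataFrame indexed by person with a
    ``mean_error`` column (and optionally decile-mean columns d1..d10).
    Returns one row per wave pair and summary column with r and the overlap n.
    """
    waves = sorted(wave_summaries)
    if len(waves) < 2:
        raise ValueError("need at least 2 waves")
    rows = []
    for wa, wb in itertools.combinations(waves, 2):
        A, B = wave_summaries[wa], wave_summaries[wb]
        common = A.index.intersection(B.index)
        if len(common) == 0:
            raise ValueError(f"no overlapping persons between waves {wa} and {wb}")
        cols = columns or [c for c in A.columns if c in B.columns and c != "n_items_scored"]
        for col in cols:
            a = A.loc[common, col].astype(float)
            b = B.loc[common, col].astype(float)
            ok = a.notna() & b.notna()
            r = float(np.corrcoef(a[ok], b[ok])[0, 1]) if ok.sum() >= 3 else np.nan
            rows.append({"wave_a": wa, "wave_b": wb, "column": col,
                         "r": r, "n_overlap": int(ok.sum())})
    return pd.DataFrame(rows)
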