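"""Graded response models and item-level response-error scores.

The central quantity of the package is the *response error score*: for an
ordinal item with ``m`` categories, a person's observed response ``y`` is
compared against the response the fitted item response model statistically
expects for that person,

    error = |y - E(Y | theta_hat)| / (m - 1),

which lies in [0, 1] (0 = response exactly matches the model expectation,
1 = maximally deviant response).  The expectation comes from a unidimensional
graded response model (GRM) fitted per scale, with person traits estimated by
expected-a-posteriori (EAP) scoring under a standard-normal prior.

The GRM is fitted by marginal maximum likelihood with an EM algorithm over
fixed Gaussian-Hermite-style quadrature (equally spaced nodes weighted by the
normal density).  The latent trait is identified as N(0, 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logsumexp

__all__ = [
    "ItemParameters",
    "GradedResponseModel",
    "GRMResults",
    "category_probabilities",
    "cumulative_probabilities",
    "expected_score",
    "response_error_score",
    "eap_theta",
    "score_all_scales",
    "default_quadrature",
]

_P_FLOOR = 1e-10


@dataclass(frozen=True)
class ItemParameters:
    """GRM parameters for one ordinal item.

    ``thresholds`` has length ``n_categories - 1`` and must be strictly
    increasing; ``discrimination`` must be finite and positive.
    """

    item_id: str
    scale_id: str
    n_categories: int
    discrimination: float
    thresholds: tuple[float, ...]

    def __post_init__(self):
        if self.n_categories < 2:
            raise ValueError(f"item {self.item_id}: need >= 2 categories")
        if len(self.thresholds) != self.n_categories - 1:
            raise ValueError(
                f"item {self.item_id}: expected {self.n_categories - 1} "
                f"thresholds, got {len(self.thresholds)}"
            )
        b = np.asarray(self.thresholds, dtype=float)
        if not np.all(np.isfinite(b)) or np.any(np.diff(b) <= 0):
            raise ValueError(f"item {self.item_id}: thresholds must be finite and strictly increasing")
        a = float(self.discrimination)
        if not np.isfinite(a) or a <= 0:
            raise ValueError(f"item {self.item_id}: discrimination must be finite and > 0")


def default_quadrature(n_nodes: int = 61, bound: float = 6.0) -> tuple[np.ndarray, np.ndarray]:
    """Equally spaced quadrature nodes on [-bound, bound] with standard-normal
    weights (normalized to sum to one)."""
    nodes = np.linspace(-bound, bound, n_nodes)
    w = np.exp(-0.5 * nodes**2)
    return nodes, w / w.sum()


def cumulative_probabilities(theta, item: ItemParameters) -> np.ndarray:
    """P*(Y >= k | theta) for k = 1..m; column 0 is identically 1.

    Returns an array of shape ``(*theta.shape, m)`` where entry ``[..., k-1]``
    is P(Y >= k).  Logistic link, no scaling constant.
    """
    theta = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(theta)):
        raise ValueError("theta must be finite")
    b = np.asarray(item.thresholds, dtype=float)
    pstar = np.empty(theta.shape + (item.n_categories,))
    pstar[..., 0] = 1.0
    pstar[..., 1:] = expit(item.discrimination * (theta[..., None] - b))
    return pstar


def category_probabilities(theta, item: ItemParameters) -> np.ndarray:
    """P(Y = k | theta) for k = 1..m as adjacent differences of the
    cumulative curves (the item category response function)."""
    pstar = cumulative_probabilities(theta, item)
    p = np.empty_like(pstar)
    p[..., :-1] = pstar[..., :-1] - pstar[..., 1:]
    p[..., -1] = pstar[..., -1]
    return p


def expected_score(theta, item: ItemParameters) -> np.ndarray | float:
    """Model-expected response E(Y | theta) = sum_k k P(Y = k | theta),
    a nondecreasing function of theta with range (1, m)."""
    p = category_probabilities(theta, item)
    k = np.arange(1, item.n_categories + 1)
    out = p @ k
    return float(out) if np.isscalar(theta) or np.ndim(theta) == 0 else out


def response_error_score(y, theta, item: ItemParameters) -> np.ndarray | float:
    """|y - E(Y | theta)| / (m - 1), in [0, 1]."""
    y = np.asarray(y)
    if np.any((y < 1) | (y > item.n_categories)):
        raise ValueError(
            f"item {item.item_id}: observed response outside 1..{item.n_categories}"
        )
    e = expected_score(theta, item)
    out = np.abs(y - e) / (item.n_categories - 1)
    return float(out) if np.ndim(out) == 0 else out


def eap_theta(
    responses: np.ndarray,
    items: list[ItemParameters],
    n_nodes: int = 61,
    bound: float = 6.0,
) -> tuple[np.ndarray, np.ndarray]:
    """EAP trait estimates under a standard-normal prior.

    Parameters
    ----------
    responses : int array (n_persons, n_items), 0 = missing, else 1..m_j
    items : GRM parameters, one per column of ``responses``

    Returns ``(theta_hat, posterior_sd)``.  Persons with no observed
    responses raise an error.
    """
    responses = np.atleast_2d(np.asarray(responses, dtype=int))
    if responses.shape[1] != len(items):
        raise ValueError("responses/items column mismatch")
    if np.any((responses == 0).all(axis=1)):
        raise ValueError("EAP requires at least one non-missing response per person")
    nodes, w = default_quadrature(n_nodes, bound)
    loglik = np.zeros((responses.shape[0], n_nodes))
    for j, item in enumerate(items):
        logp = np.log(np.clip(category_probabilities(nodes, item), _P_FLOOR, None))
        yj = responses[:, j]
        obs = yj > 0
        loglik[obs] += logp[:, yj[obs] - 1].T
    logpost = loglik + np.log(w)
    logpost -= logsumexp(logpost, axis=1, keepdims=True)
    post = np.exp(logpost)
    theta_hat = post @ nodes
    var = post @ nodes**2 - theta_hat**2
    return theta_hat, np.sqrt(np.clip(var, 1e-12, None))


def _ordered_params_to_ab(p: np.ndarray) -> tuple[float, np.ndarray]:
    """(log a, b1, log diffs...) -> (a, strictly increasing b)."""
    a = np.exp(p[0])
    b = np.empty(len(p) - 1)
    b[0] = p[1]
    if len(b) > 1:
        b[1:] = p[1] + np.cumsum(np.exp(p[2:]))
    return a, b


def _ab_to_ordered_params(a: float, b: np.ndarray) -> np.ndarray:
    p = np.empty(len(b) + 1)
    p[0] = np.log(a)
    p[1] = b[0]
    if len(b) > 1:
        p[2:] = np.log(np.diff(b))
    return p


def _item_prob_table(a: float, b: np.ndarray, nodes: np.ndarray) -> np.ndarray:
    """(Q, m) category probability table for one item, floored for logs."""
    m = len(b) + 1
    pstar = np.empty((len(nodes), m + 1))
    pstar[:, 0] = 1.0
    pstar[:, -1] = 0.0
    pstar[:, 1:m] = expit(a * (nodes[:, None] - b))
    return np.clip(pstar[:, :-1] - pstar[:, 1:], _P_FLOOR, None)


class GradedResponseModel:
    """Unidimensional graded response model for one multi-item scale.

    Parameters
    ----------
    responses : DataFrame (persons x items) of integer category codes;
        NaN marks missingness.  Codes need not start at 1 or be contiguous:
        observed codes are mapped onto 1..m (unused categories collapsed)
        with the mapping recorded on the results.
    scale_id : label carried into the fitted item parameters.
    reverse_detect : if True (default), items whose item-rest correlation is
        negative in a pre-pass are reverse-coded before fitting, with an
        audit record on the results.  The GRM itself constrains a_j > 0.
    """

    def __init__(self, responses: pd.DataFrame, scale_id: str = "scale", reverse_detect: bool = True):
        if responses.shape[1] < 2:
            raise ValueError("a scale needs at least 2 items")
        self.scale_id = str(scale_id)
        self.item_ids = [str(c) for c in responses.columns]
        self.person_index = responses.index
        raw = responses.to_numpy(dtype=float)
        self._raw = raw
        self.reverse_detect = reverse_detect

        # map observed codes onto 1..m per item, collapsing unused categories
        n, J = raw.shape
        Y = np.zeros((n, J), dtype=int)
        self.category_maps: dict[str, dict[int, int]] = {}
        self.m = np.empty(J, dtype=int)
        for j in range(J):
            col = raw[:, j]
            obs = np.unique(col[np.isfinite(col)]).astype(int)
            if len(obs) < 2:
                raise ValueError(
                    f"item {self.item_ids[j]} has a single observed category; cannot fit"
                )
            cmap = {int(c): k + 1 for k, c in enumerate(obs)}
            self.category_maps[self.item_ids[j]] = cmap
            self.m[j] = len(obs)
            fin = np.isfinite(col)
            Y[fin, j] = np.vectorize(cmap.get)(col[fin].astype(int))

        self.reverse_coded: list[str] = []
        if reverse_detect:
            self._apply_reverse_coding(Y)
        self.Y = Y

    def _apply_reverse_coding(self, Y: np.ndarray) -> None:
        # pre-pass: negatively keying items (negative item-rest correlation
        # on observed codes) are flipped so all fitted a_j > 0 refer to the
        # common trait direction
        total = np.where(Y > 0, Y, 0).sum(axis=1).astype(float)
        cnt = (Y > 0).sum(axis=1).astype(float)
        for j in range(Y.shape[1]):
            obs = Y[:, j] > 0
            rest = (total[obs] - Y[obs, j]) / np.maximum(cnt[obs] - 1, 1)
            yj = Y[obs, j].astype(float)
            if np.std(rest) == 0 or np.std(yj) == 0:
                continue
            if np.corrcoef(yj, rest)[0, 1] < 0:
                Y[obs, j] = self.m[j] + 1 - Y[obs, j]
                self.reverse_coded.append(self.item_ids[j])

    # -- EM fitting ---------------------------------------------------------

    def loglike(self, items: list[ItemParameters], n_nodes: int = 61, bound: float = 6.0) -> float:
        """Marginal log-likelihood at the given item parameters."""
        nodes, w = default_quadrature(n_nodes, bound)
        ll = self._person_loglik_nodes(items, nodes)
        return float(logsumexp(ll + np.log(w), axis=1).sum())

    def _person_loglik_nodes(self, items: list[ItemParameters], nodes: np.ndarray) -> np.ndarray:
        out = np.zeros((self.Y.shape[0], len(nodes)))
        for j, item in enumerate(items):
            logp = np.log(_item_prob_table(item.discrimination, np.asarray(item.thresholds), nodes))
            yj = self.Y[:, j]
            obs = yj > 0
            out[obs] += logp[:, yj[obs] - 1].T
        return out

    def fit(
        self,
        n_nodes: int = 61,
        bound: float = 6.0,
        tol: float = 1e-4,
        max_iter: int = 500,
        compute_se: bool = True,
        a_max: float = 6.0,
    ) -> "GRMResults":
        """Marginal-ML EM fit.  Discriminations are bounded above by
        ``a_max`` (short contaminated scales can otherwise drive an item's
        discrimination to infinity); items at the bound are flagged."""
        nodes, w = default_quadrature(n_nodes, bound)
        n, J = self.Y.shape
        logw = np.log(w)

        # starting values: a = 1, thresholds from observed cumulative proportions
        params = []
        for j in range(J):
            yj = self.Y[self.Y[:, j] > 0, j]
            b0 = np.empty(self.m[j] - 1)
            for k in range(2, self.m[j] + 1):
                p = np.clip(np.mean(yj >= k), 0.01, 0.99)
                b0[k - 2] = -np.log(p / (1 - p))
            b0 = np.sort(b0)
            b0 += np.linspace(0, 1e-3, len(b0))  # break exact ties
            params.append(_ab_to_ordered_params(1.0, b0))

        converged = False
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            ab = [_ordered_params_to_ab(p) for p in params]
            # E-step: posterior over nodes per person
            loglik = np.zeros((n, len(nodes)))
            tables = []
            for j, (a, b) in enumerate(ab):
                tab = _item_prob_table(a, b, nodes)
                tables.append(tab)
                yj = self.Y[:, j]
                obs = yj > 0
                loglik[obs] += np.log(tab)[:, yj[obs] - 1].T
            logpost = loglik + logw
            logpost -= logsumexp(logpost, axis=1, keepdims=True)
            post = np.exp(logpost)

            # expected counts r[q, k] per item, then per-item M-step
            max_change = 0.0
            for j in range(J):
                yj = self.Y[:, j]
                r = np.zeros((len(nodes), self.m[j]))
                for k in range(1, self.m[j] + 1):
                    sel = yj == k
                    if sel.any():
                        r[:, k - 1] = post[sel].sum(axis=0)

                def negq(p, r=r):
                    a, b = _ordered_params_to_ab(p)
                    return -(r * np.log(_item_prob_table(a, b, nodes))).sum()

                m_j = self.m[j]
                bounds = ([(np.log(0.05), np.log(a_max)), (-10.0, 10.0)]
                          + [(np.log(1e-3), np.log(20.0))] * (m_j - 2))
                res = minimize(negq, np.clip(params[j], [b[0] for b in bounds],
                                             [b[1] for b in bounds]),
                               method="L-BFGS-B", bounds=bounds,
                               options={"maxiter": 30, "ftol": 1e-12})
                a_old, b_old = _ordered_params_to_ab(params[j])
                a_new, b_new = _ordered_params_to_ab(res.x)
                max_change = max(max_change, abs(a_new - a_old),
                                 float(np.max(np.abs(b_new - b_old))))
                params[j] = res.x
            if max_change < tol:
                converged = True
                break

        if not converged:
            # EM can crawl along a boundary ridge (e.g. a discrimination at
            # its cap); finish with a direct quasi-Newton step on the
            # marginal likelihood under the same bounds
            params, converged = self._direct_polish(params, nodes, logw, a_max)
        if not converged:
            warnings.warn(
                f"GRM EM for scale {self.scale_id} did not converge in {max_iter} iterations",
                RuntimeWarning,
            )

        items = []
        boundary_items = []
        for j in range(J):
            a, b = _ordered_params_to_ab(params[j])
            if a >= 0.999 * a_max:
                boundary_items.append(self.item_ids[j])
            items.append(ItemParameters(self.item_ids[j], self.scale_id, int(self.m[j]),
                                        float(min(a, a_max)), tuple(b)))
        if boundary_items:
            warnings.warn(
                f"scale {self.scale_id}: discrimination at upper bound {a_max} "
                f"for item(s) {boundary_items}", RuntimeWarning)
        llf = self.loglike(items, n_nodes, bound)
        se = self._opg_se(items, nodes, logw) if compute_se else None
        res = GRMResults(self, items, llf, converged, n_iter, se,
                         n_nodes=n_nodes, bound=bound)
        res.boundary_items = boundary_items
        return res

    def _direct_polish(self, params, nodes, logw, a_max):
        n, J = self.Y.shape
        sizes = [len(p) for p in params]
        edges = np.concatenate([[0], np.cumsum(sizes)])
        x0 = np.concatenate(params)
        bounds = []
        for j in range(J):
            bounds += ([(np.log(0.05), np.log(a_max)), (-10.0, 10.0)]
                       + [(np.log(1e-3), np.log(20.0))] * (self.m[j] - 2))

        def nll(x):
            ll = np.zeros((n, len(nodes)))
            for j in range(J):
                a, b = _ordered_params_to_ab(x[edges[j]:edges[j + 1]])
                logp = np.log(_item_prob_table(a, b, nodes))
                yj = self.Y[:, j]
                obs = yj > 0
                ll[obs] += logp[:, yj[obs] - 1].T
            return -logsumexp(ll + logw, axis=1).sum()

        res = minimize(nll, np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds]),
                       method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": 300, "ftol": 1e-12})
        new = [res.x[edges[j]:edges[j + 1]] for j in range(J)]
        return new, bool(res.success)

    def _opg_se(self, items: list[ItemParameters], nodes, logw) -> dict[str, np.ndarray]:
        """Standard errors from the outer product of per-person scores
        (numerical derivatives of the marginal log-likelihood)."""
        theta_vec = []
        slices = []
        pos = 0
        for it in items:
            v = np.concatenate([[it.discrimination], it.thresholds])
            theta_vec.append(v)
            slices.append(slice(pos, pos + len(v)))
            pos += len(v)
        theta_vec = np.concatenate(theta_vec)

        def person_ll(vec):
            its = []
            for it, sl in zip(items, slices):
                v = vec[sl]
                its.append(ItemParameters(it.item_id, it.scale_id, it.n_categories,
                                          float(v[0]), tuple(v[1:])))
            return logsumexp(self._person_loglik_nodes(its, nodes) + logw, axis=1)

        G = np.empty((self.Y.shape[0], len(theta_vec)))
        h = 1e-5
        for k in range(len(theta_vec)):
            vp, vm = theta_vec.copy(), theta_vec.copy()
            vp[k] += h
            vm[k] -= h
            G[:, k] = (person_ll(vp) - person_ll(vm)) / (2 * h)
        info = G.T @ G
        try:
            cov = np.linalg.inv(info)
            ses = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            ses = np.full(len(theta_vec), np.nan)
        out = {}
        for it, sl in zip(items, slices):
            out[it.item_id] = ses[sl]
        return out


class GRMResults:
    """Fitted GRM for one scale: item parameters, log-likelihood, residual fit
    summary, EAP scoring and response-error computation."""

    def __init__(self, model, items, llf, converged, n_iter, se, n_nodes, bound):
        self.model = model
        self.items = items
        self.llf = float(llf)
        self.converged = bool(converged)
        self.n_iter = int(n_iter)
        self.se = se
        self.n_nodes = n_nodes
        self.bound = bound
        self.scale_id = model.scale_id
        self.reverse_coded = list(model.reverse_coded)
        self.category_maps = dict(model.category_maps)

    @property
    def params(self) -> pd.DataFrame:
        rows = []
        for it in self.items:
            row = {"item_id": it.item_id, "scale_id": it.scale_id,
                   "n_categories": it.n_categories, "a": it.discrimination}
            for k, b in enumerate(it.thresholds, 1):
                row[f"b{k}"] = b
            rows.append(row)
        return pd.DataFrame(rows).set_index("item_id")

    def eap_scores(self, responses: np.ndarray | None = None) -> pd.DataFrame:
        """EAP theta and posterior SD for each person (training data by
        default, already recoded/reverse-coded)."""
        Y = self.model.Y if responses is None else np.asarray(responses, dtype=int)
        keep = (Y > 0).any(axis=1)
        th = np.full(Y.shape[0], np.nan)
        sd = np.full(Y.shape[0], np.nan)
        if keep.any():
            th[keep], sd[keep] = eap_theta(Y[keep], self.items, self.n_nodes, self.bound)
        return pd.DataFrame(
            {"scale_id": self.scale_id, "theta_hat": th, "posterior_sd": sd},
            index=self.model.person_index if responses is None else None,
        )

    def error_scores(self, require_complete: bool = True) -> pd.DataFrame:
        """Long table of response-error scores (person, item, y, expected,
        error).  With ``require_complete`` (the default) only persons with no
        missing response on this scale are scored; everyone with at least one
        response still contributes a theta estimate."""
        Y = self.model.Y
        eap = self.eap_scores()
        theta = eap["theta_hat"].to_numpy()
        complete = (Y > 0).all(axis=1)
        rows = []
        for j, it in enumerate(self.items):
            scoreable = complete if require_complete else (Y[:, j] > 0)
            scoreable = scoreable & np.isfinite(theta)
            if not scoreable.any():
                continue
            th = theta[scoreable]
            y = Y[scoreable, j]
            e = expected_score(th, it)
            err = np.abs(y - e) / (it.n_categories - 1)
            rows.append(pd.DataFrame({
                "person_id": np.asarray(self.model.person_index)[scoreable],
                "scale_id": self.scale_id,
                "item_id": it.item_id,
                "y": y,
                "expected": e,
                "error": err,
            }))
        if not rows:
            return pd.DataFrame(columns=["person_id", "scale_id", "item_id", "y", "expected", "error"])
        return pd.concat(rows, ignore_index=True)

    def srmr(self) -> float:
        """SRMR-style residual summary: root-mean-square difference between
        observed and model-implied pairwise Pearson item-score correlations."""
        Y = self.model.Y
        J = len(self.items)
        if J < 2:
            return np.nan
        nodes, w = default_quadrature(self.n_nodes, self.bound)
        mu = np.empty(J)
        s2 = np.empty(J)
        ey_nodes = np.empty((J, len(nodes)))
        for j, it in enumerate(self.items):
            p = category_probabilities(nodes, it)
            k = np.arange(1, it.n_categories + 1)
            ey = p @ k
            ey2 = p @ k**2
            ey_nodes[j] = ey
            mu[j] = w @ ey
            s2[j] = w @ ey2 - mu[j] ** 2
        resid = []
        for j in range(J):
            for l in range(j + 1, J):
                implied = (w @ (ey_nodes[j] * ey_nodes[l]) - mu[j] * mu[l]) / np.sqrt(s2[j] * s2[l])
                both = (Y[:, j] > 0) & (Y[:, l] > 0)
                if both.sum() < 3:
                    continue
                obs = np.corrcoef(Y[both, j], Y[both, l])[0, 1]
                resid.append(obs - implied)
        return float(np.sqrt(np.mean(np.square(resid)))) if resid else np.nan

    def summary(self) -> str:
        lines = [
            f"Graded response model — scale {self.scale_id}",
            f"  persons: {self.model.Y.shape[0]}, items: {len(self.items)}",
            f"  log-likelihood: {self.llf:.4f}  (EM iterations: {self.n_iter}, "
            f"converged: {self.converged})",
            f"  SRMR-style residual correlation summary: {self.srmr():.4f}",
        ]
        if self.reverse_coded:
            lines.append(f"  reverse-coded items: {', '.join(self.reverse_coded)}")
        lines.append("")
        lines.append(self.params.round(3).to_string())
        return "\n".join(lines)


def score_all_scales(
    responses: pd.DataFrame,
    items: pd.DataFrame,
    n_nodes: int = 61,
    bound: float = 6.0,
    tol: float = 1e-4,
    max_iter: int = 500,
    compute_se: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Fit one GRM per scale (per wave) and compute response-error scores.

    Parameters
    ----------
    responses : long table with columns person_id, scale_id, item_id, response
        and optionally wave (missing responses simply absent or NaN)
    items : table with columns item_id, scale_id (defines scale membership)

    Returns
    -------
    (error_scores, thetas, fits) where ``error_scores`` has one row per scored
    person x item (persons are scored on a scale only if they answered every
    item of that scale — the complete-block rule; all available responses
    still inform the GRM fit and theta estimates), ``thetas`` holds the EAP
    estimates, and ``fits`` maps (wave, scale_id) to GRMResults.
    """
    responses = responses.copy()
    if "wave" not in responses.columns:
        responses["wave"] = 1
    item_scale = items.set_index(items["item_id"].astype(str))["scale_id"]
    dup = item_scale.index.duplicated()
    if dup.any():
        raise ValueError(f"items assigned to multiple scales: {list(item_scale.index[dup])}")
    # scale membership comes from the item table, not from the response rows
    responses["scale_id"] = responses["item_id"].astype(str).map(item_scale)
    if responses["scale_id"].isna().any():
        unknown = responses.loc[responses["scale_id"].isna(), "item_id"].unique()
        raise ValueError(f"responses reference items absent from the item table: "
                         f"{list(unknown)[:10]}")

    err_frames, theta_frames, fits = [], [], {}
    for (wave, scale), grp in responses.groupby(["wave", "scale_id"], sort=True):
        scale_items = items.loc[items["scale_id"] == scale, "item_id"].astype(str).tolist()
        if len(scale_items) < 2:
            raise ValueError(f"scale {scale} has fewer than 2 items")
        wide = grp.pivot_table(index="person_id", columns="item_id",
                               values="response", aggfunc="first")
        wide = wide.reindex(columns=scale_items)
        model = GradedResponseModel(wide, scale_id=str(scale))
        res = model.fit(n_nodes=n_nodes, bound=bound, tol=tol,
                        max_iter=max_iter, compute_se=compute_se)
        fits[(wave, str(scale))] = res
        err = res.error_scores(require_complete=True)
        err.insert(1, "wave", wave)
        err_frames.append(err)
        th = res.eap_scores().reset_index(names="person_id")
        th.insert(1, "wave", wave)
        theta_frames.append(th)

    error_scores = pd.concat(err_frames, ignore_index=True)
    thetas = pd.concat(theta_frames, ignore_index=True)
    return error_scores, thetas, fits
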