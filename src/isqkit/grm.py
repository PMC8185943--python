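"""Unidimensional graded response model: estimation, fit, and scoring.

Estimation is marginal maximum likelihood via the Bock-Aitkin EM
algorithm: the latent trait is fixed to N(0, 1) and integrated over a
fixed rectangular quadrature grid; M-steps solve each item's weighted
multinomial likelihood exactly with threshold ordering enforced through a
log-gap reparameterization.  Standard errors come from the empirical
cross-product (outer product of per-person Fisher-identity scores)
information matrix.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from scipy.special import logsumexp

from .data import ResponseMatrix
from .simulate import ItemParams, grm_category_probs, slope_to_loading


class ConvergenceError(RuntimeError):
    def __init__(self, msg, trace=None):
        super().__init__(msg)
        self.trace = trace


def default_quadrature(n_nodes: int = 61, bound: float = 6.0):
    """Equally spaced nodes with standard-normal weights, normalized."""
    nodes = np.linspace(-bound, bound, n_nodes)
    w = np.exp(-0.5 * nodes**2)
    return nodes, w / w.sum()


# -- parameter transforms ---------------------------------------------------

_LOG_GAP_MIN, _LOG_GAP_MAX = np.log(1e-4), np.log(12.0)


def _pack(a: float, b: np.ndarray) -> np.ndarray:
    gaps = np.diff(b)
    return np.concatenate([[np.log(a), b[0]], np.log(np.clip(gaps, 1e-4, None))])


def _unpack(z: np.ndarray) -> Tuple[float, np.ndarray]:
    a = float(np.exp(z[0]))
    b = z[1] + np.concatenate([[0.0], np.cumsum(np.exp(z[2:]))])
    return a, b


def _item_tables(a: float, b: np.ndarray, nodes: np.ndarray):
    """P*(X>=k+1) (Q, K-1) and category probs (Q, K) on the grid."""
    z = a * (nodes[:, None] - b[None, :])
    pstar = special.expit(z)
    Q = nodes.size
    cum = np.concatenate([np.ones((Q, 1)), pstar, np.zeros((Q, 1))], axis=1)
    return pstar, np.clip(-np.diff(cum, axis=1), 1e-300, None)


def _mstep_objective(z, r_table, nodes):
    """Negative expected complete-data log-likelihood and gradient for one
    item, in the (log a, b1, log-gaps) parameterization."""
    a, b = _unpack(z)
    pstar, P = _item_tables(a, b, nodes)
    Q, K = P.shape
    nll = -float(np.sum(r_table * np.log(P)))
    # gradient wrt (a, b): dP*_m/da = P*(1-P*)(theta - b_m); dP*_m/db_m = -a P*(1-P*)
    W = r_table / P                              # (Q, K)
    dW = W[:, :-1] - W[:, 1:]                    # coefficient of dP*_{m}
    s = pstar * (1.0 - pstar)                    # (Q, K-1)
    ga = float(np.sum(dW * s * (nodes[:, None] - b[None, :])))
    gb = -float(a) * np.sum(dW * s, axis=0)      # (K-1,)
    # chain rule into z
    g = np.empty_like(z)
    g[0] = ga * a
    g[1] = gb.sum()
    gaps = np.exp(z[2:])
    for m in range(gaps.size):
        g[2 + m] = gb[m + 1:].sum() * gaps[m]
    return nll, g


class GradedResponseModel:
    """Marginal-maximum-likelihood GRM for a response matrix.

    Parameters
    ----------
    X : ResponseMatrix
    n_quad, quad_bound : quadrature specification (rectangular nodes with
        normal weights on [-quad_bound, quad_bound]).
    """

    def __init__(self, X: ResponseMatrix, n_quad: int = 61,
                 quad_bound: float = 6.0):
        self.X = X
        self.nodes, self.weights = default_quadrature(n_quad, quad_bound)
        for iid in X.item_ids:
            if np.sum(X.category_counts(iid) > 0) < 2:
                raise ValueError(f"item {iid} has < 2 observed categories")
        if X.n < 100:
            warnings.warn(f"n = {X.n} < 100; GRM estimates will be unstable")
        self.codes = np.where(np.isnan(X.values), 0, X.values - 1).astype(int)
        self.obs = ~np.isnan(X.values)

    def _start_values(self) -> List[ItemParams]:
        items = []
        K = self.X.n_categories
        for iid in self.X.item_ids:
            counts = np.maximum(self.X.category_counts(iid), 0.5)
            cum = np.cumsum(counts)[:-1] / counts.sum()
            b = np.clip(stats.norm.ppf(cum), -3.5, 3.5) * 1.7
            b = np.maximum.accumulate(b + np.arange(K - 1) * 1e-3)
            for k in range(1, b.size):
                b[k] = max(b[k], b[k - 1] + 1e-3)
            items.append(ItemParams(iid, 1.5, b))
        return items

    def loglik(self, items: Sequence[ItemParams]) -> float:
        ll = self._person_log_post(items)[1]
        return float(ll.sum())

    def _person_log_post(self, items):
        """(n, Q) posterior log-weights (unnormalized) and per-person
        log marginal likelihood."""
        n, Q = self.X.n, self.nodes.size
        acc = np.tile(np.log(self.weights), (n, 1))
        for j, it in enumerate(items):
            _, P = _item_tables(it.slope, it.thresholds, self.nodes)
            logP = np.log(P)                       # (Q, K)
            contrib = logP[:, self.codes[:, j]].T  # (n, Q)
            acc += np.where(self.obs[:, [j]], contrib, 0.0)
        return acc, logsumexp(acc, axis=1)

    def fit(self, start: Optional[Sequence[ItemParams]] = None,
            tol: float = 1e-4, maxiter: int = 1000) -> "GRMResults":
        items = list(start) if start is not None else self._start_values()
        zs = [_pack(it.slope, it.thresholds) for it in items]
        last_ll = -np.inf
        ll_trace = []
        bounds0 = [(np.log(0.01), np.log(50.0)), (-12.0, 12.0)]
        for it_num in range(maxiter):
            acc, ll_i = self._person_log_post(items)
            ll = float(ll_i.sum())
            ll_trace.append(ll)
            if ll < last_ll - 1e-6 * abs(last_ll):
                raise ConvergenceError("EM log-likelihood decreased", ll_trace)
            post = np.exp(acc - ll_i[:, None])     # (n, Q)
            max_delta = 0.0
            for j in range(self.X.p):
                # expected counts: r[q, k] = sum_i post[i, q] * 1{x_ij = k}
                r = np.zeros((self.nodes.size, self.X.n_categories))
                m = self.obs[:, j]
                pm = post[m]
                cj = self.codes[m, j]
                for k in range(self.X.n_categories):
                    sel = cj == k
                    if sel.any():
                        r[:, k] = pm[sel].sum(axis=0)
                nb = bounds0 + [(_LOG_GAP_MIN, _LOG_GAP_MAX)] * (len(zs[j]) - 2)
                # normalize so the M-step is invariant to replication weight
                r = r / max(r.sum(), 1e-300)
                res = optimize.minimize(_mstep_objective, zs[j],
                                        args=(r, self.nodes), jac=True,
                                        method="L-BFGS-B", bounds=nb,
                                        options={"maxiter": 50})
                a_new, b_new = _unpack(res.x)
                old = np.concatenate([[items[j].slope], items[j].thresholds])
                new = np.concatenate([[a_new], b_new])
                max_delta = max(max_delta, float(np.max(np.abs(new - old))))
                items[j] = ItemParams(items[j].item_id, a_new, b_new)
                zs[j] = res.x
            # stop on parameter stability, or on a stalled log-likelihood
            # (flat directions, e.g. a weakly identified slope)
            if it_num > 0 and (max_delta < tol
                               or abs(ll - last_ll) < 1e-7 * (1 + abs(ll) * 1e-4)):
                final_ll = self.loglik(items)
                return GRMResults(self, items, final_ll, it_num + 1,
                                  ll_trace, converged=True)
            last_ll = ll
        raise ConvergenceError(
            f"EM did not converge in {maxiter} iterations", ll_trace)


def _score_matrix(model: GradedResponseModel, items: Sequence[ItemParams]):
    """Per-person Fisher-identity scores for all item parameters.

    Returns (S, names): S is (n, sum_j K_j) with K_j = 1 + (K-1) params
    per item in (a_j, b_j1..b_j,K-1) order.
    """
    acc, ll_i = model._person_log_post(items)
    post = np.exp(acc - ll_i[:, None])
    cols, names = [], []
    for j, it in enumerate(items):
        pstar, P = _item_tables(it.slope, it.thresholds, model.nodes)
        s = pstar * (1.0 - pstar)
        Q, K = P.shape
        dPda = np.zeros((Q, K))
        tmb = model.nodes[:, None] - it.thresholds[None, :]
        dPda[:, :-1] += s * tmb
        dPda[:, 1:] -= s * tmb
        dlda = dPda / P
        dPdb = np.zeros((Q, K, K - 1))
        for mth in range(K - 1):
            dPdb[:, mth, mth] += -it.slope * s[:, mth]
            dPdb[:, mth + 1, mth] += it.slope * s[:, mth]
        dldb = dPdb / P[:, :, None]
        m = model.obs[:, j]
        cj = model.codes[:, j]
        sc_a = np.zeros(model.X.n)
        sc_b = np.zeros((model.X.n, K - 1))
        sc_a[m] = np.sum(post[m] * dlda[:, cj[m]].T, axis=1)
        for mth in range(K - 1):
            sc_b[m, mth] = np.sum(post[m] * dldb[:, cj[m], mth].T, axis=1)
        cols.append(sc_a[:, None])
        cols.append(sc_b)
        names += [f"{it.item_id}:a"] + [f"{it.item_id}:b{k+1}" for k in range(K - 1)]
    return np.hstack(cols), names


@dataclass
class GRMResults:
    """Fitted graded response model."""

    model: GradedResponseModel
    item_params: List[ItemParams]
    loglik: float
    n_iter: int
    ll_trace: List[float]
    converged: bool = True

    # -- parameter access -------------------------------------------------
    @property
    def item_ids(self) -> List[str]:
        return [it.item_id for it in self.item_params]

    def params_table(self, standard_errors: bool = True) -> pd.DataFrame:
        K = self.model.X.n_categories
        rows = []
        se = self.standard_errors() if standard_errors else None
        for it in self.item_params:
            row = {"item": it.item_id, "slope": it.slope,
                   "loading": slope_to_loading(it.slope)}
            for k, b in enumerate(it.thresholds, start=1):
                row[f"b{k}"] = b
            if se is not None:
                row["se_slope"] = se.get(f"{it.item_id}:a", np.nan)
                for k in range(1, K):
                    row[f"se_b{k}"] = se.get(f"{it.item_id}:b{k}", np.nan)
            rows.append(row)
        return pd.DataFrame(rows).set_index("item")

    def standard_errors(self) -> dict:
        S, names = _score_matrix(self.model, self.item_params)
        info = S.T @ S
        try:
            cov = np.linalg.pinv(info)
        except np.linalg.LinAlgError:
            return {nm: float("nan") for nm in names}
        return dict(zip(names, np.sqrt(np.maximum(np.diag(cov), 0.0))))

    # -- EAP scoring ------------------------------------------------------
    def eap_score(self, pattern) -> dict:
        """EAP latent trait for one response pattern (NaN = missing)."""
        pattern = np.asarray(pattern, dtype=float)
        if pattern.size != len(self.item_params):
            raise ValueError("pattern length does not match item count")
        nodes, w = self.model.nodes, self.model.weights
        logpost = np.log(w).copy()
        any_obs = False
        for j, it in enumerate(self.item_params):
            if np.isnan(pattern[j]):
                continue
            k = int(pattern[j]) - 1
            if not 0 <= k < it.n_categories:
                raise ValueError(f"response {pattern[j]} out of range for "
                                 f"{it.item_id}")
            _, P = _item_tables(it.slope, it.thresholds, nodes)
            logpost += np.log(P[:, k])
            any_obs = True
        post = np.exp(logpost - logsumexp(logpost))
        post /= post.sum()
        theta = float(np.sum(post * nodes))
        psd = float(np.sqrt(max(np.sum(post * nodes**2) - theta**2, 1e-12)))
        return {"theta": theta, "psd": psd,
                "reliability": 1.0 - psd**2,
                "t_score": 50.0 + 10.0 * theta,
                "no_information": not any_obs}

    def eap_scores(self, X: Optional[ResponseMatrix] = None) -> pd.DataFrame:
        """EAP scores for every person (vectorized over the sample)."""
        X = X if X is not None else self.model.X
        idx = [X.item_ids.index(i) for i in self.item_ids]
        vals = X.values[:, idx]
        nodes, w = self.model.nodes, self.model.weights
        codes = np.where(np.isnan(vals), 0, vals - 1).astype(int)
        obs = ~np.isnan(vals)
        acc = np.tile(np.log(w), (X.n, 1))
        for j, it in enumerate(self.item_params):
            _, P = _item_tables(it.slope, it.thresholds, nodes)
            logP = np.log(P)
            acc += np.where(obs[:, [j]], logP[:, codes[:, j]].T, 0.0)
        post = np.exp(acc - logsumexp(acc, axis=1)[:, None])
        post /= post.sum(axis=1, keepdims=True)
        theta = post @ nodes
        psd = np.sqrt(np.maximum(post @ nodes**2 - theta**2, 1e-12))
        return pd.DataFrame({
            "theta": theta, "psd": psd, "reliability": 1.0 - psd**2,
            "t_score": 50.0 + 10.0 * theta,
            "n_answered": obs.sum(axis=1),
        }, index=pd.Index(X.person_ids, name="person_id"))

    # -- reliability ------------------------------------------------------
    def marginal_reliability(self, X: Optional[ResponseMatrix] = None,
                             n_boot: int = 1000, seed: int = 0):
        """Empirical marginal reliability var(theta)/(var(theta)+mean(PSD^2))
        with a percentile bootstrap CI over persons (scores fixed)."""
        scores = self.eap_scores(X)
        if len(scores) < 50:
            raise ValueError("need scores for >= 50 persons")
        th, ps2 = scores["theta"].to_numpy(), scores["psd"].to_numpy() ** 2
        if np.var(th) < 1e-12:
            raise ValueError("degenerate score variance")

        def rho(t, p2):
            v = np.var(t)
            return v / (v + np.mean(p2))

        rng = np.random.default_rng(seed)
        reps = np.empty(n_boot)
        for b in range(n_boot):
            idx = rng.integers(0, th.size, th.size)
            reps[b] = rho(th[idx], ps2[idx])
        return MarginalReliability(float(rho(th, ps2)),
                                   (float(np.quantile(reps, 0.025)),
                                    float(np.quantile(reps, 0.975))), n_boot)

    # -- curves -----------------------------------------------------------
    def item_curves(self, grid: Optional[np.ndarray] = None) -> pd.DataFrame:
        """Category characteristic curves and item information on a grid."""
        grid = np.linspace(-4, 4, 161) if grid is None else np.asarray(grid)
        frames = []
        for it in self.item_params:
            P = grm_category_probs(grid, it)
            pstar = 1.0 / (1.0 + np.exp(-it.slope * (grid[:, None] - it.thresholds)))
            s = pstar * (1.0 - pstar)
            dP = np.zeros_like(P)
            dP[:, :-1] += it.slope * s
            dP[:, 1:] -= it.slope * s
            info = np.sum(dP**2 / P, axis=1)
            df = pd.DataFrame(P, columns=[f"P{k+1}" for k in range(P.shape[1])])
            df.insert(0, "theta", grid)
            df.insert(1, "item", it.item_id)
            df["information"] = info
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def total_information(self, grid: np.ndarray) -> np.ndarray:
        curves = self.item_curves(grid)
        return curves.groupby("theta")["information"].sum().to_numpy()

    # -- limited-information fit ------------------------------------------
    def c2(self, X: Optional[ResponseMatrix] = None) -> "GrmFitStats":
        return c2_fit(self, X if X is not None else self.model.X)

    def ld_chi2(self, X: Optional[ResponseMatrix] = None,
                flag_threshold: float = 10.0) -> "LdMatrix":
        return ld_chi2(self, X if X is not None else self.model.X,
                       flag_threshold)

    # -- persistence ------------------------------------------------------
    def to_calibration(self, collapse_map: Optional[dict] = None,
                       metadata: Optional[dict] = None) -> dict:
        return {
            "items": [it.to_dict() for it in self.item_params],
            "quadrature": {"n_nodes": int(self.model.nodes.size),
                           "bound": float(self.model.nodes.max())},
            "collapse_map": collapse_map,
            "metadata": metadata or {},
        }

    def save_calibration(self, path, collapse_map=None, metadata=None) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_calibration(collapse_map, metadata), fh, indent=1)

    def summary(self) -> str:
        lines = [f"Graded response model (Bock-Aitkin EM), n = {self.model.X.n}, "
                 f"items = {len(self.item_params)}",
                 f"  log-likelihood = {self.loglik:.2f}, "
                 f"EM iterations = {self.n_iter}", "",
                 self.params_table(standard_errors=False).round(3).to_string()]
        return "\n".join(lines)


@dataclass
class MarginalReliability:
    rho: float
    ci: tuple
    n_boot: int

    def __repr__(self):
        return (f"MarginalReliability(rho={self.rho:.3f}, "
                f"95% CI [{self.ci[0]:.3f}, {self.ci[1]:.3f}])")


# -- C2 limited-information fit --------------------------------------------

@dataclass
class GrmFitStats:
    statistic: float
    df: int
    pvalue: float
    rmsea: float
    cfi: float
    srmr: float

    def __repr__(self):
        return (f"C2({self.df}) = {self.statistic:.1f}, p = {self.pvalue:.3g}, "
                f"CFI_C2 = {self.cfi:.3f}, RMSEA_C2 = {self.rmsea:.3f}, "
                f"SRMR = {self.srmr:.3f}")


def _implied_stats(items: Sequence[ItemParams], nodes, w):
    """Implied univariate category probabilities (cats 1..K-1 per item) and
    pairwise cross-moments E[X_j X_k] under conditional independence."""
    p = len(items)
    probs, mus = [], []
    for it in items:
        _, P = _item_tables(it.slope, it.thresholds, nodes)
        marg = w @ P
        probs.append(marg[:-1])
        k = np.arange(1, P.shape[1] + 1)
        mus.append(P @ k)            # E[X_j | theta_q]
    cross = [float(np.sum(w * mus[i] * mus[j]))
             for i, j in combinations(range(p), 2)]
    return np.concatenate(probs + [np.array(cross)])


def c2_fit(results: GRMResults, X: ResponseMatrix) -> GrmFitStats:
    """Limited-information fit from univariate margins and bivariate
    first/second moments (Browne residual-based quadratic form).

    df = p(p-1)/2 - p: the univariate margins saturate the thresholds and
    the p(p-1)/2 cross-moments test the p slopes.
    """
    items = results.item_params
    p = len(items)
    K = X.n_categories
    complete = ~np.any(np.isnan(X.values), axis=1)
    vals = X.values[complete].astype(int)
    n = vals.shape[0]
    pairs = list(combinations(range(p), 2))

    # observed per-person statistic vectors
    Z = np.empty((n, p * (K - 1) + len(pairs)))
    col = 0
    for j in range(p):
        for k in range(1, K):
            Z[:, col] = (vals[:, j] == k).astype(float)
            col += 1
    for i, j in pairs:
        Z[:, col] = vals[:, i] * vals[:, j]
        col += 1
    zbar = Z.mean(axis=0)
    Xi = np.cov(Z, rowvar=False)

    nodes, w = results.model.nodes, results.model.weights
    m_hat = _implied_stats(items, nodes, w)
    e = zbar - m_hat

    # Jacobian wrt (a_j, b_j.) by central differences, item-blocked
    q = p * K
    Delta = np.zeros((zbar.size, q))
    h = 1e-5
    for j in range(p):
        base = items[j]
        theta0 = np.concatenate([[base.slope], base.thresholds])
        for t in range(K):
            for sgn, store in ((1.0, 0), (-1.0, 1)):
                th = theta0.copy()
                th[t] += sgn * h
                pert = list(items)
                pert[j] = ItemParams(base.item_id, th[0],
                                     np.maximum.accumulate(th[1:]) +
                                     np.arange(K - 1) * 1e-12)
                if store == 0:
                    up = _implied_stats(pert, nodes, w)
                else:
                    dn = _implied_stats(pert, nodes, w)
            Delta[:, j * K + t] = (up - dn) / (2 * h)

    C2 = _browne_statistic(e, Xi, Delta, n)
    df = p * (p - 1) // 2 - p
    pval = float(stats.chi2.sf(C2, df))
    rmsea = float(np.sqrt(max(C2 - df, 0.0) / (df * n)))

    # independence baseline on the same statistics
    e_b, Delta_b = _baseline_stats(zbar, p, K, pairs)
    C2_b = _browne_statistic(e_b, Xi, Delta_b, n)
    df_b = len(pairs)
    cfi = 1.0 - max(C2 - df, 0.0) / max(C2_b - df_b, 1e-12)

    # SRMR: observed polychoric vs slope-implied loading products
    from .polychoric import polychoric_matrix
    Rp = polychoric_matrix(X.select_items([it.item_id for it in items]))
    lam = slope_to_loading(np.array([it.slope for it in items]))
    resid = [Rp.rho[i, j] - lam[i] * lam[j] for i, j in pairs]
    srmr = float(np.sqrt(np.mean(np.square(resid))))
    return GrmFitStats(float(C2), df, pval, rmsea, min(cfi, 1.0), srmr)


def _browne_statistic(e, Xi, Delta, n):
    s = e.size
    ridge = 1e-10 * np.trace(Xi) / s
    Xi_r = Xi + ridge * np.eye(s)
    try:
        Xi_inv_e = np.linalg.solve(Xi_r, e)
        Xi_inv_D = np.linalg.solve(Xi_r, Delta)
    except np.linalg.LinAlgError:
        warnings.warn("singular moment covariance; heavier ridge applied")
        Xi_r = Xi + 1e-6 * np.trace(Xi) / s * np.eye(s)
        Xi_inv_e = np.linalg.solve(Xi_r, e)
        Xi_inv_D = np.linalg.solve(Xi_r, Delta)
    H = Delta.T @ Xi_inv_D
    middle = Xi_inv_e - Xi_inv_D @ np.linalg.lstsq(H, Delta.T @ Xi_inv_e,
                                                   rcond=None)[0]
    return float(n * e @ middle)


def _baseline_stats(zbar, p, K, pairs):
    """Residuals and Jacobian of the independence model, whose parameters
    are the free univariate category probabilities."""
    s = p * (K - 1) + len(pairs)
    pi = zbar[:p * (K - 1)].reshape(p, K - 1)
    mu = K - pi @ (K - np.arange(1, K))
    e = np.zeros(s)
    for m, (i, j) in enumerate(pairs):
        e[p * (K - 1) + m] = zbar[p * (K - 1) + m] - mu[i] * mu[j]
    Delta = np.zeros((s, p * (K - 1)))
    Delta[:p * (K - 1), :] = np.eye(p * (K - 1))
    dmu = np.arange(1, K) - K  # d mu_j / d pi_jc = c - K
    for m, (i, j) in enumerate(pairs):
        row = p * (K - 1) + m
        Delta[row, i * (K - 1):(i + 1) * (K - 1)] = dmu * mu[j]
        Delta[row, j * (K - 1):(j + 1) * (K - 1)] = dmu * mu[i]
    return e, Delta


# -- local dependence -------------------------------------------------------

@dataclass
class LdMatrix:
    """Standardized LD chi-square values per item pair (symmetric storage)."""

    values: np.ndarray
    item_ids: List[str]
    flag_threshold: float = 10.0
    notes: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.item_ids,
                            columns=self.item_ids)

    def flagged_pairs(self) -> List[tuple]:
        out = []
        p = len(self.item_ids)
        for i in range(p):
            for j in range(i + 1, p):
                if self.values[i, j] > self.flag_threshold:
                    out.append((self.item_ids[i], self.item_ids[j],
                                float(self.values[i, j])))
        return out

    def max_pair(self) -> tuple:
        p = len(self.item_ids)
        best = (None, None, -np.inf)
        for i in range(p):
            for j in range(i + 1, p):
                if self.values[i, j] > best[2]:
                    best = (self.item_ids[i], self.item_ids[j],
                            float(self.values[i, j]))
        return best


def _pool_table(obs: np.ndarray, exp: np.ndarray, min_expected: float = 1.0):
    """Collapse rows/columns with tiny expected counts into neighbours."""
    pooled = False
    while exp.shape[0] > 2 and exp.min(initial=np.inf) < min_expected:
        margins = exp.sum(axis=1)
        r = int(np.argmin(margins))
        t = r - 1 if r == exp.shape[0] - 1 else r + 1
        lo, hi = min(r, t), max(r, t)
        obs = np.vstack([obs[:lo], obs[lo] + obs[hi], obs[hi + 1:]])
        exp = np.vstack([exp[:lo], exp[lo] + exp[hi], exp[hi + 1:]])
        pooled = True
        if exp.min() >= min_expected:
            break
        obs, exp = obs.T, exp.T  # alternate axes
    return obs, exp, pooled


def ld_chi2(results: GRMResults, X: ResponseMatrix,
            flag_threshold: float = 10.0) -> LdMatrix:
    """Chen-Thissen standardized local-dependence chi-square for each pair.

    Observed bivariate tables are compared to model-expected tables
    (integrated over the trait posterior-free quadrature); the Pearson
    statistic is standardized as (X2 - df) / sqrt(2 df).  Cells with
    expected counts below 1 are pooled with neighbours (noted per pair).
    """
    items = results.item_params
    p = len(items)
    nodes, w = results.model.nodes, results.model.weights
    Ps = []
    for it in items:
        _, P = _item_tables(it.slope, it.thresholds, nodes)
        Ps.append(P)
    out = np.full((p, p), np.nan)
    notes = {}
    idx = [X.item_ids.index(i) for i in [it.item_id for it in items]]
    vals = X.values[:, idx]
    for i, j in combinations(range(p), 2):
        keep = ~(np.isnan(vals[:, i]) | np.isnan(vals[:, j]))
        xi = vals[keep, i].astype(int) - 1
        xj = vals[keep, j].astype(int) - 1
        n_pair = keep.sum()
        Ki, Kj = Ps[i].shape[1], Ps[j].shape[1]
        obs = np.zeros((Ki, Kj))
        np.add.at(obs, (xi, xj), 1.0)
        joint = np.einsum("q,qk,ql->kl", w, Ps[i], Ps[j])
        exp = n_pair * joint / joint.sum()
        obs_p, exp_p, pooled = _pool_table(obs, exp)
        if pooled:
            notes[(items[i].item_id, items[j].item_id)] = "cells pooled"
        x2 = float(np.sum((obs_p - exp_p) ** 2 / exp_p))
        df = (obs_p.shape[0] - 1) * (obs_p.shape[1] - 1)
        z = (x2 - df) / np.sqrt(2.0 * df)
        out[i, j] = out[j, i] = z
    return LdMatrix(out, [it.item_id for it in items], flag_threshold, notes)


def load_calibration(path_or_dict) -> GRMResults:
    """Rebuild a scoring-capable GRMResults from a calibration artifact.

    The returned object scores new data; it carries no fitted sample.
    """
    if isinstance(path_or_dict, dict):
        cal = path_or_dict
    else:
        with open(path_or_dict) as fh:
            cal = json.load(fh)
    items = [ItemParams.from_dict(d) for d in cal["items"]]
    qspec = cal.get("quadrature", {"n_nodes": 61, "bound": 6.0})
    # minimal placeholder sample so the model object can be constructed
    K = items[0].n_categories
    dummy = ResponseMatrix(
        np.tile(np.arange(1, K + 1)[:, None], (1, len(items))).astype(float),
        [it.item_id for it in items], n_categories=K)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = GradedResponseModel(dummy, n_quad=qspec["n_nodes"],
                                    quad_bound=qspec["bound"])
    res = GRMResults(model, items, float("nan"), 0, [], converged=True)
    res.collapse_map = cal.get("collapse_map")
    res.metadata = cal.get("metadata", {})
    return res
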